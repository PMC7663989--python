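"""Synthetic lakescapes with known ground truth.

Real trawl catches and habitat rasters for western Lake Erie are
agency-held, so every downstream stage is exercised against a simulated
study unit instead: spatially autocorrelated habitat fields with the
published summary statistics, an Aquatic Habitat Area (AHA) partition
built from position/depth/fetch similarity, a known cellwise "true"
suitability surface, and overdispersed trawl catches drawn from it.

The defaults describe the study system: ten anthropogenically resistant
habitat variables (plus the nine disturbance variables: four temperature
metrics and five shoreline-modification percentages) with the published
basin means, 2,066 tows, and a suitability surface calibrated so that
about 10% of the lake is Optimal and 17% Unsuitable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.vq import kmeans2
from scipy.optimize import brentq

from .abundance import classify_abundance
from .grid import HabitatStack, ZoneMap

__all__ = [
    "LakescapeConfig",
    "TrueSuitability",
    "POTENTIAL_VARIABLES",
    "DISTURBANCE_EXTRA_VARIABLES",
    "generate_habitat_stack",
    "generate_true_suitability",
    "generate_zones",
    "simulate_trawls",
    "generate_lakescape",
]

# Published basin-wide means of the ten anthropogenically resistant
# habitat variables (variable code -> mean).
_POTENTIAL_MEANS = {
    "GLSAV": 0.094869,          # fraction of bottom with >= 50% SAV cover
    "ShoreNear_C04": 34.23136,  # % erosion-resistant bedrock shoreline
    "ShoreGeom_C09": 17.59342,  # % baymouth-barrier beaches
    "GLWetProtDist": 9989.768,  # m to nearest protected-type wetland
    "GLWetDeltaDist": 16332.54, # m to nearest delta-type wetland
    "GLWetOpenDist": 24348.54,  # m to nearest open-type wetland
    "GLBath90m": -8.0485,       # depth (m, negative down)
    "GLRivDens": 169.8925,      # major-river density (km^-2 x 10^6)
    "GLRivDist": 19072.66,      # m to nearest major river
    "GLFetch": 21895.14,        # effective fetch (m)
}
# Disturbance-model additions: monthly surface temperature summaries and
# shoreline-modification class percentages.
_DISTURBANCE_MEANS = {
    "sst_May": 13.24,
    "sst_Sep": 21.74,
    "cv_Aug": 0.055,
    "cv_Sep": 0.081,
    "SM_1": 20.03,
    "SM_2": 10.25,
    "SM_3": 39.02,
    "SM_4": 30.25,
    "SM_5": 0.43,
}
POTENTIAL_VARIABLES = list(_POTENTIAL_MEANS)
DISTURBANCE_EXTRA_VARIABLES = list(_DISTURBANCE_MEANS)

# Field standard deviations are not published; defaults are plausible
# spatial-heterogeneity levels for the western basin (roughly half the
# mean magnitude for distances/percentages, 3 m for depth).
_DEFAULT_SDS = {
    "GLSAV": 0.12, "ShoreNear_C04": 20.0, "ShoreGeom_C09": 12.0,
    "GLWetProtDist": 5000.0, "GLWetDeltaDist": 8000.0, "GLWetOpenDist": 10000.0,
    "GLBath90m": 3.0, "GLRivDens": 70.0, "GLRivDist": 9000.0, "GLFetch": 9000.0,
    "sst_May": 1.2, "sst_Sep": 1.0, "cv_Aug": 0.02, "cv_Sep": 0.025,
    "SM_1": 12.0, "SM_2": 7.0, "SM_3": 15.0, "SM_4": 15.0, "SM_5": 0.4,
}

# Signed influence of each variable on the true suitability surface, on
# z-scored fields.  Signs and relative magnitudes follow the published
# connection-weight importances of the benchmark model: suitability rises
# with distance to protected wetlands and large rivers and with fetch
# score, falls steeply with distance to delta wetlands and river density.
_TRUE_WEIGHTS = {
    "GLSAV": -1.029, "ShoreNear_C04": -0.962, "ShoreGeom_C09": -0.770,
    "GLWetProtDist": 5.337, "GLWetDeltaDist": -9.652, "GLWetOpenDist": -0.706,
    "GLBath90m": 0.194, "GLRivDens": -2.585, "GLRivDist": 3.705,
    "GLFetch": 5.467,
}


@dataclass
class LakescapeConfig:
    """Stated world for one synthetic study unit.

    The default grid is 200 x 300 cells of 90 m (~486 km^2 of lake after
    masking, the right order for a single lake unit at test scale), with
    2,066 tows of ~3,125 m^2 swept each (the area implied by the study's
    smallest positive CPUE of 0.32 fish/1,000 m^2 from one fish).
    """

    grid_rows: int = 200
    grid_cols: int = 300
    cell_size_m: float = 90.0
    variable_names: list[str] = field(
        default_factory=lambda: list(_POTENTIAL_MEANS))
    variable_means: dict[str, float] | None = None
    variable_sds: dict[str, float] | None = None
    autocorrelation_range_cells: float = 10.0
    n_aha: int = 300
    true_weights: dict[str, float] | None = None
    optimal_fraction: float = 0.103   # target class-area shares used to
    unsuitable_fraction: float = 0.171  # calibrate the suitability link
    noise_dispersion: float = 0.10    # negative-binomial size parameter,
    # Monte-Carlo calibrated once so the positive-tow fraction under the
    # default truth matches the study's 676/2,066 collections
    n_tows: int = 2066
    mean_area_swept_m2: float = 3125.0
    lake_mask: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if len(self.variable_names) < 2:
            raise ValueError("need at least two habitat variables")
        if self.n_tows < 1:
            raise ValueError("n_tows must be >= 1")
        means = dict(_POTENTIAL_MEANS) | dict(_DISTURBANCE_MEANS)
        sds = dict(_DEFAULT_SDS)
        if self.variable_means:
            means |= self.variable_means
        if self.variable_sds:
            sds |= self.variable_sds
        self.variable_means = {n: means.get(n, 0.0) for n in self.variable_names}
        self.variable_sds = {n: sds.get(n, 1.0) for n in self.variable_names}
        if any(s <= 0 for s in self.variable_sds.values()):
            raise ValueError("all variable sds must be positive")
        if self.true_weights is None:
            self.true_weights = {n: _TRUE_WEIGHTS.get(n, 0.0)
                                 for n in self.variable_names}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrueSuitability:
    """Ground truth: expected density (fish/1,000 m^2) and class per cell."""

    density: np.ndarray
    true_class: np.ndarray
    nodata_mask: np.ndarray

    def __post_init__(self):
        ok = ~self.nodata_mask
        derived = classify_abundance(self.density[ok])
        if not np.array_equal(derived, self.true_class[ok]):
            raise ValueError("true_class inconsistent with density")


def _lake_outline(rows: int, cols: int) -> np.ndarray:
    """Elliptical lake: True outside the water (nodata)."""
    r = (np.arange(rows)[:, None] - (rows - 1) / 2) / (rows / 2)
    c = (np.arange(cols)[None, :] - (cols - 1) / 2) / (cols / 2)
    return r**2 + c**2 > 0.98


def _smooth_field(rng: np.random.Generator, shape, range_cells: float) -> np.ndarray:
    """Spatially autocorrelated standard field: box-smoothed white noise,
    re-standardized to zero mean / unit sd over the grid."""
    noise = rng.standard_normal(shape)
    if range_cells > 0:
        size = 2 * int(round(range_cells)) + 1
        noise = ndimage.uniform_filter(noise, size=size, mode="reflect")
    noise -= noise.mean()
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def generate_habitat_stack(config: LakescapeConfig) -> HabitatStack:
    """Simulate one habitat raster per variable.

    Each field is box-kernel-smoothed white noise (autocorrelation range in
    cells set by the config) affinely rescaled so its over-water sample
    mean and sd equal the configured targets exactly; deterministic given
    the seed.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    mask = _lake_outline(*shape) if config.lake_mask else np.zeros(shape, bool)
    fields = []
    for name in config.variable_names:
        z = _smooth_field(rng, shape, config.autocorrelation_range_cells)
        valid = z[~mask]
        z = (z - valid.mean()) / valid.std()
        fields.append(config.variable_means[name]
                      + config.variable_sds[name] * z)
    data = np.stack(fields)
    data[:, mask] = np.nan
    return HabitatStack(data, list(config.variable_names),
                        config.cell_size_m, (0.0, config.grid_rows * config.cell_size_m))


def _softplus(x):
    return np.logaddexp(0.0, x)


def generate_true_suitability(stack: HabitatStack,
                              true_weights: dict[str, float],
                              optimal_fraction: float = 0.103,
                              unsuitable_fraction: float = 0.171) -> TrueSuitability:
    """Known suitability surface: density = s * softplus(score - b).

    ``score`` is the weighted sum of z-scored habitat fields. The two link
    constants (shift ``b``, scale ``s``) are calibrated by quantile
    matching so that the Optimal class (density >= 10.5) covers
    ``optimal_fraction`` of the lake and the Unsuitable class (density
    < 0.5) covers ``unsuitable_fraction`` — the class-area shares of the
    benchmark prediction map. The link is monotone, smooth and
    non-negative, so the class surface inherits the spatial structure of
    the habitat fields.
    """
    if set(true_weights) - set(stack.names):
        raise KeyError("true_weights refer to variables not in the stack")
    valid = ~stack.nodata_mask
    score = np.zeros(stack.shape)
    for name, w in true_weights.items():
        if w == 0:
            continue
        band = stack.variable(name)
        mu, sd = band[valid].mean(), band[valid].std()
        score += w * (band - mu) / sd
    score[~valid] = np.nan
    vals = score[valid]

    if np.allclose(vals.std(), 0):
        # constant score (e.g. all weights zero): flat density field
        density = np.full(stack.shape, np.nan)
        density[valid] = _softplus(vals)
        cls = np.full(stack.shape, -1, dtype=np.int8)
        cls[valid] = classify_abundance(density[valid])
        return TrueSuitability(density, cls, ~valid)

    q_hi = np.quantile(vals, 1.0 - optimal_fraction)
    q_lo = np.quantile(vals, unsuitable_fraction)
    ratio = 10.5 / 0.5

    def f(b):
        return _softplus(q_hi - b) / _softplus(q_lo - b) - ratio

    lo, hi = q_lo - 50 * vals.std(), q_hi + 50 * vals.std()
    if f(hi) < 0:
        raise ValueError(
            "score spread too small to separate Optimal from Unsuitable; "
            "increase the magnitude of true_weights")
    b = brentq(f, lo, hi, xtol=1e-10)
    s = 10.5 / _softplus(q_hi - b)

    density = np.full(stack.shape, np.nan)
    density[valid] = s * _softplus(vals - b)
    cls = np.full(stack.shape, -1, dtype=np.int8)
    cls[valid] = classify_abundance(density[valid])
    return TrueSuitability(density, cls, ~valid)


def generate_zones(stack: HabitatStack, config: LakescapeConfig) -> ZoneMap:
    """Partition the lake into AHAs by k-means on (x, y, depth, fetch).

    Position is weighted up relative to the standardized habitat values so
    the zones come out contiguous-ish, mirroring how real AHAs group
    nearby cells of similar depth/fetch.
    """
    valid = ~stack.nodata_mask
    rows, cols = np.nonzero(valid)
    feats = [rows / max(stack.shape) * 3.0, cols / max(stack.shape) * 3.0]
    for name in ("GLBath90m", "GLFetch"):
        if name in stack.names:
            v = stack.variable(name)[valid]
            feats.append((v - v.mean()) / v.std())
    X = np.column_stack(feats)
    rng = np.random.default_rng(config.seed + 1)
    _, labels = kmeans2(X, config.n_aha, minit="++", seed=rng)
    aha = np.full(stack.shape, -1, dtype=int)
    aha[rows, cols] = labels
    return ZoneMap(aha, alu=1, nodata_mask=~valid)


def simulate_trawls(truth: TrueSuitability, config: LakescapeConfig,
                    stack: HabitatStack | None = None) -> pd.DataFrame:
    """Simulate tows: uniform locations over the lake, gamma-distributed
    swept areas, negative-binomial catches.

    The catch in a tow over a cell with expected density ``d`` (fish per
    1,000 m^2) and swept area ``a`` has mean ``d * a / 1000`` and
    variance ``mu + mu^2 / k`` with ``k = noise_dispersion`` — catches of
    this rare, patchy species are strongly overdispersed.
    """
    rng = np.random.default_rng(config.seed + 2)
    valid = ~truth.nodata_mask
    rows, cols = np.nonzero(valid)
    if rows.size == 0:
        raise ValueError("no valid cells to sample")
    pick = rng.integers(0, rows.size, size=config.n_tows)
    r, c = rows[pick], cols[pick]
    cell = config.cell_size_m
    y0 = truth.density.shape[0] * cell if stack is None else stack.origin[1]
    x0 = 0.0 if stack is None else stack.origin[0]
    x = x0 + (c + rng.random(config.n_tows)) * cell
    y = y0 - (r + rng.random(config.n_tows)) * cell
    area = rng.gamma(4.0, config.mean_area_swept_m2 / 4.0, config.n_tows)
    mu = truth.density[r, c] * area / 1000.0
    k = config.noise_dispersion
    counts = np.zeros(config.n_tows, dtype=int)
    pos = mu > 0
    # NB(size=k, p=k/(k+mu)); mu == 0 gives a certain zero catch
    counts[pos] = rng.negative_binomial(k, k / (k + mu[pos]))
    year = rng.integers(1987, 2015, config.n_tows)
    month = rng.integers(6, 9, config.n_tows)
    day = rng.integers(1, 29, config.n_tows)
    date = pd.to_datetime({"year": year, "month": month, "day": day})
    return pd.DataFrame({
        "x": x, "y": y, "date": date, "gear": "bottom_trawl",
        "area_swept_m2": area, "count": counts,
    })


def generate_lakescape(config: LakescapeConfig):
    """Full synthetic study unit.

    Returns ``(stack, zones, truth, samples)``: the habitat raster stack,
    the AHA partition, the true suitability surface, and the simulated
    trawl table.
    """
    stack = generate_habitat_stack(config)
    truth = generate_true_suitability(
        stack, config.true_weights,
        config.optimal_fraction, config.unsuitable_fraction)
    zones = generate_zones(stack, config)
    samples = simulate_trawls(truth, config, stack)
    return stack, zones, truth, samples
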