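"""Synoptic prediction maps and their analysis: habitat signatures,
population estimation, patch delineation, fragmentation metrics, and
cell-by-cell model contrasts.

Fragmentation follows the standard categorical-raster metrics: patches
are connected components of a class raster (8-neighbour by default);
the Aggregation Index (AI) of a class is 100 x the ratio of observed
like-class rook adjacencies to the maximum possible for the same number
of cells (attained by the most square-like arrangement); nearest-
neighbour distance is the shortest edge-to-edge distance between patches
of the same class, approximated on the grid as the distance between
boundary-cell centers minus one cell size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .abundance import AbundanceClass, CLASS_BOUNDS
from .grid import AlignmentError, HabitatStack
from .network import TrainedSDM, predict_class, predict_score

__all__ = [
    "ClassRaster", "PatchSet", "predict_map", "habitat_signature",
    "population_estimate", "delineate_patches", "fragmentation_metrics",
    "aggregation_index", "max_like_adjacencies", "patch_diversity",
    "contrast_maps",
]

NODATA_CLASS = -1


@dataclass
class ClassRaster:
    """Integer grid of abundance-class codes with a nodata mask."""

    classes: np.ndarray
    nodata_mask: np.ndarray
    cell_size_m: float = 90.0

    def __post_init__(self):
        self.classes = np.asarray(self.classes)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.classes.shape != self.nodata_mask.shape:
            raise ValueError("classes and mask shapes differ")
        vals = self.classes[~self.nodata_mask]
        if vals.size and (vals.min() < 0 or vals.max() > 3):
            raise ValueError("class codes must be 0..3")

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m**2

    def class_counts(self) -> pd.Series:
        """Cells per class over the valid area (all four classes listed)."""
        vals = self.classes[~self.nodata_mask]
        return pd.Series(
            {c: int((vals == c).sum()) for c in AbundanceClass}, name="cells")


def predict_map(model: TrainedSDM, stack: HabitatStack) -> ClassRaster:
    """Apply a trained model to every valid cell of a habitat stack."""
    table = stack.table()
    codes = predict_class(model, table[model.feature_names])
    classes = np.full(stack.shape, NODATA_CLASS, dtype=np.int8)
    classes[table["row"].to_numpy(), table["col"].to_numpy()] = codes
    return ClassRaster(np.where(stack.nodata_mask, NODATA_CLASS, classes),
                       stack.nodata_mask.copy(), stack.cell_size_m)


def predict_score_map(model: TrainedSDM, stack: HabitatStack) -> np.ndarray:
    """Continuous network score per valid cell (NaN on nodata)."""
    table = stack.table()
    score = predict_score(model, table[model.feature_names])
    out = np.full(stack.shape, np.nan)
    out[table["row"].to_numpy(), table["col"].to_numpy()] = score
    return out


def habitat_signature(features: pd.DataFrame, classes,
                      reference: pd.DataFrame | None = None,
                      groups: dict[str, list[int]] | None = None) -> pd.DataFrame:
    """Mean Z-score of each habitat variable within each abundance class,
    relative to reference conditions.

    ``features`` is one row per unit (sample row or cell), ``classes``
    the class code of each row. The reference population defaults to all
    rows of ``features`` (synoptic mode); pass the model-development rows
    to reproduce the sample-based variant. ``groups`` optionally merges
    codes, e.g. ``{"Appropriate": [2, 3]}``. Variables with zero
    reference sd come back as NaN columns.
    """
    classes = np.asarray(classes, dtype=int)
    if len(classes) != len(features):
        raise ValueError("classes must align with feature rows")
    ref = features if reference is None else reference
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    sd = sd.where(sd > 0)  # zero-sd -> NaN, flagged downstream
    if groups is None:
        groups = {AbundanceClass(c).label: [int(c)] for c in np.unique(classes)}
    rows = {}
    for label, codes in groups.items():
        member = np.isin(classes, codes)
        if member.any():
            rows[label] = (features.loc[member].mean(axis=0) - mu) / sd
    return pd.DataFrame(rows).T


def population_estimate(cell_counts, bounds=None, cell_area_m2: float = 8100.0,
                        error_bands: dict | None = None) -> pd.DataFrame:
    """Population range implied by a class map.

    Per class: minimum fish = cells x (cell_area/1,000) x lower bound
    density, maximum likewise with the upper bound density (fish/1,000
    m^2). Totals are summed over classes; optional relative error bands
    (e.g. {"min": 0.30, "max": 0.04}, from model RMSE) annotate the
    totals.
    """
    bounds = CLASS_BOUNDS if bounds is None else bounds
    counts = {AbundanceClass(k): int(v) for k, v in dict(cell_counts).items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("cell counts must be non-negative")
    rows = []
    for cls in sorted(counts, reverse=True):
        n = counts[cls]
        lo, hi = bounds[cls]
        per_1000 = cell_area_m2 / 1000.0
        rows.append({
            "class": cls.label, "cells": n,
            "area_km2": n * cell_area_m2 / 1e6,
            "min_population": n * per_1000 * lo,
            "max_population": n * per_1000 * hi,
        })
    out = pd.DataFrame(rows).set_index("class")
    total = out.sum()
    total.name = "Total"
    out = pd.concat([out, total.to_frame().T])
    out["percent_area"] = 100.0 * out["cells"] / out.loc["Total", "cells"]
    if error_bands:
        out.attrs["error_bands"] = dict(error_bands)
    return out


@dataclass
class PatchSet:
    """Connected components of a class raster.

    ``patches`` has one row per patch (class code, patch id, cell count,
    area); ``labels`` maps each valid cell to its patch id (0 = none);
    boundary-cell coordinates back the nearest-neighbour distances.
    """

    patches: pd.DataFrame
    labels: np.ndarray
    cell_size_m: float
    connectivity: int
    boundary: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    class_cells: dict[int, int] = field(default_factory=dict)
    valid_cells: int = 0


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


def delineate_patches(raster: ClassRaster, connectivity: int = 8) -> PatchSet:
    """Label connected same-class components (default 8-neighbour)."""
    struct = _structure(connectivity)
    valid = ~raster.nodata_mask
    labels = np.zeros(raster.classes.shape, dtype=np.int32)
    rows, boundary = [], {}
    next_id = 1
    for cls in AbundanceClass:
        member = valid & (raster.classes == cls)
        if not member.any():
            continue
        lab, n = ndimage.label(member, structure=struct)
        eroded = ndimage.binary_erosion(member, _structure(4), border_value=0)
        edge = member & ~eroded
        for comp in range(1, n + 1):
            cells = lab == comp
            pid = next_id
            next_id += 1
            labels[cells] = pid
            rows.append({"class": int(cls), "patch_id": pid,
                         "cells": int(cells.sum()),
                         "area_m2": float(cells.sum()) * raster.cell_area_m2})
            boundary[pid] = np.argwhere(cells & edge)
    patches = pd.DataFrame(
        rows, columns=["class", "patch_id", "cells", "area_m2"])
    class_cells = {int(c): int(((raster.classes == c) & valid).sum())
                   for c in AbundanceClass}
    return PatchSet(patches, labels, raster.cell_size_m, connectivity,
                    boundary, class_cells, int(valid.sum()))


def max_like_adjacencies(n: int) -> int:
    """Largest possible number of rook like-adjacencies among n cells,
    attained by the most square-like arrangement (side m = floor(sqrt n))."""
    if n <= 0:
        return 0
    m = int(np.floor(np.sqrt(n)))
    base = 2 * m * (m - 1)
    extra = n - m * m
    if extra == 0:
        return base
    if n <= m * (m + 1):
        return base + 2 * extra - 1
    return base + 2 * extra - 2


def _like_adjacencies(member: np.ndarray) -> int:
    """Observed rook adjacencies between same-class cells."""
    horiz = member[:, :-1] & member[:, 1:]
    vert = member[:-1, :] & member[1:, :]
    return int(horiz.sum() + vert.sum())


def aggregation_index(raster: ClassRaster, cls: int) -> float:
    """AI = 100 x like rook adjacencies / maximum possible; NaN for
    classes of fewer than 2 cells (no adjacency is possible)."""
    member = (~raster.nodata_mask) & (raster.classes == cls)
    n = int(member.sum())
    max_e = max_like_adjacencies(n)
    if max_e == 0:
        return np.nan
    return 100.0 * _like_adjacencies(member) / max_e


def _nearest_neighbour_distances(patch_ids, boundary, cell_size) -> list[float]:
    """Per patch, edge-to-edge distance (m) to the nearest same-class patch."""
    if len(patch_ids) < 2:
        return []
    pts = np.vstack([boundary[p] for p in patch_ids]).astype(float) * cell_size
    owner = np.concatenate([np.full(len(boundary[p]), p) for p in patch_ids])
    out = []
    for p in patch_ids:
        mine = owner == p
        other_tree = cKDTree(pts[~mine])
        d, _ = other_tree.query(pts[mine], k=1)
        out.append(max(float(np.min(d)) - cell_size, 0.0))
    return out


def fragmentation_metrics(patchset: PatchSet,
                          raster: ClassRaster) -> pd.DataFrame:
    """Per-class fragmentation table: percent of total area, patch count,
    mean patch size (hectares), mean nearest-neighbour edge-to-edge
    distance (m), and Aggregation Index (%).

    Classes with a single patch have no neighbour distance (NaN).
    """
    rows = []
    for cls in AbundanceClass:
        sub = patchset.patches[patchset.patches["class"] == int(cls)]
        n_cells = patchset.class_cells.get(int(cls), 0)
        if n_cells == 0:
            rows.append({"class": cls.label, "percent_area": 0.0,
                         "n_patches": 0, "mean_patch_size_ha": np.nan,
                         "mean_nn_distance_m": np.nan, "aggregation_index": np.nan})
            continue
        nn = _nearest_neighbour_distances(
            list(sub["patch_id"]), patchset.boundary, patchset.cell_size_m)
        rows.append({
            "class": cls.label,
            "percent_area": 100.0 * n_cells / patchset.valid_cells,
            "n_patches": int(len(sub)),
            "mean_patch_size_ha": float(sub["area_m2"].mean()) / 1e4,
            "mean_nn_distance_m": float(np.mean(nn)) if nn else np.nan,
            "aggregation_index": aggregation_index(raster, int(cls)),
        })
    return pd.DataFrame(rows).set_index("class")


def patch_diversity(percent_areas) -> float:
    """Shannon diversity H = -sum p ln p over class area proportions.

    Accepts percentages or proportions; zero-share classes are dropped,
    the rest renormalized to sum to 1.
    """
    p = np.asarray(list(percent_areas), dtype=float)
    if (p < 0).any():
        raise ValueError("negative area share")
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("all area shares are zero")
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def contrast_maps(a: ClassRaster, b: ClassRaster,
                  group_appropriate: bool = True):
    """Cell-by-cell contrast of two class rasters (e.g. benchmark vs
    disturbance predictions).

    Returns ``(percent_same, transitions, change)``: the percent of valid
    area with identical class, a table of off-diagonal transitions (area
    and percent, with Moderate+Optimal optionally merged as
    'Appropriate'), and the signed change raster b - a.
    """
    if a.classes.shape != b.classes.shape or a.cell_size_m != b.cell_size_m:
        raise AlignmentError("class rasters are not aligned")
    valid = ~(a.nodata_mask | b.nodata_mask)
    ca, cb = a.classes[valid], b.classes[valid]
    n = ca.size

    if group_appropriate:
        def grp(codes):
            out = np.full(codes.shape, "Marginal", dtype=object)
            out[codes == 0] = "Unsuitable"
            out[codes >= 2] = "Appropriate"
            return out
        ga, gb = grp(ca), grp(cb)
    else:
        ga = np.array([AbundanceClass(c).label for c in ca], dtype=object)
        gb = np.array([AbundanceClass(c).label for c in cb], dtype=object)

    # "same" is judged at the same grouping level as the transitions, so
    # the identical share and the transition shares partition the area
    percent_same = 100.0 * float((ga == gb).sum()) / n
    tab = pd.crosstab(pd.Series(ga, name="from"), pd.Series(gb, name="to"))
    rows = []
    for f in tab.index:
        for t in tab.columns:
            if f == t:
                continue
            cells = int(tab.loc[f, t])
            if cells == 0:
                continue
            rows.append({"from": f, "to": t, "cells": cells,
                         "area_km2": cells * a.cell_area_m2 / 1e6,
                         "percent_area": 100.0 * cells / n})
    transitions = pd.DataFrame(
        rows, columns=["from", "to", "cells", "area_km2", "percent_area"])
    change = np.where(valid, b.classes - a.classes, 0).astype(np.int8)
    return percent_same, transitions, change
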