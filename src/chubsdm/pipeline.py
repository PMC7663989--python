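"""End-to-end orchestration of the benchmark ("potential") and
"disturbance" abundance-model analyses.

Stages: simulate (or load) a lakescape -> standardize catches to CPUE and
assign them to cells/AHAs -> average CPUE per AHA and classify -> rank
variables by PCA and select the top k -> train the network(s) -> evaluate
-> map predictions over the lake -> habitat signatures -> population
range -> fragmentation metrics -> cell-by-cell model contrast. Each stage
is an importable function; ``run_pipeline`` chains them and writes every
artifact plus a manifest (config hash + seed), so a rerun with the same
config and seed reproduces the tables bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, evaluate, landscape, network, varselect
from .grid import (HabitatStack, ZoneMap, aggregate_to_aha, aha_habitat_means,
                   assign_to_cells, write_ascii_grid, write_stack)
from .synthetic import (DISTURBANCE_EXTRA_VARIABLES, LakescapeConfig,
                        POTENTIAL_VARIABLES, generate_lakescape)

__all__ = ["PipelineConfig", "build_training_table", "run_pipeline",
           "validate_external", "recovery_experiment"]

log = logging.getLogger("chubsdm")


@dataclass
class PipelineConfig:
    """Everything one synthetic end-to-end run needs.

    The disturbance variable list must contain the potential list (the
    disturbance model is the benchmark model plus temperature and
    shoreline-modification inputs).
    """

    lakescape: LakescapeConfig = field(default_factory=LakescapeConfig)
    potential_variables: list[str] = field(
        default_factory=lambda: list(POTENTIAL_VARIABLES))
    disturbance_variables: list[str] = field(
        default_factory=lambda: list(POTENTIAL_VARIABLES)
        + list(DISTURBANCE_EXTRA_VARIABLES))
    n_selected: int = 10
    n_hidden_potential: int = 46
    n_hidden_disturbance: int = 55
    max_epochs: int = 20000
    patience: int = 200
    out_dir: str = "pipeline_out"
    error_bands: dict = field(default_factory=lambda: {"min": 0.30, "max": 0.04})
    seed: int = 0

    def __post_init__(self):
        if not set(self.potential_variables) <= set(self.disturbance_variables):
            raise ValueError("disturbance variables must include the "
                             "potential variables")
        # the simulator must produce a raster for every model input
        missing = [v for v in self.disturbance_variables
                   if v not in self.lakescape.variable_names]
        if missing:
            doc = asdict(self.lakescape)
            doc["variable_names"] = list(self.lakescape.variable_names) + missing
            self.lakescape = LakescapeConfig(**doc)

    def config_hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        lk = doc.pop("lakescape", {})
        return cls(lakescape=LakescapeConfig(**lk), **doc)


def build_training_table(stack: HabitatStack, zones: ZoneMap,
                         samples: pd.DataFrame) -> pd.DataFrame:
    """One row per tow: AHA-mean habitat conditions plus the abundance
    class of the tow's AHA (classified from AHA-averaged CPUE).

    Individual CPUEs of this rare, patchy species are too noisy to
    classify singly, so each tow inherits the class of its AHA; habitat
    inputs are AHA means for the same reason.
    """
    samples = samples.copy()
    samples["cpue"] = abundance.standardize_cpue(
        samples["count"], samples["area_swept_m2"])
    located = assign_to_cells(samples, stack, zones)
    per_aha = aggregate_to_aha(located)
    per_aha["class"] = abundance.classify_abundance(
        per_aha["mean_cpue"].to_numpy(),
        per_aha["any_presence"].to_numpy())
    habitat = aha_habitat_means(stack, zones)
    table = located.join(habitat, on="aha_id")
    table = table.join(per_aha[["mean_cpue", "class"]], on="aha_id",
                       rsuffix="_aha")
    log.info("training table: %d tows across %d sampled AHAs",
             len(table), per_aha.shape[0])
    return table


def _train_model(table: pd.DataFrame, variables: list[str], n_hidden: int,
                 config: PipelineConfig, seed_offset: int) -> network.TrainedSDM:
    net = network.NetConfig(
        n_inputs=len(variables), n_hidden=n_hidden,
        max_epochs=config.max_epochs, patience=config.patience,
        seed=config.seed + seed_offset)
    return network.train(table[variables], table["class"].to_numpy(), net)


def _evaluate(model: network.TrainedSDM, table: pd.DataFrame,
              variables: list[str]) -> dict:
    obs = table["class"].to_numpy()
    pred = network.predict_class(model, table[variables])
    score = network.predict_score(model, table[variables])
    cm = evaluate.confusion(obs, pred, labels=list(range(4)))
    pa = cm.presence_absence()
    stats = evaluate.error_rates(pa.counts)
    cont = score * 3.0 if model.config.output_mode == "scalar" else None
    fit = (evaluate.fit_stats(obs, cont, len(variables))
           if cont is not None else {})
    return {
        "confusion": cm, "presence_absence": pa,
        "kappa_presence_absence": evaluate.kappa(pa.counts),
        "kappa_per_class": evaluate.per_class_kappa(cm),
        "percent_correct_4class": evaluate.error_rates(cm.counts)["percent_correct"],
        **{k: v for k, v in stats.items() if k != "percent_correct"},
        "percent_correct_presence_absence": stats["percent_correct"],
        **fit,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic analysis; returns the artifacts in
    memory and writes tables/rasters/models plus a manifest to
    ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": {}}

    def record(stage: str, *paths):
        manifest["stages"][stage] = [str(p) for p in paths]
        log.info("stage %-12s -> %s", stage, ", ".join(map(str, paths)))

    # 1. simulate
    lk = config.lakescape
    stack, zones, truth, samples = generate_lakescape(lk)
    artifacts.update(stack=stack, zones=zones, truth=truth, samples=samples)
    write_stack(stack, out / "rasters")
    write_ascii_grid(out / "aha_zones.asc",
                     np.where(zones.nodata_mask, np.nan, zones.aha),
                     stack.cell_size_m, stack.origin, fmt="%d")
    samples.to_csv(out / "samples.csv", index=False)
    record("simulate", out / "rasters", out / "aha_zones.asc",
           out / "samples.csv")

    # 2-3. standardize + classify (per AHA) -> training table
    table = build_training_table(stack, zones, samples)
    table.to_csv(out / "training_table.csv", index=False)
    artifacts["training_table"] = table
    record("classify", out / "training_table.csv")

    # 4. variable selection
    ranking = varselect.pca_rank(table[config.potential_variables])
    selected = varselect.select_top_k(
        ranking, min(config.n_selected, len(config.potential_variables)))
    ranking.table.to_csv(out / "pca_ranking.csv")
    artifacts.update(ranking=ranking, selected=selected)
    record("select_vars", out / "pca_ranking.csv")

    # 5. train both models
    disturbance_vars = selected + [v for v in config.disturbance_variables
                                   if v not in config.potential_variables
                                   and v in table.columns]
    models = {
        "potential": _train_model(table, selected,
                                  config.n_hidden_potential, config, 10),
    }
    run_disturbance = len(disturbance_vars) > len(selected)
    if run_disturbance:
        models["disturbance"] = _train_model(
            table, disturbance_vars, config.n_hidden_disturbance, config, 20)
    for name, m in models.items():
        m.save(out / f"model_{name}.json")
        m.history.to_csv(out / f"history_{name}.csv", index=False)
    artifacts["models"] = models
    record("train", *[out / f"model_{n}.json" for n in models])

    # 6. evaluate
    evals, eval_rows = {}, []
    for name, m in models.items():
        vars_ = selected if name == "potential" else disturbance_vars
        ev = _evaluate(m, table, vars_)
        evals[name] = ev
        row = {k: v for k, v in ev.items()
               if isinstance(v, (int, float, np.floating))}
        row["model"] = name
        eval_rows.append(row)
        ev["confusion"].to_frame().to_csv(out / f"confusion_{name}.csv")
    pd.DataFrame(eval_rows).set_index("model").to_csv(out / "evaluation.csv")
    artifacts["evaluation"] = evals
    record("evaluate", out / "evaluation.csv")

    # 7. synoptic maps
    maps = {}
    for name, m in models.items():
        cmap = landscape.predict_map(m, stack)
        maps[name] = cmap
        write_ascii_grid(out / f"class_map_{name}.asc",
                         np.where(cmap.nodata_mask, np.nan,
                                  cmap.classes.astype(float)),
                         cmap.cell_size_m, stack.origin, fmt="%d")
    artifacts["maps"] = maps
    record("map", *[out / f"class_map_{n}.asc" for n in maps])

    # 8. habitat signatures (synoptic, grouped as in the study)
    cells = stack.table()
    groups = {"Appropriate": [2, 3], "Marginal": [1], "Unsuitable": [0]}
    pot_map = maps["potential"]
    cell_classes = pot_map.classes[cells["row"], cells["col"]]
    signature = landscape.habitat_signature(
        cells[stack.names], cell_classes, groups=groups)
    signature.to_csv(out / "habitat_signature.csv")
    artifacts["signature"] = signature
    record("signature", out / "habitat_signature.csv")

    # 9. population estimate
    population = landscape.population_estimate(
        pot_map.class_counts(), cell_area_m2=stack.cell_area_m2,
        error_bands=config.error_bands)
    population.to_csv(out / "population.csv")
    artifacts["population"] = population
    record("population", out / "population.csv")

    # 10. fragmentation
    frag = {}
    for name, cmap in maps.items():
        patches = landscape.delineate_patches(cmap)
        metrics = landscape.fragmentation_metrics(patches, cmap)
        metrics["shannon_diversity"] = landscape.patch_diversity(
            metrics["percent_area"])
        frag[name] = metrics
        metrics.to_csv(out / f"fragmentation_{name}.csv")
    artifacts["fragmentation"] = frag
    record("fragment", *[out / f"fragmentation_{n}.csv" for n in frag])

    # 11. contrast
    if run_disturbance:
        same, transitions, change = landscape.contrast_maps(
            maps["potential"], maps["disturbance"])
        transitions.to_csv(out / "contrast_transitions.csv", index=False)
        write_ascii_grid(out / "contrast_change.asc", change.astype(float),
                         stack.cell_size_m, stack.origin, fmt="%d")
        artifacts["contrast"] = {"percent_same": same,
                                 "transitions": transitions,
                                 "change": change}
        record("contrast", out / "contrast_transitions.csv",
               out / "contrast_change.asc")

    manifest["tables_sha256"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.glob("*.csv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = manifest
    return artifacts


def recovery_experiment(lakescape: LakescapeConfig | None = None,
                        n_hidden: int = 46, max_epochs: int = 8000,
                        patience: int = 300, seed: int = 0) -> dict:
    """Parameter-recovery check of the network on a known suitability
    function.

    Generates a synthetic lakescape, takes the habitat values and the
    *true* abundance class at each simulated tow location (one row per
    tow, cell-level features), trains the network, and asks two
    questions: does the held-out presence-absence kappa reach the
    'substantial' bar (> 0.6), and do the signs of the connection-weight
    importances match the true drivers for the largest-magnitude true
    weights? Truth labels (rather than noisy catch-derived labels) are
    used so the check isolates what the network machinery can recover;
    the catch-noise pipeline is exercised separately.
    """
    lakescape = lakescape or LakescapeConfig(seed=seed)
    stack, _, truth, samples = generate_lakescape(lakescape)
    r, c = stack.cell_of(samples["x"].to_numpy(), samples["y"].to_numpy())
    features = pd.DataFrame(
        {n: stack.variable(n)[r, c] for n in stack.names})
    y = truth.true_class[r, c]
    net = network.NetConfig(
        n_inputs=stack.n_variables, n_hidden=n_hidden,
        max_epochs=max_epochs, patience=patience, seed=seed)
    model = network.train(features, y, net)
    pred = network.predict_class(model, features.iloc[model.holdout_index])
    true_h = y[model.holdout_index]
    pa = evaluate.confusion((true_h > 0).astype(int), (pred > 0).astype(int),
                            labels=[0, 1])
    importances = network.relative_weights(model)
    true_w = pd.Series(lakescape.true_weights)
    top = true_w.abs().sort_values(ascending=False).index
    sign_match = {v: bool(np.sign(importances[v]) == np.sign(true_w[v]))
                  for v in top if true_w[v] != 0}
    return {
        "model": model,
        "kappa_presence_absence": evaluate.kappa(pa.counts),
        "holdout_accuracy": float((pred == true_h).mean()),
        "importances": importances,
        "true_weights": true_w,
        "sign_match": sign_match,
    }


def validate_external(model: network.TrainedSDM, test_samples: pd.DataFrame,
                      stack: HabitatStack, zones: ZoneMap,
                      class_map: landscape.ClassRaster,
                      min_class: int = 2, alpha: float = 0.05) -> dict:
    """Validate a trained model against an independent, presence-only
    test set.

    Absences and (by default) Marginal-class records are excluded — the
    independent surveys differ in gear and catchability, so only Moderate
    and Optimal collections are compared. Each retained sample is binned
    by the predicted class at its location; the match is summarized by
    the simple linear correlation of observed vs predicted class codes
    and a binned K-S test of the samples' predicted-class distribution
    against the class-area shares of the prediction map (low classes 0-1
    pooled vs high classes >1, mirroring the study's binning).
    """
    s = test_samples.copy()
    s["cpue"] = abundance.standardize_cpue(s["count"], s["area_swept_m2"])
    s = s[s["count"] > 0]
    s["obs_class"] = abundance.classify_abundance(
        s["cpue"].to_numpy(), True)
    s = s[s["obs_class"] >= min_class]
    if s.empty:
        raise ValueError("no test samples left after filtering")
    located = assign_to_cells(s, stack, zones)
    habitat = aha_habitat_means(stack, zones)
    feats = located.join(habitat, on="aha_id")
    pred = network.predict_class(model, feats[model.feature_names])
    obs = feats["obs_class"].to_numpy()
    if len(obs) > 1 and np.std(obs) > 0 and np.std(pred) > 0:
        r = float(np.corrcoef(obs, pred)[0, 1])
    else:
        r = np.nan  # degenerate: one of the vectors is constant

    counts = class_map.class_counts()
    low_share = (counts[0] + counts[1]) / counts.sum()
    expected = np.array([low_share, 1.0 - low_share])
    observed = np.array([(pred <= 1).sum(), (pred > 1).sum()], dtype=float)
    ks = evaluate.ks_test(observed, expected, n=len(pred), alpha=alpha)
    return {"n": len(pred), "correlation": r, "ks": ks,
            "observed_bins": observed, "expected_freqs": expected}
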