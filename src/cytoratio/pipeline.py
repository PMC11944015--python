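"""End-to-end orchestration: cohort → ratios → FCBF → statistics → models.

``run_pipeline`` executes the stages in order, writes each stage's CSV
output under the configured directory, and returns (and writes) a JSON
manifest recording the seed, stage row/column counts, per-stage wall time
and the final metrics, so a fixed seed reproduces a run byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify_eval import MODEL_IDS, evaluate_all, nb_fit, stratified_kfold
from .cohort_stats import demographics_table
from .fcbf import fcbf_select, scores_to_frame
from .nomogram import build_nomogram
from .panel import DEFAULT_PANEL
from .ratio_engine import enumerate_ratios, evaluate_ratios
from .synthetic_cohort import (config_from_dict, generate_cohort,
                               read_cohort, write_cohort)
from .univariate import compare_table

log = logging.getLogger("cytoratio")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    outdir: Path
    input_path: Path | None = None          # tidy cohort CSV, or None to
    simulation: dict | None = None          # simulate with these settings
    label: str = "bsi"                      # target column: bsi | gram
    positive: str = "yes"                   # declared positive class
    reference: str | None = None            # univariate reference (= positive)
    max_terms: int = 3
    seed: int = 0
    nested: bool = False                    # per-fold (leakage-free) FCBF
    k: int = 5
    models: tuple[str, ...] = MODEL_IDS

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.label not in ("bsi", "gram"):
            raise ValueError("label must be 'bsi' or 'gram'")
        if self.reference is None:
            self.reference = self.positive

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _stage(manifest: dict, name: str, t0: float, **info) -> None:
    # Wall time goes to the log only: the manifest must be byte-identical
    # across equal-seed runs.
    manifest["stages"][name] = dict(info)
    log.info("stage %s done in %.2fs %s", name, time.perf_counter() - t0, info)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and return the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = DEFAULT_PANEL
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "label": config.label, "positive": config.positive,
                      "nested_selection": config.nested, "stages": {}}

    # -- load or simulate -------------------------------------------------
    t0 = time.perf_counter()
    if config.input_path is not None:
        cohort = read_cohort(config.input_path, panel=panel)
        source = str(config.input_path)
    else:
        sim = dict(config.simulation or {})
        sim.setdefault("seed", config.seed)
        cohort = generate_cohort(config_from_dict(sim))
        source = "simulated"
    if config.label == "gram":
        cohort = cohort[cohort["gram"].isin(["negative", "positive"])]
        cohort = cohort.reset_index(drop=True)
    write_cohort(cohort, outdir / "cohort.csv")
    _stage(manifest, "cohort", t0, source=source, n_samples=len(cohort))

    # -- ratio features ----------------------------------------------------
    t0 = time.perf_counter()
    specs = enumerate_ratios(panel, max_terms=config.max_terms)
    features = evaluate_ratios(cohort, specs, panel=panel)
    features.to_csv(outdir / "features.csv", index=False)
    _stage(manifest, "ratios", t0, n_ratios=len(specs),
           n_features=features.shape[1])

    labels = cohort[config.label].to_numpy()

    # -- FCBF selection ----------------------------------------------------
    t0 = time.perf_counter()
    scores = fcbf_select(features, labels)
    scores_to_frame(scores).to_csv(outdir / "fcbf_scores.csv", index=False)
    selected = [s.feature for s in scores if s.selected]
    _stage(manifest, "fcbf", t0, n_selected=len(selected))

    # -- univariate + demographics ------------------------------------------
    t0 = time.perf_counter()
    uni = compare_table(cohort, config.label, config.reference, panel=panel)
    uni.to_csv(outdir / "univariate.csv")
    demo = demographics_table(
        cohort, label=config.label,
        reference=config.reference)
    demo.to_csv(outdir / "demographics.csv")
    _stage(manifest, "univariate", t0, n_features=len(uni))

    # -- cross-validated evaluation -----------------------------------------
    t0 = time.perf_counter()
    eval_features = features if config.nested else features[selected]
    if not config.nested and not selected:
        raise RuntimeError("evaluate stage: FCBF selected no features and "
                           "nested selection is off")
    metrics = evaluate_all(eval_features, labels, config.positive,
                           k=config.k, seed=config.seed,
                           models=config.models,
                           nested_select=config.nested)
    metrics.to_csv(outdir / "metrics.csv")
    manifest["metrics"] = {
        m: {k: round(float(v), 6) for k, v in row.items()}
        for m, row in metrics.iterrows()}
    _stage(manifest, "evaluate", t0, n_models=len(metrics))

    # -- nomogram (naive Bayes on the selected features) ---------------------
    t0 = time.perf_counter()
    if selected:
        nb = nb_fit(features[selected], labels)
        nomo = build_nomogram(nb, scores, target=config.positive)
        nomo.to_frame().to_csv(outdir / "nomogram.csv", index=False)
        manifest["nomogram"] = {
            "prior_log_odds": round(nomo.prior_log_odds, 6),
            "n_features": len(nomo.features)}
    else:
        manifest["nomogram"] = None
    _stage(manifest, "nomogram", t0)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
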