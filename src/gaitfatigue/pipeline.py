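"""End-to-end orchestration: simulate → extract → select → evaluate →
interpret → report, with plain-text logging, per-stage timers and a
reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .features import FEATURE_NAMES, build_dataset
from .io import write_feature_table, write_recording
from .models import (
    default_model_spec,
    losocv_evaluate,
    samples_to_arrays,
    sequential_forward_select,
    single_feature_accuracy,
    source_ablation,
    tune_hyperparameters,
)
from .simulate import cohort_to_triples, simulate_cohort
from .stats import (
    bonferroni,
    feature_correlations,
    paired_wilcoxon,
    per_participant_state_means,
)

__all__ = ["EvaluationReport", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Full pipeline results: selection traces, model comparisons,
    per-participant accuracies, interpretation statistics."""

    per_family: dict = field(default_factory=dict)
    best_family: str = ""
    interpretation: dict = field(default_factory=dict)
    ablation: dict = field(default_factory=dict)
    dataset: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "per_family": self.per_family,
            "best_family": self.best_family,
            "interpretation": self.interpretation,
            "ablation": self.ablation,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    logger.info("stage %s: start", name)
    return time.perf_counter()


def _stage_done(name: str, t0: float) -> float:
    dt = time.perf_counter() - t0
    logger.info("stage %s: done in %.1f s", name, dt)
    return dt


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> EvaluationReport:
    """Run every stage in order and write all artifacts under *outdir*.

    Artifacts: ``features.csv`` (the window feature table), per-family
    selection traces, ``report.json`` and ``manifest.json`` (config,
    seeds, versions and artifact hashes).  Identical configs produce
    byte-identical feature tables and traces.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = _stage("simulate")
    cohort = simulate_cohort(
        cfg.cohort_config(), cfg.effect_spec(), compute_truth=False
    )
    if cfg.write_recordings:
        recdir = outdir / "recordings"
        recdir.mkdir(exist_ok=True)
        for p in cohort:
            for state, rec in p.recordings.items():
                write_recording(rec, recdir / f"{p.participant_id}_{state}.csv")
    timings["simulate"] = _stage_done("simulate", t0)

    t0 = _stage("extract")
    samples = build_dataset(cohort_to_triples(cohort), cfg.extraction_params())
    feature_path = outdir / "features.csv"
    write_feature_table(samples, feature_path)
    timings["extract"] = _stage_done("extract", t0)
    logger.info("dataset: %d window samples", len(samples))

    report = EvaluationReport(
        dataset={
            "n_samples": len(samples),
            "n_participants": cfg.n_participants,
            "n_features": len(FEATURE_NAMES),
        }
    )

    X, y, _ = samples_to_arrays(samples, FEATURE_NAMES)
    for family in cfg.families:
        t0 = _stage(f"select[{family}]")
        spec = default_model_spec(family)
        trace = sequential_forward_select(
            X, y, spec,
            k=cfg.cv_folds, seed=cfg.cv_seed,
            feature_names=list(FEATURE_NAMES),
            max_features=cfg.sfs_max_features,
        )
        subset = trace.selected if trace.selected else [FEATURE_NAMES[0]]
        cols = [FEATURE_NAMES.index(n) for n in subset]
        tuned = tune_hyperparameters(
            X[:, cols], y, family,
            k=cfg.cv_folds, budget=cfg.tune_budget, seed=cfg.cv_seed,
        )
        timings[f"select[{family}]"] = _stage_done(f"select[{family}]", t0)

        t0 = _stage(f"losocv[{family}]")
        res = losocv_evaluate(samples, subset, tuned)
        timings[f"losocv[{family}]"] = _stage_done(f"losocv[{family}]", t0)
        report.per_family[family] = {
            "selected": trace.selected,
            "step_rates": trace.step_rates,
            "baseline_rate": trace.baseline_rate,
            "fivefold_rate": trace.final_rate,
            "hyperparameters": tuned.hyperparameters,
            "losocv_accuracy": res.accuracy,
            "losocv_misclassification_rate": res.misclassification_rate,
            "per_participant_accuracy": res.per_participant_accuracy,
        }
        (outdir / f"selection_{family}.json").write_text(
            json.dumps(report.per_family[family], indent=2)
        )

    report.best_family = max(
        cfg.families, key=lambda f: report.per_family[f]["losocv_accuracy"]
    )
    best = report.per_family[report.best_family]
    best_subset = best["selected"] or [FEATURE_NAMES[0]]
    best_spec = default_model_spec(report.best_family)

    t0 = _stage("interpret")
    wilcoxon_table = []
    p_values = []
    if cfg.n_participants < 5:
        logger.warning(
            "interpret: paired Wilcoxon needs >= 5 participants, have %d; "
            "skipping the before/after comparison",
            cfg.n_participants,
        )
        best_subset_for_tests = []
    else:
        best_subset_for_tests = best_subset
    for name in best_subset_for_tests:
        nf, fa, _ = per_participant_state_means(samples, name)
        res = paired_wilcoxon(nf, fa)
        direction = "increased" if np.mean(fa) > np.mean(nf) else "decreased"
        wilcoxon_table.append(
            {
                "feature": name,
                "W": res.statistic,
                "p": res.p_value,
                "direction": direction,
            }
        )
        p_values.append(res.p_value)
    flags = bonferroni(p_values, cfg.alpha) if p_values else []
    for row, flag in zip(wilcoxon_table, flags):
        row["significant"] = bool(flag)
    corr, strong = feature_correlations(samples, best_subset)
    single_acc = {}
    if cfg.run_single_feature:
        for name in best_subset:
            single_acc[name] = single_feature_accuracy(samples, name, best_spec)
    report.interpretation = {
        "wilcoxon": wilcoxon_table,
        "bonferroni_alpha": cfg.alpha,
        "bonferroni_m": len(p_values),
        "correlations": {
            "features": best_subset,
            "r": corr.tolist(),
            "strong": strong.tolist(),
        },
        "single_feature_accuracy": single_acc,
    }
    timings["interpret"] = _stage_done("interpret", t0)

    if cfg.run_ablation:
        t0 = _stage("ablation")
        report.ablation = source_ablation(
            samples, best_spec, k=cfg.cv_folds, seed=cfg.cv_seed
        )
        timings["ablation"] = _stage_done("ablation", t0)

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2))

    import sklearn

    manifest = {
        "config": cfg.to_dict(),
        "versions": {
            "gaitfatigue": __version__,
            "numpy": np.__version__,
            "sklearn": sklearn.__version__,
        },
        "timings_s": timings,
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(outdir.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def render_report(report: dict) -> str:
    """Plain-text summary of a report dict (the `report` CLI subcommand)."""
    lines = []
    ds = report.get("dataset", {})
    lines.append(
        f"dataset: {ds.get('n_samples', '?')} windows, "
        f"{ds.get('n_participants', '?')} participants"
    )
    for fam, r in report.get("per_family", {}).items():
        lines.append(
            f"{fam}: LOSOCV accuracy {r['losocv_accuracy']:.3f}  "
            f"({len(r['selected'])} features: {', '.join(r['selected'][:6])}"
            f"{'...' if len(r['selected']) > 6 else ''})"
        )
    if report.get("best_family"):
        lines.append(f"best model: {report['best_family']}")
    for row in report.get("interpretation", {}).get("wilcoxon", []):
        mark = "*" if row.get("significant") else " "
        lines.append(
            f"  {row['feature']:<16} {row['direction']:<9} "
            f"W={row['W']:.1f} p={row['p']:.4g} {mark}"
        )
    for source, r in report.get("ablation", {}).items():
        lines.append(f"{source}: LOSOCV accuracy {r['losocv_accuracy']:.3f}")
    return "\n".join(lines)
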