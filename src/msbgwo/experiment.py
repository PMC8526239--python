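"""Experimental protocol: repeated seeded runs, averaging, and testing.

Mirrors the standard wrapper-selection benchmark protocol: each
optimizer variant is run k times (default 10) from deterministically
derived seeds; after every run the best mask is re-evaluated with the
full stratified 10-fold CV to produce the reported metrics; per-variant
results are summarized as max/min/mean+-sd accuracy plus the averaged
selected-feature count, precision, recall and F-measure; and variant
pairs are compared with a two-sided Wilcoxon rank-sum test on the
per-run accuracies at the 5% level.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from msbgwo.core import OptimizerConfig, run_optimizer, VARIANT_MSBGWO, VARIANT_BGWO2
from msbgwo.data import Dataset, SyntheticSpec, generate_synthetic, load_dataset, minmax_normalize
from msbgwo.fitness import FitnessConfig, MaskEvaluator


@dataclass
class ExperimentConfig:
    """Settings for a multi-run comparison experiment.

    Exactly one of ``dataset_path`` / ``synthetic`` supplies the data.
    Per-run seeds are a pure function of (base_seed, variant, run index),
    so adding a variant never changes another variant's runs.
    """

    dataset_path: Optional[str] = None
    synthetic: Optional[SyntheticSpec] = None
    variants: Sequence[str] = (VARIANT_MSBGWO, VARIANT_BGWO2)
    runs: int = 10
    n_wolves: int = 10
    n_iterations: int = 100
    omega: float = 0.1
    alpha: float = 0.8
    knn_k: int = 5
    folds: int = 10
    base_seed: int = 0
    out_dir: str = "results"
    label_column: Optional[str] = None
    positive_label: Optional[str] = None
    boxplot: bool = False

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError(f"runs must be >= 1, got {self.runs}")
        if (self.dataset_path is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of dataset_path or synthetic")


@dataclass(frozen=True)
class RunSummary:
    """Per-variant aggregate over k runs (the benchmark-table row)."""

    variant: str
    runs: int
    max_acc: float
    min_acc: float
    avg_acc: float
    sd_acc: float
    avg_sf: float
    avg_pre: float
    avg_rec: float
    avg_f: float


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided rank-sum comparison; h = 1 rejects equal medians at 5%."""

    p_value: float
    h: int
    z: float


def run_seed(base_seed: int, variant: str, run_index: int, stream: str = "opt") -> int:
    """Deterministic per-run seed below 2^31, independent across variants."""
    token = f"{base_seed}:{variant}:{run_index}:{stream}".encode()
    return zlib.crc32(token) & 0x7FFFFFFF


def average_runs(records: Sequence[dict]) -> RunSummary:
    """Aggregate per-run metric records for one variant.

    Each record needs keys ``accuracy``, ``precision``, ``recall``,
    ``f_measure`` and ``selected_features``.  Accuracy spread is the
    sample standard deviation (0 for a single run).
    """
    if not records:
        raise ValueError("average_runs needs at least one run record")
    acc = np.array([r["accuracy"] for r in records], dtype=float)
    sd = float(np.std(acc, ddof=1)) if len(acc) > 1 else 0.0
    return RunSummary(
        variant=records[0].get("variant", ""),
        runs=len(records),
        max_acc=float(acc.max()),
        min_acc=float(acc.min()),
        avg_acc=float(acc.mean()),
        sd_acc=sd,
        avg_sf=float(np.mean([r["selected_features"] for r in records])),
        avg_pre=float(np.mean([r["precision"] for r in records])),
        avg_rec=float(np.mean([r["recall"] for r in records])),
        avg_f=float(np.mean([r["f_measure"] for r in records])),
    )


def wilcoxon_compare(a, b, level: float = 0.05) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test on two samples.

    Uses the normal approximation with midranks for ties.  When every
    value in both samples is identical the test statistic is degenerate;
    that case returns p = 1, h = 0 explicitly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return WilcoxonResult(p_value=1.0, h=0, z=0.0)
    z, p = stats.ranksums(a, b)
    return WilcoxonResult(p_value=float(p), h=int(p < level), z=float(z))


def _load_experiment_dataset(cfg: ExperimentConfig):
    if cfg.dataset_path is not None:
        ds = load_dataset(cfg.dataset_path, cfg.label_column, cfg.positive_label)
        return minmax_normalize(ds), None
    ds, planted = generate_synthetic(cfg.synthetic)
    return ds, planted


def _single_run(dataset: Dataset, cfg: ExperimentConfig, variant: str, run_index: int):
    opt_cfg = OptimizerConfig(
        n_wolves=cfg.n_wolves,
        n_iterations=cfg.n_iterations,
        omega=cfg.omega,
        variant=variant,
        seed=run_seed(cfg.base_seed, variant, run_index, "opt"),
    )
    fit_cfg = FitnessConfig(
        alpha=cfg.alpha,
        knn_k=cfg.knn_k,
        folds=cfg.folds,
        cv_seed=run_seed(cfg.base_seed, variant, run_index, "cv"),
    )
    evaluator = MaskEvaluator(dataset, fit_cfg)
    trace = run_optimizer(dataset, opt_cfg, evaluator)
    # reported metrics come from a fresh CV pass, not the fitness cache
    metrics = evaluator.metrics(trace.best_mask)
    record = {
        "variant": variant,
        "run": run_index,
        "seed": opt_cfg.seed,
        "accuracy": metrics.accuracy,
        "precision": metrics.precision,
        "recall": metrics.recall,
        "f_measure": metrics.f_measure,
        "selected_features": metrics.selected_features,
        "fitness": trace.best_fitness,
    }
    return record, trace


def _summary_text(summaries, comparisons):
    lines = []
    header = (
        f"{'Algorithm':<10}{'Max':>8}{'Min':>8}{'AvgAcc':>16}"
        f"{'AvgSF':>10}{'AvgPre':>8}{'AvgRec':>8}{'AvgF':>8}"
    )
    lines.append(header)
    for s in summaries:
        lines.append(
            f"{s.variant:<10}{s.max_acc:>8.3f}{s.min_acc:>8.3f}"
            f"{s.avg_acc:>9.3f} +- {s.sd_acc:.3f}"
            f"{s.avg_sf:>10.1f}{s.avg_pre:>8.3f}{s.avg_rec:>8.3f}{s.avg_f:>8.3f}"
        )
    if comparisons:
        lines.append("")
        lines.append("Wilcoxon rank sum test at 5% significance level")
        lines.append(f"{'Comparison':<24}{'p value':>12}{'h':>4}{'z':>10}")
        for name, res in comparisons.items():
            lines.append(
                f"{name:<24}{res.p_value:>12.4e}{res.h:>4}{res.z:>10.4f}"
            )
    return "\n".join(lines) + "\n"


def run_experiment(cfg: ExperimentConfig):
    """Execute the full protocol and write report files.

    Writes into ``cfg.out_dir``:

    * ``runs.csv`` — one row per (variant, run) with the re-evaluated
      metrics of the best mask;
    * ``summary.json`` — per-variant aggregates, pairwise Wilcoxon
      results, convergence traces and (for synthetic data) planted-
      feature recovery;
    * ``summary.txt`` — human-readable benchmark table plus the
      Wilcoxon block;
    * ``boxplot.png`` — optional, when ``cfg.boxplot`` is set.

    Output is a pure function of the config, so reruns are
    byte-identical.  Returns the summary dictionary.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise ValueError(f"output directory {out} is unusable")

    dataset, planted = _load_experiment_dataset(cfg)

    records, traces = [], {}
    for variant in cfg.variants:
        for i in range(cfg.runs):
            rec, trace = _single_run(dataset, cfg, variant, i)
            if planted is not None:
                hits = int(np.asarray(trace.best_mask)[planted].sum())
                rec["planted_recovered"] = hits
            records.append(rec)
            traces[(variant, i)] = trace

    df = pd.DataFrame.from_records(records)
    df.to_csv(out / "runs.csv", index=False)

    summaries = [
        average_runs([r for r in records if r["variant"] == v])
        for v in cfg.variants
    ]
    comparisons = {}
    baseline = cfg.variants[0]
    acc_by_variant = {
        v: [r["accuracy"] for r in records if r["variant"] == v]
        for v in cfg.variants
    }
    for v in cfg.variants[1:]:
        comparisons[f"{v} vs. {baseline}"] = wilcoxon_compare(
            acc_by_variant[v], acc_by_variant[baseline]
        )

    summary = {
        "config": {
            **{k: v for k, v in asdict(cfg).items() if k != "synthetic"},
            "synthetic": asdict(cfg.synthetic) if cfg.synthetic else None,
        },
        "variants": {s.variant: asdict(s) for s in summaries},
        "wilcoxon": {k: asdict(v) for k, v in comparisons.items()},
        "convergence": {
            f"{v}:{i}": traces[(v, i)].convergence.tolist()
            for v in cfg.variants
            for i in range(cfg.runs)
        },
    }
    if planted is not None:
        summary["planted_indices"] = [int(i) for i in planted]

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    (out / "summary.txt").write_text(_summary_text(summaries, comparisons))

    if cfg.boxplot:
        _boxplot(records, cfg.variants, out / "boxplot.png")
    return summary


def _boxplot(records, variants, path):
    """Optional per-variant accuracy box plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = [
        [r["accuracy"] for r in records if r["variant"] == v] for v in variants
    ]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(data, tick_labels=list(variants))
    ax.set_ylabel("CV accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
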