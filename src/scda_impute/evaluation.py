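"""Masked-entry scoring, repeated-split benchmarking and the architecture
sweep.

The experimental design: a fully observed genotype matrix is corrupted by
masking a fraction of entries to the missing code, split sample-wise
65/15/20 into train/validation/test, every method completes the corrupted
test split, and accuracy is the fraction of *masked* test entries whose
imputed class equals the held-out truth. Each (method, missing level) cell
is repeated with fresh masking/splitting seeds and summarised by mean and
standard deviation, plus a "total" row averaging the per-level results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import (
    KNNConfig,
    SVDConfig,
    impute_column_central,
    impute_knn,
    impute_svd_em,
)
from .genotype_io import (
    GenotypeMatrix,
    ImputationResult,
    MaskIndex,
    SplitSpec,
    mask_random,
    split_indices,
)
from .model import SCDAConfig, TrainConfig, build_model, impute, train
from .simulate import CrossSimConfig, PopSimConfig, simulate_cross, simulate_population

logger = logging.getLogger(__name__)

__all__ = [
    "EvalSummary",
    "SweepResult",
    "SplitBundle",
    "masked_accuracy",
    "run_experiment",
    "sweep_architecture",
    "report",
    "ColumnCentralMethod",
    "KNNMethod",
    "SVDMethod",
    "SCDAMethod",
    "OracleMethod",
]


def masked_accuracy(
    result: ImputationResult, truth: GenotypeMatrix, mask: MaskIndex
) -> float:
    """Fraction of masked coordinates imputed to the true class."""
    if len(mask) == 0:
        raise ValueError("mask is empty; accuracy undefined")
    i, j = mask.coords[:, 0], mask.coords[:, 1]
    pred = result.completed.values[i, j]
    true = truth.values[i, j]
    return float((pred == true).mean())


@dataclass
class EvalSummary:
    """Mean/sd of masked accuracy over repeated runs of one method at one
    missing level. ``missing_level=None`` marks the cross-level total row,
    whose mean and sd are the unweighted averages of the per-level means
    and sds (caption semantics), not moments of the pooled run list."""

    method: str
    missing_level: float | None
    n_repeats: int
    mean_accuracy: float
    sd_accuracy: float
    per_run_accuracies: list[float] = field(default_factory=list)

    @classmethod
    def from_runs(
        cls, method: str, missing_level: float, accs: list[float]
    ) -> "EvalSummary":
        a = np.asarray(accs, dtype=float)
        return cls(
            method=method,
            missing_level=missing_level,
            n_repeats=len(a),
            mean_accuracy=float(a.mean()),
            sd_accuracy=float(a.std(ddof=0)) if len(a) > 1 else 0.0,
            per_run_accuracies=[float(x) for x in a],
        )


@dataclass
class SweepResult:
    """Validation accuracies over an architecture grid."""

    entries: list[dict]
    best: dict


@dataclass
class SplitBundle:
    """Everything one repeat of the experiment hands to a method."""

    train_corrupted: GenotypeMatrix
    train_clean: GenotypeMatrix
    val_corrupted: GenotypeMatrix
    val_clean: GenotypeMatrix
    test_corrupted: GenotypeMatrix
    test_clean: GenotypeMatrix
    test_mask: MaskIndex


# ---------------------------------------------------------------------------
# Method plug-ins: corrupted matrix in, ImputationResult out
# ---------------------------------------------------------------------------

class ImputationMethod:
    """Uniform interface the harness drives for SCDA and the baselines."""

    name: str = "base"

    def run(self, bundle: SplitBundle, seed: int) -> ImputationResult:
        raise NotImplementedError


class ColumnCentralMethod(ImputationMethod):
    def __init__(self, statistic: str = "mode"):
        self.statistic = statistic
        self.name = f"column_{statistic}"

    def run(self, bundle: SplitBundle, seed: int) -> ImputationResult:
        return impute_column_central(bundle.test_corrupted, self.statistic)


class KNNMethod(ImputationMethod):
    def __init__(self, cfg: KNNConfig = KNNConfig()):
        self.cfg = cfg
        self.name = "knn"

    def run(self, bundle: SplitBundle, seed: int) -> ImputationResult:
        return impute_knn(bundle.test_corrupted, self.cfg)


class SVDMethod(ImputationMethod):
    def __init__(self, cfg: SVDConfig = SVDConfig()):
        self.cfg = cfg
        self.name = "svd"

    def run(self, bundle: SplitBundle, seed: int) -> ImputationResult:
        return impute_svd_em(bundle.test_corrupted, self.cfg)


class SCDAMethod(ImputationMethod):
    """Trains the denoising autoencoder on the corrupted→clean training
    split and imputes the corrupted test split."""

    def __init__(
        self,
        cfg: SCDAConfig = SCDAConfig(),
        tcfg: TrainConfig = TrainConfig(),
    ):
        self.cfg = cfg
        self.tcfg = tcfg
        self.name = "scda"

    def run(self, bundle: SplitBundle, seed: int) -> ImputationResult:
        from dataclasses import replace

        model = build_model(
            self.cfg,
            bundle.train_corrupted.n_markers,
            bundle.train_corrupted.n_classes,
            seed=seed,
        )
        tcfg = replace(self.tcfg, seed=seed)
        train(
            model,
            (bundle.train_corrupted, bundle.train_clean),
            (bundle.val_corrupted, bundle.val_clean),
            tcfg,
        )
        return impute(model, bundle.test_corrupted)


class OracleMethod(ImputationMethod):
    """Reads the held-out truth; the accuracy upper bound for harness tests."""

    name = "oracle"

    def run(self, bundle: SplitBundle, seed: int) -> ImputationResult:
        completed = bundle.test_clean.copy()
        return ImputationResult(completed)


# ---------------------------------------------------------------------------
# Repeated-split experiment
# ---------------------------------------------------------------------------

def _resolve_data(data_source) -> GenotypeMatrix:
    if isinstance(data_source, GenotypeMatrix):
        return data_source
    if isinstance(data_source, CrossSimConfig):
        return simulate_cross(data_source)
    if isinstance(data_source, PopSimConfig):
        return simulate_population(data_source)
    raise TypeError(f"unsupported data source {type(data_source).__name__}")


def make_bundle(
    gm: GenotypeMatrix, missing_level: float, mask_seed: int, split: SplitSpec
) -> SplitBundle:
    """Mask the full matrix, split sample-wise, restrict the mask to the
    test rows (renumbered to the subset)."""
    corrupted, mask = mask_random(gm, missing_level, mask_seed)
    idx_tr, idx_va, idx_te = split_indices(gm.n_samples, split)
    return SplitBundle(
        train_corrupted=corrupted.take_samples(idx_tr),
        train_clean=gm.take_samples(idx_tr),
        val_corrupted=corrupted.take_samples(idx_va),
        val_clean=gm.take_samples(idx_va),
        test_corrupted=corrupted.take_samples(idx_te),
        test_clean=gm.take_samples(idx_te),
        test_mask=mask.restrict_rows(idx_te),
    )


def run_experiment(
    data_source,
    methods: list[ImputationMethod],
    missing_levels: list[float] | None = None,
    n_repeats: int = 10,
    base_seed: int = 0,
    split: SplitSpec | None = None,
) -> list[EvalSummary]:
    """Repeated-split benchmark of every method at every missing level.

    For each (method, level, repeat) a repeat seed ``base_seed + repeat``
    drives masking and the 65/15/20 sample split; methods see identical
    bundles within a repeat. Masked accuracy is scored on the test split
    only. Per-level summaries are followed by one "total" row per method
    averaging the per-level means and sds. Failed runs are excluded from
    the summary with a warning.
    """
    missing_levels = missing_levels or [0.05, 0.10, 0.20]
    gm = _resolve_data(data_source)
    accs: dict[tuple[str, float], list[float]] = {
        (m.name, lv): [] for m in methods for lv in missing_levels
    }
    for li, level in enumerate(missing_levels):
        for repeat in range(n_repeats):
            seed_r = base_seed + repeat
            mask_seed = seed_r * 1009 + li
            bundle = make_bundle(gm, level, mask_seed, SplitSpec(seed=seed_r))
            for method in methods:
                try:
                    result = method.run(bundle, seed=mask_seed + 31)
                    acc = masked_accuracy(result, bundle.test_clean, bundle.test_mask)
                except Exception:
                    logger.warning(
                        "method %s failed at level %.2f repeat %d",
                        method.name,
                        level,
                        repeat,
                        exc_info=True,
                    )
                    continue
                accs[(method.name, level)].append(acc)
                logger.info(
                    "%s level=%.2f repeat=%d accuracy=%.4f",
                    method.name,
                    level,
                    repeat,
                    acc,
                )
    summaries: list[EvalSummary] = []
    for method in methods:
        per_level = [
            EvalSummary.from_runs(method.name, lv, accs[(method.name, lv)])
            for lv in missing_levels
            if accs[(method.name, lv)]
        ]
        summaries.extend(per_level)
        if per_level:
            all_runs = [a for s in per_level for a in s.per_run_accuracies]
            summaries.append(
                EvalSummary(
                    method=method.name,
                    missing_level=None,
                    n_repeats=len(all_runs),
                    mean_accuracy=float(
                        np.mean([s.mean_accuracy for s in per_level])
                    ),
                    sd_accuracy=float(np.mean([s.sd_accuracy for s in per_level])),
                    per_run_accuracies=all_runs,
                )
            )
    return summaries


# ---------------------------------------------------------------------------
# Architecture sweep
# ---------------------------------------------------------------------------

def _hidden_for_depth(grid: tuple[int, ...], depth: str) -> tuple[int, ...]:
    """A seven-layer hidden 5-tuple (a, b, c, c, b) maps to (a, b, a) for
    the five-layer variant."""
    if depth == "seven_layer":
        return grid
    return (grid[0], grid[1], grid[0])


def sweep_architecture(
    bundle: SplitBundle,
    depths: tuple[str, ...] = ("five_layer", "seven_layer"),
    filter_sizes: tuple[int, ...] = tuple(range(3, 20, 2)),
    kernel_grids: tuple[tuple[int, ...], ...] = ((32, 64, 128, 128, 64),),
    tcfg: TrainConfig = TrainConfig(max_epochs=20, early_stop_patience=5),
    base_seed: int = 0,
) -> SweepResult:
    """Grid search over depth × filter size × kernel counts.

    Each grid point trains at the (reduced) epoch budget of ``tcfg`` and is
    scored by masked accuracy on the validation split. Failures are
    recorded with NaN accuracy. The best entry is the accuracy argmax
    (first on ties).
    """
    from .genotype_io import MaskIndex as _MI

    val_miss = (bundle.val_corrupted.values == 0) & (bundle.val_clean.values > 0)
    vi, vj = np.nonzero(val_miss)
    if len(vi) == 0:
        raise ValueError("validation split has no masked entries to score")
    val_mask = _MI(
        np.stack([vi, vj], axis=1), bundle.val_clean.values[vi, vj], 0.0
    )
    entries: list[dict] = []
    for depth in depths:
        for grid in kernel_grids:
            hidden = _hidden_for_depth(tuple(grid), depth)
            for k in filter_sizes:
                cfg = SCDAConfig(
                    kernel_counts=hidden, filter_size=k, depth_variant=depth
                )
                entry = {
                    "depth_variant": depth,
                    "filter_size": k,
                    "kernel_counts": hidden,
                    "val_accuracy": float("nan"),
                }
                try:
                    model = build_model(
                        cfg,
                        bundle.train_corrupted.n_markers,
                        bundle.train_corrupted.n_classes,
                        seed=base_seed,
                    )
                    train(
                        model,
                        (bundle.train_corrupted, bundle.train_clean),
                        (bundle.val_corrupted, bundle.val_clean),
                        tcfg,
                    )
                    result = impute(model, bundle.val_corrupted)
                    entry["val_accuracy"] = masked_accuracy(
                        result, bundle.val_clean, val_mask
                    )
                except Exception:
                    logger.warning("sweep point %s failed", entry, exc_info=True)
                entries.append(entry)
    scored = [e for e in entries if np.isfinite(e["val_accuracy"])]
    if not scored:
        raise RuntimeError("every sweep grid point failed")
    best = max(scored, key=lambda e: e["val_accuracy"])
    return SweepResult(entries=entries, best=best)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report(
    summaries: list[EvalSummary], out_dir: str | Path, plot: bool = False
) -> Path:
    """Write the summary CSV (one row per method × level plus a total row
    per method) and optionally a violin plot of per-run accuracies.

    Returns the CSV path.
    """
    if not summaries:
        raise ValueError("no summaries to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    totals = {
        s.method: (s.mean_accuracy, s.sd_accuracy)
        for s in summaries
        if s.missing_level is None
    }
    rows = []
    for s in summaries:
        tot = totals.get(s.method, (float("nan"), float("nan")))
        rows.append(
            {
                "method": s.method,
                "level": "total" if s.missing_level is None else s.missing_level,
                "mean": s.mean_accuracy,
                "sd": s.sd_accuracy,
                "total_mean": tot[0],
                "total_sd": tot[1],
            }
        )
    csv_path = out_dir / "summary.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if plot:
        _violin_plot(summaries, out_dir / "accuracy_violin.png")
    return csv_path


def _violin_plot(summaries: list[EvalSummary], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    per_method: dict[str, list[float]] = {}
    for s in summaries:
        if s.missing_level is not None:
            per_method.setdefault(s.method, []).extend(s.per_run_accuracies)
    fig, ax = plt.subplots(figsize=(1.5 * len(per_method) + 2, 4))
    names = list(per_method)
    ax.violinplot([per_method[n] for n in names], showmedians=True)
    ax.set_xticks(range(1, len(names) + 1), names)
    ax.set_ylabel("masked-entry accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
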