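"""Scoring, the repeated-split harness, the sweep and reporting."""

import numpy as np
import pandas as pd
import pytest

from scda_impute.evaluation import (
    ColumnCentralMethod,
    EvalSummary,
    ImputationMethod,
    KNNMethod,
    OracleMethod,
    make_bundle,
    masked_accuracy,
    report,
    run_experiment,
    sweep_architecture,
)
from scda_impute.genotype_io import (
    GenotypeMatrix,
    ImputationResult,
    MaskIndex,
    SplitSpec,
)
from scda_impute.model import TrainConfig
from scda_impute.simulate import CrossSimConfig, simulate_cross


class NoisyStub(ImputationMethod):
    """Imputes randomly; accuracy varies between repeats (harness tests)."""

    name = "noisy_stub"

    def run(self, bundle, seed):
        r = np.random.default_rng(seed)
        completed = bundle.test_corrupted.copy()
        miss = completed.values == 0
        completed.values[miss] = r.integers(
            1, completed.n_classes + 1, size=int(miss.sum())
        )
        return ImputationResult(completed)


class FailingStub(ImputationMethod):
    name = "failing_stub"

    def run(self, bundle, seed):
        raise RuntimeError("always fails")


class TestMaskedAccuracy:
    def test_counting(self):
        truth = GenotypeMatrix(np.arange(1, 13).reshape(2, 6) % 3 + 1, 3)
        completed = truth.copy()
        coords = np.array([[0, j] for j in range(6)] + [[1, j] for j in range(4)])
        # corrupt 3 of the 10 masked coordinates
        for i, j in coords[:3]:
            completed.values[i, j] = completed.values[i, j] % 3 + 1
        mask = MaskIndex(coords, truth.values[coords[:, 0], coords[:, 1]], 0.1)
        acc = masked_accuracy(ImputationResult(completed), truth, mask)
        assert acc == pytest.approx(0.7)

    def test_perfect_and_worst_case(self):
        truth = GenotypeMatrix(np.ones((3, 4), dtype=int), 2, ploidy_mode="cross")
        mask = MaskIndex(np.array([[0, 0], [1, 1]]), np.array([1, 1]), 0.1)
        perfect = masked_accuracy(ImputationResult(truth.copy()), truth, mask)
        assert perfect == 1.0
        wrong = truth.copy()
        wrong.values[0, 0] = 2
        wrong.values[1, 1] = 2
        assert masked_accuracy(ImputationResult(wrong), truth, mask) == 0.0

    def test_empty_mask_rejected(self):
        truth = GenotypeMatrix(np.ones((2, 2), dtype=int), 2, ploidy_mode="cross")
        empty = MaskIndex(np.empty((0, 2), dtype=int), np.empty(0, dtype=int), 0.1)
        with pytest.raises(ValueError):
            masked_accuracy(ImputationResult(truth.copy()), truth, empty)


@pytest.fixture(scope="module")
def data():
    return simulate_cross(CrossSimConfig(40, 32, 0.05, seed=3))


class TestRunExperiment:

    def test_oracle_scores_one_with_zero_sd(self, data):
        summaries = run_experiment(
            data, [OracleMethod()], [0.05, 0.10, 0.20], n_repeats=3, base_seed=1
        )
        per_level = [s for s in summaries if s.missing_level is not None]
        assert len(per_level) == 3
        for s in per_level:
            assert s.mean_accuracy == 1.0
            assert s.sd_accuracy == 0.0
            assert s.n_repeats == 3

    def test_total_row_averages_level_means_and_sds(self, data):
        summaries = run_experiment(
            data, [NoisyStub()], [0.05, 0.10, 0.20], n_repeats=4, base_seed=2
        )
        per_level = [s for s in summaries if s.missing_level is not None]
        total = [s for s in summaries if s.missing_level is None]
        assert len(total) == 1
        t = total[0]
        assert t.mean_accuracy == pytest.approx(
            np.mean([s.mean_accuracy for s in per_level])
        )
        assert t.sd_accuracy == pytest.approx(
            np.mean([s.sd_accuracy for s in per_level])
        )
        assert t.n_repeats == 12

    def test_single_repeat_has_zero_sd(self, data):
        summaries = run_experiment(
            data, [NoisyStub()], [0.10], n_repeats=1, base_seed=0
        )
        assert all(s.sd_accuracy == 0.0 for s in summaries)

    def test_summary_moments_match_run_list(self, data):
        summaries = run_experiment(
            data, [NoisyStub()], [0.10], n_repeats=5, base_seed=3
        )
        s = [x for x in summaries if x.missing_level is not None][0]
        a = np.asarray(s.per_run_accuracies)
        assert s.mean_accuracy == pytest.approx(a.mean(), abs=1e-12)
        assert s.sd_accuracy == pytest.approx(a.std(), abs=1e-12)

    def test_deterministic_for_deterministic_methods(self, data):
        kwargs = dict(missing_levels=[0.1], n_repeats=2, base_seed=7)
        s1 = run_experiment(data, [ColumnCentralMethod("mode"), KNNMethod()], **kwargs)
        s2 = run_experiment(data, [ColumnCentralMethod("mode"), KNNMethod()], **kwargs)
        for a, b in zip(s1, s2):
            assert a.per_run_accuracies == b.per_run_accuracies

    def test_failed_method_excluded_with_surviving_methods_reported(self, data):
        summaries = run_experiment(
            data,
            [FailingStub(), OracleMethod()],
            [0.10],
            n_repeats=2,
            base_seed=0,
        )
        names = {s.method for s in summaries}
        assert "oracle" in names and "failing_stub" not in names


class TestSweep:
    def test_grid_cardinality_and_best_membership(self):
        gm = simulate_cross(CrossSimConfig(150, 64, 0.02, seed=5))
        bundle = make_bundle(gm, 0.10, mask_seed=1, split=SplitSpec(seed=2))
        result = sweep_architecture(
            bundle,
            depths=("five_layer", "seven_layer"),
            filter_sizes=(3, 5),
            kernel_grids=((8, 12, 16, 16, 12),),
            tcfg=TrainConfig(
                max_epochs=10, early_stop_patience=10, seed=0, learning_rate=3e-3
            ),
        )
        assert len(result.entries) == 4
        assert result.best in result.entries
        accs = [e["val_accuracy"] for e in result.entries]
        assert np.isfinite(accs).all()
        # easy cross data: every grid point beats per-column majority
        from scda_impute.baselines import impute_column_central

        base = impute_column_central(bundle.val_corrupted, "mode")
        vm = (bundle.val_corrupted.values == 0) & (bundle.val_clean.values > 0)
        vi, vj = np.nonzero(vm)
        mode_acc = (
            base.completed.values[vi, vj] == bundle.val_clean.values[vi, vj]
        ).mean()
        assert min(accs) > mode_acc


class TestReport:
    def _summaries(self):
        out = []
        for m in ("a", "b", "c", "d"):
            means = []
            sds = []
            for lv in (0.05, 0.10, 0.20):
                s = EvalSummary.from_runs(m, lv, [0.5, 0.6, 0.7])
                out.append(s)
                means.append(s.mean_accuracy)
                sds.append(s.sd_accuracy)
            out.append(
                EvalSummary(m, None, 9, float(np.mean(means)), float(np.mean(sds)))
            )
        return out

    def test_csv_shape_and_roundtrip(self, tmp_path):
        path = report(self._summaries(), tmp_path)
        df = pd.read_csv(path)
        assert len(df) == 4 * (3 + 1)
        in_memory = {
            (s.method, "total" if s.missing_level is None else s.missing_level):
                s.mean_accuracy
            for s in self._summaries()
        }
        for _, row in df.iterrows():
            lv = row["level"] if row["level"] == "total" else float(row["level"])
            assert row["mean"] == in_memory[(row["method"], lv)]

    def test_empty_summaries_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            report([], tmp_path)
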