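"""Training loop and cross-validation protocols (reduced budgets)."""

import numpy as np
import pytest

from artmech import DomainError
from artmech.synthdata import CohortConfig, make_cohort
from artmech.trainer import (
    CVResult,
    FoldResult,
    Split,
    TrainConfig,
    _FoldData,
    loo_cv_full,
    make_batches,
    mse_loss,
    train_once,
    train_with_restarts,
)


@pytest.fixture(scope="module")
def tiny_cohort():
    config = CohortConfig(n_samples=5, seed=2)
    samples, truths = make_cohort(config)
    return {s.sample_id: s for s in samples}


def tiny_split(samples_by_id):
    ids = sorted(samples_by_id)
    return Split(train_ids=tuple(ids[:-2]), test_id=ids[-2],
                 validation_id=ids[-1])


class TestMseLoss:
    def test_perfect_prediction(self):
        assert mse_loss([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_mean_convention(self):
        assert abs(mse_loss([1.0, 2.0], [1.0, 3.0]) - 0.5) < 1e-15

    def test_order_invariance(self):
        a = mse_loss([1.0, 2.0, 5.0], [0.0, 4.0, 5.0])
        b = mse_loss([5.0, 1.0, 2.0], [5.0, 0.0, 4.0])
        assert a == b

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            mse_loss([1.0], [1.0, 2.0])


class TestMakeBatches:
    def test_partition_sizes(self):
        rng = np.random.default_rng(0)
        sizes = [len(b) for b in make_batches(100, rng)]
        assert sizes == [32, 32, 32, 4]

    def test_seed_reproducibility(self):
        b1 = make_batches(100, np.random.default_rng(5))
        b2 = make_batches(100, np.random.default_rng(5))
        assert all(np.array_equal(x, y) for x, y in zip(b1, b2))

    def test_conservation(self):
        batches = make_batches(77, np.random.default_rng(1))
        union = np.sort(np.concatenate(batches))
        np.testing.assert_array_equal(union, np.arange(77))


class TestTrainConfig:
    def test_published_defaults(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 0.001
        assert cfg.epochs == 1000
        assert cfg.batch_size == 32
        assert cfg.restarts == 10

    def test_positivity_enforced(self):
        with pytest.raises(DomainError):
            TrainConfig(epochs=0)


class TestSplit:
    def test_no_overlap_allowed(self):
        with pytest.raises(DomainError):
            Split(train_ids=("a", "b"), test_id="a", validation_id="c")


class TestFoldData:
    def test_augmentation_expands_pairs(self, tiny_cohort):
        split = tiny_split(tiny_cohort)
        cfg = TrainConfig(epochs=1, restarts=1, aug_copies=4)
        rng = np.random.default_rng(0)
        data = _FoldData(tiny_cohort, split, cfg, rng)
        n_train = len(split.train_ids)
        assert data.n_copies == n_train * 4
        pairs_per_sample = sum(len(c) for c in
                               tiny_cohort[split.train_ids[0]].curves)
        assert data.n_pairs == sum(
            4 * sum(len(c) for c in tiny_cohort[sid].curves)
            for sid in split.train_ids)

    def test_validation_sample_absent(self, tiny_cohort):
        split = tiny_split(tiny_cohort)
        cfg = TrainConfig(epochs=1, restarts=1, aug_copies=2)
        data = _FoldData(tiny_cohort, split, cfg, np.random.default_rng(0))
        assert split.validation_id not in data.copy_sample_ids
        assert split.test_id not in data.copy_sample_ids


class TestTrainOnce:
    def test_epoch_log_and_descent(self, tiny_cohort):
        split = tiny_split(tiny_cohort)
        cfg = TrainConfig(epochs=4, restarts=1, aug_copies=2, master_seed=0)
        state = train_once(tiny_cohort, split, cfg, init_seed=3, batch_seed=5)
        assert len(state.epoch_log) == 4
        assert 1 <= state.best_epoch <= 4
        losses = [e[1] for e in state.epoch_log]
        assert losses[-1] < losses[0]   # training reduces the loss

    def test_determinism(self, tiny_cohort):
        split = tiny_split(tiny_cohort)
        cfg = TrainConfig(epochs=3, restarts=1, aug_copies=2, master_seed=0)
        s1 = train_once(tiny_cohort, split, cfg, init_seed=3, batch_seed=5)
        s2 = train_once(tiny_cohort, split, cfg, init_seed=3, batch_seed=5)
        assert s1.epoch_log == s2.epoch_log
        assert s1.best_epoch == s2.best_epoch


class TestTrainWithRestarts:
    def test_restart_selection_by_validation_metric(self, tiny_cohort,
                                                    monkeypatch):
        from artmech import trainer as tr

        split = tiny_split(tiny_cohort)
        cfg = TrainConfig(epochs=2, restarts=3, aug_copies=2, master_seed=1)
        metrics = iter([0.2, 0.9, 0.5])

        def fake_eval(net, sample, fs):
            if net.n_lanes > 1:     # per-epoch test eval during training
                return np.zeros(net.n_lanes)
            return np.array([next(metrics)])

        monkeypatch.setattr(tr, "_eval_sample_r2", fake_eval)
        best, states = train_with_restarts(tiny_cohort, split, cfg,
                                           fold_seed=4)
        assert states.index(best) == 1
        assert [round(s.validation_r2, 1) for s in states] == [0.2, 0.9, 0.5]

    def test_derived_seeds_distinct_and_reproducible(self, tiny_cohort):
        split = tiny_split(tiny_cohort)
        cfg = TrainConfig(epochs=2, restarts=2, aug_copies=2, master_seed=1)
        b1, s1 = train_with_restarts(tiny_cohort, split, cfg, fold_seed=11)
        b2, s2 = train_with_restarts(tiny_cohort, split, cfg, fold_seed=11)
        assert [x.best_test_r2 for x in s1] == [x.best_test_r2 for x in s2]
        assert s1[0].best_test_r2 != s1[1].best_test_r2  # different inits


class TestLooCvFull:
    def test_one_fold_per_sample_and_leakage_flags(self):
        config = CohortConfig(n_samples=3, seed=6)
        samples, _ = make_cohort(config)
        cfg = TrainConfig(epochs=2, restarts=1, aug_copies=2, master_seed=2)
        cv = loo_cv_full(samples, cfg)
        assert len(cv.folds) == 3
        assert {f.validation_id for f in cv.folds} == \
            {s.sample_id for s in samples}
        assert cv.leakage_checked
        assert "early stopping" in cv.leakage_note
        for f in cv.folds:
            assert f.test_id == f.validation_id   # data-rich mimicry


class TestLooCvRoi:
    class _Fit:
        def __init__(self, c, k1, k2):
            from artmech import MaterialParams

            self.params = MaterialParams(c, k1, k2)

    def test_folds_iterate_over_roi_members_only(self):
        # craft fitted latent points: 3 clustered at (1,1,1) decades, 3 far
        config = CohortConfig(n_samples=6, seed=3)
        samples, _ = make_cohort(config)
        ids = sorted(s.sample_id for s in samples)
        fits = {ids[0]: self._Fit(10, 10, 10),
                ids[1]: self._Fit(11, 11, 11),
                ids[2]: self._Fit(9, 9, 9),
                ids[3]: self._Fit(1000, 1000, 1000),
                ids[4]: self._Fit(0.01, 0.01, 0.01),
                ids[5]: self._Fit(1000, 0.01, 1000)}
        from artmech.trainer import loo_cv_roi

        cfg = TrainConfig(epochs=2, restarts=1, aug_copies=2, master_seed=0)
        cv = loo_cv_roi(samples, cfg, fits=fits)
        assert {f.validation_id for f in cv.folds} == set(ids[:3])
        assert all(f.validation_id not in (f.test_id,) for f in cv.folds)

    def test_max_folds_keeps_most_central(self):
        config = CohortConfig(n_samples=6, seed=3)
        samples, _ = make_cohort(config)
        ids = sorted(s.sample_id for s in samples)
        fits = {ids[0]: self._Fit(10, 10, 10),
                ids[1]: self._Fit(12, 12, 12),
                ids[2]: self._Fit(30, 30, 30),   # inside but least central
                ids[3]: self._Fit(1000, 1000, 1000),
                ids[4]: self._Fit(0.01, 0.01, 0.01),
                ids[5]: self._Fit(1000, 0.01, 1000)}
        from artmech.trainer import loo_cv_roi

        cfg = TrainConfig(epochs=2, restarts=1, aug_copies=2, master_seed=0)
        cv = loo_cv_roi(samples, cfg, fits=fits, max_folds=2)
        assert {f.validation_id for f in cv.folds} == set(ids[:2])

    def test_empty_roi_rejected(self):
        config = CohortConfig(n_samples=2, seed=3)
        samples, _ = make_cohort(config)
        ids = sorted(s.sample_id for s in samples)
        fits = {ids[0]: self._Fit(1e-3, 1e-3, 1e-3),
                ids[1]: self._Fit(1e3, 1e3, 1e3)}
        from artmech.trainer import loo_cv_roi

        cfg = TrainConfig(epochs=2, restarts=1, aug_copies=2, master_seed=0)
        with pytest.raises(DomainError):
            loo_cv_roi(samples, cfg, fits=fits)


class TestCVResult:
    def _cv(self, values):
        return CVResult(strategy="roi", folds=[
            FoldResult(validation_id=f"s{i}", test_id="t", r2=v,
                       best_restart=0, best_epoch=1, restart_val_r2=[v])
            for i, v in enumerate(values)])

    def test_median_recomputable(self):
        cv = self._cv([0.2, 0.9, 0.5])
        assert cv.median_r2() == 0.5
        assert cv.per_fold_r2 == {"s0": 0.2, "s1": 0.9, "s2": 0.5}

    def test_exclusion_rule(self):
        cv = self._cv([0.9, -5.0, 0.8, -2.0])
        assert cv.n_excluded == 2
        assert cv.median_r2(exclude_below=-1.0) == pytest.approx(0.85)
        assert cv.median_r2() == pytest.approx(-0.6)
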