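"""Metrics arithmetic, the LR scheduler, and short training runs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apocvit.nn import Adam, Parameter
from apocvit.train_eval import (ConfusionCounts,
                                ReduceLROnPlateau, TrainConfig,
                                compute_metrics, confusion_from_predictions,
                                f1_from_pr)


class TestComputeMetrics:
    def test_reference_confusion_counts(self):
        # 96-positive test set: 92 hits, 1 false alarm, 4 misses
        m = compute_metrics(ConfusionCounts(tp=92, fp=1, fn=4, tn=95))
        assert (m.precision, m.recall, m.f1) == (98.92, 95.83, 97.35)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=10))
        assert (m.precision, m.recall, m.f1) == (100.0, 100.0, 100.0)
        assert not m.degenerate

    def test_no_positive_predictions_is_degenerate(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
        assert m.degenerate

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_f1_between_precision_and_recall(self, tp, fp, fn, tn):
        m = compute_metrics(ConfusionCounts(tp, fp, fn, tn))
        if m.precision_raw + m.recall_raw > 0:
            lo = min(m.precision_raw, m.recall_raw)
            hi = max(m.precision_raw, m.recall_raw)
            assert lo - 1e-9 <= m.f1_raw <= hi + 1e-9

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_counts_match_per_sample_recount(self, pairs):
        # oracle equivalence: brute-force per-sample counting
        y_true = np.array([a for a, _ in pairs])
        y_pred = np.array([b for _, b in pairs])
        c = confusion_from_predictions(y_true, y_pred)
        tp = sum(1 for t, p in pairs if t == 1 and p == 1)
        fp = sum(1 for t, p in pairs if t == 0 and p == 1)
        fn = sum(1 for t, p in pairs if t == 1 and p == 0)
        tn = sum(1 for t, p in pairs if t == 0 and p == 0)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
        assert c.total == len(pairs)

    def test_swapping_fp_fn_swaps_precision_and_recall(self):
        a = compute_metrics(ConfusionCounts(tp=30, fp=5, fn=9, tn=50))
        b = compute_metrics(ConfusionCounts(tp=30, fp=9, fn=5, tn=50))
        assert a.precision == b.recall and a.recall == b.precision
        assert a.f1 == b.f1


class TestF1FromPR:
    @pytest.mark.parametrize("p,r,expected", [
        (98.92, 95.83, 97.35),
        (96.88, 95.09, 95.98),
        (92.11, 93.96, 93.03),
        (75.30, 73.85, 74.57),
        (91.20, 89.60, 90.39),
        (93.45, 91.80, 92.62),
        (82.15, 80.90, 81.52),
    ])
    def test_published_style_pr_tables(self, p, r, expected):
        assert f1_from_pr(p, r) == expected

    def test_truncated_row_within_one_cent(self):
        # 2*88.75*86.20/(88.75+86.20) = 87.456: half-up rounding gives
        # 87.46, one cent above the commonly printed truncated 87.45
        assert f1_from_pr(88.75, 86.20) == 87.46
        assert abs(f1_from_pr(88.75, 86.20) - 87.45) <= 0.01

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_equal_pr_is_fixed_point(self, x):
        assert abs(f1_from_pr(x, x) - round(x, 2)) <= 0.005

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            f1_from_pr(0.0, 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f1_from_pr(101.0, 50.0)


class TestScheduler:
    def test_exactly_one_drop_at_epoch_seven(self):
        opt = Adam([Parameter(np.zeros(1))], lr=1.0)
        sched = ReduceLROnPlateau(opt, factor=0.1, patience=5)
        for v in [1.0, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9]:
            sched.step(v)
        assert sched.drops == [7]
        assert opt.lr == pytest.approx(0.1)

    def test_improvement_resets_patience(self):
        opt = Adam([Parameter(np.zeros(1))], lr=1.0)
        sched = ReduceLROnPlateau(opt, factor=0.1, patience=3)
        for v in [1.0, 0.9, 0.95, 0.95, 0.8, 0.9, 0.9, 0.9]:
            sched.step(v)
        assert sched.drops == [8]

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_drop_factor=1.5)


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_setup(self):
        from apocvit.experiments import build_experiment_data, small_config
        from apocvit.synthetic_data import SyntheticSpec
        cfg = small_config()
        spec = SyntheticSpec(n_pairs=24, seed=5)
        return cfg, build_experiment_data(spec, cfg, 5)

    def test_same_seed_identical_loss_history(self, tiny_setup):
        from apocvit.model import ApoCvit
        from apocvit.train_eval import train_model
        cfg, (tr, va, te) = tiny_setup
        histories = []
        for _ in range(2):
            model = ApoCvit(cfg, np.random.default_rng(9))
            tc = TrainConfig(batch_size=8, epochs=2, seed=9)
            _, hist = train_model(model, tr, va, tc)
            histories.append((hist.train_loss, hist.val_loss))
        assert histories[0] == histories[1]

    def test_loss_decreases_on_tiny_run(self, tiny_setup):
        from apocvit.model import ApoCvit
        from apocvit.train_eval import train_model
        cfg, (tr, va, te) = tiny_setup
        model = ApoCvit(cfg, np.random.default_rng(2))
        tc = TrainConfig(batch_size=8, epochs=4, seed=2)
        _, hist = train_model(model, tr, va, tc)
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert np.all(np.isfinite(hist.train_loss))

    def test_empty_split_rejected(self, tiny_setup):
        from apocvit.model import ApoCvit
        from apocvit.train_eval import ModelDataset, train_model
        cfg, (tr, va, te) = tiny_setup
        model = ApoCvit(cfg, np.random.default_rng(0))
        empty = ModelDataset(images=np.zeros((0, 32, 32)),
                             waves=np.zeros((0, 2000)),
                             labels=np.zeros(0, dtype=int))
        with pytest.raises(ValueError, match="empty"):
            train_model(model, empty, va, TrainConfig(epochs=1))

    def test_unknown_ablation_condition_rejected(self, tiny_setup):
        from apocvit.train_eval import run_ablation
        cfg, (tr, va, te) = tiny_setup
        with pytest.raises(ValueError, match="unknown condition"):
            run_ablation(["nonsense"], tr, va, te, TrainConfig(epochs=1))
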