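import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegid.augment import Segment, SegmentedDataset
from eegid.data_io import Session
from eegid.model import ModelConfig, build_model
from eegid.train_eval import (
    EvalReport,
    ScoreSet,
    TrainConfig,
    compute_eer,
    evaluate,
    rank1,
    score_claims,
    train,
)

CFG = ModelConfig(
    n_channels=4, n_points=16, n_classes=2, n_sources=4, conv_width=4,
    fc_width=8, dropout_p=0.5,
)


def _toy_dataset(n_per_class=20, n_classes=2, p=16, c=4, seed=0, offset=3.0):
    """Segments separable by a constant per-class offset a linear map finds."""
    rng = np.random.default_rng(seed)
    segments = []
    for k in range(n_classes):
        for _ in range(n_per_class):
            data = rng.normal(size=(p, c)) * 0.1 + k * offset
            segments.append(
                Segment(data, k, f"S{k + 1:03d}", Session.EO, 0)
            )
    label_map = {f"S{k + 1:03d}": k for k in range(n_classes)}
    return SegmentedDataset(segments, label_map)


class TestTrain:
    def test_loss_decreases_on_learnable_data(self, tmp_path):
        ds = _toy_dataset(seed=1)
        net = build_model(CFG, seed=1)
        res = train(net, ds, TrainConfig(epochs=15, batch_size=8, seed=1))
        assert res.trace[-1]["loss"] < res.trace[0]["loss"]
        res.trace_to_csv(tmp_path / "trace.csv")
        assert (tmp_path / "trace.csv").read_text().startswith("epoch,loss,")

    def test_separable_classes_reach_perfect_training_rank1(self):
        ds = _toy_dataset(seed=2)
        net = build_model(CFG, seed=2)
        train(net, ds, TrainConfig(epochs=30, batch_size=8, seed=2))
        assert rank1(net, ds) == 100.0

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError, match="epochs"):
            TrainConfig(epochs=0)

    def test_empty_dataset_rejected(self):
        net = build_model(CFG, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(net, SegmentedDataset([], {}), TrainConfig(epochs=1))

    def test_label_gap_rejected(self):
        ds = _toy_dataset(n_classes=3)
        ds.segments = [s for s in ds.segments if s.label != 1]  # drop class 1
        net = build_model(
            ModelConfig(n_channels=4, n_points=16, n_classes=3, n_sources=4,
                        conv_width=4, fc_width=8), seed=0)
        with pytest.raises(ValueError, match="missing"):
            train(net, ds, TrainConfig(epochs=1))

    def test_identical_seeds_give_identical_traces(self):
        ds = _toy_dataset(seed=3)
        r1 = train(build_model(CFG, seed=4), ds, TrainConfig(epochs=3, batch_size=8, seed=4))
        r2 = train(build_model(CFG, seed=4), ds, TrainConfig(epochs=3, batch_size=8, seed=4))
        assert r1.trace == r2.trace


class TestRank1:
    def test_equals_confusion_matrix_oracle(self):
        from sklearn.metrics import confusion_matrix

        ds = _toy_dataset(seed=5, offset=0.5)
        net = build_model(CFG, seed=5)
        train(net, ds, TrainConfig(epochs=5, batch_size=8, seed=5))
        x, y = ds.arrays()
        pred = net.predict_logp(x).argmax(axis=1)
        cm = confusion_matrix(y, pred, labels=[0, 1])
        accuracy = 100.0 * cm.trace() / cm.sum()
        assert rank1(net, ds) == pytest.approx(accuracy, abs=1e-9)
        assert rank1(net, ds) == pytest.approx(100.0 - (100.0 * (cm.sum() - cm.trace()) / cm.sum()), abs=1e-9)

    def test_uniform_scores_tie_break_to_lowest_class(self):
        """Zeroed output layer -> uniform posteriors; balanced 2-class test
        set then scores exactly 50% under the lowest-index tie-break."""
        ds = _toy_dataset(n_per_class=10, n_classes=2)
        net = build_model(CFG, seed=9)
        fc2 = net.stack.layers[-1]
        fc2.W.value[...] = 0
        fc2.b.value[...] = 0
        assert rank1(net, ds) == 50.0

    def test_extra_subject_in_test_set_rejected(self):
        ds = _toy_dataset(n_classes=3)
        net = build_model(CFG, seed=0)  # enrolled for 2 classes only
        with pytest.raises(ValueError, match="closed-set"):
            rank1(net, ds)


class TestScoreClaims:
    def test_counts_follow_all_claims_construction(self):
        ds = _toy_dataset(n_per_class=5, n_classes=3)
        cfg = ModelConfig(n_channels=4, n_points=16, n_classes=3, n_sources=4,
                          conv_width=4, fc_width=8)
        net = build_model(cfg, seed=6)
        s = score_claims(net, ds)
        assert s.genuine.size == 15
        assert s.impostor.size == 15 * 2

    def test_scores_per_segment_sum_to_one(self):
        ds = _toy_dataset(n_per_class=4, n_classes=3)
        cfg = ModelConfig(n_channels=4, n_points=16, n_classes=3, n_sources=4,
                          conv_width=4, fc_width=8)
        net = build_model(cfg, seed=7)
        s = score_claims(net, ds)
        imp = s.impostor.reshape(len(ds), 2)
        np.testing.assert_allclose(s.genuine + imp.sum(axis=1), 1.0, atol=1e-5)
        assert ((s.genuine >= 0) & (s.genuine <= 1)).all()


def eer_bruteforce(genuine, impostor):
    """Independent oracle: scan every candidate threshold in a Python loop and
    interpolate the FAR/FRR crossing from first principles."""
    cands = sorted(set(list(genuine) + list(impostor)))
    cands.append(cands[-1] + 1.0)
    pts = []
    for t in cands:
        far = 100.0 * sum(1 for s in impostor if s >= t) / len(impostor)
        frr = 100.0 * sum(1 for s in genuine if s < t) / len(genuine)
        pts.append((t, far, frr))
    for (t0, f0, r0), (t1, f1, r1) in zip(pts, pts[1:]):
        if f0 - r0 == 0:
            return f0
        if (f0 - r0) > 0 and (f1 - r1) <= 0:
            if f1 - r1 == 0:
                return f1
            a = (f0 - r0) / ((f0 - r0) - (f1 - r1))
            return f0 + a * (f1 - f0)
    return pts[-1][1]


class TestComputeEer:
    def test_perfect_separation_gives_zero(self):
        _, _, _, eer, _ = compute_eer(ScoreSet([1, 1, 1], [0, 0, 0]))
        assert eer == 0.0

    def test_identical_distributions_give_chance(self):
        rng = np.random.default_rng(0)
        vals = rng.random(400)
        _, _, _, eer, _ = compute_eer(ScoreSet(vals, vals.copy()))
        assert eer == pytest.approx(50.0, abs=1.0)

    def test_worked_example(self):
        s = ScoreSet([0.9, 0.8, 0.4], [0.5, 0.3, 0.1])
        _, _, _, eer, thr = compute_eer(s)
        assert eer == pytest.approx(100 / 3, abs=1e-9)
        assert thr == pytest.approx(0.5)

    @given(
        seed=st.integers(0, 10_000),
        ng=st.integers(2, 40),
        ni=st.integers(2, 60),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_sweep(self, seed, ng, ni):
        rng = np.random.default_rng(seed)
        gen = rng.beta(5, 2, size=ng)
        imp = rng.beta(2, 5, size=ni)
        _, _, _, eer, _ = compute_eer(ScoreSet(gen, imp))
        assert eer == pytest.approx(eer_bruteforce(gen, imp), abs=1e-9)

    def test_far_nonincreasing_frr_nondecreasing(self):
        rng = np.random.default_rng(1)
        s = ScoreSet(rng.random(300), rng.random(500))
        _, far, frr, _, _ = compute_eer(s)
        assert (np.diff(far) <= 1e-12).all()
        assert (np.diff(frr) >= -1e-12).all()

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_monotone_score_transform(self, seed):
        rng = np.random.default_rng(seed)
        gen = rng.beta(4, 2, size=25)
        imp = rng.beta(2, 4, size=30)
        _, _, _, eer0, _ = compute_eer(ScoreSet(gen, imp))
        f = lambda x: np.log1p(3 * x) ** 2  # strictly increasing on [0, 1]
        _, _, _, eer1, _ = compute_eer(ScoreSet(f(gen), f(imp)))
        assert eer1 == pytest.approx(eer0, abs=1e-9)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            compute_eer(ScoreSet([], [0.5]))


class TestEvaluateReport:
    def test_report_fields_and_det_points(self, tmp_path):
        ds = _toy_dataset(seed=8)
        net = build_model(CFG, seed=8)
        train(net, ds, TrainConfig(epochs=10, batch_size=8, seed=8))
        rep = evaluate(net, ds)
        assert 0 <= rep.rank1 <= 100
        assert 0 <= rep.eer <= 100
        assert rep.det_points.shape == (len(rep.thresholds), 2)
        rep.to_json(tmp_path / "summary.json")
        rep.curves_to_csv(tmp_path / "curves.csv")
        assert (tmp_path / "summary.json").exists()
        assert (tmp_path / "curves.csv").read_text().startswith("threshold,")

    def test_det_curve_renders_to_file(self, tmp_path):
        from eegid.train_eval import plot_det

        rng = np.random.default_rng(10)
        _, far, frr, eer, thr = compute_eer(
            ScoreSet(rng.beta(5, 2, 50), rng.beta(2, 5, 80))
        )
        rep = EvalReport(
            rank1=95.0, eer=eer, eer_threshold=thr,
            thresholds=np.zeros_like(far), far_curve=far, frr_curve=frr,
        )
        out = plot_det({"demo": rep}, tmp_path / "det.png")
        assert out.exists() and out.stat().st_size > 0
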