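"""AnoP aggregation, AUC, t-test, boxplot stats, baselines, ablation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duincoder import (RecordScore, anop, boxplot_stats, journey_decision,
                       roc_auc, run_ablation, run_baseline, summarize, ttest)
from duincoder.detector import FrameFlags
from duincoder.evaluation import _balanced_record_subsample, scores_to_frame
from duincoder.records import WindowBatch


def _score(anop_v, status, rid="r"):
    return RecordScore(record_id=rid, status=status, anop=anop_v,
                       n_frames=100)


class TestAnop:
    @pytest.mark.parametrize("n_flagged,total,expected",
                             [(3, 100, 0.03), (0, 50, 0.0), (80, 80, 1.0)])
    def test_definition(self, n_flagged, total, expected):
        flags = np.zeros(total, dtype=int)
        flags[:n_flagged] = 1
        ff = FrameFlags("r", "normal", flags)
        assert anop(ff).anop == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            anop(FrameFlags("r", "normal", np.zeros(0, dtype=int)))

    def test_concatenation_is_frame_weighted_mean(self):
        rng = np.random.default_rng(0)
        f1 = rng.integers(0, 2, 70)
        f2 = rng.integers(0, 2, 30)
        a1 = anop(FrameFlags("a", "normal", f1)).anop
        a2 = anop(FrameFlags("b", "normal", f2)).anop
        cat = anop(FrameFlags("c", "normal", np.concatenate([f1, f2]))).anop
        assert cat == pytest.approx((70 * a1 + 30 * a2) / 100)


class TestJourneyDecision:
    def test_rules(self):
        assert journey_decision(_score(0.03, "normal"), 0.02) == "drunk"
        assert journey_decision(_score(0.02, "normal"), 0.02) == "normal"
        assert journey_decision(_score(1.0, "drunk"), 1.0) == "normal"


def brute_force_auc(scores):
    """Exhaustive pair enumeration: wins + half-ties over all pairs."""
    pos = [s.anop for s in scores if s.status == "drunk"]
    neg = [s.anop for s in scores if s.status == "normal"]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        scores = [_score(0.1, "normal"), _score(0.2, "normal"),
                  _score(0.15, "drunk"), _score(0.3, "drunk")]
        assert roc_auc(scores) == pytest.approx(0.75)

    def test_separated_and_tied(self):
        sep = [_score(0.0, "normal"), _score(0.01, "normal"),
               _score(0.5, "drunk"), _score(0.9, "drunk")]
        assert roc_auc(sep) == 1.0
        tied = [_score(0.3, s) for s in
                ("normal", "normal", "drunk", "drunk")]
        assert roc_auc(tied) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([_score(0.1, "normal"), _score(0.2, "normal")])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 8), st.booleans()),
                    min_size=2, max_size=12))
    def test_agrees_with_pair_enumeration(self, items):
        statuses = {b for _, b in items}
        if len(statuses) < 2:
            items = items + [(4, True), (4, False)]
        scores = [_score(v / 10.0, "drunk" if b else "normal", rid=str(i))
                  for i, (v, b) in enumerate(items)]
        assert roc_auc(scores) == pytest.approx(brute_force_auc(scores))


class TestTTest:
    def test_matches_hand_welch_formula(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.02, 0.01, 12)
        b = rng.normal(0.10, 0.05, 9)
        scores = [_score(float(np.clip(v, 0, 1)), "normal") for v in a] + \
                 [_score(float(np.clip(v, 0, 1)), "drunk") for v in b]
        va = np.array([s.anop for s in scores if s.status == "normal"])
        vb = np.array([s.anop for s in scores if s.status == "drunk"])
        se2a, se2b = va.var(ddof=1) / len(va), vb.var(ddof=1) / len(vb)
        t = (va.mean() - vb.mean()) / np.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (se2a ** 2 / (len(va) - 1)
                                   + se2b ** 2 / (len(vb) - 1))
        from scipy.stats import t as tdist
        p_oracle = 2 * tdist.sf(abs(t), df)
        assert ttest(scores) == pytest.approx(p_oracle, abs=1e-6)

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(1)
        rejections = 0
        for _ in range(200):
            vals = rng.uniform(0, 1, 40)
            scores = [_score(v, "normal") for v in vals[:20]] + \
                     [_score(v, "drunk") for v in vals[20:]]
            rejections += ttest(scores) < 0.05
        assert 0.01 <= rejections / 200 <= 0.10

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ttest([_score(0.1, "normal"), _score(0.2, "drunk")])


class TestBoxplotStats:
    def test_tukey_trimming_worked_example(self):
        out = boxplot_stats([1, 2, 3, 4, 100])
        assert out["n_removed"] == 1
        assert out["min"] == 1 and out["max"] == 4
        assert out["median"] == pytest.approx(2.5)

    def test_constant_and_clean_lists(self):
        out = boxplot_stats([3.0] * 7)
        assert (out["min"], out["median"], out["max"], out["iqr"]) == \
            (3.0, 3.0, 3.0, 0.0)
        clean = [0.1, 0.2, 0.3, 0.4, 0.5]
        out2 = boxplot_stats(clean)
        assert out2["n_removed"] == 0
        assert out2["median"] == pytest.approx(0.3)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=30).tolist()
        assert boxplot_stats(vals) == boxplot_stats(sorted(vals))

    def test_summary_combines_groups(self):
        scores = [_score(v, "normal", rid=f"n{i}")
                  for i, v in enumerate([0.0, 0.01, 0.02])] + \
                 [_score(v, "drunk", rid=f"d{i}")
                  for i, v in enumerate([0.2, 0.4, 0.5])]
        s = summarize(scores)
        assert s.auc == 1.0
        assert s.groups["normal"]["min"] <= s.groups["normal"]["median"] \
            <= s.groups["normal"]["max"]
        assert len(scores_to_frame(scores)) == 6


def _labeled_batch(n_records, status_of, frames_per=30, seed=0, shift=2.0):
    """Windows where drunk records are mean-shifted (linearly separable)."""
    rng = np.random.default_rng(seed)
    data, ids, labels = [], [], []
    for i in range(n_records):
        status = status_of(i)
        mu = shift if status == "drunk" else 0.0
        data.append(mu + rng.normal(size=(frames_per, 12)))
        ids += [f"r{i:03d}"] * frames_per
        labels += [status] * frames_per
    return WindowBatch(data=np.concatenate(data),
                       center_frames=np.tile(np.arange(frames_per), n_records),
                       record_ids=np.array(ids, dtype=object),
                       window_frames=1,
                       labels=np.array(labels, dtype=object))


class TestBaselines:
    def test_balanced_record_subsample_rule(self):
        batch = _labeled_batch(7, lambda i: "drunk" if i < 2 else "normal")
        mask = _balanced_record_subsample(batch, seed=0)
        used = set(batch.record_ids[mask])
        statuses = [batch.labels[batch.record_ids == r][0] for r in used]
        assert statuses.count("drunk") == 2 and statuses.count("normal") == 2

    def test_rf_separates_separable_windows(self):
        train = _labeled_batch(12, lambda i: "drunk" if i % 2 else "normal",
                               seed=1)
        test = _labeled_batch(8, lambda i: "drunk" if i % 2 else "normal",
                              seed=2)
        scores = run_baseline("rf", train, test, {"seed": 0})
        assert len(scores) == 8
        assert roc_auc(scores) > 0.9

    def test_supervised_needs_both_classes(self):
        train = _labeled_batch(4, lambda i: "normal")
        test = _labeled_batch(2, lambda i: "normal")
        with pytest.raises(ValueError, match="both"):
            run_baseline("lda", train, test)

    def test_vae_baseline_trains_on_normal_only(self):
        train = _labeled_batch(4, lambda i: "normal", seed=3)
        test = _labeled_batch(4, lambda i: "drunk" if i % 2 else "normal",
                              seed=4, shift=4.0)
        scores = run_baseline(
            "vae", train, test,
            {"seed": 0, "k_infer": 4, "en_layers": (16,), "latent_dim": 4,
             "epochs": 10})
        assert len(scores) == 4
        drunk = [s.anop for s in scores if s.status == "drunk"]
        normal = [s.anop for s in scores if s.status == "normal"]
        assert np.mean(drunk) > np.mean(normal)

    def test_unknown_baseline(self):
        batch = _labeled_batch(2, lambda i: "normal")
        with pytest.raises(ValueError):
            run_baseline("nope", batch, batch)


class TestAblation:
    def test_grid_shape_and_filters(self):
        from duincoder import SimConfig, simulate_dataset
        records = simulate_dataset(SimConfig(seed=5, records_per_cell=4,
                                             duration_override_s=20.0))
        tiny_model = dict(epochs=4, n_categories=4, latent_dim=8,
                          hidden_cat=(16,), hidden_en=(16,), hidden_de=(16,),
                          val_interval_epochs=2, k_val=2)
        table = run_ablation(
            {"data_proportion": [0.5, 1.0]},
            base_config=dict(window_seconds=2, k_infer=2,
                             model_params=tiny_model,
                             max_train_windows=400, max_val_windows=100,
                             split_ratio=(2, 1, 1), seed=0),
            records=records)
        assert len(table) == 2
        assert {"auc", "p_value"} <= set(table.columns)

    def test_unknown_dimension_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            run_ablation({"nonsense": [1]})

    def test_window_seconds_to_frames_rule(self):
        from duincoder import window_frames_for
        assert window_frames_for(5) == 51
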