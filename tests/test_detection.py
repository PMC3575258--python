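"""Expert-system oracles: reference selection, threshold arithmetic,
neighbour-pair rule, confusion counts, tuning and rater utilities."""

import math

import numpy as np
import pytest

from hdemgmap import (
    ChannelFeatureTable,
    DetectorConfig,
    channel_features,
    classify_channels,
    compute_global_thresholds,
    evaluate_detection,
    fleiss_kappa,
    majority_vote,
    neighbor_rms_threshold,
    neighbor_rms_threshold_grid,
    select_reference,
    tune_constants,
)
from hdemgmap.detection import NoReferenceError, UndefinedNeighborhoodError
from hdemgmap.grids import ElectrodeGrid
from hdemgmap.synthetic import ActivationBlob, generate_from_gains, generate_recording, inject_artifact


def table(p_lt, p_linet, rms=None):
    p_lt = np.asarray(p_lt, dtype=float)
    rms = np.ones_like(p_lt) if rms is None else np.asarray(rms, dtype=float)
    return ChannelFeatureTable(p_lt, np.asarray(p_linet, dtype=float), rms, p_lt.shape)


class TestReferenceSelection:
    def test_identical_features_keep_all_channels(self):
        t = table(np.full((4, 5), 0.01), np.full((4, 5), 0.02))
        ref = select_reference(t)
        assert ref.n_members == 20

    def test_single_line_outlier_excluded(self):
        rng = np.random.default_rng(0)
        p_line = 0.02 + 0.002 * rng.standard_normal((10, 10))
        p_line[3, 4] = 0.9
        t = table(0.01 + 0.001 * rng.standard_normal((10, 10)), p_line)
        ref = select_reference(t)
        assert not ref.member_mask[3, 4]
        med = np.median(p_line)
        iqr = np.subtract(*np.percentile(p_line, [75, 25]))
        expected = np.abs(p_line - med) < 1.5 * iqr
        # the other condition barely excludes anything here
        assert ref.member_mask[expected & (np.abs(p_line - med) < 1.5 * iqr)].mean() > 0.9

    def test_tight_unimodal_distribution_keeps_most_channels(self):
        rng = np.random.default_rng(1)
        kept = []
        for _ in range(20):
            t = table(rng.normal(0.01, 0.001, (6, 17)), rng.normal(0.02, 0.002, (6, 17)))
            kept.append(select_reference(t).n_members / 102)
        assert np.mean(kept) >= 0.90


class TestGlobalThresholds:
    def test_line_threshold_capped_at_085(self):
        t = table(np.full((3, 4), 0.01), np.full((3, 4), 0.4))
        ref = select_reference(t)
        _, t_line = compute_global_thresholds(ref, DetectorConfig(k_line=2.5))
        assert t_line == pytest.approx(0.85)

    def test_zero_iqr_arithmetic(self):
        t = table(np.full((3, 4), 0.01), np.full((3, 4), 0.02))
        ref = select_reference(t)
        t_lt, _ = compute_global_thresholds(ref, DetectorConfig(k1=11.2))
        assert t_lt == pytest.approx(11.2 * 0.01)

    def test_matches_brute_force_median_iqr_oracle(self):
        rng = np.random.default_rng(2)
        p_lt = rng.uniform(0.001, 0.02, (6, 17))
        p_li = rng.uniform(0.01, 0.1, (6, 17))
        t = table(p_lt, p_li)
        ref = select_reference(t)
        t_lt, t_line = compute_global_thresholds(ref, DetectorConfig(k1=7.1, k_line=2.5))

        def iqr_sorted(v):
            q75, q25 = np.percentile(np.sort(v), [75, 25])
            return q75 - q25

        members_lt = p_lt[ref.member_mask]
        members_li = p_li[ref.member_mask]
        assert t_lt == pytest.approx(7.1 * np.median(members_lt) + 1.5 * iqr_sorted(members_lt))
        assert t_line == pytest.approx(
            min(0.85, 2.5 * np.median(members_li) + 1.5 * iqr_sorted(members_li))
        )


class TestNeighborRule:
    def test_uniform_neighbors_zero_std(self):
        t = table(np.zeros((5, 5)), np.zeros((5, 5)), np.ones((5, 5)))
        assert neighbor_rms_threshold(t, 2, 2, k2=0.2) == pytest.approx(1.0)

    def test_hand_arithmetic_with_pair_std_convention(self):
        # p_a = [2, 2], p_b = [1, 3], p_c = [2, 2] around the centre channel
        rms = np.array([
            [9.0, 1.0, 9.0, 9.0, 9.0],
            [9.0, 9.0, 2.0, 9.0, 9.0],
            [9.0, 9.0, 5.0, 9.0, 9.0],
            [9.0, 2.0, 2.0, 3.0, 9.0],
            [9.0, 9.0, 9.0, 9.0, 9.0],
        ])
        # centre (2,2): p_a = [rms[1,2], rms[3,2]] = [2,2]
        #               p_b = [rms[1,1], rms[3,3]] = [9,3] -> use p_c for [1,3]
        #               p_c = [rms[3,1], rms[1,3]] = [2,9]
        # build explicit values instead:
        rms = np.full((3, 3), 0.0)
        rms[0, 1], rms[2, 1] = 2.0, 2.0          # p_a
        rms[0, 0], rms[2, 2] = 1.0, 3.0          # p_b
        rms[2, 0], rms[0, 2] = 2.0, 2.0          # p_c
        t = table(np.zeros((3, 3)), np.zeros((3, 3)), rms)
        expected = 2.0 + 0.2 * (abs(1.0 - 3.0) / math.sqrt(2))  # min means + k2*std([1,3])
        assert neighbor_rms_threshold(t, 1, 1, k2=0.2) == pytest.approx(expected)

    def test_border_equals_explicit_mirror_padding_oracle(self):
        rng = np.random.default_rng(3)
        rms = rng.uniform(0.5, 2.0, (6, 17))
        grid = neighbor_rms_threshold_grid(rms, k2=0.2)
        padded = np.pad(rms, 1, mode="reflect")
        for col in range(17):
            pa = [padded[0, 1 + col], padded[2, 1 + col]]
            pb = [padded[0, col], padded[2, col + 2]]
            pc = [padded[2, col], padded[0, col + 2]]
            means = [np.mean(pa), np.mean(pb), np.mean(pc)]
            stds = [np.std(p, ddof=1) for p in (pa, pb, pc)]
            assert grid[0, col] == pytest.approx(min(means) + 0.2 * max(stds))

    def test_single_row_grid_rejected(self):
        with pytest.raises(UndefinedNeighborhoodError):
            neighbor_rms_threshold_grid(np.ones((1, 5)), 0.2)


class TestClassification:
    def test_clean_sets_have_high_specificity(self):
        from hdemgmap import qc_benchmark_set

        cfg = DetectorConfig(k1=11.2, k2=0.002)
        flagged = total = 0
        for seed in range(30):
            rec, _ = qc_benchmark_set(seed + 1000, max_prevalence=0.0)
            mask = classify_channels(channel_features(rec), cfg)
            flagged += mask.n_flagged
            total += rec.grid.n_channels
        assert 1 - flagged / total >= 0.99

    def test_powerline_saturated_channel_flagged_with_line_rule(self, center_blob_recording):
        rec, _ = inject_artifact(center_blob_recording, 1, 5, "powerline", 5.0, seed=2)
        mask = classify_channels(channel_features(rec), DetectorConfig(k1=11.2, k2=0.002))
        assert mask.flags[1, 5]
        assert "line" in mask.rules[(1, 5)]

    def test_low_amplitude_flagged_in_active_region_not_in_inactive(self):
        """An isolated weak channel inside the active area is an artifact;
        a channel of the same absolute amplitude in a low-activity area
        whose neighbours are equally low is not."""
        grid = ElectrodeGrid(6, 17, origin_row=2, origin_col=4)
        ii, jj = np.meshgrid(np.arange(6), np.arange(17), indexing="ij")
        hump = 1.0 * np.exp(-((jj - 4.0) ** 2) / (2 * 2.0**2))   # active muscle, left
        plateau = 0.05 * np.exp(-((jj - 13.0) ** 2) / (2 * 3.0**2))  # faint region, right
        rec = generate_from_gains(grid, [hump, plateau, np.full((6, 17), 0.002)],
                                  seed=5)
        rec, truth = inject_artifact(rec, 2, 4, "isolated_amplitude", 0.05, seed=6)
        mask = classify_channels(channel_features(rec), DetectorConfig(k1=11.2, k2=0.002))
        assert mask.flags[2, 4] and "rms" in mask.rules[(2, 4)]
        assert not mask.flags[2, 13]  # same amplitude scale, consistent neighbours

    def test_scale_invariance_of_the_mask(self, center_blob_recording):
        from hdemgmap.grids import GridRecording

        rec, _ = inject_artifact(center_blob_recording, 2, 8, "powerline", 3.0, seed=2)
        cfg = DetectorConfig(k1=11.2, k2=0.02)
        m1 = classify_channels(channel_features(rec), cfg)
        scaled = GridRecording(rec.samples * 13.0, rec.fs_hz, rec.grid)
        m2 = classify_channels(channel_features(scaled), cfg)
        assert np.array_equal(m1.flags, m2.flags)

    def test_monotonicity_in_k1_and_k2(self):
        from hdemgmap import qc_benchmark_set

        rec, _ = qc_benchmark_set(77)
        feats = channel_features(rec)
        low_counts, rms_counts = [], []
        for k1 in (2.0, 5.0, 11.2, 30.0):
            m = classify_channels(feats, DetectorConfig(k1=k1, k2=0.01))
            low_counts.append(sum("lowfreq" in r for r in m.rules.values()))
        assert all(a >= b for a, b in zip(low_counts, low_counts[1:]))
        for k2 in (0.01, 0.05, 0.2, 0.5):
            m = classify_channels(feats, DetectorConfig(k1=11.2, k2=k2))
            rms_counts.append(sum("rms" in r for r in m.rules.values()))
        assert all(a <= b for a, b in zip(rms_counts, rms_counts[1:]))


class TestEvaluation:
    def test_perfect_detector(self):
        truth = np.zeros((10, 10), bool)
        truth.ravel()[:5] = True
        perf = evaluate_detection(truth, truth)
        assert (perf.sensitivity, perf.specificity, perf.precision, perf.accuracy) == (1, 1, 1, 1)

    def test_hand_confusion_arithmetic(self):
        truth = np.zeros(100, bool)
        truth[:4] = True
        mask = np.zeros(100, bool)
        mask[:3] = True        # 3 TP, 1 FN
        mask[50] = True        # 1 FP
        perf = evaluate_detection(mask.reshape(10, 10), truth.reshape(10, 10))
        assert perf.tp == 3 and perf.fn == 1 and perf.fp == 1 and perf.tn == 95
        assert perf.sensitivity == pytest.approx(0.75)
        assert perf.specificity == pytest.approx(95 / 96)
        assert perf.precision == pytest.approx(0.75)
        assert perf.accuracy == pytest.approx(0.98)

    def test_degenerate_empty_truth(self):
        empty = np.zeros((5, 5), bool)
        perf = evaluate_detection(empty, empty)
        assert perf.specificity == 1.0 and perf.accuracy == 1.0
        assert math.isnan(perf.sensitivity) and math.isnan(perf.precision)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_detection(np.zeros((2, 3), bool), np.zeros((3, 2), bool))


class TestTuning:
    def test_perfect_grid_point_selected_by_both_criteria(self):
        from hdemgmap import qc_benchmark_set

        sets = []
        for seed in range(6):
            rec, truth = qc_benchmark_set(seed + 50)
            sets.append((channel_features(rec), truth.mask()))
        (k1_pr, k2_pr), curve = tune_constants(sets, criterion="pr")
        (k1_roc, k2_roc), _ = tune_constants(sets, criterion="roc")
        best_pr = curve[(curve.k1 == k1_pr) & (curve.k2 == k2_pr)].iloc[0]
        best_roc = curve[(curve.k1 == k1_roc) & (curve.k2 == k2_roc)].iloc[0]
        assert best_pr.P >= best_roc.P  # precision-recall favours precision
        assert best_pr.S <= best_roc.S or best_pr.S == 1.0

    def test_roc_distance_arithmetic_prefers_closer_point(self):
        # synthetic two-point comparison: (S=1, SP=0.9) vs (S=0.8, SP=1)
        d1 = math.hypot(1 - 0.9, 1 - 1.0)
        d2 = math.hypot(1 - 1.0, 1 - 0.8)
        assert d1 < d2

    def test_requires_positive_labels(self):
        t = table(np.full((3, 4), 0.01), np.full((3, 4), 0.02))
        with pytest.raises(ValueError):
            tune_constants([(t, np.zeros((3, 4), bool))])


class TestRaterUtilities:
    def test_majority_vote_basic_and_oracle(self):
        assert majority_vote(np.array([[1], [1], [0]]))[0] == 1
        assert majority_vote(np.array([[0], [0], [0]]))[0] == 0
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, size=(5, 40))
        vote = majority_vote(labels)
        oracle = (labels.sum(axis=0) > 2.5).astype(int)
        assert np.array_equal(vote, oracle)

    def test_even_rater_count_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(np.zeros((4, 10), dtype=int))

    def test_fleiss_kappa_perfect_agreement(self):
        rng = np.random.default_rng(5)
        row = rng.integers(0, 2, size=50)
        labels = np.tile(row, (3, 1))
        assert fleiss_kappa(labels) == pytest.approx(1.0)

    def test_fleiss_kappa_random_raters_near_zero(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, size=(3, 1000))
        assert abs(fleiss_kappa(labels)) < 0.05

    def test_fleiss_kappa_toy_table_matches_hand_formula(self):
        labels = np.array([
            [1, 0, 1, 1, 0, 0],
            [1, 0, 0, 1, 0, 1],
            [1, 1, 1, 1, 0, 0],
        ])
        n_raters, n_items = labels.shape
        counts = np.stack([(labels == 0).sum(0), (labels == 1).sum(0)], axis=1)
        p_i = ((counts**2).sum(1) - n_raters) / (n_raters * (n_raters - 1))
        p_bar = p_i.mean()
        p_j = counts.sum(0) / (n_raters * n_items)
        p_e = (p_j**2).sum()
        expected = (p_bar - p_e) / (1 - p_e)
        assert fleiss_kappa(labels) == pytest.approx(expected)

    def test_fleiss_kappa_single_category_undefined(self):
        assert math.isnan(fleiss_kappa(np.ones((3, 10), dtype=int)))
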