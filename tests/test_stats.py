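import dataclasses
import itertools

import numpy as np
import pytest
from scipy import stats as sps

from hubnet import (
    SimulationConfig,
    simulate_islet,
    wilcoxon_matched_pairs,
    hub_follower_by_label,
    cohort_hub_follower_test,
    compare_auc_by_label,
)
from hubnet.stats import IsletHubComparison, LabelCounts


def exact_wilcoxon_enumeration(d: np.ndarray) -> float:
    """Independent oracle: two-sided p by enumerating all 2^n sign
    assignments of the ranked |d| (midranks for ties)."""
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w_obs = min(w_plus, w_minus)
    count = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        if wp <= w_obs + 1e-12:
            count += 1
        total += 1
    return min(1.0, 2.0 * count / total)


class TestWilcoxonMatchedPairs:
    def test_equal_samples_give_p_one(self):
        res = wilcoxon_matched_pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.n_effective == 0
        assert res.method == "degenerate"

    def test_six_positive_differences_closed_form(self):
        x = np.arange(1.0, 7.0)
        res = wilcoxon_matched_pairs(x, np.zeros(6))
        assert res.method == "exact"
        np.testing.assert_allclose(res.p_value, 2 / 64)
        assert res.statistic == 0.0

    def test_agrees_with_full_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(2, 11)
            d = np.round(rng.standard_normal(n) * 2, 1)
            res = wilcoxon_matched_pairs(d, np.zeros(n))
            if res.n_effective == 0:
                continue
            expected = exact_wilcoxon_enumeration(d)
            np.testing.assert_allclose(res.p_value, expected, atol=1e-12)

    def test_agrees_with_scipy_when_no_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            ours = wilcoxon_matched_pairs(x, y)
            ref = sps.wilcoxon(x, y, mode="exact")
            np.testing.assert_allclose(ours.p_value, ref.pvalue, atol=1e-12)

    def test_normal_approximation_reasonable_at_large_n(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(60)
        y = rng.standard_normal(60) + 0.8
        ours = wilcoxon_matched_pairs(x, y)
        ref = sps.wilcoxon(x, y, correction=True, mode="approx")
        assert ours.method == "approximate"
        np.testing.assert_allclose(ours.p_value, ref.pvalue, rtol=1e-6)

    def test_type_one_error_calibrated(self):
        # paired samples from identical distributions; rejection rate at
        # alpha=0.05 stays in [0.04, 0.06]
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 10_000
        for _ in range(n_rep):
            d = rng.standard_normal(20)
            res = wilcoxon_matched_pairs(d, np.zeros(20))
            rejections += res.p_value < 0.05
        assert 0.04 <= rejections / n_rep <= 0.06

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_matched_pairs([1.0, 2.0], [1.0])


# ---------------------------------------------------------------------------
# Hub/follower composition by label
# ---------------------------------------------------------------------------


def _comparison(n_pos, hubs_pos, n_neg, hubs_neg, islet_id="i"):
    return IsletHubComparison(
        islet_id=islet_id,
        pos=LabelCounts(n_pos, hubs_pos, n_pos - hubs_pos),
        neg=LabelCounts(n_neg, hubs_neg, n_neg - hubs_neg),
    )


class TestHubFollowerByLabel:
    def test_counting(self, default_islet):
        _, rec, _, result = default_islet
        comp = hub_follower_by_label(result)
        pos = rec.labels == "pos"
        hubs = result.hub_flags.astype(bool)
        assert comp.pos.n_cells == pos.sum()
        assert comp.pos.n_hubs == (hubs & pos).sum()
        assert comp.pos.n_hubs + comp.pos.n_followers == comp.pos.n_cells
        assert comp.neg.n_cells == (~pos).sum()

    def test_ratio_and_pct(self):
        comp = _comparison(10, 1, 20, 0)
        assert comp.pos.hub_pct == 10.0
        np.testing.assert_allclose(comp.pos.hub_follower_ratio, 1 / 9)
        assert comp.neg.hub_follower_ratio == 0.0

    def test_zero_followers_gives_undefined_ratio(self):
        comp = _comparison(3, 3, 5, 1)
        assert comp.pos.hub_follower_ratio is None

    def test_counts_invariant_to_cell_order(self, default_islet):
        _, rec, _, result = default_islet
        perm = np.random.default_rng(0).permutation(result.n_cells)
        shuffled = dataclasses.replace(
            result,
            hub_flags=result.hub_flags[perm],
            labels=rec.labels[perm],
            connectivity_pct=result.connectivity_pct[perm],
        )
        a = hub_follower_by_label(result)
        b = hub_follower_by_label(shuffled)
        assert (a.pos, a.neg) == (b.pos, b.neg)

    def test_label_odds_lower_positive_hub_ratio_in_truth(self):
        # generative check on the label machinery across 50 seeds: the
        # positive label carries proportionally fewer planted hubs
        lower = 0
        used = 0
        for seed in range(50):
            cfg = SimulationConfig(
                n_cells=400, hub_fraction=0.1, event_rate=0.0, noise_sd=0.0,
                n_frames=20, glucose_step_frame=10,
                label_hub_odds=0.2, seed=seed,
            )
            _, truth = simulate_islet(cfg)
            hubs = np.zeros(cfg.n_cells, bool)
            hubs[list(truth.hub_ids)] = True
            pos = truth.labels.astype(bool)
            r_pos = hubs[pos].mean() if pos.any() else np.nan
            r_neg = hubs[~pos].mean() if (~pos).any() else np.nan
            if np.isnan(r_pos) or np.isnan(r_neg):
                continue
            used += 1
            lower += r_pos < r_neg
        assert lower > used / 2


class TestCohortTest:
    def test_requires_two_usable_islets(self):
        with pytest.raises(ValueError):
            cohort_hub_follower_test([_comparison(5, 1, 5, 1)])

    def test_excludes_islets_missing_a_label(self):
        comps = [
            _comparison(5, 1, 5, 0, "a"),
            _comparison(0, 0, 5, 1, "b"),
            _comparison(6, 0, 4, 1, "c"),
        ]
        report = cohort_hub_follower_test(comps)
        assert report["excluded"] == ["b"]
        assert report["islet_ids"] == ["a", "c"]

    def test_undefined_ratio_treated_as_missing(self):
        comps = [
            _comparison(5, 1, 5, 0, "a"),
            _comparison(3, 3, 5, 1, "b"),  # pos ratio undefined
            _comparison(6, 0, 4, 1, "c"),
        ]
        report = cohort_hub_follower_test(comps)
        assert report["excluded"] == ["b"]

    def test_within_islet_label_shuffle_destroys_effect(self):
        # build a cohort with a strong planted label effect from ground
        # truth, then check that shuffling labels within islets yields a
        # roughly uniform p (rarely significant)
        rng = np.random.default_rng(8)
        cohorts = []
        for seed in range(30):
            cfg = SimulationConfig(
                n_cells=200, hub_fraction=0.1, event_rate=0.0, noise_sd=0.0,
                n_frames=20, glucose_step_frame=10,
                label_hub_odds=0.2, seed=seed,
            )
            _, truth = simulate_islet(cfg)
            hubs = np.zeros(cfg.n_cells, bool)
            hubs[list(truth.hub_ids)] = True
            cohorts.append((hubs, truth.labels.astype(bool)))

        def ratios(hubs, pos):
            return (
                hubs[pos].sum() / max(1, (~hubs & pos).sum()),
                hubs[~pos].sum() / max(1, (~hubs & ~pos).sum()),
            )

        true_pairs = np.array([ratios(h, p) for h, p in cohorts])
        p_true = wilcoxon_matched_pairs(true_pairs[:, 0], true_pairs[:, 1]).p_value
        assert p_true < 0.05

        hits = 0
        n_shuffles = 40
        for _ in range(n_shuffles):
            pairs = []
            for hubs, pos in cohorts:
                pairs.append(ratios(hubs, rng.permutation(pos)))
            pairs = np.array(pairs)
            p = wilcoxon_matched_pairs(pairs[:, 0], pairs[:, 1]).p_value
            hits += p < 0.05
        assert hits <= 0.2 * n_shuffles


# ---------------------------------------------------------------------------
# AUC comparison
# ---------------------------------------------------------------------------


def _half_amplitude_cohort(base_seed, n_islets=45):
    """Small islets where positive-label cells respond with half the
    Ca2+ amplitude."""
    recs = []
    cfg = SimulationConfig(
        n_cells=20, hub_fraction=0.1, n_frames=400, glucose_step_frame=60,
        noise_sd=0.1, label_fraction=0.3,
    )
    for i in range(n_islets):
        rec, truth = simulate_islet(
            dataclasses.replace(cfg, seed=base_seed + i), islet_id=f"islet{i:03d}"
        )
        pos = rec.labels == "pos"
        values = rec.values.copy()
        values[pos] = 1.0 + 0.5 * (values[pos] - 1.0)
        recs.append(dataclasses.replace(rec, values=np.maximum(values, 1e-3)))
    return recs


class TestCompareAUCByLabel:
    def test_identical_dynamics_give_p_one(self):
        # positive and negative cells with literally identical traces
        values = np.tile(1.0 + np.abs(np.sin(np.arange(120) / 7.0)), (4, 1))
        from hubnet import FluorescenceRecording

        recs = [
            FluorescenceRecording(
                islet_id=f"islet{i}",
                values=values,
                frame_interval=1.0,
                labels=np.array(["pos", "pos", "neg", "neg"], dtype=object),
                stimulus_onset=20,
            )
            for i in range(3)
        ]
        report = compare_auc_by_label(recs)
        assert report["test"].p_value == 1.0

    def test_half_amplitude_positive_cells_detected(self):
        detected = 0
        n_cohorts = 10
        for k in range(n_cohorts):
            recs = _half_amplitude_cohort(1000 * k)
            report = compare_auc_by_label(recs)
            assert report["mean_difference"] < 0
            detected += report["test"].p_value < 0.05
        assert detected > n_cohorts / 2

    def test_single_islet_rejected(self):
        recs = _half_amplitude_cohort(0, n_islets=1)
        with pytest.raises(ValueError):
            compare_auc_by_label(recs)
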