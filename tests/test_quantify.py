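"""Noise filter, batch ANOVA, pooling, window, selectivity and read-level
statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bequant.quantify import (
    AnovaConfig,
    NoiseFilterConfig,
    WindowConfig,
    abe_cbe_ratio,
    apply_noise_filter,
    average_editing_efficiency,
    batch_anova,
    conditional_coediting,
    editing_window,
    noise_probability,
    pool_replicates,
    selectivity,
)

from _oracles import binom_tail


def make_counts(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "member_id", "replicate", "position", "ref_base", "alt_base",
            "edited_reads", "total_reads",
        ],
    )


class TestNoiseProbability:
    def test_zero_counts_not_kept(self):
        assert noise_probability(0, 100, 0, 100) == pytest.approx(1.0)

    def test_single_replicate_hit_not_kept(self):
        """k=1 in one replicate only: P = 1 - 0.999^100 ~ 0.0952 >= 0.05."""
        p = noise_probability(1, 100, 0, 100)
        assert p == pytest.approx(1 - 0.999**100, abs=1e-12)
        assert p == pytest.approx(0.0952, abs=5e-5)
        assert p >= 0.05

    def test_dual_replicate_hit_kept(self):
        """k=1 in both replicates: P ~ 0.00906 < 0.05, so a low-count
        mutation present across both replicates survives."""
        p = noise_probability(1, 100, 1, 100)
        assert p == pytest.approx((1 - 0.999**100) ** 2, abs=1e-12)
        assert p == pytest.approx(0.00906, abs=5e-6)
        assert p < 0.05

    def test_matches_direct_binomial_summation(self):
        cfg = NoiseFilterConfig()
        for k1, n1, k2, n2 in [(2, 300, 1, 310), (0, 50, 3, 280), (5, 300, 5, 300)]:
            expected = binom_tail(k1, n1, 1e-3) * binom_tail(k2, n2, 1e-3)
            assert noise_probability(k1, n1, k2, n2, cfg) == pytest.approx(
                expected, rel=1e-9
            )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            noise_probability(5, 3, 0, 10)


class TestApplyNoiseFilter:
    def test_keeps_dual_replicate_low_counts(self):
        counts = make_counts(
            [
                ("m1", "r1", 6, "C", "T", 1, 100),
                ("m1", "r2", 6, "C", "T", 1, 100),
                ("m2", "r1", 6, "C", "T", 1, 100),
                ("m2", "r2", 6, "C", "T", 0, 100),
            ]
        )
        keep = apply_noise_filter(counts).set_index("member_id")["keep"]
        assert bool(keep["m1"]) is True
        assert bool(keep["m2"]) is False


class TestBatchAnova:
    def _counts_for_freqs(self, freqs_by_rep, pos=6):
        rows = []
        for rep, freqs in freqs_by_rep.items():
            for i, f in enumerate(freqs):
                rows.append((f"m{i}", rep, pos, "C", "T", int(round(f * 100)), 100))
        return make_counts(rows)

    def test_similar_groups_not_flagged(self):
        counts = self._counts_for_freqs(
            {"r1": [0.10, 0.11, 0.09], "r2": [0.10, 0.09, 0.11]}
        )
        out = batch_anova(counts)
        row = out.iloc[0]
        assert row["testable"]
        assert not row["flagged"]
        # cross-check p-value against the closed-form F statistic
        from scipy import stats

        g1, g2 = np.array([0.10, 0.11, 0.09]), np.array([0.10, 0.09, 0.11])
        f, p = stats.f_oneway(g1, g2)
        assert row["p_value"] == pytest.approx(p)

    def test_separated_groups_flagged(self):
        counts = self._counts_for_freqs(
            {"r1": [0.10, 0.10, 0.10], "r2": [0.50, 0.50, 0.50]}
        )
        out = batch_anova(counts)
        assert out.iloc[0]["p_value"] == pytest.approx(0.0)
        assert out.iloc[0]["flagged"].item() is True

    def test_constant_values_convention(self):
        counts = self._counts_for_freqs(
            {"r1": [0.10, 0.10, 0.10], "r2": [0.10, 0.10, 0.10]}
        )
        out = batch_anova(counts)
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)
        assert not out.iloc[0]["flagged"]

    def test_single_group_untestable(self):
        counts = self._counts_for_freqs({"r1": [0.1, 0.2, 0.3]})
        out = batch_anova(counts)
        assert not out.iloc[0]["testable"]
        assert not out.iloc[0]["flagged"]

    def test_bonferroni_uses_testable_count(self):
        # 20 hypotheses, one with a moderate p-value that would pass alone
        rows = []
        rng = np.random.default_rng(4)
        for pos in range(1, 21):
            for rep in ("r1", "r2"):
                for i in range(5):
                    k = int(rng.integers(8, 13))
                    rows.append((f"m{i}", rep, pos, "C", "T", k, 100))
        out = batch_anova(make_counts(rows), AnovaConfig(family_alpha=0.005))
        m = int(out["testable"].sum())
        assert m == 20
        assert (
            out["flagged"] == (out["testable"] & (out["p_value"] < 0.005 / m))
        ).all()


class TestPooling:
    def test_pooled_is_sum_ratio(self):
        counts = make_counts(
            [
                ("m1", "r1", 6, "C", "T", 10, 100),
                ("m1", "r2", 6, "C", "T", 20, 100),
            ]
        )
        pooled = pool_replicates(counts)
        assert pooled["efficiency"].iloc[0] == pytest.approx(0.15)

    def test_pooling_is_not_mean_of_ratios(self):
        counts = make_counts(
            [
                ("m1", "r1", 6, "C", "T", 5, 10),
                ("m1", "r2", 6, "C", "T", 0, 990),
            ]
        )
        pooled = pool_replicates(counts)
        assert pooled["efficiency"].iloc[0] == pytest.approx(0.005)

    def test_zero_coverage_is_missing_not_zero(self):
        counts = make_counts(
            [
                ("m1", "r1", 6, "C", "T", 0, 0),
                ("m1", "r2", 6, "C", "T", 0, 0),
            ]
        )
        pooled = pool_replicates(counts)
        assert np.isnan(pooled["efficiency"].iloc[0])

    def test_replicate_order_invariant(self):
        rows = [
            ("m1", "r1", 6, "C", "T", 3, 50),
            ("m1", "r2", 6, "C", "T", 9, 70),
        ]
        a = pool_replicates(make_counts(rows))
        b = pool_replicates(make_counts(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)


class TestEditingWindow:
    def test_flat_profile_includes_all(self):
        prof = {p: 0.2 for p in range(1, 10)}
        assert editing_window(prof) == set(range(1, 10))

    def test_threshold_arithmetic(self):
        prof = {2: 0.05, 3: 0.35, 4: 0.10}
        assert editing_window(prof) == {3}

    def test_scale_invariance(self):
        prof = {2: 0.05, 3: 0.35, 4: 0.12}
        scaled = {p: 0.5 * e for p, e in prof.items()}
        assert editing_window(prof) == editing_window(scaled)

    def test_all_zero_profile_empty_window(self):
        assert editing_window({1: 0.0, 2: 0.0}) == set()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        effs=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=10),
        below=st.floats(0.0001, 0.2),
    )
    def test_adding_subthreshold_position_never_changes_window(self, effs, below):
        prof = {i: e for i, e in enumerate(effs)}
        win = editing_window(prof)
        peak = max(prof.values())
        extra = dict(prof)
        extra[99] = below * 0.3 * peak * 0.99  # strictly below threshold
        assert editing_window(extra) == win


class TestSelectivity:
    def test_identical_profiles_give_one(self):
        prof = {3: 0.2, 4: 0.3}
        assert selectivity(prof, prof, {3, 4}) == pytest.approx(1.0)

    def test_geometric_mean_arithmetic(self):
        c = {3: 0.4, 4: 0.4}
        a = {3: 0.01, 4: 0.04}
        assert selectivity(c, a, {3, 4}) == pytest.approx(20.0)

    def test_single_position_reduces_to_ratio(self):
        assert selectivity({5: 0.3}, {5: 0.06}, {5}) == pytest.approx(5.0)

    def test_zero_denominator_positions_excluded(self):
        c = {3: 0.4, 4: 0.4}
        a = {3: 0.0, 4: 0.04}
        assert selectivity(c, a, {3, 4}) == pytest.approx(10.0)

    def test_bounded_by_extreme_position_ratios(self, rng):
        for _ in range(50):
            pos = list(range(5))
            c = {p: rng.uniform(0.05, 0.8) for p in pos}
            a = {p: rng.uniform(0.005, 0.2) for p in pos}
            ratios = [c[p] / a[p] for p in pos]
            s = selectivity(c, a, set(pos))
            assert min(ratios) - 1e-9 <= s <= max(ratios) + 1e-9

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            selectivity({1: 0.1}, {1: 0.1}, set())


def make_calls(rows):
    return pd.DataFrame(
        rows,
        columns=["replicate", "member_id", "read_index", "position",
                 "ref_base", "alt_base"],
    )


def make_rpm(rows):
    return pd.DataFrame(rows, columns=["replicate", "member_id", "n_reads"])


class TestReadLevelStats:
    def test_no_edits_gives_zero(self):
        avg, _ = average_editing_efficiency(
            make_calls([]), make_rpm([("r1", "m1", 100)])
        )
        assert avg == 0.0

    def test_unweighted_mean_over_members(self):
        """Members at 50% and 10% of reads edited average to 30%."""
        calls = make_calls(
            [("r1", "m1", i, 6, "C", "T") for i in range(50)]
            + [("r1", "m2", i, 6, "C", "T") for i in range(10)]
        )
        rpm = make_rpm([("r1", "m1", 100), ("r1", "m2", 100)])
        avg, per = average_editing_efficiency(calls, rpm)
        assert avg == pytest.approx(0.30)
        assert per["m1"] == pytest.approx(0.5)

    def test_member_without_reads_excluded(self):
        avg, per = average_editing_efficiency(
            make_calls([("r1", "m1", 0, 6, "C", "T")]),
            make_rpm([("r1", "m1", 10), ("r1", "m2", 0)]),
        )
        assert avg == pytest.approx(0.1)
        assert "m2" not in per.index

    def test_conditional_coediting_fraction(self):
        rows = []
        for i in range(10):  # 10 reads with a C>T call
            rows.append(("r1", "m1", i, 6, "C", "T"))
        for i in range(4):  # 4 of them also carry an A>G call
            rows.append(("r1", "m1", i, 8, "A", "G"))
        rows.append(("r1", "m1", 50, 8, "A", "G"))  # A-only read doesn't count
        assert conditional_coediting(make_calls(rows)) == pytest.approx(0.4)

    def test_conditional_coediting_no_a_edits(self):
        rows = [("r1", "m1", i, 6, "C", "T") for i in range(5)]
        assert conditional_coediting(make_calls(rows)) == 0.0

    def test_conditional_undefined_without_c_edits(self):
        assert np.isnan(conditional_coediting(make_calls([])))

    def test_abe_cbe_ratio(self):
        assert abe_cbe_ratio(0.11, 0.10) == pytest.approx(1.1)
        assert abe_cbe_ratio(0.1, 0.1) == pytest.approx(1.0)
        assert abe_cbe_ratio(0.0, 0.2) == pytest.approx(0.0)
        assert np.isnan(abe_cbe_ratio(0.1, 0.0))


class TestAgainstGenerator:
    def test_average_efficiency_tracks_engagement(self, dual_run):
        """With saturating per-site rates the any-edit fraction approaches the
        engagement probability; here it must match the analytic truth."""
        truth = dual_run["truth"]
        results = dual_run["results"]
        got = results.average_efficiency["C2T"]
        expected = truth.average_efficiency["C2T"]
        assert got == pytest.approx(expected, rel=0.05)

    def test_conditional_coediting_matches_latent_engagement_model(self, dual_run):
        """Pipeline P(A>G | C>T) agrees with the closed-form conditional of
        the latent-engagement editor within 3 s.e."""
        truth = dual_run["truth"]
        results = dual_run["results"]
        expected = truth.conditional_coediting
        # denominator: reads with >= 1 C>T call
        n_ct = sum(
            tally["kept"] for tally in results.report.values()
        ) * truth.average_efficiency["C2T"]
        se = math.sqrt(expected * (1 - expected) / n_ct)
        assert abs(results.conditional_coediting - expected) < 3 * se + 0.01
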