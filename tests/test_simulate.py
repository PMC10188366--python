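"""Synthetic library, outcome simulation and analytic ground truth."""

import math
from dataclasses import replace

import numpy as np
import pytest

from bequant.library import WINDOW_POSITIONS
from bequant.simulate import (
    CONTEXT_OFFSETS,
    EditorModel,
    SimConfig,
    benchmark_preset,
    build_library,
    cbe_preset,
    dual_preset,
    logistic,
    null_preset,
    simulate_experiment,
    simulate_outcomes,
    simulate_reads,
    truth_statistics,
)


class TestBuildLibrary:
    def test_dinucleotide_context_coverage_at_32(self):
        members = build_library(SimConfig(n_members=32, rng_seed=1))
        assert len(members) == 32
        for base in "CA":
            sub = [m for m in members if m.target_base == base]
            assert len(sub) == 16
            contexts = {(m.base_at(5), m.base_at(7)) for m in sub}
            assert len(contexts) == 16  # all (5', 3') combinations
        for m in members:
            assert m.base_at(6) == m.target_base

    def test_deterministic_given_seed(self):
        a = build_library(SimConfig(n_members=5, rng_seed=7))
        b = build_library(SimConfig(n_members=5, rng_seed=7))
        assert a == b
        c = build_library(SimConfig(n_members=5, rng_seed=8))
        assert a != c

    def test_spacer_uniqueness_exhaustive(self):
        members = build_library(SimConfig(n_members=500, rng_seed=3))
        spacers = [m.spacer for m in members]
        for i in range(len(spacers)):
            for j in range(i + 1, len(spacers)):
                assert spacers[i] != spacers[j]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_members=0)
        with pytest.raises(ValueError):
            SimConfig(n_members=1, mean_depth=0)


class TestEditorModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            EditorModel(engage_prob=1.5)
        with pytest.raises(ValueError):
            EditorModel(byproduct_frac_g=0.6, byproduct_frac_a=0.6)
        with pytest.raises(ValueError):
            EditorModel(window_weights_c={25: 0.0})
        with pytest.raises(ValueError):
            EditorModel(context_weights={(0, "A"): 1.0})

    def test_attenuated_scales_engagement(self):
        m = dual_preset()
        assert m.attenuated(1.25).engage_prob == pytest.approx(m.engage_prob / 1.25)

    def test_benchmark_preset_truth(self):
        """The recovery benchmark has window exactly 3..8 and selectivity 25."""
        model = benchmark_preset()
        library = build_library(SimConfig(n_members=64, rng_seed=2))
        truth = truth_statistics(model, library)
        assert truth.window == {3, 4, 5, 6, 7, 8}
        assert truth.selectivity == pytest.approx(25.0, rel=1e-9)


class TestSimulateOutcomes:
    def test_no_engagement_means_no_edits(self, rng):
        member = build_library(SimConfig(n_members=1, rng_seed=5))[0]
        model = replace(benchmark_preset(), engage_prob=0.0)
        outcomes = simulate_outcomes(member, model, 50, rng)
        assert all(o == member.cassette for o in outcomes)

    def test_marginal_rate_matches_binomial(self, rng):
        """One C site at conversion probability 0.5: sampled fraction within 3 s.e."""
        member = build_library(SimConfig(n_members=2, rng_seed=5))[0]
        assert member.target_base == "C"
        model = EditorModel(mu=0.0, window_weights_c={6: 0.0}, engage_prob=1.0)
        depth = 10_000
        outcomes = simulate_outcomes(member, model, depth, rng)
        off = member.offset_of(6)
        frac = sum(o[off] == "T" for o in outcomes) / depth
        se = math.sqrt(0.25 / depth)
        assert abs(frac - 0.5) < 3 * se

    def test_byproduct_partition(self, rng):
        member = build_library(SimConfig(n_members=2, rng_seed=5))[0]
        model = EditorModel(
            mu=50.0, window_weights_c={6: 0.0}, engage_prob=1.0,
            byproduct_frac_g=0.25, byproduct_frac_a=0.25,
        )
        depth = 8000
        outcomes = simulate_outcomes(member, model, depth, rng)
        off = member.offset_of(6)
        counts = {b: sum(o[off] == b for o in outcomes) for b in "TGA"}
        assert counts["T"] + counts["G"] + counts["A"] == depth
        for b, expected in (("T", 0.5), ("G", 0.25), ("A", 0.25)):
            se = math.sqrt(expected * (1 - expected) / depth)
            assert abs(counts[b] / depth - expected) < 4 * se

    def test_latent_engagement_couples_sites(self, rng):
        """engage 0.5 with saturating per-site rates: both sites edit together."""
        lib = build_library(SimConfig(n_members=4, rng_seed=5))
        member = next(m for m in lib if m.target_base == "C")
        positions = [p for p in (5, 6, 7) if member.base_at(p) == "C"][:2]
        assert len(positions) >= 1
        model = EditorModel(
            mu=50.0,  # conversion prob 1 given engagement
            window_weights_c={p: 0.0 for p in positions},
            engage_prob=0.5,
        )
        outcomes = simulate_outcomes(member, model, 2000, rng)
        offsets = [member.offset_of(p) for p in positions]
        edited_counts = [sum(o[off] == "T" for off in offsets) for o in outcomes]
        # every read is either fully edited or untouched
        assert set(edited_counts) <= {0, len(offsets)}
        frac_both = sum(c == len(offsets) for c in edited_counts) / len(outcomes)
        assert abs(frac_both - 0.5) < 3 * math.sqrt(0.25 / len(outcomes))

    def test_no_edits_outside_window(self, rng):
        member = build_library(SimConfig(n_members=1, rng_seed=5))[0]
        model = replace(benchmark_preset(), seq_error_rate=0.0)
        outcomes = simulate_outcomes(member, model, 300, rng)
        lo = member.offset_of(-9)
        hi = member.offset_of(20)
        for o in outcomes:
            assert o[:lo] == member.cassette[:lo]
            assert o[hi + 1 :] == member.cassette[hi + 1 :]


class TestSimulateReads:
    def test_error_free_reads_are_exact(self, rng):
        cfg = SimConfig(n_members=1, rng_seed=5)
        member = build_library(cfg)[0]
        model = replace(null_preset(), seq_error_rate=0.0, q_fail_frac=0.0)
        reads = simulate_reads([member.cassette] * 10, member, model, cfg, rng)
        for rid, fwd, fq, rev, rq in reads:
            assert fwd == member.cassette[: cfg.fwd_len]
            assert member.spacer in rev
            assert set(fq) == {chr(30 + 33)}
            assert rid.split(":")[0] == member.member_id

    def test_error_rate_calibration(self, rng):
        """~1e6 simulated bases: observed substitution rate within 3 s.e. of 1e-3."""
        cfg = SimConfig(n_members=1, rng_seed=5)
        member = build_library(cfg)[0]
        model = replace(null_preset(), seq_error_rate=1e-3)
        depth = 11_000
        reads = simulate_reads([member.cassette] * depth, member, model, cfg, rng)
        ref = member.cassette[: cfg.fwd_len]
        n_bases = depth * cfg.fwd_len
        n_err = sum(
            sum(a != b for a, b in zip(fwd, ref)) for _, fwd, _, _, _ in reads
        )
        rate = n_err / n_bases
        se = math.sqrt(1e-3 * (1 - 1e-3) / n_bases)
        assert abs(rate - 1e-3) < 3 * se

    def test_quality_failure_fraction(self, rng):
        cfg = SimConfig(n_members=1, rng_seed=5)
        member = build_library(cfg)[0]
        model = replace(null_preset(), q_fail_frac=1.0)
        reads = simulate_reads([member.cassette] * 5, member, model, cfg, rng)
        for _, _, fq, _, rq in reads:
            assert set(fq) == {chr(20 + 33)}
            assert set(rq) == {chr(20 + 33)}

    def test_cassette_shorter_than_read_rejected(self, rng):
        cfg = SimConfig(n_members=1, rng_seed=5, fwd_len=200)
        member = build_library(SimConfig(n_members=1, rng_seed=5))[0]
        with pytest.raises(ValueError, match="shorter"):
            simulate_reads([member.cassette], member, null_preset(), cfg, rng)


class TestExperiment:
    def test_byte_identical_under_fixed_seed(self):
        cfg = SimConfig(n_members=6, mean_depth=30, rng_seed=21)
        model = cbe_preset()
        a = simulate_experiment(cfg, model)
        b = simulate_experiment(cfg, model)
        assert a.reads == b.reads

    def test_reads_map_to_exactly_one_member(self):
        cfg = SimConfig(n_members=6, mean_depth=20, rng_seed=22)
        exp = simulate_experiment(cfg, cbe_preset())
        ids = {m.member_id for m in exp.library}
        for rep, reads in exp.reads.items():
            for rid, *_ in reads:
                mid, rep_tag, _ = rid.split(":")
                assert mid in ids
                assert rep_tag == rep


class TestTruthStatistics:
    def test_flat_profile_gives_full_window(self):
        lib = build_library(SimConfig(n_members=16, rng_seed=2))
        model = EditorModel(
            mu=0.0,
            window_weights_c={p: 0.0 for p in WINDOW_POSITIONS},
            window_weights_a={p: 0.0 for p in WINDOW_POSITIONS},
            engage_prob=1.0,
        )
        truth = truth_statistics(model, lib)
        assert truth.window == set(WINDOW_POSITIONS)
        assert truth.selectivity == pytest.approx(1.0)

    def test_two_position_selectivity_arithmetic(self):
        """C->T [0.4, 0.4] vs A->G [0.01, 0.04] => sqrt(40 * 10) = 20."""
        assert math.sqrt((0.4 / 0.01) * (0.4 / 0.04)) == pytest.approx(20.0)
        # and through truth_statistics on a crafted model: positions 6 (C
        # members) and the A members' position 6 carry the matching rates
        lib = build_library(SimConfig(n_members=32, rng_seed=2))
        p_c, p_a1 = 0.4, 0.01
        model = EditorModel(
            window_weights_c={6: math.log(p_c / (1 - p_c)), 5: math.log(p_c / (1 - p_c))},
            window_weights_a={6: math.log(p_a1 / (1 - p_a1)),
                              5: math.log(0.04 / 0.96)},
            engage_prob=1.0,
        )
        # restrict to members whose bases at 5/6 give defined rates on both axes
        truth = truth_statistics(model, lib)
        prof_ct = {p: e for (p, r, a), e in truth.position_efficiency.items()
                   if (r, a) == ("C", "T")}
        assert prof_ct[6] == pytest.approx(0.4)

    def test_truth_matches_monte_carlo(self, rng):
        """Analytic member probabilities agree with simulation at depth 1e5."""
        lib = build_library(SimConfig(n_members=2, rng_seed=9))
        member = lib[0]
        model = dual_preset()
        truth = truth_statistics(model, lib)
        depth = 100_000
        outcomes = simulate_outcomes(member, model, depth, rng)
        ct_offsets = [
            member.offset_of(p)
            for p in WINDOW_POSITIONS
            if member.base_at(p) == "C"
        ]
        frac = (
            sum(any(o[off] == "T" for off in ct_offsets) for o in outcomes) / depth
        )
        expected = truth.member_any_edit["C2T"][member.member_id]
        se = math.sqrt(expected * (1 - expected) / depth)
        assert abs(frac - expected) < 3 * se
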