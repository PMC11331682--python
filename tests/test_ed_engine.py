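from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edtool import (
    Cohort,
    CdnsEvaluator,
    MutationRecord,
    PairThresholds,
    SigmoidParams,
    build_opportunity_tables,
    call_pairs,
    cdns_score,
    fisher_ant_test,
    permutation_test,
    sample_size_correction,
    simulate_cohort,
    split_by_context,
    subsample_stability,
)
from edtool.ed_engine import (
    CdnsResult,
    _apply_filters,
    fisher_ant_from_counts,
    permutation_p,
)
from edtool.synthetic_data import EdPairSpec, SimulationConfig

from helpers import exhaustive_permutation_p, hypergeom_depletion_p

from conftest import make_records


class TestSplitByContext:
    def test_silent_mutations_do_not_count(self, small_cohort):
        ctx = split_by_context(small_cohort, "A")
        assert ctx.positive_samples == {"S1", "S2"}
        assert ctx.negative_samples == {"S3", "S4", "S5"}

    def test_unmutated_gene_gives_empty_positive(self, small_cohort):
        ctx = split_by_context(small_cohort, "ZZZ")
        assert ctx.positive_samples == set()
        assert ctx.negative_samples == set(small_cohort.sample_ids)

    def test_fully_mutated_gene_gives_empty_negative(self):
        records = make_records([(f"S{i}", "A", "missense") for i in range(4)])
        cohort = Cohort.from_records(records)
        ctx = split_by_context(cohort, "A")
        assert ctx.negative_samples == set()

    def test_partition_invariant(self, small_cohort):
        ctx = split_by_context(small_cohort, "B")
        assert ctx.positive_samples | ctx.negative_samples == set(small_cohort.sample_ids)
        assert ctx.positive_samples & ctx.negative_samples == set()


class TestCdnsScore:
    def test_simple_ratio(self):
        assert cdns_score(4.0, 1.0) == pytest.approx(2.0)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_identity(self, x):
        assert cdns_score(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_printed_log2_values(self):
        # a drop from 3.6 to 1.0 on the log2 scale is a cdNS of -2.6
        assert cdns_score(2**1.0, 2**3.6) == pytest.approx(-2.6)
        assert cdns_score(2**-0.9, 2**1.1) == pytest.approx(-2.0)

    def test_zero_is_undefined(self):
        assert math.isnan(cdns_score(0.0, 1.0))
        assert math.isnan(cdns_score(1.0, 0.0))
        assert math.isnan(cdns_score(0.0, 0.0))

    @given(
        st.floats(min_value=1e-6, max_value=1e6),
        st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_antisymmetry(self, a, b):
        assert cdns_score(a, b) == pytest.approx(-cdns_score(b, a), rel=1e-9, abs=1e-9)


class TestPermutationP:
    def test_add_one_formula(self):
        null = np.full(1000, -5.0)  # nothing as extreme as the observed +1
        p, direction, n_undef = permutation_p(1.0, null, 1000)
        assert p == pytest.approx(1 / 1001)
        assert direction == 1
        assert n_undef == 0

    def test_nan_counts_as_non_exceeding(self):
        null = np.array([np.nan] * 10 + [2.0] * 10)
        p, _, n_undef = permutation_p(1.0, null, 20)
        assert n_undef == 10
        assert p == pytest.approx((1 + 10) / 21)

    def test_negative_direction(self):
        null = np.array([-3.0, -1.0, 0.0, 1.0])
        p, direction, _ = permutation_p(-2.0, null, 4)
        assert direction == -1
        assert p == pytest.approx((1 + 1) / 5)


@pytest.fixture(scope="module")
def ed_sim():
    cfg = SimulationConfig(
        seed=21,
        n_samples=400,
        n_genes=8,
        length_codons=200,
        mutation_rate=1.5e-3,
        ed_pairs=[EdPairSpec("G001", "G002", "missense", cdns_true=2.0, context_prevalence=0.3)],
    )
    sim = simulate_cohort(cfg)
    tables = build_opportunity_tables(sim.genes)
    return sim, tables


class TestPermutationTest:
    def test_determinism(self, ed_sim):
        sim, tables = ed_sim
        r1 = permutation_test(sim.cohort, "G001", "G002", "missense", n_perm=100, seed=4, tables=tables)
        r2 = permutation_test(sim.cohort, "G001", "G002", "missense", n_perm=100, seed=4, tables=tables)
        assert r1.p == r2.p
        np.testing.assert_array_equal(r1.null_cdns, r2.null_cdns)

    def test_programmed_pair_is_significant(self, ed_sim):
        sim, tables = ed_sim
        r = permutation_test(sim.cohort, "G001", "G002", "missense", n_perm=500, seed=4, tables=tables)
        assert r.p < 0.01
        assert r.observed_cdns == pytest.approx(2.0, abs=1.0)

    def test_n_perm_validation(self, ed_sim):
        sim, tables = ed_sim
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(sim.cohort, "G001", "G002", "missense", n_perm=0, tables=tables)

    def test_undefined_observed_raises(self, ed_sim):
        sim, tables = ed_sim
        # a gene with no truncating mutations in either arm has undefined cdNS
        cfg = SimulationConfig(seed=3, n_samples=30, n_genes=3, length_codons=50,
                               mutation_rate=5e-4)
        tiny = simulate_cohort(cfg)
        tiny_tables = build_opportunity_tables(tiny.genes)
        with pytest.raises(ValueError, match="undefined"):
            permutation_test(
                tiny.cohort, "G001", "G002", "truncating", n_perm=10, tables=tiny_tables
            )

    def test_matches_exhaustive_enumeration_on_tiny_cohort(self):
        # 7 samples, synonymous calibration counts and gene-B counts chosen by
        # hand; the engine's sampled p must converge to the exact one
        roster = [f"S{i}" for i in range(7)]
        b_counts = [3, 0, 1, 0, 2, 0, 0]
        syn_counts = [1, 1, 2, 1, 1, 1, 1]
        spec = []
        for s, nb in zip(roster, b_counts):
            spec += [(s, "B", "missense")] * nb
        for s, ns in zip(roster, syn_counts):
            spec += [(s, "B", "synonymous")] * ns
        spec += [(s, "A", "missense") for s in roster[:3]]
        cohort = Cohort.from_records(make_records(spec), roster=roster)
        # single-gene panel: opportunity factors cancel between arms
        from edtool import GeneModel, build_opportunity_table

        table = build_opportunity_table(GeneModel("B", "ATG" + "CTGGAT" * 30 + "TAA"))
        tables = {"B": table}
        ev = CdnsEvaluator(cohort, tables)
        obs = ev.pair_cdns("A", "B", "missense")
        exact = exhaustive_permutation_p(b_counts, syn_counts, 3, obs["cdns"])
        r = permutation_test(
            cohort, "A", "B", "missense", n_perm=20000, seed=9, tables=tables
        )
        assert r.p == pytest.approx(exact, abs=0.02)


class TestSampleSizeCorrection:
    def test_force_w_one_is_identity(self):
        c = sample_size_correction(100, 900, SigmoidParams(force_w=1.0))
        assert c.w == 1.0
        assert c.corrected_n == 1000

    def test_closed_form(self):
        params = SigmoidParams(midpoint=0.05, slope=50.0)
        c = sample_size_correction(100, 9900, params)
        f = 100 / 10000
        w = 1.0 / (1.0 + math.exp(-50.0 * (f - 0.05)))
        assert c.w == pytest.approx(w)
        assert c.corrected_n == pytest.approx(100 + w * 9900)

    def test_monotone_in_positive_fraction(self):
        ws = [
            sample_size_correction(k, 1000 - k).w for k in (5, 20, 50, 100, 300)
        ]
        assert ws == sorted(ws)

    def test_corrected_n_bounded_by_n(self):
        c = sample_size_correction(50, 950)
        assert c.corrected_n <= 1000

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            sample_size_correction(0, 0)


class TestFisherAnt:
    def test_strong_depletion_matches_enumeration(self):
        p = fisher_ant_from_counts(0, 100, 100, 900, w=1.0)
        assert p == pytest.approx(hypergeom_depletion_p(0, 100, 100, 800), rel=1e-9)
        assert p < 1e-3

    def test_independence_table_matches_enumeration(self):
        p = fisher_ant_from_counts(10, 100, 90, 900, w=1.0)
        assert p == pytest.approx(hypergeom_depletion_p(10, 90, 90, 810), rel=1e-9)
        assert 0.4 < p <= 1.0

    def test_w_one_equals_uncorrected_scipy(self):
        from scipy.stats import fisher_exact

        p = fisher_ant_from_counts(3, 50, 40, 450, w=1.0)
        expected = fisher_exact([[3, 47], [40, 410]], alternative="less")[1]
        assert p == pytest.approx(expected, rel=1e-12)

    def test_correction_shrinks_negative_row(self):
        p_corr = fisher_ant_from_counts(0, 50, 100, 950, w=0.5)
        expected = fisher_ant_from_counts(0, 50, 50, 475, w=1.0)
        assert p_corr == pytest.approx(expected, rel=1e-9)

    def test_zero_margin_flagged(self):
        assert math.isnan(fisher_ant_from_counts(0, 50, 0, 950, w=1.0))

    def test_cohort_wrapper(self, small_cohort):
        p = fisher_ant_test(
            small_cohort, "A", "B", sigmoid=SigmoidParams(force_w=1.0)
        )
        assert 0 < p <= 1


class TestApplyFilters:
    def _result(self, **kw):
        base = dict(
            gene_a="A", gene_b="B", impact_class="missense",
            dnds_plus=4.0, dnds_minus=1.0, cdns=2.0, ed_ratio=4.0,
            n_mut_plus=5, n_mut_minus=5, p_perm=0.005, p_fisher=None, call="",
        )
        base.update(kw)
        return CdnsResult(**base)

    def test_syn_retained(self):
        r = self._result(ed_ratio=4.0, p_perm=0.005, n_mut_plus=3)
        assert _apply_filters(r, "pancancer", PairThresholds()) == "SYN"

    def test_ratio_filter_excludes(self):
        r = self._result(dnds_plus=2.0, cdns=1.0, ed_ratio=2.0, p_perm=0.001)
        assert _apply_filters(r, "pancancer", PairThresholds()) == "not_significant"

    def test_pancancer_ant_uses_fisher(self):
        r = self._result(cdns=-2.0, ed_ratio=0.25, p_perm=0.001, p_fisher=0.5, n_mut_plus=1)
        assert _apply_filters(r, "pancancer", PairThresholds()) == "not_significant"
        r2 = self._result(cdns=-2.0, ed_ratio=0.25, p_perm=0.5, p_fisher=0.001, n_mut_plus=1)
        assert _apply_filters(r2, "pancancer", PairThresholds()) == "ANT"

    def test_tumor_type_ant_uses_permutation(self):
        r = self._result(cdns=-2.0, ed_ratio=0.25, p_perm=0.001, p_fisher=None, n_mut_plus=1)
        assert _apply_filters(r, "tumor_type", PairThresholds()) == "ANT"

    def test_minimum_mutations(self):
        r = self._result(n_mut_plus=2)
        assert _apply_filters(r, "pancancer", PairThresholds()) == "not_significant"
        r_ant = self._result(cdns=-2.0, ed_ratio=0.2, p_fisher=0.001, n_mut_plus=0)
        assert _apply_filters(r_ant, "pancancer", PairThresholds()) == "not_significant"

    def test_undefined(self):
        r = self._result(cdns=float("nan"))
        assert _apply_filters(r, "pancancer", PairThresholds()) == "undefined"

    def test_enumerable_toy_table(self):
        rows = [
            self._result(),                                    # SYN
            self._result(ed_ratio=2.5, cdns=1.3),              # fails ratio
            self._result(p_perm=0.02),                         # fails p
            self._result(n_mut_plus=1),                        # fails min-mut
            self._result(cdns=-2.1, ed_ratio=0.23, p_fisher=0.003, n_mut_plus=1),  # ANT
            self._result(cdns=float("nan")),                   # undefined
        ]
        calls = [_apply_filters(r, "pancancer", PairThresholds()) for r in rows]
        assert calls == ["SYN", "not_significant", "not_significant",
                         "not_significant", "ANT", "undefined"]


class TestCallPairs:
    def test_programmed_pair_called_syn(self, ed_sim):
        sim, tables = ed_sim
        out = call_pairs(
            sim.cohort, tables, ["G001"], ["G002", "G003"],
            impact_classes=("missense",), n_perm=300, seed=5,
        )
        row = out[(out.gene_b == "G002")].iloc[0]
        assert row["call"] == "SYN"
        null_calls = out[(out.gene_b == "G003")]["call"]
        assert set(null_calls) <= {"not_significant", "undefined"}

    def test_self_pair_skipped(self, ed_sim):
        sim, tables = ed_sim
        out = call_pairs(
            sim.cohort, tables, ["G001"], ["G001"], impact_classes=("missense",),
            n_perm=10, seed=0,
        )
        assert out.empty

    def test_both_orientations_evaluated(self, ed_sim):
        sim, tables = ed_sim
        out = call_pairs(
            sim.cohort, tables, ["G003", "G004"], ["G003", "G004"],
            impact_classes=("missense",), n_perm=10, seed=0,
        )
        assert set(zip(out.gene_a, out.gene_b)) == {("G003", "G004"), ("G004", "G003")}


class TestSubsampleStability:
    def test_full_size_reproduces_estimate(self, ed_sim):
        sim, tables = ed_sim
        ev = CdnsEvaluator(sim.cohort, tables, indel_background_exclude={"G001"})
        full = ev.pair_cdns("G001", "G002", "missense")
        n_pos = full["n_pos"]
        out = subsample_stability(
            sim.cohort, tables, "G001", "G002", "missense", sizes=[n_pos], reps=5, seed=1
        )
        assert np.allclose(out["cdns"], full["cdns"])
        assert (out["n_mut_plus"] == full["n_mut_plus"]).all()

    def test_seed_determinism(self, ed_sim):
        sim, tables = ed_sim
        a = subsample_stability(sim.cohort, tables, "G001", "G002", "missense",
                                sizes=[10, 20], reps=5, seed=3)
        b = subsample_stability(sim.cohort, tables, "G001", "G002", "missense",
                                sizes=[10, 20], reps=5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_subsample_raises(self, ed_sim):
        sim, tables = ed_sim
        with pytest.raises(ValueError, match="exceeds"):
            subsample_stability(sim.cohort, tables, "G001", "G002", "missense",
                                sizes=[10**6], reps=2, seed=0)

    def test_signal_stabilizes_with_enough_mutations(self, ed_sim):
        sim, tables = ed_sim
        ev = CdnsEvaluator(sim.cohort, tables, indel_background_exclude={"G001"})
        full = ev.pair_cdns("G001", "G002", "missense")
        out = subsample_stability(
            sim.cohort, tables, "G001", "G002", "missense",
            sizes=[min(60, full["n_pos"])], reps=50, seed=2,
        )
        ok = out[out["n_mut_plus"] >= 3]
        assert np.median(ok["cdns"]) == pytest.approx(full["cdns"], abs=0.5)
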