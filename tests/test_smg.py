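"""SMG statistics against independent brute-force oracles, plus cohort-level
driver recovery on synthetic cohorts."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mfsomics import smg
from mfsomics.synthdata import (
    CohortSpec,
    DriverSpec,
    default_cohort_spec,
    generate_mutation_table,
    make_gene_models,
)
from mfsomics.types import GeneModel, MutationRecord


from _oracles import bh_bruteforce, binom_upper_tail, poisson_upper_tail


# --- unit tests ------------------------------------------------------------

class TestBackground:
    def test_rate_is_direct_ratio(self):
        genes = [
            GeneModel(f"g{i}", "chr1", [(i * 2000, i * 2000 + 1500)],
                      [(i * 2000, i * 2000 + 1500)])
            for i in range(1000)
        ]  # 1.5 Mb CDS total
        muts = [
            MutationRecord(f"s{j % 100}", f"g{j % 1000}", "chr1", 1, "A", "C",
                           "missense", 0.3, 5, 5)
            for j in range(150)
        ]
        bg = smg.estimate_background(muts, genes, n_samples=100)
        assert bg.total_rate == pytest.approx(1e-6)

    def test_single_gene_single_sample(self):
        g = GeneModel("g", "chr1", [(0, 1002)], [(0, 1002)])
        muts = [
            MutationRecord("s", "g", "chr1", i, "A", "C", "missense", 0.3, 5, 5)
            for i in range(3)
        ]
        bg = smg.estimate_background(muts, [g], n_samples=1)
        assert bg.total_rate == pytest.approx(3 / 1002)

    def test_null_cohort_rate_recovered(self):
        errs = []
        for seed in range(20):
            spec = CohortSpec(
                n_samples=100,
                gene_models=make_gene_models(200, seed=seed),
                background_rate=1e-5,
                seed=seed,
            )
            muts = generate_mutation_table(spec)
            bg = smg.estimate_background(muts, spec.gene_models, 100)
            errs.append(bg.total_rate / 1e-5 - 1.0)
        assert abs(np.mean(errs)) < 0.10


class TestAMMTest:
    def test_zero_observed_gives_one(self):
        assert smg.amm_test(0, 5.0) == 1.0

    def test_one_observed_unit_lambda(self):
        assert smg.amm_test(1, 1.0) == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_matches_tail_summation_oracle(self):
        for obs, lam in [(20, 2.0), (3, 0.5), (50, 10.0), (100, 50.0), (7, 7.0)]:
            assert smg.amm_test(obs, lam) == pytest.approx(
                poisson_upper_tail(obs, lam), abs=1e-12
            )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            smg.amm_test(-1, 1.0)
        with pytest.raises(ValueError):
            smg.amm_test(1, -1.0)


class TestBiasTests:
    def test_single_mutation_no_recurrence_signal(self):
        assert smg.activation_bias_test([100], 1000) == 1.0

    def test_recurrent_hotspot_is_significant(self):
        p = smg.activation_bias_test([7] * 5, 1000)
        assert p < 1e-8
        assert p == pytest.approx(1000 * binom_upper_tail(5, 5, 1 / 1000), rel=1e-9)

    def test_distinct_positions_give_one(self):
        assert smg.activation_bias_test([1, 2, 3, 4, 5], 1000) == 1.0

    def test_inactivation_no_truncating_gives_one(self):
        assert smg.inactivation_bias_test({"missense": 5}, 0.1) == 1.0

    def test_inactivation_matches_binomial_oracle(self):
        counts = {"nonsense": 5, "frameshift_indel": 3, "missense": 2}
        p = smg.inactivation_bias_test(counts, 0.1)
        assert p == pytest.approx(binom_upper_tail(8, 10, 0.1), rel=1e-10)

    def test_all_truncating_closed_form(self):
        for n in (1, 4, 9):
            counts = {"nonsense": n}
            assert smg.inactivation_bias_test(counts, 0.5) == pytest.approx(0.5**n)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            smg.inactivation_bias_test({"nonsense": 1}, 1.5)


class TestBH:
    def test_single_p_unchanged(self):
        assert smg.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_textbook_example(self):
        np.testing.assert_allclose(
            smg.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_equal_ps_stay_equal(self):
        q = smg.bh_adjust([0.2] * 7)
        np.testing.assert_allclose(q, 0.2)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_definition_and_basic_properties(self, pvals):
        q = smg.bh_adjust(pvals)
        np.testing.assert_allclose(q, bh_bruteforce(pvals), atol=1e-12)
        assert (q >= np.asarray(pvals) - 1e-15).all()
        # monotone in the sorted order of p
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        # re-adjustment can only move q values up
        assert (smg.bh_adjust(q) >= q - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            smg.bh_adjust([0.5, 1.5])


class TestCombineQ:
    def test_identical_qs(self):
        assert smg.combine_q(0.3, 0.3, 0.3) == pytest.approx(0.3)

    def test_mixed(self):
        assert smg.combine_q(0.01, 1.0, 1.0) == pytest.approx(0.01 ** (1 / 3))

    def test_between_min_and_max(self, rng):
        for _ in range(200):
            qs = rng.uniform(1e-6, 1.0, 3)
            c = smg.combine_q(*qs)
            assert qs.min() - 1e-12 <= c <= qs.max() + 1e-12

    def test_zero_q_floored_not_annihilating(self):
        assert smg.combine_q(0.0, 1.0, 1.0) > 0.0


class TestSubclonalFilter:
    def test_null_type_one_error_controlled(self, rng):
        flagged = 0
        n_sim = 1000
        cohort = rng.beta(5, 15, size=300)
        for _ in range(n_sim):
            gene = rng.choice(cohort, size=6, replace=False)
            flagged += smg.subclonal_bias_filter(gene, cohort, alpha=0.01)
        assert flagged / n_sim <= 0.01 + 0.02

    def test_clearly_subclonal_gene_flagged(self, rng):
        cohort = rng.normal(0.3, 0.05, size=200).clip(0.01, 0.99)
        assert smg.subclonal_bias_filter([0.03] * 10, cohort)

    def test_two_vafs_never_flagged(self):
        assert not smg.subclonal_bias_filter([0.01, 0.01], [0.5] * 100)


def _null_spec(seed, n_genes=1000, n_samples=100, drivers=()):
    return CohortSpec(
        n_samples=n_samples,
        gene_models=make_gene_models(n_genes, seed=seed),
        background_rate=1.6e-6,
        driver_specs=list(drivers),
        seed=seed,
    )


class TestCallSMGs:
    def test_null_amm_p_distribution_conservative(self):
        spec = _null_spec(seed=77)
        muts = generate_mutation_table(spec)
        res = smg.call_smgs(muts, spec.gene_models, spec.n_samples)
        frac = np.mean([r.p_amm < 0.05 for r in res])
        assert frac <= 0.07

    def test_planted_driver_ranks_first(self):
        hits = 0
        for seed in range(5):
            spec = _null_spec(
                seed, drivers=[DriverSpec("G0001", 50.0, hotspot=True,
                                          truncation_bias=True)]
            )
            muts = generate_mutation_table(spec)
            res = smg.call_smgs(muts, spec.gene_models, spec.n_samples,
                                exclude_genes={"G0001"})
            if res[0].gene == "G0001" and res[0].final_call:
                hits += 1
        assert hits == 5

    def test_subclonal_passenger_not_called(self):
        for seed in range(5):
            spec = _null_spec(
                seed + 30, drivers=[DriverSpec("G0002", 20.0, subclonal=True)]
            )
            muts = generate_mutation_table(spec)
            res = smg.call_smgs(muts, spec.gene_models, spec.n_samples,
                                exclude_genes={"G0002"})
            r = next(r for r in res if r.gene == "G0002")
            assert not r.final_call
            if r.observed >= 3:
                assert r.subclonal_flag

    def test_disabling_subclonal_filter_never_reduces_calls(self):
        spec = default_cohort_spec(seed=5)
        muts = generate_mutation_table(spec)
        with_filter = smg.call_smgs(muts, spec.gene_models, spec.n_samples)
        without = smg.call_smgs(muts, spec.gene_models, spec.n_samples,
                                apply_subclonal_filter=False)
        assert sum(r.final_call for r in without) >= sum(
            r.final_call for r in with_filter
        )

    def test_results_sorted_by_combined_q_then_gene(self):
        spec = default_cohort_spec(seed=6)
        muts = generate_mutation_table(spec)
        res = smg.call_smgs(muts, spec.gene_models, spec.n_samples)
        keys = [(r.combined_q, r.gene) for r in res]
        assert keys == sorted(keys)

    def test_focal_events_enter_aggregated_count(self):
        spec = _null_spec(seed=50, n_genes=100)
        muts = generate_mutation_table(spec)
        events = {"G0042": ["AMP"] * 20}
        res = smg.call_smgs(muts, spec.gene_models, spec.n_samples,
                            cn_gene_events=events)
        r = next(r for r in res if r.gene == "G0042")
        assert r.observed >= 20
        assert r.p_amm < 1e-6
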