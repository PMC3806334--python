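"""Combining meta-analysis summaries, equivalence, and overlap correction."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metasynth import (
    EffectDomainError,
    EffectEstimate,
    MetaSummary,
    OverlapSpec,
    StudyTable,
    apply_overlap,
    meta_analyze,
    overlap_corrected_variance,
    pooled_individual_mixed,
    synthesize_mixed,
    synthesize_or_summaries,
    synthesize_same_type,
    to_smd,
    two_step_equivalence_gap,
)


def summary(meta_id, effect_type, estimate, variance):
    return MetaSummary(meta_id, effect_type, estimate, variance)


class TestSameType:
    def test_published_fixed_effects_combination(self):
        res = synthesize_same_type(
            [summary("m1", "r", 0.1774, 0.00095), summary("m2", "r", 0.1041, 0.00064)]
        )
        assert res.estimate == pytest.approx(0.1334, abs=2e-3)
        assert res.variance == pytest.approx(0.00038, abs=5e-5)

    def test_published_random_effects_combination(self):
        res = synthesize_same_type(
            [summary("m1", "r", 0.1827, 0.0027), summary("m2", "r", 0.1370, 0.0018)]
        )
        assert res.estimate == pytest.approx(0.1553, abs=2e-3)
        assert res.variance == pytest.approx(0.00108, abs=5e-5)

    def test_single_summary_is_identity(self):
        res = synthesize_same_type([summary("m", "smd", 0.4, 0.02)])
        assert res.estimate == 0.4
        assert res.variance == 0.02

    def test_mixed_types_redirected(self):
        with pytest.raises(ValueError, match="synthesize_mixed"):
            synthesize_same_type(
                [summary("a", "smd", 0.4, 0.02), summary("b", "r", 0.1, 0.001)]
            )

    def test_ci_only_summary_resolved(self):
        explicit = synthesize_same_type(
            [summary("a", "smd", 0.4, 0.01), summary("b", "smd", 0.2, 0.04)]
        )
        via_ci = synthesize_same_type(
            [
                summary("a", "smd", 0.4, 0.01),
                MetaSummary("b", "smd", 0.2, ci_lower=0.2 - 1.96 * 0.2, ci_upper=0.2 + 1.96 * 0.2),
            ]
        )
        assert via_ci.estimate == pytest.approx(explicit.estimate, rel=1e-12)

    @given(
        summaries=st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.001, 1)), min_size=2, max_size=6
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_variance_shrinks_and_estimate_in_range(self, summaries):
        inputs = [
            summary(f"m{i}", "smd", e, v) for i, (e, v) in enumerate(summaries)
        ]
        res = synthesize_same_type(inputs)
        assert res.variance < min(v for _, v in summaries)
        assert min(e for e, _ in summaries) - 1e-12 <= res.estimate
        assert res.estimate <= max(e for e, _ in summaries) + 1e-12
        assert res.variance == pytest.approx(
            1.0 / sum(w for _, w in res.weights), rel=1e-12
        )


class TestMixed:
    def longhand(self, smd, lor, r, c_r):
        wm = 1.0 / smd[1]
        wo = 1.0 / lor[1]
        wr = (1 - r[0] ** 2) ** 2 / r[1]
        num = wm * smd[0] + 1.81 * wo * lor[0] + c_r * wr * math.log((1 + r[0]) / (1 - r[0]))
        den = wm + 1.81**2 * wo + 0.25 * wr
        return num / den, 1.0 / den

    def test_published_mixed_combination(self):
        inputs = [
            summary("smd", "smd", 0.4355, 0.0059),
            summary("or", "log_or", 0.3304, 0.0183),
            summary("r", "r", 0.0711, 0.0011),
        ]
        res = synthesize_mixed(inputs)
        assert res.estimate == pytest.approx(0.2973, abs=2e-3)
        assert res.variance == pytest.approx(0.0017, abs=2e-4)
        oracle_est, oracle_var = self.longhand(
            (0.4355, 0.0059), (0.3304, 0.0183), (0.0711, 0.0011), 0.5
        )
        assert res.estimate == pytest.approx(oracle_est, rel=1e-12)
        assert res.variance == pytest.approx(oracle_var, rel=1e-12)

    def test_delta_consistent_mode(self):
        inputs = [
            summary("smd", "smd", 0.4355, 0.0059),
            summary("or", "log_or", 0.3304, 0.0183),
            summary("r", "r", 0.0711, 0.0011),
        ]
        res = synthesize_mixed(inputs, numerator_mode="delta_consistent")
        oracle_est, _ = self.longhand(
            (0.4355, 0.0059), (0.3304, 0.0183), (0.0711, 0.0011), 0.25
        )
        assert res.estimate == pytest.approx(oracle_est, rel=1e-12)
        assert res.estimate == pytest.approx(0.2416, abs=2e-3)

    def test_or_summary_with_ci_accepted(self):
        with_var = synthesize_mixed(
            [
                summary("smd", "smd", 0.4, 0.01),
                summary("or", "log_or", math.log(1.33), 0.09476),
            ]
        )
        with_ci = synthesize_mixed(
            [
                summary("smd", "smd", 0.4, 0.01),
                MetaSummary("or", "or", 1.33, ci_lower=0.73, ci_upper=2.44),
            ]
        )
        assert with_ci.estimate == pytest.approx(with_var.estimate, abs=1e-4)

    @pytest.mark.parametrize("mode", ["as_printed", "delta_consistent"])
    def test_smd_only_reduces_to_same_type(self, mode):
        inputs = [summary("a", "smd", 0.4, 0.01), summary("b", "smd", 0.1, 0.02)]
        mixed = synthesize_mixed(inputs, numerator_mode=mode)
        same = synthesize_same_type(inputs)
        assert mixed.estimate == pytest.approx(same.estimate, rel=1e-12)
        assert mixed.variance == pytest.approx(same.variance, rel=1e-12)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="numerator_mode"):
            synthesize_mixed([summary("a", "smd", 0.4, 0.01)], numerator_mode="exact")

    @given(
        smd=st.tuples(st.floats(-1.5, 1.5), st.floats(0.005, 0.5)),
        lor=st.tuples(st.floats(-2, 2), st.floats(0.01, 1)),
        r=st.tuples(st.floats(-0.9, 0.9), st.floats(0.001, 0.05)),
    )
    @settings(max_examples=200, deadline=None)
    def test_delta_consistent_estimate_within_converted_inputs(self, smd, lor, r):
        inputs = [
            summary("smd", "smd", *smd),
            summary("or", "log_or", *lor),
            summary("r", "r", *r),
        ]
        res = synthesize_mixed(inputs, numerator_mode="delta_consistent")
        converted = [smd[0], lor[0] / 1.81, 2 * math.atanh(r[0])]
        assert min(converted) - 1e-9 <= res.estimate <= max(converted) + 1e-9
        assert res.variance == pytest.approx(
            1.0 / sum(w for _, w in res.weights), rel=1e-12
        )


class TestORSynthesis:
    def test_published_acl_example(self, acl):
        res = synthesize_or_summaries([(o, lo, up) for _, o, lo, up in acl])
        assert res.estimate == pytest.approx(0.2321, abs=2e-3)
        assert res.variance == pytest.approx(0.0695, abs=2e-4)
        assert res.or_estimate == pytest.approx(1.2613, abs=2e-3)
        assert res.or_ci[0] == pytest.approx(0.7523, abs=2e-3)

    def test_single_input_unchanged(self):
        res = synthesize_or_summaries([(2.0, 1.0, 4.0)])
        assert res.or_estimate == pytest.approx(2.0, rel=1e-12)

    def test_two_identical_inputs_halve_variance(self):
        one = synthesize_or_summaries([(1.5, 0.9, 2.5)])
        two = synthesize_or_summaries([(1.5, 0.9, 2.5), (1.5, 0.9, 2.5)])
        assert two.or_estimate == pytest.approx(one.or_estimate, rel=1e-12)
        assert two.variance == pytest.approx(one.variance / 2, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(EffectDomainError):
            synthesize_or_summaries([(1.2, -0.1, 2.0)])
        with pytest.raises((EffectDomainError, ValueError)):
            synthesize_or_summaries([(0.0, 0.5, 2.0)])

    @given(
        ors=st.lists(
            st.tuples(st.floats(0.2, 5), st.floats(1.1, 4)), min_size=2, max_size=5
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_pooled_or_between_inputs(self, ors):
        triples = [(o, o / spread, o * spread) for o, spread in ors]
        res = synthesize_or_summaries(triples)
        values = [o for o, _ in ors]
        assert min(values) * (1 - 1e-9) <= res.or_estimate <= max(values) * (1 + 1e-9)


class TestPooledIndividualMixed:
    def test_three_study_longhand_oracle(self):
        table = StudyTable(
            [
                EffectEstimate("1", "m", "smd", 0.5, variance=0.04),
                EffectEstimate("2", "m", "log_or", 0.9, variance=0.09),
                EffectEstimate("3", "m", "r", 0.2, variance=0.002),
            ]
        )
        res = pooled_individual_mixed(table, model="fixed")
        converted = [to_smd(rec) for rec in table]
        num = sum(r.estimate / r.variance for r in converted)
        den = sum(1.0 / r.variance for r in converted)
        assert res.estimate == pytest.approx(num / den, abs=1e-12)
        assert res.variance == pytest.approx(1.0 / den, abs=1e-12)

    def test_identical_studies_recover_value(self):
        table = StudyTable(
            [EffectEstimate(str(i), "m", "smd", 0.3, variance=0.05) for i in range(4)]
        )
        res = pooled_individual_mixed(table, model="random")
        assert res.estimate == pytest.approx(0.3, abs=1e-12)
        # homogeneous data: tau2 truncates to 0, so variance = v/k
        assert res.variance == pytest.approx(0.05 / 4, rel=1e-12)

    def test_mixed_table_close_to_direct_comparator(self, table2):
        # one-stage conversion-and-pool of the mixed table lands near the
        # all-correlation comparator 0.2692 (they differ by conversion error)
        res = pooled_individual_mixed(table2, model="fixed")
        assert res.estimate == pytest.approx(0.2692, abs=0.05)

    def test_unconvertible_record_named(self):
        table = StudyTable([EffectEstimate("orphan", "m", "smd", 0.4)])
        with pytest.raises(ValueError, match="orphan"):
            pooled_individual_mixed(table)


class TestTwoStepEquivalence:
    def test_fixed_effects_equivalence_on_published_split(self, table1_split):
        pooled, two_step, gap = two_step_equivalence_gap(table1_split, model="fixed")
        assert gap <= 1e-10
        assert pooled.estimate == pytest.approx(0.1334, abs=2e-3)

    def test_random_effects_gap_on_published_split(self, table1_split):
        pooled, two_step, gap = two_step_equivalence_gap(table1_split, model="random")
        assert pooled.estimate == pytest.approx(0.1597, abs=2e-3)
        assert two_step.estimate == pytest.approx(0.1553, abs=2e-3)
        assert gap == pytest.approx(0.0044, abs=1e-3)

    def test_identical_copies_gap_zero(self):
        records = []
        for j in range(3):
            for i, (e, v) in enumerate([(0.2, 0.01), (0.5, 0.02), (0.1, 0.05)]):
                records.append(
                    EffectEstimate(f"s{i}", f"copy_{j}", "smd", e, variance=v)
                )
        _, _, gap = two_step_equivalence_gap(StudyTable(records), model="fixed")
        assert gap <= 1e-12

    def test_requires_two_groups(self, table1_all):
        with pytest.raises(ValueError, match="at least 2"):
            two_step_equivalence_gap(table1_all)


class TestOverlapCorrection:
    def test_no_overlap_is_identity(self):
        spec = OverlapSpec(n_meta=3, overlap_weights=[], nonoverlap_weight_sum=25.0)
        var, inflation = overlap_corrected_variance(0.01, spec)
        assert inflation == 1.0
        assert var == 0.01

    def test_complete_overlap_inflates_by_j(self):
        # J meta-analyses of the same study set: all weight is shared
        for j in (2, 3, 7):
            spec = OverlapSpec(n_meta=j, overlap_weights=[10.0, 5.0, 2.5])
            _, inflation = overlap_corrected_variance(0.02, spec)
            assert inflation == pytest.approx(j, rel=1e-12)

    def test_partial_overlap_by_hand(self):
        # J=2, one shared study of weight 10, non-shared weight 10:
        # IF = (4*10 + 10) / (2*10 + 10) = 5/3
        spec = OverlapSpec(n_meta=2, overlap_weights=[10.0], nonoverlap_weight_sum=10.0)
        var, inflation = overlap_corrected_variance(0.03, spec)
        assert inflation == pytest.approx(5 / 3, rel=1e-12)
        assert var == pytest.approx(0.05, rel=1e-12)

    def test_explicit_inflation_factor(self):
        spec = OverlapSpec(n_meta=2, inflation_factor=1.4)
        assert overlap_corrected_variance(0.1, spec) == (pytest.approx(0.14), 1.4)

    def test_inconsistent_specs_rejected(self):
        with pytest.raises(ValueError):
            OverlapSpec(n_meta=2)  # neither weights nor IF
        with pytest.raises(ValueError):
            OverlapSpec(n_meta=2, overlap_weights=[1.0], inflation_factor=2.0)
        with pytest.raises(ValueError):
            OverlapSpec(n_meta=2, inflation_factor=0.5)
        with pytest.raises(ValueError):
            OverlapSpec(n_meta=0, inflation_factor=1.5)

    @given(
        j=st.integers(2, 6),
        weights=st.lists(st.floats(0.1, 50), min_size=1, max_size=8),
        rest=st.floats(0, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_inflation_nondecreasing_in_overlap(self, j, weights, rest):
        factors = []
        for p in range(len(weights) + 1):
            spec = OverlapSpec(
                n_meta=j,
                overlap_weights=weights[:p],
                nonoverlap_weight_sum=rest + sum(weights[p:]),
            )
            factors.append(spec.compute_inflation_factor())
        assert factors[0] == 1.0
        assert all(a <= b + 1e-12 for a, b in zip(factors, factors[1:]))
        if rest + sum(weights[1:]) > 0:
            assert factors[-1] >= 1.0
        # a single meta-analysis never inflates
        solo = OverlapSpec(n_meta=1, overlap_weights=weights)
        assert solo.compute_inflation_factor() == 1.0

    def test_apply_overlap_keeps_estimate_and_naive_variance(self):
        res = synthesize_same_type(
            [summary("a", "smd", 0.4, 0.01), summary("b", "smd", 0.2, 0.02)]
        )
        spec = OverlapSpec(n_meta=2, inflation_factor=2.0)
        corrected = apply_overlap(res, spec)
        assert corrected.estimate == res.estimate
        assert corrected.naive_variance == res.variance
        assert corrected.variance == pytest.approx(2 * res.variance)
        assert corrected.inflation_factor == 2.0
        width = res.ci_upper - res.ci_lower
        assert corrected.ci_upper - corrected.ci_lower == pytest.approx(
            width * math.sqrt(2), rel=1e-9
        )
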