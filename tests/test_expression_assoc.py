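"""Percentile, Tukey-fence, and association-testing unit tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fusionscape.breakpoint_annot import (
    AnnotatedFusion,
    FIVE_KINASE,
    THREE_KINASE,
)
from fusionscape.expression_assoc import (
    EQUAL,
    PARTNER_HIGHER,
    PARTNER_LOWER,
    apply_fdr_and_flags,
    cohort_percentiles,
    copy_number_category,
    copy_number_filter,
    expression_percentile,
    fusion_expression_association,
    kinase_partner_comparison,
    tukey_fences,
)
from fusionscape.fusion_ingest import FusionCall
from fusionscape.genome_model import Region, TranscriptLocus


class TestExpressionPercentile:
    def test_maximum_of_distinct_cohort_is_100(self):
        assert expression_percentile([1, 5, 2, 9, 3], 9) == 100.0

    def test_fully_tied_cohort_maps_to_50(self):
        assert expression_percentile([4.0] * 5, 4.0) == 50.0

    def test_tied_value_uses_average_rank(self):
        # cohort [1,2,2,3]: ranks 1, 2.5, 2.5, 4 -> (2.5-1)/3*100 = 50
        ranks = stats.rankdata([1, 2, 2, 3])
        expected = (ranks[1] - 1) / 3 * 100
        assert expression_percentile([1, 2, 2, 3], 2) == pytest.approx(expected)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            expression_percentile([], 1.0)

    def test_cohort_mean_percentile_is_50(self):
        rng = np.random.default_rng(0)
        for n in (5, 20, 101):
            vals = rng.normal(size=n)
            assert np.mean(cohort_percentiles(vals)) == pytest.approx(50.0)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        pct = cohort_percentiles(rng.normal(size=200))
        assert pct.min() >= 0 and pct.max() <= 100


class TestTukeyFences:
    def test_hand_computed_example(self):
        values = list(range(1, 9)) + [100]  # q1=3, q3=7 under type-7
        fences, over, under = tukey_fences(values)
        assert fences.q1 == 3 and fences.q3 == 7
        assert fences.iqr == 4 and fences.upper == 13 and fences.lower == -3
        assert list(np.flatnonzero(over)) == [8]
        assert not under.any()

    def test_constant_vector_has_no_outliers(self):
        _, over, under = tukey_fences([5.0] * 10)
        assert not over.any() and not under.any()

    def test_mirrored_data_swaps_flags(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=60).tolist() + [8.0, -9.0]
        _, over, under = tukey_fences(vals)
        _, over_m, under_m = tukey_fences([-v for v in vals])
        assert (over == under_m).all() and (under == over_m).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tukey_fences([1, 2, 3])

    def test_matches_brute_force_quantiles(self):
        """Type-7 quartiles recomputed from first principles on random data."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            vals = rng.normal(size=n)
            fences, _, _ = tukey_fences(vals)
            srt = np.sort(vals)
            for q, got in ((0.25, fences.q1), (0.75, fences.q3)):
                h = (n - 1) * q
                lo = int(np.floor(h))
                expected = srt[lo] + (h - lo) * (srt[min(lo + 1, n - 1)] - srt[lo])
                assert got == pytest.approx(expected)


def _lognormal_cohort(rng, n=100, mu=6.0, sigma=1.0):
    return np.round(np.exp2(rng.normal(mu, sigma, size=n)) - 1, 4)


class TestAssociation:
    def _run(self, shift_sd, n_carriers, seed=0, n_null_genes=5):
        rng = np.random.default_rng(seed)
        samples = [f"S{i}" for i in range(100)]
        data = {}
        for g in range(n_null_genes):
            data[f"NULL{g}"] = _lognormal_cohort(rng)
        target = rng.normal(6.0, 1.0, size=100)
        carriers = [f"S{i}" for i in range(n_carriers)]
        target[: n_carriers] += shift_sd * 1.0
        data["TARGET"] = np.round(np.exp2(target) - 1, 4)
        expr = pd.DataFrame(data, index=samples).T
        fusions = {"TARGET": set(carriers)}
        for g in range(min(2, n_null_genes)):
            fusions[f"NULL{g}"] = {f"S{90 + g}"}
        return fusion_expression_association(expr, fusions, "CT", fdr=0.05)

    def test_injected_shift_is_flagged(self):
        results = self._run(shift_sd=5.0, n_carriers=5)
        target = next(r for r in results if r.gene == "TARGET")
        assert target.flagged_for_review
        assert target.median_fusion_percentile > 90

    def test_two_carriers_never_flagged_even_with_huge_shift(self):
        results = self._run(shift_sd=12.0, n_carriers=2)
        target = next(r for r in results if r.gene == "TARGET")
        assert not target.flagged_for_review

    def test_no_fusions_no_results(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            {"A": _lognormal_cohort(rng, 10)}, index=[f"S{i}" for i in range(10)]
        ).T
        assert fusion_expression_association(expr, {}, "CT") == []

    def test_q_values_monotone_in_p_and_flags_shrink(self):
        results = self._run(shift_sd=5.0, n_carriers=5, seed=4)
        by_p = sorted(results, key=lambda r: r.t_p)
        qs = [r.t_q for r in by_p]
        assert qs == sorted(qs)
        flags_strict = None
        for fdr in (0.05, 1e-6):
            apply_fdr_and_flags(results, fdr=fdr)
            flagged = {r.gene for r in results if r.flagged_for_review}
            if flags_strict is None:
                flags_strict = flagged
            else:
                assert flagged <= flags_strict


def _annotated(gene5, gene3, role, sample="S0"):
    call = FusionCall(
        sample_id=sample,
        cancer_type="CT",
        gene5=gene5,
        gene3=gene3,
        bp5=("chr1", 1, "+"),
        bp3=("chr2", 1, "+"),
        junction_reads=10,
        spanning_frags=0,
        total_frags=10**6,
    )
    f = AnnotatedFusion(
        call=call,
        locus5=TranscriptLocus(region=Region.CDS, cds_offset=0, aa_pos=1, codon_phase=0),
        locus3=TranscriptLocus(region=Region.CDS, cds_offset=0, aa_pos=1, codon_phase=0),
    )
    f.kinase_role = role
    return f


class TestCopyNumberFilter:
    def _table(self, value):
        return pd.DataFrame({"S0": [value]}, index=["K"])

    @pytest.mark.parametrize("cn, kept", [(1, True), (2, True), (3, True), (4, False), (0, False)])
    def test_inclusive_bounds(self, cn, kept):
        fusions = [_annotated("A", "K", THREE_KINASE)]
        result = copy_number_filter(fusions, self._table(cn))
        assert bool(result) == kept

    def test_missing_value_excluded_with_warning(self):
        fusions = [_annotated("A", "K", THREE_KINASE)]
        with pytest.warns(UserWarning):
            assert copy_number_filter(fusions, self._table(np.nan)) == []

    def test_category_cut_points(self):
        assert copy_number_category(-2.5) == "DEEP_DELETION"
        assert copy_number_category(-1.5) == "LOSS"
        assert copy_number_category(0.0) == "NEUTRAL"
        assert copy_number_category(1.5) == "GAIN"
        assert copy_number_category(2.5) == "HIGH_AMPLIFICATION"


class TestKinasePartnerComparison:
    def _expr(self, kin_vals, par_vals):
        samples = [f"S{i}" for i in range(len(kin_vals))]
        return pd.DataFrame({"K": kin_vals, "P": par_vals}, index=samples).T

    def test_partner_higher(self):
        # sample S0: partner at the top, kinase at the bottom
        expr = self._expr([1, 50, 60, 70], [100, 5, 6, 7])
        f = _annotated("P", "K", THREE_KINASE)
        out = kinase_partner_comparison(expr, [f], equal_band=5)
        assert out.category.tolist() == [PARTNER_HIGHER]

    def test_equal_within_band(self):
        expr = self._expr([10, 20, 30, 40], [11, 21, 31, 41])
        f = _annotated("P", "K", THREE_KINASE)
        out = kinase_partner_comparison(expr, [f], equal_band=5)
        assert out.category.tolist() == [EQUAL]

    def test_absent_partner_gives_na(self):
        expr = self._expr([10, 20, 30, 40], [1, 2, 3, 4]).drop(index="P")
        f = _annotated("P", "K", THREE_KINASE)
        out = kinase_partner_comparison(expr, [f])
        assert out.category.tolist() == ["NA"]

    def test_recovers_promoter_strength_pattern(self):
        """3'-kinases fused to strong promoters score higher kinase quantiles.

        Build a 200-sample cohort where half the fusions pair the kinase
        with a highly expressed partner that drags kinase expression up
        (promoter capture), and half with a weak partner.  The rank-sum
        test must separate the kinase quantiles of the two groups.
        """
        rng = np.random.default_rng(5)
        n = 200
        samples = [f"S{i}" for i in range(n)]
        kin = rng.normal(6, 1, size=n)
        par = rng.normal(6, 1, size=n)
        fusions = []
        for i in range(40):
            strength = 3.0 if i % 2 == 0 else -3.0
            par[i] += strength  # partner promoter strength in this sample
            kin[i] += 0.3 * strength  # partial promoter capture by the kinase
            fusions.append(_annotated("P", "K", THREE_KINASE, sample=samples[i]))
        expr = pd.DataFrame(
            {
                s: [np.exp2(kin[i]) - 1, np.exp2(par[i]) - 1]
                for i, s in enumerate(samples)
            },
            index=["K", "P"],
        )
        out = kinase_partner_comparison(expr, fusions, equal_band=5)
        higher = out[out.category == PARTNER_HIGHER].kinase_quantile
        lower = out[out.category == PARTNER_LOWER].kinase_quantile
        assert len(higher) and len(lower)
        p = stats.mannwhitneyu(higher, lower, alternative="greater").pvalue
        assert p < 0.05
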