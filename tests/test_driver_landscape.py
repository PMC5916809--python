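"""Alteration profiles, driver groups, burden, druggability, smoking tests."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fusionscape.driver_landscape import (
    AlterationProfile,
    DRIVER_GROUPS,
    DRIVER_MUT_AND_FUSION,
    DRIVER_MUT_ONLY,
    DrugEntry,
    FUSION_ONLY,
    MUT_AND_FUSION,
    MUT_ONLY,
    NO_ALTERATION,
    annotate_druggable,
    build_alteration_profiles,
    burden_comparison,
    chi_square_2x2,
    classify_driver_group,
    cooccurrence_counts,
    driver_group_sizes,
    exclusivity_matrix,
    smoking_association,
)
from fusionscape.fusion_ingest import FusionCall

DRIVERS = ["TP53X", "ESR1X", "KINX"]


def maf_row(gene, sample, vclass="Missense_Mutation", is_driver=False):
    return {
        "Hugo_Symbol": gene,
        "Tumor_Sample_Barcode": sample,
        "Variant_Classification": vclass,
        "is_driver": is_driver,
    }


def fusion(sample, gene5, gene3, cancer="CT"):
    return FusionCall(
        sample_id=sample,
        cancer_type=cancer,
        gene5=gene5,
        gene3=gene3,
        bp5=("chr1", 100, "+"),
        bp3=("chr2", 200, "+"),
        junction_reads=10,
        spanning_frags=2,
        total_frags=10**7,
    )


def metadata(samples, cancer="CT", smoking=None):
    return pd.DataFrame(
        {
            "cancer_type": cancer,
            "smoking_status": smoking or ["smoker"] * len(samples),
        },
        index=pd.Index(samples, name="sample_id"),
    )


class TestBuildProfiles:
    def test_driver_missense_without_fusion(self):
        maf = pd.DataFrame([maf_row("TP53X", "S1", is_driver=True)])
        profiles = build_alteration_profiles(maf, [], DRIVERS, metadata(["S1"]))
        p = profiles[0]
        assert p.has_driver_mutation and p.has_driver_gene_mutation
        assert not p.has_driver_fusion
        assert p.n_mutations == 1

    def test_silent_driver_gene_mutation_does_not_qualify(self):
        maf = pd.DataFrame([maf_row("TP53X", "S1", vclass="Silent")])
        p = build_alteration_profiles(maf, [], DRIVERS, metadata(["S1"]))[0]
        assert not p.has_driver_gene_mutation
        assert p.n_mutations == 1  # still counted in the burden

    def test_msh2_nonsense_marks_mmr(self):
        maf = pd.DataFrame([maf_row("MSH2", "S1", vclass="Nonsense_Mutation")])
        p = build_alteration_profiles(maf, [], DRIVERS, metadata(["S1"]))[0]
        assert p.mmr_mutated

    def test_fusion_in_driver_gene_sets_flag(self):
        maf = pd.DataFrame([maf_row("OTHER", "S1")])
        p = build_alteration_profiles(
            maf, [fusion("S1", "PARTNER", "ESR1X")], DRIVERS, metadata(["S1"])
        )[0]
        assert p.has_driver_fusion

    def test_missing_variant_class_column_rejected(self):
        maf = pd.DataFrame({"Hugo_Symbol": ["X"], "Tumor_Sample_Barcode": ["S1"]})
        with pytest.raises(ValueError, match="Variant_Classification"):
            build_alteration_profiles(maf, [], DRIVERS, metadata(["S1"]))

    def test_sample_without_maf_rows_gets_empty_profile(self):
        maf = pd.DataFrame([maf_row("X", "S1")])
        profiles = build_alteration_profiles(maf, [], DRIVERS, metadata(["S1", "S2"]))
        p2 = next(p for p in profiles if p.sample_id == "S2")
        assert p2.n_mutations == 0 and not p2.has_driver_gene_mutation


def profile(sample="S", driver_mut=False, gene_mut=False, fus=False, n=5, mmr=False):
    return AlterationProfile(
        sample_id=sample,
        cancer_type="CT",
        has_driver_mutation=driver_mut,
        has_driver_gene_mutation=gene_mut,
        has_driver_fusion=fus,
        n_mutations=n,
        mmr_mutated=mmr,
    )


class TestDriverGroups:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(driver_mut=True), DRIVER_MUT_ONLY),
            (dict(gene_mut=True), MUT_ONLY),
            (dict(driver_mut=True, fus=True), DRIVER_MUT_AND_FUSION),
            (dict(gene_mut=True, fus=True), MUT_AND_FUSION),
            (dict(fus=True), FUSION_ONLY),
            (dict(), NO_ALTERATION),
        ],
    )
    def test_mapping(self, kwargs, expected):
        assert classify_driver_group(profile(**kwargs)) == expected

    def test_groups_partition_the_cohort(self):
        rng = np.random.default_rng(0)
        profiles = [
            profile(
                sample=f"S{i}",
                driver_mut=bool(rng.integers(2)),
                gene_mut=bool(rng.integers(2)),
                fus=bool(rng.integers(2)),
            )
            for i in range(97)
        ]
        sizes = driver_group_sizes(profiles)
        assert set(sizes) == set(DRIVER_GROUPS)
        assert sum(sizes.values()) == 97


def exact_mannwhitney_p(xa, xb):
    """Brute-force two-sided p by enumerating all rank arrangements."""
    pooled = xa + xb
    n = len(xa)

    def u_of(indices):
        a = [pooled[i] for i in indices]
        b = [pooled[i] for i in range(len(pooled)) if i not in indices]
        return sum(1 for x in a for y in b if x > y)

    observed = sum(1 for x in xa for y in xb if x > y)
    m = len(xa) * len(xb)
    us = [u_of(set(c)) for c in itertools.combinations(range(len(pooled)), n)]
    dev = abs(observed - m / 2)
    extreme = sum(1 for u in us if abs(u - m / 2) >= dev - 1e-12)
    return extreme / len(us)


class TestBurdenComparison:
    def _profiles(self, burdens_a, burdens_b, mmr_extra=()):
        out = [
            profile(sample=f"A{i}", fus=True, n=x)
            for i, x in enumerate(burdens_a)
        ]
        out += [
            profile(sample=f"B{i}", driver_mut=True, n=x)
            for i, x in enumerate(burdens_b)
        ]
        out += [
            profile(sample=f"M{i}", driver_mut=True, n=x, mmr=True)
            for i, x in enumerate(mmr_extra)
        ]
        return out

    def test_separated_groups_match_enumeration(self):
        profiles = self._profiles([1, 2, 3], [10, 11, 12])
        p = burden_comparison(profiles, FUSION_ONLY, DRIVER_MUT_ONLY)
        assert p == pytest.approx(exact_mannwhitney_p([1, 2, 3], [10, 11, 12]))
        assert p == pytest.approx(2 / 20)

    def test_matches_enumeration_on_random_small_groups(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            na, nb = rng.integers(3, 7, size=2)
            vals = rng.choice(1000, size=na + nb, replace=False)
            xa, xb = list(vals[:na]), list(vals[na:])
            profiles = self._profiles(xa, xb)
            p = burden_comparison(profiles, FUSION_ONLY, DRIVER_MUT_ONLY)
            assert p == pytest.approx(exact_mannwhitney_p(xa, xb))

    def test_hypermutators_excluded_before_testing(self):
        base = self._profiles([1, 2, 3], [2, 3, 4])
        with_mmr = self._profiles([1, 2, 3], [2, 3, 4], mmr_extra=[5000] * 3)
        assert burden_comparison(
            base, FUSION_ONLY, DRIVER_MUT_ONLY
        ) == pytest.approx(
            burden_comparison(with_mmr, FUSION_ONLY, DRIVER_MUT_ONLY)
        )

    def test_empty_group_rejected(self):
        profiles = self._profiles([1, 2, 3], [])
        with pytest.raises(ValueError):
            burden_comparison(profiles, FUSION_ONLY, DRIVER_MUT_ONLY)

    def test_pooled_groups(self):
        profiles = self._profiles([1, 2, 3], [4, 5, 6])
        profiles.append(profile(sample="X1", gene_mut=True, n=7))
        p = burden_comparison(
            profiles, FUSION_ONLY, (DRIVER_MUT_ONLY, MUT_ONLY)
        )
        assert p == pytest.approx(exact_mannwhitney_p([1, 2, 3], [4, 5, 6, 7]))


class TestExclusivityMatrix:
    def test_cell_types(self):
        maf = pd.DataFrame(
            [maf_row("ESR1X", "S2"), maf_row("TP53X", "S3")]
        )
        fusions = [fusion("S1", "ESR1X", "B"), fusion("S3", "TP53X", "B")]
        mat = exclusivity_matrix(fusions, maf, ["ESR1X", "TP53X"], ["S1", "S2", "S3"])
        assert mat.loc["ESR1X", "S1"] == "FUSION"
        assert mat.loc["ESR1X", "S2"] == "MUTATION"
        assert mat.loc["TP53X", "S3"] == "BOTH"
        assert mat.loc["TP53X", "S1"] == "NONE"

    def test_empty_gene_list(self):
        mat = exclusivity_matrix([], pd.DataFrame(columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]), [], ["S1"])
        assert mat.empty

    def test_cooccurrence_counts(self):
        maf = pd.DataFrame([maf_row("ESR1X", "S2")])
        mat = exclusivity_matrix(
            [fusion("S1", "ESR1X", "B")], maf, ["ESR1X"], ["S1", "S2"]
        )
        counts = cooccurrence_counts(mat).set_index("gene")
        assert counts.loc["ESR1X", "n_fusion"] == 1
        assert counts.loc["ESR1X", "n_both"] == 0


DRUGS = [
    DrugEntry(gene="KINX", drug="drugA", label_status="ON_LABEL"),
    DrugEntry(
        gene="PMLX", partner="RARAX", drug="drugB", label_status="ON_LABEL"
    ),
    DrugEntry(gene="EGFRX", drug="drugC", label_status="OFF_LABEL"),
]


class TestDruggability:
    def test_gene_match(self):
        matches, flags = annotate_druggable([fusion("S1", "A", "KINX")], DRUGS)
        assert flags["S1"] and matches.drug.tolist() == ["drugA"]

    def test_pair_restricted_entry_requires_partner(self):
        _, flags = annotate_druggable([fusion("S1", "PMLX", "OTHER")], DRUGS)
        assert not flags["S1"]
        _, flags = annotate_druggable([fusion("S1", "PMLX", "RARAX")], DRUGS)
        assert flags["S1"]

    def test_off_label_honored_only_when_allowed(self):
        calls = [fusion("S1", "EGFRX", "B")]
        _, strict = annotate_druggable(calls, DRUGS, allow_off_label=False)
        _, loose = annotate_druggable(calls, DRUGS, allow_off_label=True)
        assert not strict["S1"] and loose["S1"]

    def test_off_label_matches_are_a_superset(self):
        calls = [
            fusion("S1", "EGFRX", "B"),
            fusion("S2", "A", "KINX"),
            fusion("S3", "X", "Y"),
        ]
        m_strict, f_strict = annotate_druggable(calls, DRUGS, allow_off_label=False)
        m_loose, f_loose = annotate_druggable(calls, DRUGS, allow_off_label=True)
        assert set(m_strict.call_id) <= set(m_loose.call_id)
        assert {s for s, v in f_strict.items() if v} <= {
            s for s, v in f_loose.items() if v
        }


class TestSmokingAssociation:
    def test_published_style_contingency_is_significant(self):
        # 15 of 75 never smokers vs 9 of 425 smokers druggable
        table = np.array([[15, 60], [9, 416]])
        stat, p = chi_square_2x2(table)
        assert p < 1e-6

    def test_identical_proportions_give_zero_statistic(self):
        stat, p = chi_square_2x2(np.array([[10, 90], [20, 180]]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_returns_none(self):
        with pytest.warns(UserWarning, match="margin"):
            assert chi_square_2x2(np.array([[0, 0], [5, 10]])) is None

    def test_mapping_interface(self):
        flags = {f"N{i}": i < 15 for i in range(75)}
        flags.update({f"S{i}": i < 9 for i in range(425)})
        smoking = {s: ("never" if s.startswith("N") else "smoker") for s in flags}
        stat, p = smoking_association(flags, smoking)
        assert p < 1e-6
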