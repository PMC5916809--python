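"""Fusion translation, junction-window enumeration, and neoantigen tests."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from fusionscape.breakpoint_annot import annotate_fusion
from fusionscape.fusion_ingest import FusionCall
from fusionscape.genome_model import GeneModel, transcript_protein
from fusionscape.neoepitope import (
    EpitopeCall,
    FusionProtein,
    call_neoantigens,
    enumerate_junction_peptides,
    neoantigen_counts,
    translate_fusion,
)
from fusionscape.synthetic_data import toy_affinity_model

# two single-exon toy genes with UTRs -----------------------------------

rng = np.random.default_rng(42)
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def toy_gene(symbol, chrom, offset, n_codons, u5=12, u3=12, seed=0):
    r = np.random.default_rng(seed)
    cds = "ATG" + "".join(r.choice(_CODONS, size=n_codons - 2)) + "TAA"
    seq = (
        "".join(r.choice(list("ACGT"), size=u5))
        + cds
        + "".join(r.choice(list("ACGT"), size=u3))
    )
    model = GeneModel(
        gene_id=symbol,
        symbol=symbol,
        chromosome=chrom,
        strand="+",
        exons=[(offset, offset + len(seq))],
        transcript_id=f"t{symbol}",
        is_coding=True,
        cds_start=offset + u5,
        cds_end=offset + u5 + len(cds),
    )
    return model, seq


M5, S5 = toy_gene("FG5", "chr1", 1000, 40, seed=1)
M3, S3 = toy_gene("FG3", "chr2", 5000, 40, seed=2)
MODELS = {"FG5": M5, "FG3": M3}
SEQS = {"FG5": S5, "FG3": S3}


def make_fusion(off5, off3, junction_reads=10):
    """Fusion with given retained-5'/discarded-3' coding-base offsets."""
    bp5 = 1000 + 12 + off5 + 1  # junction base, 1-based
    bp3 = 5000 + 12 + off3 + 1
    call = FusionCall(
        sample_id="S1",
        cancer_type="CT",
        gene5="FG5",
        gene3="FG3",
        bp5=("chr1", bp5, "+"),
        bp3=("chr2", bp3, "+"),
        junction_reads=junction_reads,
        spanning_frags=0,
        total_frags=10**6,
    )
    return annotate_fusion(call, MODELS)


class TestTranslateFusion:
    def test_inframe_matches_hand_translation(self):
        f = make_fusion(9, 6)
        assert f.frame == "INFRAME"
        protein = translate_fusion(f, SEQS, MODELS)
        # independent construction: 5' CDS prefix + 3' CDS suffix
        cds5 = S5[12 : 12 + 9]
        cds3 = S3[12 + 6 : 12 + 120]
        expected = str(Seq(cds5 + cds3).translate(to_stop=True))
        assert protein.sequence == expected
        assert protein.junction_index == 3
        assert not protein.novel_tail

    def test_inframe_preserves_wildtype_suffix(self):
        f = make_fusion(9, 6)
        protein = translate_fusion(f, SEQS, MODELS)
        wt3 = transcript_protein(M3, S3)
        assert protein.sequence[protein.junction_index :] == wt3[2:]

    def test_frameshift_tail_differs_from_wildtype_everywhere(self):
        f = make_fusion(10, 6)
        assert f.frame == "FRAMESHIFT"
        protein = translate_fusion(f, SEQS, MODELS)
        assert protein.novel_tail
        wt3 = transcript_protein(M3, S3)
        tail = protein.sequence[protein.junction_index + 1 :]
        aligned = wt3[2 + 1 : 2 + 1 + len(tail)]
        # shifted-frame residues should not reproduce the wild-type run
        matches = sum(a == b for a, b in zip(tail, aligned))
        assert matches <= len(tail) // 3

    def test_promoter_swap_returns_wildtype_three_prime_protein(self):
        # both breakpoints inside the 5'UTRs
        call = FusionCall(
            sample_id="S1",
            cancer_type="CT",
            gene5="FG5",
            gene3="FG3",
            bp5=("chr1", 1000 + 6, "+"),
            bp3=("chr2", 5000 + 6, "+"),
            junction_reads=10,
            spanning_frags=0,
            total_frags=10**6,
        )
        f = annotate_fusion(call, MODELS)
        assert f.frame == "NO_FRAME"
        protein = translate_fusion(f, SEQS, MODELS)
        assert protein.sequence == transcript_protein(M3, S3)
        assert protein.junction_index == 0 and not protein.novel_tail

    def test_lost_start_codon_rejected(self):
        f = make_fusion(9, 6)
        # 5' breakpoint inside the 5'UTR but 3' breakpoint in CDS: NO_FRAME
        call = FusionCall(
            sample_id="S1",
            cancer_type="CT",
            gene5="FG5",
            gene3="FG3",
            bp5=("chr1", 1000 + 6, "+"),
            bp3=("chr2", 5000 + 12 + 7, "+"),
            junction_reads=10,
            spanning_frags=0,
            total_frags=10**6,
        )
        f = annotate_fusion(call, MODELS)
        with pytest.raises(ValueError):
            translate_fusion(f, SEQS, MODELS)


def brute_force_windows(protein: FusionProtein, lengths=(8, 9, 10, 11)):
    """Oracle: scan every substring and keep qualifying windows."""
    seq, j = protein.sequence, protein.junction_index
    out = []
    for k in lengths:
        for s in range(0, len(seq) - k + 1):
            spans_junction = s <= j - 1 and s + k - 1 >= j and 1 <= j < len(seq)
            in_tail = protein.novel_tail and s >= j
            if spans_junction or in_tail:
                out.append(seq[s : s + k])
    return out


class TestEnumerateJunctionPeptides:
    def test_centered_junction_yields_34_windows(self):
        protein = FusionProtein(sequence="A" * 40, junction_index=20, novel_tail=False)
        assert len(enumerate_junction_peptides(protein)) == 7 + 8 + 9 + 10

    def test_short_n_terminal_flank_limits_counts(self):
        protein = FusionProtein(sequence="ACDEFGHIKLMNPQRSTVWY", junction_index=3, novel_tail=False)
        windows = enumerate_junction_peptides(protein)
        assert sorted(windows) == sorted(brute_force_windows(protein))
        # at most 3 start positions per length
        for k in (8, 9, 10, 11):
            assert sum(len(w) == k for w in windows) <= 3

    def test_promoter_swap_product_has_no_windows(self):
        protein = FusionProtein(sequence="M" + "A" * 30, junction_index=0, novel_tail=False)
        assert enumerate_junction_peptides(protein) == []

    def test_junction_at_c_terminus_empty(self):
        protein = FusionProtein(sequence="A" * 20, junction_index=20, novel_tail=False)
        assert enumerate_junction_peptides(protein) == []

    @pytest.mark.parametrize("novel_tail", [False, True])
    def test_matches_brute_force_scan(self, novel_tail):
        r = np.random.default_rng(9)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(25):
            L = int(r.integers(5, 60))
            j = int(r.integers(0, L + 1))
            protein = FusionProtein(
                sequence="".join(r.choice(aas, size=L)),
                junction_index=j,
                novel_tail=novel_tail,
            )
            got = sorted(enumerate_junction_peptides(protein))
            assert got == sorted(brute_force_windows(protein))


class ConstantPredictor:
    def __init__(self, affinity, fail_on=()):
        self.affinity = affinity
        self.fail_on = set(fail_on)

    def predict(self, peptide, allele):
        if peptide in self.fail_on:
            raise RuntimeError("predictor failure")
        return self.affinity


class TestCallNeoantigens:
    PROTEIN = FusionProtein(sequence="ACDEFGHIKLMNPQRSTVWY", junction_index=10, novel_tail=False)

    def _call(self, predictor, junction_reads=10, wildtype=()):
        return call_neoantigens(
            {"f1": self.PROTEIN},
            {"f1": list(wildtype)},
            predictor,
            {"f1": ["HLA-A*01:01"]},
            {"f1": junction_reads},
        )

    def test_binders_below_threshold_are_neoantigens(self):
        calls = self._call(ConstantPredictor(100.0))
        assert calls and all(c.is_neoantigen for c in calls)

    def test_weak_binders_are_not_neoantigens(self):
        calls = self._call(ConstantPredictor(600.0))
        assert calls and not any(c.is_neoantigen for c in calls)

    def test_wildtype_substrings_excluded_before_prediction(self):
        calls = self._call(ConstantPredictor(100.0), wildtype=[self.PROTEIN.sequence])
        assert calls == []

    def test_low_junction_support_skips_fusion(self):
        assert self._call(ConstantPredictor(100.0), junction_reads=4) == []

    def test_predictor_failure_yields_na_call(self):
        windows = enumerate_junction_peptides(self.PROTEIN)
        calls = self._call(ConstantPredictor(100.0, fail_on={windows[0]}))
        failed = [c for c in calls if c.affinity_nM is None]
        assert len(failed) == 1 and not failed[0].is_neoantigen
        assert len(calls) == len(windows)

    def test_counts_per_fusion(self):
        calls = [
            EpitopeCall("f1", "A" * 8, "x", 100.0, True),
            EpitopeCall("f1", "C" * 8, "x", 700.0, False),
            EpitopeCall("f2", "D" * 8, "x", 10.0, True),
        ]
        assert neoantigen_counts(calls) == {"f1": 1, "f2": 1}

    def test_toy_predictor_integration(self):
        predictor = toy_affinity_model(seed=3)
        calls = self._call(predictor)
        assert calls
        for c in calls:
            assert 0 < c.affinity_nM <= 50000
            assert c.is_neoantigen == (c.affinity_nM <= 500)
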