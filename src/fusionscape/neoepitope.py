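"""Fusion junction peptide enumeration and neoantigen calling.

The fusion protein is rebuilt from the two partner transcripts: the 5'
segment up to (excluding) the 5' breakpoint base is joined to the 3'
segment from the 3' breakpoint base onward, and the chimeric transcript
is translated from the 5' gene's start codon until the first stop.  For
in-frame fusions this yields 5' prefix + wild-type 3' suffix; for
frameshifts the suffix is a novel tail read in the shifted frame; for a
5'UTR-swap (both breakpoints in 5'UTRs) the product is the unaltered 3'
protein driven by the partner's promoter.

Candidate epitopes are all 8-11-mer windows spanning the junction (plus,
for frameshift products, every window inside the novel tail).  Peptides
occurring verbatim in either partner's wild-type protein are discarded;
the rest are scored against a pluggable MHC binding predictor, and a
peptide-allele pair is called a neoantigen at affinity <= 500 nM.
Fusions with fewer than 5 junction-spanning RNA reads are skipped as too
lowly expressed to present antigen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence

from Bio.Seq import Seq

from .breakpoint_annot import AnnotatedFusion, FRAMESHIFT, INFRAME, NO_FRAME
from .genome_model import GeneModel, Region, transcript_protein

PEPTIDE_LENGTHS = (8, 9, 10, 11)


class AffinityPredictor(Protocol):
    """Deterministic peptide x allele -> binding affinity in nM."""

    def predict(self, peptide: str, allele: str) -> float: ...


@dataclass(frozen=True)
class FusionProtein:
    """Translated fusion product.

    ``junction_index`` is the number of residues fully encoded by the 5'
    gene; the junction lies between residues ``junction_index`` and
    ``junction_index + 1`` (1-based).  ``novel_tail`` marks frameshift
    products whose entire post-junction suffix is non-wild-type.
    """

    sequence: str
    junction_index: int
    novel_tail: bool

    def __post_init__(self) -> None:
        if not 0 <= self.junction_index <= len(self.sequence):
            raise ValueError("junction_index outside protein")


@dataclass(frozen=True)
class EpitopeCall:
    call_id: str
    peptide: str
    allele: str
    affinity_nM: float | None
    is_neoantigen: bool


def translate_fusion(
    fusion: AnnotatedFusion,
    transcripts: Mapping[str, str],
    models: Mapping[str, GeneModel],
) -> FusionProtein:
    """Translate the chimeric transcript of an annotated fusion.

    Requires a predicted frame, or the no-frame 5'UTR-swap case where the
    3' ORF is carried over whole.  ``transcripts`` maps gene symbol to
    spliced transcript sequence.
    """
    call = fusion.call
    m5, m3 = models[call.gene5], models[call.gene3]
    seq5, seq3 = transcripts[call.gene5], transcripts[call.gene3]
    k5 = m5.transcript_index(call.bp5[1] - 1)
    k3 = m3.transcript_index(call.bp3[1] - 1)
    if k5 is None or k3 is None:
        raise ValueError(f"{call.call_id}: intronic breakpoint; no transcript")

    if fusion.frame == NO_FRAME:
        if (
            fusion.locus5.region is Region.FIVE_UTR
            and fusion.locus3.region is Region.FIVE_UTR
            and m3.is_coding
        ):
            # promoter swap: the full 3' ORF rides along unchanged
            return FusionProtein(
                sequence=transcript_protein(m3, seq3),
                junction_index=0,
                novel_tail=False,
            )
        raise ValueError(
            f"{call.call_id}: no reading frame and not a 5'UTR swap"
        )

    if not m5.is_coding:
        raise ValueError(f"{call.call_id}: 5' gene has no start codon context")
    chimera = seq5[:k5] + seq3[k3:]
    u5 = m5.utr5_length
    if k5 <= u5:
        raise ValueError(f"{call.call_id}: 5' start codon not retained")
    coding = chimera[u5:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate(to_stop=True))
    junction = min(fusion.locus5.cds_offset // 3, len(protein))
    return FusionProtein(
        sequence=protein,
        junction_index=junction,
        novel_tail=fusion.frame == FRAMESHIFT,
    )


def enumerate_junction_peptides(
    protein: FusionProtein,
    lengths: Sequence[int] = PEPTIDE_LENGTHS,
    include_tail: bool = True,
) -> list[str]:
    """All candidate epitope windows of the fusion product.

    Junction windows are the full-length k-mers containing residues
    ``junction_index`` and ``junction_index + 1``; truncated windows at
    the protein ends are dropped.  For novel-tail (frameshift) products
    every full k-mer lying entirely in the tail is added as well (the
    whole tail is tumor-specific).  A promoter-swap product
    (junction_index 0, no novel tail) yields nothing.
    """
    if not protein.sequence:
        raise ValueError("empty protein")
    seq = protein.sequence
    L = len(seq)
    j = protein.junction_index  # junction between residues j and j+1 (1-based)
    out: list[str] = []
    seen: set[tuple[int, int]] = set()

    def emit(start0: int, k: int) -> None:
        if (start0, k) not in seen:
            seen.add((start0, k))
            out.append(seq[start0 : start0 + k])

    if 1 <= j < L:
        for k in lengths:
            # window [start0, start0+k) must contain 0-based residues j-1 and j
            for start0 in range(max(0, j - k + 1), min(j - 1, L - k) + 1):
                emit(start0, k)
    if protein.novel_tail and include_tail:
        for k in lengths:
            for start0 in range(j, L - k + 1):
                emit(start0, k)
    return out


def call_neoantigens(
    fusion_proteins: Mapping[str, FusionProtein],
    wildtype_proteins: Mapping[str, Sequence[str]],
    predictor: AffinityPredictor,
    alleles: Mapping[str, Sequence[str]],
    junction_reads: Mapping[str, int],
    affinity_max: float = 500.0,
    min_split_reads: int = 5,
    lengths: Sequence[int] = PEPTIDE_LENGTHS,
    include_tail: bool = True,
) -> list[EpitopeCall]:
    """Score junction peptides and call neoantigens.

    ``fusion_proteins``, ``wildtype_proteins`` (the two partners' wild
    type proteins per call), ``alleles`` and ``junction_reads`` are all
    keyed by call id.  Fusions with fewer than ``min_split_reads``
    junction-spanning reads yield no calls; peptides found verbatim in a
    wild-type partner protein are excluded before prediction.  A
    predictor failure yields an NA call instead of aborting the run.
    """
    calls: list[EpitopeCall] = []
    for call_id, protein in fusion_proteins.items():
        if junction_reads.get(call_id, 0) < min_split_reads:
            continue
        wt = [p for p in wildtype_proteins.get(call_id, ()) if p]
        peptides = enumerate_junction_peptides(
            protein, lengths=lengths, include_tail=include_tail
        )
        novel = [p for p in peptides if not any(p in w for w in wt)]
        for peptide in novel:
            for allele in alleles.get(call_id, ()):
                try:
                    aff = float(predictor.predict(peptide, allele))
                except Exception:
                    calls.append(
                        EpitopeCall(call_id, peptide, allele, None, False)
                    )
                    continue
                calls.append(
                    EpitopeCall(
                        call_id, peptide, allele, aff, aff <= affinity_max
                    )
                )
    return calls


def neoantigen_counts(calls: Iterable[EpitopeCall]) -> dict[str, int]:
    """Neoantigens per fusion call id."""
    counts: dict[str, int] = {}
    for c in calls:
        counts.setdefault(c.call_id, 0)
        counts[c.call_id] += bool(c.is_neoantigen)
    return counts
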