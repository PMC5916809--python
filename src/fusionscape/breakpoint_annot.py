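"""Breakpoint categories, reading frame, kinase role/domain, group statistics.

Each kept fusion call is mapped onto the two partner transcripts and
annotated with:

* a breakpoint category — the ordered (5' region, 3' region) pair, with
  intronic loci folded into the non-coding category for display;
* a reading-frame label — INFRAME when the retained 5' coding bases and
  the discarded 3' coding bases are congruent mod 3 (the downstream ORF
  is preserved), FRAMESHIFT when both loci are coding but incongruent,
  NO_FRAME when either breakpoint falls outside a CDS;
* a kinase role (which side is the kinase) and whether the annotated
  catalytic domain survives in the fusion product;
* the kinase's phylogenetic group (AGC, CAMK, CK1, CMGC, STE, TK, TKL,
  or OTHER).

The per-cancer-type kinase-group profile is reported as a normalized
percentage: raw per-group counts are divided by the group's pan-cancer
share ``p_g`` and rescaled to sum to 100, so cancer types are compared
against the pan-cancer background rather than absolute group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fusion_ingest import FusionCall
from .genome_model import GeneModel, Region, TranscriptLocus, locate_breakpoint

INFRAME = "INFRAME"
FRAMESHIFT = "FRAMESHIFT"
NO_FRAME = "NO_FRAME"

FIVE_KINASE = "FIVE_KINASE"
THREE_KINASE = "THREE_KINASE"
BOTH_KINASE = "BOTH_KINASE"
NO_KINASE = "NONE"

INTACT = "INTACT"
DISRUPTED = "DISRUPTED"
DOMAIN_NA = "NA"

KINASE_GROUPS = ("AGC", "CAMK", "CK1", "CMGC", "STE", "TK", "TKL", "OTHER")


@dataclass
class AnnotatedFusion:
    """A fusion call enriched with transcript-level annotation."""

    call: FusionCall
    locus5: TranscriptLocus
    locus3: TranscriptLocus
    category: tuple[str, str] = ("", "")
    frame: str = NO_FRAME
    kinase_role: str = NO_KINASE
    domain_status: str = DOMAIN_NA
    kinase_group: str | None = None

    @property
    def kinase_gene(self) -> str | None:
        if self.kinase_role == FIVE_KINASE:
            return self.call.gene5
        if self.kinase_role == THREE_KINASE:
            return self.call.gene3
        return None


def classify_breakpoint_pair(
    locus5: TranscriptLocus, locus3: TranscriptLocus
) -> tuple[str, str]:
    """Ordered (5' region, 3' region) category; introns fold into NONCODING."""

    def squash(locus: TranscriptLocus) -> str:
        if locus.region in (Region.INTRON, Region.NONCODING):
            return Region.NONCODING.value
        return locus.region.value

    return (squash(locus5), squash(locus3))


def predict_frame(locus5: TranscriptLocus, locus3: TranscriptLocus) -> str:
    """Reading-frame label of the 3' gene across the junction.

    ``locus5.cds_offset`` counts the retained 5' coding bases,
    ``locus3.cds_offset`` the discarded 3' coding bases (see the
    breakpoint convention in :mod:`fusionscape.genome_model`); the 3'
    ORF survives exactly when the two are congruent mod 3.
    """
    if locus5.region is not Region.CDS or locus3.region is not Region.CDS:
        return NO_FRAME
    if locus5.cds_offset % 3 == locus3.cds_offset % 3:
        return INFRAME
    return FRAMESHIFT


@dataclass(frozen=True)
class DomainRow:
    gene: str
    name: str
    aa_start: int  # 1-based, inclusive
    aa_end: int


def read_domain_table(path) -> list[DomainRow]:
    df = pd.read_csv(path, sep="\t")
    return [
        DomainRow(r.gene, r.domain, int(r.aa_start), int(r.aa_end))
        for r in df.itertuples()
    ]


def read_kinase_table(path) -> dict[str, str]:
    """symbol -> kinase group."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene"], df["group"]))


def _domains_for(gene: str, domains: Sequence[DomainRow]) -> list[DomainRow]:
    rows = [d for d in domains if d.gene == gene]
    if not rows:
        raise KeyError(f"kinase gene {gene!r} missing from the domain table")
    return rows


def _side_domain_intact(
    side: str,
    locus: TranscriptLocus,
    frame: str,
    dom: DomainRow,
) -> bool:
    """Does the fusion product retain this domain on the given side?

    5'-kinase: the domain is retained when the junction lies at or beyond
    the domain's C-terminal residue (boundary residue counts as retained:
    its codon is complete) or in the 3'UTR — the kinase ORF portion sits
    upstream of the junction, so the partner's frame is irrelevant.
    3'-kinase: retained when the whole ORF is carried over (breakpoint in
    the kinase's 5'UTR) or when the junction lies at or before the
    domain's N-terminal residue *and* the reading frame survives.
    """
    if side == FIVE_KINASE:
        if locus.region is Region.THREE_UTR:
            return True
        return locus.region is Region.CDS and locus.aa_pos >= dom.aa_end
    if side == THREE_KINASE:
        if locus.region is Region.FIVE_UTR:
            return True
        return (
            locus.region is Region.CDS
            and locus.aa_pos <= dom.aa_start
            and frame == INFRAME
        )
    raise ValueError(side)


def assess_domain_retention(
    fusion: AnnotatedFusion, domains: Sequence[DomainRow]
) -> str:
    """INTACT/DISRUPTED for the kinase partner's annotated domain(s).

    A gene with several annotated kinase-domain rows counts as INTACT when
    any one of them survives.
    """
    role = fusion.kinase_role
    if role not in (FIVE_KINASE, THREE_KINASE):
        raise ValueError("domain retention needs a resolved single-kinase role")
    locus = fusion.locus5 if role == FIVE_KINASE else fusion.locus3
    rows = _domains_for(fusion.kinase_gene, domains)
    intact = any(
        _side_domain_intact(role, locus, fusion.frame, d) for d in rows
    )
    return INTACT if intact else DISRUPTED


def classify_kinase_role(
    fusion: AnnotatedFusion,
    kinase_groups: Mapping[str, str],
    domains: Sequence[DomainRow],
) -> tuple[str, str | None, str]:
    """(kinase_role, kinase_group, domain_status) for a fusion.

    Both-kinase fusions with exactly one intact domain are reassigned to
    the side carrying it; with two or zero intact domains they stay
    BOTH_KINASE (domain status INTACT / DISRUPTED accordingly).
    """
    g5, g3 = fusion.call.gene5, fusion.call.gene3
    is5, is3 = g5 in kinase_groups, g3 in kinase_groups
    if not is5 and not is3:
        return NO_KINASE, None, DOMAIN_NA
    if is5 and not is3:
        role = FIVE_KINASE
    elif is3 and not is5:
        role = THREE_KINASE
    else:
        intact5 = any(
            _side_domain_intact(FIVE_KINASE, fusion.locus5, fusion.frame, d)
            for d in _domains_for(g5, domains)
        )
        intact3 = any(
            _side_domain_intact(THREE_KINASE, fusion.locus3, fusion.frame, d)
            for d in _domains_for(g3, domains)
        )
        if intact5 != intact3:
            role = FIVE_KINASE if intact5 else THREE_KINASE
        else:
            group = kinase_groups.get(g5, "OTHER")
            return (
                BOTH_KINASE,
                group if group in KINASE_GROUPS else "OTHER",
                INTACT if intact5 else DISRUPTED,
            )
    probe = AnnotatedFusion(
        call=fusion.call,
        locus5=fusion.locus5,
        locus3=fusion.locus3,
        frame=fusion.frame,
        kinase_role=role,
    )
    status = assess_domain_retention(probe, domains)
    gene = g5 if role == FIVE_KINASE else g3
    group = kinase_groups.get(gene, "OTHER")
    return role, group if group in KINASE_GROUPS else "OTHER", status


def annotate_fusion(
    call: FusionCall,
    models: Mapping[str, GeneModel],
    kinase_groups: Mapping[str, str] | None = None,
    domains: Sequence[DomainRow] | None = None,
) -> AnnotatedFusion:
    """Full annotation of one kept call: loci, category, frame, kinase."""
    m5, m3 = models[call.gene5], models[call.gene3]
    locus5 = locate_breakpoint(m5, call.bp5[1])
    locus3 = locate_breakpoint(m3, call.bp3[1])
    fusion = AnnotatedFusion(call=call, locus5=locus5, locus3=locus3)
    fusion.category = classify_breakpoint_pair(locus5, locus3)
    fusion.frame = predict_frame(locus5, locus3)
    if kinase_groups is not None and domains is not None:
        role, group, status = classify_kinase_role(fusion, kinase_groups, domains)
        fusion.kinase_role = role
        fusion.kinase_group = group
        fusion.domain_status = status
    return fusion


def normalized_group_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Background-normalized kinase-group percentages per cancer type.

    ``counts`` is a cancer type x kinase group table of fused-kinase-gene
    counts.  The pan-cancer share of group g is ``p_g = sum_c count_gc /
    sum_gc count_gc``; each cancer type's count is divided by ``p_g``
    (``n_g``) and the ``n_g`` are rescaled to percentages summing to 100.
    Groups absent pan-cancer are dropped before normalization; cancer
    types with no kinase fusions are omitted with a warning.
    """
    import warnings

    totals = counts.sum(axis=0)
    if totals.sum() <= 0:
        raise ValueError("pan-cancer kinase-fusion total is zero")
    keep = totals[totals > 0].index
    counts = counts[keep]
    p_g = totals[keep] / totals[keep].sum()

    rows = {}
    for cancer, row in counts.iterrows():
        if row.sum() == 0:
            warnings.warn(f"cancer type {cancer} has no kinase fusions; omitted")
            continue
        n_g = row / p_g
        rows[cancer] = n_g / n_g.sum() * 100.0
    return pd.DataFrame.from_dict(rows, orient="index", columns=keep)


def group_counts(fusions: Iterable[AnnotatedFusion]) -> pd.DataFrame:
    """Cancer type x kinase group table of distinct fused kinase genes."""
    seen: dict[tuple[str, str], set[str]] = {}
    for f in fusions:
        if f.kinase_gene is None or f.kinase_group is None:
            continue
        seen.setdefault((f.call.cancer_type, f.kinase_group), set()).add(
            f.kinase_gene
        )
    cancers = sorted({c for c, _ in seen})
    data = {
        g: [len(seen.get((c, g), ())) for c in cancers] for g in KINASE_GROUPS
    }
    return pd.DataFrame(data, index=cancers)


def fusions_to_frame(fusions: Iterable[AnnotatedFusion]) -> pd.DataFrame:
    """Flat table of annotated fusions for reports and serialization."""
    rows = []
    for f in fusions:
        c = f.call
        rows.append(
            {
                "call_id": c.call_id,
                "sample_id": c.sample_id,
                "cancer_type": c.cancer_type,
                "gene5": c.gene5,
                "gene3": c.gene3,
                "region5": f.category[0],
                "region3": f.category[1],
                "frame": f.frame,
                "kinase_role": f.kinase_role,
                "kinase_group": f.kinase_group or "",
                "domain_status": f.domain_status,
                "junction_reads": c.junction_reads,
            }
        )
    return pd.DataFrame(rows)
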