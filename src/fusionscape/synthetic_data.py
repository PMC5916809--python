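"""Synthetic cohort generator with known ground truth.

Every input the pipeline consumes can be generated here with labels
attached: multi-exon gene models on both strands (GTF + spliced
transcript FASTA), kinase/domain/paralog/exclusion resources, per-caller
fusion TSVs in three dialects, a log-normal expression matrix with
injected outlier shifts for fusion carriers, gene-level copy numbers, a
MAF-like mutation table with configurable driver and MSI structure,
per-sample WGS alignments with a chosen number of discordant pairs, and
a deterministic toy MHC-affinity predictor.  The same seed and config
always produce byte-identical outputs.

The default truth set covers every behaviour downstream stages must
recover: in-frame and frameshift fusions on both kinase sides, domain
intact and disrupted placements, a promoter-swap (both breakpoints in
5'UTRs), one decoy violating each of the five filter rules, an
allowlisted recurrent event that must survive rule 5, validated and
non-validated WGS support levels, and expression outlier shifts in both
directions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .breakpoint_annot import DomainRow, KINASE_GROUPS
from .fusion_ingest import (
    BREAKFAST_LIKE,
    ERICSCRIPT_LIKE,
    STARFUSION_LIKE,
    compute_ffpm,
)
from .genome_model import GeneModel

_STOP_CODONS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]

KEPT = "KEPT"


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Expression is log-normal per gene (location/scale drawn once per
    gene from the configured ranges, log2 units); fusion carriers of an
    outlier gene are shifted by ``outlier_effect`` gene-level standard
    deviations on the log scale.  ``msi_fraction`` of samples receive a
    mismatch-repair mutation plus a hypermutator burden.  WGS support is
    the intended number of qualifying discordant pairs per fusion.
    """

    seed: int = 0
    cancer_types: dict[str, int] = field(
        default_factory=lambda: {"CTA": 50, "CTB": 50}
    )
    n_genes: int = 48
    carrier_fraction: float = 0.05
    outlier_effect: float = 5.0
    expression_mu_range: tuple[float, float] = (4.0, 9.0)
    expression_sigma_range: tuple[float, float] = (0.6, 1.2)
    background_mutation_rate: float = 8.0
    msi_mutation_rate: float = 80.0
    msi_fraction: float = 0.1
    never_smoker_fraction: float = 0.15
    driver_mutation_fraction: float = 0.45
    driver_gene_mutation_fraction: float = 0.25
    wgs_support: int = 3
    total_frags: int = 40_000_000
    kinase_domain_aa: tuple[int, int] | None = None
    hla_alleles: tuple[str, ...] = ("HLA-A*01:01", "HLA-B*07:02")

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if not self.cancer_types:
            raise ValueError("need at least one cancer type")
        if not 0 <= self.msi_fraction <= 1:
            raise ValueError("msi_fraction must be in [0, 1]")


@dataclass
class Annotation:
    """Everything produced by :func:`generate_annotation`."""

    models: dict[str, GeneModel]
    transcripts: dict[str, str]
    domains: list[DomainRow]
    kinase_groups: dict[str, str]
    paralog_pairs: list[tuple[str, str]]
    exclusion_genes: list[str]
    normals_pairs: list[tuple[str, str]]
    allowlist_pairs: list[tuple[str, str]]
    driver_genes: list[str]
    chrom_lengths: dict[str, int]


@dataclass
class TruthRecord:
    """Ground-truth labels for one fusion event (shared by its carriers)."""

    fusion_id: str
    gene5: str
    gene3: str
    bp5: tuple[str, int, str]
    bp3: tuple[str, int, str]
    region_pair: tuple[str, str]
    frame: str
    kinase_role: str
    domain_status: str
    filter_fate: str  # KEPT or the rule id the event must fail
    callers: tuple[str, ...]
    samples: tuple[str, ...]
    junction_reads: int = 12
    spanning_frags: int = 8
    expression_gene: str | None = None
    expression_shift_sd: float = 0.0
    wgs_support: int = 3
    validated: bool = True


# ----------------------------------------------------------------------
# annotation
# ----------------------------------------------------------------------


def _gene_symbols(config: CohortConfig) -> tuple[list[str], dict[str, str]]:
    per_group = 2 if config.n_genes >= 40 else 1
    kinase_groups: dict[str, str] = {}
    for group in KINASE_GROUPS:
        for i in range(1, per_group + 1):
            kinase_groups[f"KIN{group}{i}"] = group
    n_other = config.n_genes - len(kinase_groups)
    if n_other < 2:
        raise ValueError("n_genes too small for the kinase panel")
    others = [f"GENE{i:02d}" for i in range(1, n_other + 1)]
    return others, kinase_groups


def generate_annotation(config: CohortConfig) -> Annotation:
    """Gene models, transcript sequences, and all filter/kinase resources."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    others, kinase_groups = _gene_symbols(config)
    symbols = others + sorted(kinase_groups)

    chroms = [f"chr{i}" for i in range(1, 5)]
    cursor = {c: 300_000 for c in chroms}
    models: dict[str, GeneModel] = {}
    transcripts: dict[str, str] = {}
    domains: list[DomainRow] = []

    for idx, symbol in enumerate(symbols):
        chrom = chroms[idx % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        u5 = int(rng.integers(30, 91))
        u3 = int(rng.integers(30, 91))
        n_codons = int(rng.integers(80, 161))  # incl. stop
        cds_len = 3 * n_codons
        L = u5 + cds_len + u3
        n_exons = int(rng.integers(2, 6))
        exon_lens = _split_lengths(rng, L, n_exons, min_len=40)
        intron_lens = [int(rng.integers(200, 801)) for _ in range(n_exons - 1)]

        start = cursor[chrom]
        genomic_exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            genomic_exons.append((pos, pos + el))
            pos += el
            if i < n_exons - 1:
                pos += intron_lens[i]
        cursor[chrom] = pos + 250_000

        exons = genomic_exons if strand == "+" else genomic_exons[::-1]
        # transcript sequence: UTRs random, CDS = ATG + sense codons + stop
        utr5 = "".join(rng.choice(list("ACGT"), size=u5))
        utr3 = "".join(rng.choice(list("ACGT"), size=u3))
        body = "".join(rng.choice(_CODONS, size=n_codons - 2))
        cds = "ATG" + body + str(rng.choice(_STOP_CODONS))
        seq = utr5 + cds + utr3
        assert len(seq) == L

        g_first = _tx_to_genomic(exons, strand, u5)
        g_last = _tx_to_genomic(exons, strand, u5 + cds_len - 1)
        model = GeneModel(
            gene_id=f"G_{symbol}",
            symbol=symbol,
            chromosome=chrom,
            strand=strand,
            exons=exons,
            transcript_id=f"T_{symbol}.1",
            is_coding=True,
            cds_start=min(g_first, g_last),
            cds_end=max(g_first, g_last) + 1,
        )
        models[symbol] = model
        transcripts[symbol] = seq

        if symbol in kinase_groups:
            P = n_codons - 1  # protein length excl. stop
            if config.kinase_domain_aa is not None:
                d_start, d_end = config.kinase_domain_aa
                if d_end > P:
                    raise ValueError(
                        f"configured kinase domain end {d_end} exceeds "
                        f"protein length {P} of {symbol}"
                    )
            else:
                d_start = max(2, P // 4)
                d_end = d_start + P // 3
            domains.append(DomainRow(symbol, "Pkinase", d_start, d_end))

    exclusion = ["IGPSEUDO1", "MTRNR2LX"]
    for sym in exclusion:
        # excluded genes get ordinary models too; the filter must reject them
        models[sym], transcripts[sym] = _clone_locus(
            rng, sym, chroms[0], cursor, models
        )

    paralogs = [(others[0], others[1])]
    normals = [(others[2], others[3])]
    allowlist = [(others[6], others[7])]
    kin_sorted = sorted(kinase_groups)
    driver_genes = sorted(
        set(others[8:14]) | {kin_sorted[0], _kinase_of(kinase_groups, "TK", 1),
                             _kinase_of(kinase_groups, "TK", 2),
                             _kinase_of(kinase_groups, "CAMK", 1)}
    )
    chrom_lengths = {c: cursor[c] + 300_000 for c in chroms}
    return Annotation(
        models=models,
        transcripts=transcripts,
        domains=domains,
        kinase_groups=kinase_groups,
        paralog_pairs=paralogs,
        exclusion_genes=exclusion,
        normals_pairs=normals,
        allowlist_pairs=allowlist,
        driver_genes=driver_genes,
        chrom_lengths=chrom_lengths,
    )


def _kinase_of(groups: Mapping[str, str], group: str, i: int) -> str:
    name = f"KIN{group}{i}"
    if name in groups:
        return name
    return next(g for g in sorted(groups) if groups[g] == group)


def _clone_locus(rng, symbol, chrom, cursor, models) -> tuple[GeneModel, str]:
    """A small single-exon coding gene for exclusion-list decoys."""
    u5, n_codons, u3 = 40, 60, 40
    L = u5 + 3 * n_codons + u3
    start = cursor[chrom]
    cursor[chrom] = start + L + 250_000
    body = "".join(rng.choice(_CODONS, size=n_codons - 2))
    seq = (
        "".join(rng.choice(list("ACGT"), size=u5))
        + "ATG"
        + body
        + "TAA"
        + "".join(rng.choice(list("ACGT"), size=u3))
    )
    model = GeneModel(
        gene_id=f"G_{symbol}",
        symbol=symbol,
        chromosome=chrom,
        strand="+",
        exons=[(start, start + L)],
        transcript_id=f"T_{symbol}.1",
        is_coding=True,
        cds_start=start + u5,
        cds_end=start + u5 + 3 * n_codons,
    )
    return model, seq


def _tx_to_genomic(
    exons: Sequence[tuple[int, int]], strand: str, t_index: int
) -> int:
    """Genomic base of a transcript offset, given exons in transcript order."""
    offset = 0
    for s, e in exons:
        n = e - s
        if t_index < offset + n:
            w = t_index - offset
            return s + w if strand == "+" else e - 1 - w
        offset += n
    raise IndexError(t_index)


def _split_lengths(rng, total: int, parts: int, min_len: int) -> list[int]:
    """Random composition of ``total`` into ``parts`` pieces >= min_len."""
    if total < parts * min_len:
        raise ValueError("transcript too short for requested exon count")
    free = total - parts * min_len
    cuts = np.sort(rng.integers(0, free + 1, size=parts - 1))
    pieces = np.diff(np.concatenate([[0], cuts, [free]]))
    return [int(min_len + p) for p in pieces]


# ----------------------------------------------------------------------
# truth design
# ----------------------------------------------------------------------


def _breakpoint_at(
    model: GeneModel, transcript_index: int
) -> tuple[str, int, str]:
    pos0 = model.genomic_position(transcript_index)
    return (model.chromosome, pos0 + 1, model.strand)


def _cds_bp(model: GeneModel, cds_offset: int) -> tuple[str, int, str]:
    return _breakpoint_at(model, model.utr5_length + cds_offset)


def _utr5_bp(model: GeneModel) -> tuple[str, int, str]:
    return _breakpoint_at(model, model.utr5_length // 2)


def _utr3_bp(model: GeneModel) -> tuple[str, int, str]:
    u = model.utr5_length + model.cds_length
    return _breakpoint_at(model, u + (model.length - u) // 2)


def _domain(domains: Sequence[DomainRow], gene: str) -> DomainRow:
    return next(d for d in domains if d.gene == gene)


def design_truth(ann: Annotation, config: CohortConfig) -> list[TruthRecord]:
    """The default labelled fusion set (see module docstring)."""
    rng = np.random.default_rng(config.seed + 1)
    others = [g for g in ann.models if g.startswith("GENE")]
    if len(others) < 26:
        raise ValueError("n_genes too small for the default truth design")
    samples = cohort_sample_ids(config)
    by_type: dict[str, list[str]] = {}
    for s, ct in samples.items():
        by_type.setdefault(ct, []).append(s)
    types = sorted(by_type)
    cta, ctb = types[0], types[-1]

    def pick(ct: str, n: int, used: set[str]) -> tuple[str, ...]:
        pool = [s for s in by_type[ct] if s not in used]
        chosen = tuple(sorted(rng.choice(pool, size=n, replace=False)))
        used.update(chosen)
        return chosen

    used: set[str] = set()
    truths: list[TruthRecord] = []
    M = ann.models

    def inframe_offsets(g5: str, g3: str, off3: int) -> tuple[int, int]:
        # any retained-5' count congruent to off3 mod 3, well inside the CDS
        off5 = 3 * (M[g5].cds_length // 6) + (off3 % 3)
        return off5, off3

    tk1 = _kinase_of(ann.kinase_groups, "TK", 1)
    tk2 = _kinase_of(ann.kinase_groups, "TK", 2)
    agc1 = _kinase_of(ann.kinase_groups, "AGC", 1)
    camk1 = _kinase_of(ann.kinase_groups, "CAMK", 1)

    # F01: inframe 3'-kinase, domain intact, overexpressed, validated
    d = _domain(ann.domains, tk1)
    off3 = 3 * max(0, d.aa_start - 3)
    off5, off3 = inframe_offsets(others[8], tk1, off3)
    truths.append(
        TruthRecord(
            fusion_id="F01",
            gene5=others[8],
            gene3=tk1,
            bp5=_cds_bp(M[others[8]], off5),
            bp3=_cds_bp(M[tk1], off3),
            region_pair=("CDS", "CDS"),
            frame="INFRAME",
            kinase_role="THREE_KINASE",
            domain_status="INTACT",
            filter_fate=KEPT,
            callers=(STARFUSION_LIKE, ERICSCRIPT_LIKE),
            samples=pick(cta, 5, used),
            expression_gene=tk1,
            expression_shift_sd=config.outlier_effect,
            wgs_support=config.wgs_support,
            validated=config.wgs_support >= 3,
        )
    )

    # F02: frameshift 3'-kinase, domain disrupted, under-supported in WGS
    d = _domain(ann.domains, tk2)
    off3 = 3 * (d.aa_start + 2) + 1  # inside the domain, off-phase
    off5 = 3 * (M[others[10]].cds_length // 6)
    truths.append(
        TruthRecord(
            fusion_id="F02",
            gene5=others[10],
            gene3=tk2,
            bp5=_cds_bp(M[others[10]], off5),
            bp3=_cds_bp(M[tk2], off3),
            region_pair=("CDS", "CDS"),
            frame="FRAMESHIFT",
            kinase_role="THREE_KINASE",
            domain_status="DISRUPTED",
            filter_fate=KEPT,
            callers=(STARFUSION_LIKE,),
            samples=pick(ctb, 4, used),
            wgs_support=2,
            validated=False,
        )
    )

    # F03: inframe 5'-kinase with the domain upstream of the junction
    d = _domain(ann.domains, agc1)
    off5 = 3 * (d.aa_end + 4)
    off5, off3 = off5, (3 * (M[others[11]].cds_length // 6) + off5 % 3)
    truths.append(
        TruthRecord(
            fusion_id="F03",
            gene5=agc1,
            gene3=others[11],
            bp5=_cds_bp(M[agc1], off5),
            bp3=_cds_bp(M[others[11]], off3),
            region_pair=("CDS", "CDS"),
            frame="INFRAME",
            kinase_role="FIVE_KINASE",
            domain_status="INTACT",
            filter_fate=KEPT,
            callers=(STARFUSION_LIKE, BREAKFAST_LIKE),
            samples=pick(cta, 3, used),
            wgs_support=config.wgs_support,
            validated=config.wgs_support >= 3,
        )
    )

    # F04: promoter swap — both breakpoints in 5'UTRs, kinase ORF intact
    truths.append(
        TruthRecord(
            fusion_id="F04",
            gene5=others[12],
            gene3=camk1,
            bp5=_utr5_bp(M[others[12]]),
            bp3=_utr5_bp(M[camk1]),
            region_pair=("FIVE_UTR", "FIVE_UTR"),
            frame="NO_FRAME",
            kinase_role="THREE_KINASE",
            domain_status="INTACT",
            filter_fate=KEPT,
            callers=(ERICSCRIPT_LIKE, BREAKFAST_LIKE),
            samples=pick(ctb, 5, used),
            junction_reads=9,
            expression_gene=camk1,
            expression_shift_sd=config.outlier_effect,
            wgs_support=config.wgs_support,
            validated=config.wgs_support >= 3,
        )
    )

    # F05: frameshift TSG fusion with under-expression of the 5' gene
    off5 = 3 * (M[others[13]].cds_length // 6) + 1
    off3 = 3 * (M[others[14]].cds_length // 6)
    truths.append(
        TruthRecord(
            fusion_id="F05",
            gene5=others[13],
            gene3=others[14],
            bp5=_cds_bp(M[others[13]], off5),
            bp3=_cds_bp(M[others[14]], off3),
            region_pair=("CDS", "CDS"),
            frame="FRAMESHIFT",
            kinase_role="NONE",
            domain_status="NA",
            filter_fate=KEPT,
            callers=(STARFUSION_LIKE,),
            samples=pick(cta, 5, used),
            expression_gene=others[13],
            expression_shift_sd=-config.outlier_effect,
            wgs_support=config.wgs_support,
            validated=config.wgs_support >= 3,
        )
    )

    # F06: inframe but too few junction reads for neoantigen calling
    off5, off3 = inframe_offsets(others[15], others[16], 3 * 10)
    truths.append(
        TruthRecord(
            fusion_id="F06",
            gene5=others[15],
            gene3=others[16],
            bp5=_cds_bp(M[others[15]], off5),
            bp3=_cds_bp(M[others[16]], off3),
            region_pair=("CDS", "CDS"),
            frame="INFRAME",
            kinase_role="NONE",
            domain_status="NA",
            filter_fate=KEPT,
            callers=(STARFUSION_LIKE, ERICSCRIPT_LIKE),
            samples=pick(ctb, 2, used),
            junction_reads=4,
            wgs_support=config.wgs_support,
            validated=config.wgs_support >= 3,
        )
    )

    # F07-F10: extra inframe/frameshift events for the neoepitope contrast
    extra = [
        ("F07", others[17], others[18], "INFRAME"),
        ("F08", others[19], others[20], "INFRAME"),
        ("F09", others[21], others[22], "FRAMESHIFT"),
        ("F10", others[23], others[24], "FRAMESHIFT"),
    ]
    for fid, g5, g3, frame in extra:
        off3 = 3 * (M[g3].cds_length // 6)
        if frame == "INFRAME":
            off5, off3 = inframe_offsets(g5, g3, off3)
        else:
            off5 = 3 * (M[g5].cds_length // 6) + 1
        truths.append(
            TruthRecord(
                fusion_id=fid,
                gene5=g5,
                gene3=g3,
                bp5=_cds_bp(M[g5], off5),
                bp3=_cds_bp(M[g3], off3),
                region_pair=("CDS", "CDS"),
                frame=frame,
                kinase_role="NONE",
                domain_status="NA",
                filter_fate=KEPT,
                callers=(STARFUSION_LIKE, ERICSCRIPT_LIKE),
                samples=pick(cta if fid in ("F07", "F09") else ctb, 2, used),
                wgs_support=config.wgs_support,
                validated=config.wgs_support >= 3,
            )
        )

    # decoys: one per filter rule
    def cds_pair(g5: str, g3: str) -> tuple:
        off5, off3 = inframe_offsets(g5, g3, 3 * 8)
        return _cds_bp(M[g5], off5), _cds_bp(M[g3], off3)

    bp5, bp3 = cds_pair(ann.exclusion_genes[0], others[15])
    truths.append(
        TruthRecord(
            fusion_id="D1",
            gene5=ann.exclusion_genes[0],
            gene3=others[15],
            bp5=bp5,
            bp3=bp3,
            region_pair=("CDS", "CDS"),
            frame="INFRAME",
            kinase_role="NONE",
            domain_status="NA",
            filter_fate="R1_EXCLUDED_GENE",
            callers=(STARFUSION_LIKE,),
            samples=pick(cta, 2, used),
            wgs_support=0,
            validated=False,
        )
    )
    pa, pb = ann.paralog_pairs[0]
    bp5, bp3 = cds_pair(pa, pb)
    truths.append(
        TruthRecord(
            fusion_id="D2",
            gene5=pa,
            gene3=pb,
            bp5=bp5,
            bp3=bp3,
            region_pair=("CDS", "CDS"),
            frame="INFRAME",
            kinase_role="NONE",
            domain_status="NA",
            filter_fate="R2_SELF_OR_PARALOG",
            callers=(STARFUSION_LIKE, ERICSCRIPT_LIKE),
            samples=pick(ctb, 2, used),
            wgs_support=0,
            validated=False,
        )
    )
    na, nb = ann.normals_pairs[0]
    bp5, bp3 = cds_pair(na, nb)
    truths.append(
        TruthRecord(
            fusion_id="D3",
            gene5=na,
            gene3=nb,
            bp5=bp5,
            bp3=bp3,
            region_pair=("CDS", "CDS"),
            frame="INFRAME",
            kinase_role="NONE",
            domain_status="NA",
            filter_fate="R3_NORMALS_PANEL",
            callers=(STARFUSION_LIKE,),
            samples=pick(cta, 2, used),
            wgs_support=0,
            validated=False,
        )
    )
    bp5, bp3 = cds_pair(others[16], others[17])
    truths.append(
        TruthRecord(
            fusion_id="D4",
            gene5=others[16],
            gene3=others[17],
            bp5=bp5,
            bp3=bp3,
            region_pair=("CDS", "CDS"),
            frame="INFRAME",
            kinase_role="NONE",
            domain_status="NA",
            filter_fate="R4_FFPM",
            callers=(STARFUSION_LIKE,),
            samples=pick(ctb, 1, used),
            junction_reads=1,
            spanning_frags=1,
            wgs_support=0,
            validated=False,
        )
    )
    # D5: identical breakpoints recurring across both cancer types
    bp5, bp3 = cds_pair(others[4], others[5])
    rec_samples = pick(cta, 5, used) + pick(ctb, 5, used)
    truths.append(
        TruthRecord(
            fusion_id="D5",
            gene5=others[4],
            gene3=others[5],
            bp5=bp5,
            bp3=bp3,
            region_pair=("CDS", "CDS"),
            frame="INFRAME",
            kinase_role="NONE",
            domain_status="NA",
            filter_fate="R5_RECURRENT_ARTIFACT",
            callers=(STARFUSION_LIKE, ERICSCRIPT_LIKE),
            samples=rec_samples,
            wgs_support=0,
            validated=False,
        )
    )
    # A1: equally recurrent but allowlisted — must be kept
    aa, ab = ann.allowlist_pairs[0]
    bp5, bp3 = cds_pair(aa, ab)
    rec_samples = pick(cta, 5, used) + pick(ctb, 5, used)
    truths.append(
        TruthRecord(
            fusion_id="A1",
            gene5=aa,
            gene3=ab,
            bp5=bp5,
            bp3=bp3,
            region_pair=("CDS", "CDS"),
            frame="INFRAME",
            kinase_role="NONE",
            domain_status="NA",
            filter_fate=KEPT,
            callers=(STARFUSION_LIKE, ERICSCRIPT_LIKE),
            samples=rec_samples,
            wgs_support=config.wgs_support,
            validated=config.wgs_support >= 3,
        )
    )
    return truths


# ----------------------------------------------------------------------
# cohort tables
# ----------------------------------------------------------------------


def cohort_sample_ids(config: CohortConfig) -> dict[str, str]:
    """sample id -> cancer type, stable across runs."""
    out: dict[str, str] = {}
    i = 1
    for ct in sorted(config.cancer_types):
        for _ in range(config.cancer_types[ct]):
            out[f"S{i:04d}"] = ct
            i += 1
    return out


def simulate_cohort(
    truth: Sequence[TruthRecord], ann: Annotation, config: CohortConfig
) -> dict[str, pd.DataFrame]:
    """Expression, copy number, MAF-like mutations, and sample metadata."""
    rng = np.random.default_rng(config.seed + 2)
    samples = cohort_sample_ids(config)
    sample_ids = list(samples)
    genes = sorted(ann.models)

    # expression: per-gene log-normal with carrier shifts
    mu = rng.uniform(*config.expression_mu_range, size=len(genes))
    sigma = rng.uniform(*config.expression_sigma_range, size=len(genes))
    z = rng.normal(mu[:, None], sigma[:, None], size=(len(genes), len(sample_ids)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    col_idx = {s: j for j, s in enumerate(sample_ids)}
    for t in truth:
        if t.expression_gene is None or t.filter_fate != KEPT:
            continue
        gi = gene_idx[t.expression_gene]
        for s in t.samples:
            z[gi, col_idx[s]] += t.expression_shift_sd * sigma[gi]
    expression = pd.DataFrame(
        np.round(np.exp2(z) - 1.0, 4), index=genes, columns=sample_ids
    )

    # copy number: mostly neutral; one F01 carrier amplified to exercise
    # the copy filter
    copy = pd.DataFrame(
        rng.choice([1, 2, 2, 2, 2, 3], size=(len(genes), len(sample_ids))),
        index=genes,
        columns=sample_ids,
    )
    for t in truth:
        if t.kinase_role in ("FIVE_KINASE", "THREE_KINASE") and t.filter_fate == KEPT:
            kin = t.gene5 if t.kinase_role == "FIVE_KINASE" else t.gene3
            for s in t.samples:
                copy.loc[kin, s] = 2
    f01 = next((t for t in truth if t.fusion_id == "F01"), None)
    if f01 is not None:
        copy.loc[f01.gene3, f01.samples[0]] = 4

    # mutations
    n = len(sample_ids)
    n_msi = int(round(config.msi_fraction * n))
    msi_samples = set(rng.choice(sample_ids, size=n_msi, replace=False))
    classes = [
        "Missense_Mutation",
        "Silent",
        "Nonsense_Mutation",
        "Splice_Site",
        "In_Frame_Del",
        "3'UTR",
    ]
    class_p = [0.45, 0.25, 0.1, 0.08, 0.06, 0.06]
    non_driver = [g for g in genes if g not in set(ann.driver_genes)]
    rows = []
    for s in sample_ids:
        rate = config.background_mutation_rate + (
            config.msi_mutation_rate if s in msi_samples else 0.0
        )
        for _ in range(int(rng.poisson(rate))):
            rows.append(
                {
                    "Hugo_Symbol": str(rng.choice(non_driver)),
                    "Tumor_Sample_Barcode": s,
                    "Variant_Classification": str(
                        rng.choice(classes, p=class_p)
                    ),
                    "is_driver": False,
                }
            )
        if s in msi_samples:
            rows.append(
                {
                    "Hugo_Symbol": str(rng.choice(["MSH2", "MLH1", "POLE"])),
                    "Tumor_Sample_Barcode": s,
                    "Variant_Classification": "Nonsense_Mutation",
                    "is_driver": False,
                }
            )
        r = rng.random()
        if r < config.driver_mutation_fraction:
            rows.append(
                {
                    "Hugo_Symbol": str(rng.choice(ann.driver_genes)),
                    "Tumor_Sample_Barcode": s,
                    "Variant_Classification": "Missense_Mutation",
                    "is_driver": True,
                }
            )
        elif r < config.driver_mutation_fraction + config.driver_gene_mutation_fraction:
            rows.append(
                {
                    "Hugo_Symbol": str(rng.choice(ann.driver_genes)),
                    "Tumor_Sample_Barcode": s,
                    "Variant_Classification": "Missense_Mutation",
                    "is_driver": False,
                }
            )
    maf = pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol",
            "Tumor_Sample_Barcode",
            "Variant_Classification",
            "is_driver",
        ],
    )

    smoking = [
        "never" if rng.random() < config.never_smoker_fraction else "smoker"
        for _ in sample_ids
    ]
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cancer_type": [samples[s] for s in sample_ids],
            "smoking_status": smoking,
            "hla_alleles": ";".join(config.hla_alleles),
            "has_wgs": True,
        }
    ).set_index("sample_id")

    return {
        "expression": expression,
        "copy_number": copy,
        "maf": maf,
        "metadata": metadata,
    }


# ----------------------------------------------------------------------
# caller TSVs
# ----------------------------------------------------------------------


def simulate_fusion_calls(
    truth: Sequence[TruthRecord], config: CohortConfig, outdir: str | Path
) -> dict[str, Path]:
    """Write the three per-caller TSV dialects for the whole cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = cohort_sample_ids(config)
    rows: dict[str, list[list]] = {
        STARFUSION_LIKE: [],
        ERICSCRIPT_LIKE: [],
        BREAKFAST_LIKE: [],
    }
    for t in truth:
        for s in t.samples:
            ct = samples[s]
            c5, p5, s5 = t.bp5
            c3, p3, s3 = t.bp3
            support = t.junction_reads + t.spanning_frags
            ffpm = compute_ffpm(support, config.total_frags)
            if STARFUSION_LIKE in t.callers:
                rows[STARFUSION_LIKE].append(
                    [
                        f"{t.gene5}--{t.gene3}",
                        t.junction_reads,
                        t.spanning_frags,
                        t.gene5,
                        f"{c5}:{p5}:{s5}",
                        t.gene3,
                        f"{c3}:{p3}:{s3}",
                        f"{ffpm:.6g}",
                        s,
                        ct,
                        config.total_frags,
                    ]
                )
            if ERICSCRIPT_LIKE in t.callers:
                rows[ERICSCRIPT_LIKE].append(
                    [
                        s,
                        ct,
                        t.gene5,
                        t.gene3,
                        c5,
                        p5,
                        s5,
                        c3,
                        p3,
                        s3,
                        t.junction_reads,
                        t.spanning_frags,
                        config.total_frags,
                    ]
                )
            if BREAKFAST_LIKE in t.callers:
                rows[BREAKFAST_LIKE].append(
                    [
                        s,
                        ct,
                        t.gene5,
                        t.gene3,
                        c5,
                        p5,
                        s5,
                        c3,
                        p3,
                        s3,
                        t.junction_reads,
                        config.total_frags,
                    ]
                )

    from .fusion_ingest import _DIALECT_HEADERS

    paths = {}
    names = {
        STARFUSION_LIKE: "calls_starfusion.tsv",
        ERICSCRIPT_LIKE: "calls_ericscript.tsv",
        BREAKFAST_LIKE: "calls_breakfast.tsv",
    }
    for dialect, fname in names.items():
        path = outdir / fname
        with open(path, "w") as fh:
            fh.write("\t".join(_DIALECT_HEADERS[dialect]) + "\n")
            for row in rows[dialect]:
                fh.write("\t".join(str(x) for x in row) + "\n")
        paths[dialect] = path
    return paths


# ----------------------------------------------------------------------
# WGS support
# ----------------------------------------------------------------------


def simulate_wgs_support(
    truth: Sequence[TruthRecord],
    ann: Annotation,
    config: CohortConfig,
    outdir: str | Path,
    with_header: bool = True,
    decoy_mapq: int = 10,
) -> dict[str, Path]:
    """One SAM file per carrier sample with the intended discordant support.

    For each fusion the configured number of qualifying pairs is written
    (one mate in each partner-gene window, MAPQ 60), plus one concordant
    decoy pair inside the 5' gene window and one low-MAPQ pair that must
    not be counted downstream.
    """
    if not with_header:
        raise ValueError("SAM output requires a header")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chroms = sorted(ann.chrom_lengths)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": c, "LN": int(ann.chrom_lengths[c])} for c in chroms
            ],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}

    per_sample: dict[str, list[pysam.AlignedSegment]] = {}

    def pair(qname, c1, p1, c2, p2, mapq):
        recs = []
        for i, (c, p, co, po) in enumerate(
            [(c1, p1, c2, p2), (c2, p2, c1, p1)]
        ):
            rec = pysam.AlignedSegment(header)
            rec.query_name = qname
            rec.query_sequence = "A" * 100
            rec.flag = 0x1 | (0x40 if i == 0 else 0x80)
            rec.reference_id = tid[c]
            rec.reference_start = p
            rec.mapping_quality = mapq
            rec.cigar = [(0, 100)]
            rec.next_reference_id = tid[co]
            rec.next_reference_start = po
            recs.append(rec)
        return recs

    for t in truth:
        m5, m3 = ann.models[t.gene5], ann.models[t.gene3]
        mid5 = sum(m5.span) // 2
        mid3 = sum(m3.span) // 2
        for s in t.samples:
            bucket = per_sample.setdefault(s, [])
            for i in range(t.wgs_support):
                bucket.extend(
                    pair(
                        f"{t.fusion_id}:{s}:disc{i}",
                        m5.chromosome,
                        mid5 + 10 * i,
                        m3.chromosome,
                        mid3 + 10 * i,
                        60,
                    )
                )
            # concordant decoy: both mates near the 5' gene
            bucket.extend(
                pair(
                    f"{t.fusion_id}:{s}:conc",
                    m5.chromosome,
                    mid5,
                    m5.chromosome,
                    mid5 + 300,
                    60,
                )
            )
            # low-quality cross-locus pair: must be ignored at MAPQ>=20
            bucket.extend(
                pair(
                    f"{t.fusion_id}:{s}:lowq",
                    m5.chromosome,
                    mid5 + 5,
                    m3.chromosome,
                    mid3 + 5,
                    decoy_mapq,
                )
            )

    paths = {}
    for sample, records in sorted(per_sample.items()):
        path = outdir / f"{sample}.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for rec in records:
                fh.write(rec)
        paths[sample] = path
    return paths


# ----------------------------------------------------------------------
# toy affinity model
# ----------------------------------------------------------------------


class ToyAffinityPredictor:
    """Deterministic hash-based peptide/allele -> affinity (nM) mapping.

    Not a binding model: a seeded stand-in for an MHC predictor with the
    same call contract.  Affinities fall in (0, 50000]; peptides
    containing a designated strong-binder motif always score <= 500 nM.
    The marginal strong-binder rate of non-motif peptides is ~10%
    (affinity = 50000 * u^2 for hash-uniform u).
    """

    def __init__(self, seed: int, strong_motifs: Sequence[str] = ()):
        self.seed = int(seed)
        self.strong_motifs = tuple(strong_motifs)

    def _u(self, peptide: str, allele: str) -> float:
        digest = hashlib.sha256(
            f"{self.seed}|{peptide}|{allele}".encode()
        ).digest()
        x = int.from_bytes(digest[:8], "big")
        return (x % 10**9 + 1) / 10**9  # in (0, 1]

    def predict(self, peptide: str, allele: str) -> float:
        if not 8 <= len(peptide) <= 11:
            raise ValueError(
                f"peptide length {len(peptide)} outside 8-11: {peptide!r}"
            )
        u = self._u(peptide, allele)
        if any(m in peptide for m in self.strong_motifs):
            return u * 500.0
        return 50000.0 * u * u


def toy_affinity_model(
    seed: int, strong_motifs: Sequence[str] = ()
) -> ToyAffinityPredictor:
    return ToyAffinityPredictor(seed, strong_motifs)


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------


def write_gtf(ann: Annotation, path: str | Path) -> None:
    """Emit the annotation as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for symbol in sorted(ann.models):
            m = ann.models[symbol]
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_name "{m.symbol}"; gene_biotype "protein_coding";'
            )
            lo, hi = m.span
            for feat, s, e in [("gene", lo, hi), ("transcript", lo, hi)]:
                fh.write(
                    f"{m.chromosome}\tfusionscape\t{feat}\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
            for s, e in sorted(m.exons):
                fh.write(
                    f"{m.chromosome}\tfusionscape\texon\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
                if m.is_coding:
                    cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                    if ce > cs:
                        fh.write(
                            f"{m.chromosome}\tfusionscape\tCDS\t{cs + 1}\t{ce}"
                            f"\t.\t{m.strand}\t.\t{attrs}\n"
                        )


def write_transcript_fasta(ann: Annotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for symbol in sorted(ann.transcripts):
            seq = ann.transcripts[symbol]
            fh.write(f">{symbol}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def default_drug_table(ann: Annotation) -> pd.DataFrame:
    """A small drug-evidence table targeting genes in the truth design."""
    tk1 = _kinase_of(ann.kinase_groups, "TK", 1)
    camk1 = _kinase_of(ann.kinase_groups, "CAMK", 1)
    others = sorted(g for g in ann.models if g.startswith("GENE"))
    return pd.DataFrame(
        [
            {
                "gene": tk1,
                "partner": "",
                "cancer_types": "CTA",
                "drug": "inhibitor_a",
                "label": "ON_LABEL",
            },
            {
                "gene": camk1,
                "partner": "",
                "cancer_types": "",
                "drug": "inhibitor_b",
                "label": "OFF_LABEL",
            },
            {
                "gene": others[17],
                "partner": others[18],
                "cancer_types": "",
                "drug": "inhibitor_c",
                "label": "ON_LABEL",
            },
        ]
    )


def generate_cohort(config: CohortConfig, outdir: str | Path) -> dict:
    """Generate and write every pipeline input; returns paths and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = generate_annotation(config)
    truth = design_truth(ann, config)
    tables = simulate_cohort(truth, ann, config)
    caller_paths = simulate_fusion_calls(truth, config, outdir)
    wgs_paths = simulate_wgs_support(truth, ann, config, outdir / "wgs")

    write_gtf(ann, outdir / "annotation.gtf")
    write_transcript_fasta(ann, outdir / "transcripts.fa")
    pd.DataFrame(
        [
            {"gene": d.gene, "domain": d.name, "aa_start": d.aa_start, "aa_end": d.aa_end}
            for d in ann.domains
        ]
    ).to_csv(outdir / "domains.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(ann.kinase_groups.items()), columns=["gene", "group"]
    ).to_csv(outdir / "kinases.tsv", sep="\t", index=False)
    (outdir / "exclusion.txt").write_text(
        "".join(f"{g}\n" for g in ann.exclusion_genes)
    )
    (outdir / "paralogs.tsv").write_text(
        "".join(f"{a}\t{b}\n" for a, b in ann.paralog_pairs)
    )
    (outdir / "normals_panel.tsv").write_text(
        "".join(f"{a}\t{b}\n" for a, b in ann.normals_pairs)
    )
    (outdir / "allowlist.tsv").write_text(
        "".join(f"{a}\t{b}\n" for a, b in ann.allowlist_pairs)
    )
    (outdir / "drivers.txt").write_text(
        "".join(f"{g}\n" for g in ann.driver_genes)
    )
    default_drug_table(ann).to_csv(outdir / "drugs.tsv", sep="\t", index=False)

    tables["expression"].to_csv(outdir / "expression.tsv", sep="\t")
    tables["copy_number"].to_csv(outdir / "copy_number.tsv", sep="\t")
    tables["maf"].to_csv(outdir / "mutations.maf", sep="\t", index=False)
    tables["metadata"].to_csv(outdir / "metadata.tsv", sep="\t")

    truth_json = [
        {**asdict(t), "bp5": list(t.bp5), "bp3": list(t.bp3)} for t in truth
    ]
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1))

    return {
        "annotation": ann,
        "truth": truth,
        "tables": tables,
        "caller_paths": caller_paths,
        "wgs_paths": wgs_paths,
        "outdir": outdir,
    }
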