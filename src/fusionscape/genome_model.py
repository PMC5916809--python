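"""Gene/transcript data model and coordinate mapping.

The package works with one canonical transcript per gene.  A
:class:`GeneModel` stores the transcript's exon chain in genomic
coordinates (internally 0-based half-open, exons ordered 5'->3' along the
transcript, i.e. genomically descending for minus-strand genes) together
with the genomic span of the coding region.  :func:`locate_breakpoint`
maps a genomic fusion breakpoint onto the transcript and reports which
functional region it falls in (5'UTR, CDS, 3'UTR, intron, or non-coding)
plus, for coding loci, the coding-base offset and protein residue.

Breakpoint convention
---------------------
Fusion callers report one genomic coordinate per partner.  Throughout the
package a breakpoint coordinate is read as the *junction base*: the first
base of the transcript segment lying 3' of the junction.  For the 3'
partner this is the first retained base; for the 5' partner it is the
first base *not* retained.  Under this single convention
``TranscriptLocus.cds_offset`` (coding bases strictly 5' of the
breakpoint) simultaneously counts the retained coding bases of a 5'
partner and the discarded coding bases of a 3' partner, which is exactly
what reading-frame prediction needs.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq


class Region(str, Enum):
    """Functional region of a transcript position."""

    FIVE_UTR = "FIVE_UTR"
    CDS = "CDS"
    THREE_UTR = "THREE_UTR"
    INTRON = "INTRON"
    NONCODING = "NONCODING"


class GTFParseError(ValueError):
    """Raised for malformed GTF input; carries the offending line number."""


class BreakpointOutOfRange(ValueError):
    """Genomic position outside the gene span."""


class AmbiguousSequenceError(ValueError):
    """CDS contains non-ACGT characters; positions are listed in args."""


@dataclass(frozen=True)
class TranscriptLocus:
    """Where a genomic breakpoint lands on a transcript.

    ``cds_offset`` counts coding bases strictly 5' of the breakpoint along
    the transcript; it is only defined for CDS loci, as are ``aa_pos``
    (1-based residue containing the breakpoint base) and ``codon_phase``
    (``cds_offset mod 3``).
    """

    region: Region
    cds_offset: int | None = None
    aa_pos: int | None = None
    codon_phase: int | None = None


@dataclass
class GeneModel:
    """One canonical transcript of a gene.

    exons: genomic intervals, 0-based half-open, in transcript (5'->3')
    order.  ``cds_start``/``cds_end`` delimit the genomic span of the
    coding region (half-open; includes the stop codon) when ``is_coding``.
    """

    gene_id: str
    symbol: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    transcript_id: str
    is_coding: bool = False
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon interval ({s}, {e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError("exons overlap")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError("exons not in transcript (5'->3') order")
        if self.is_coding:
            if self.cds_start is None or self.cds_end is None:
                raise ValueError("coding model requires cds_start/cds_end")
            if not (self.span[0] <= self.cds_start < self.cds_end <= self.span[1]):
                raise ValueError("CDS outside exon span")

    # ------------------------------------------------------------------
    # derived geometry
    # ------------------------------------------------------------------
    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) half-open span over all exons."""
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    @property
    def length(self) -> int:
        """Transcript length (sum of exon lengths)."""
        return sum(e - s for s, e in self.exons)

    def _coding_mask(self, s: int, e: int) -> tuple[int, int]:
        """Overlap of exon [s, e) with the genomic CDS span."""
        lo = max(s, self.cds_start)
        hi = min(e, self.cds_end)
        return (lo, hi) if hi > lo else (0, 0)

    @property
    def cds_length(self) -> int:
        if not self.is_coding:
            return 0
        total = 0
        for s, e in self.exons:
            lo, hi = self._coding_mask(s, e)
            total += hi - lo
        return total

    @property
    def utr5_length(self) -> int:
        """Transcript bases 5' of the first coding base."""
        if not self.is_coding:
            return 0
        n = 0
        for s, e in self.exons:
            if self.strand == "+":
                n += min(e, self.cds_start) - s if s < self.cds_start else 0
            else:
                n += e - max(s, self.cds_end) if e > self.cds_end else 0
        return n

    # ------------------------------------------------------------------
    # coordinate mapping
    # ------------------------------------------------------------------
    def transcript_index(self, genomic_pos0: int) -> int | None:
        """0-based transcript offset of a genomic base, or None if intronic."""
        offset = 0
        for s, e in self.exons:
            if s <= genomic_pos0 < e:
                if self.strand == "+":
                    return offset + (genomic_pos0 - s)
                return offset + (e - 1 - genomic_pos0)
            offset += e - s
        return None

    def genomic_position(self, t_index: int) -> int:
        """Genomic 0-based coordinate of a transcript offset (inverse map)."""
        if not 0 <= t_index < self.length:
            raise IndexError(f"transcript index {t_index} out of range")
        offset = 0
        for s, e in self.exons:
            n = e - s
            if t_index < offset + n:
                within = t_index - offset
                return s + within if self.strand == "+" else e - 1 - within
            offset += n
        raise AssertionError("unreachable")


def locate_breakpoint(model: GeneModel, genomic_pos: int) -> TranscriptLocus:
    """Map a 1-based genomic breakpoint onto the transcript.

    Returns the region of the breakpoint base plus, for CDS loci, the
    count of coding bases strictly 5' of it (``cds_offset``), the 1-based
    residue number (``aa_pos = cds_offset // 3 + 1``), and codon phase.
    Positions between exons map to INTRON; any position in a non-coding
    gene maps to NONCODING.
    """
    p0 = genomic_pos - 1
    lo, hi = model.span
    if not lo <= p0 < hi:
        raise BreakpointOutOfRange(
            f"position {genomic_pos} outside {model.symbol} span "
            f"[{lo + 1}, {hi}] on {model.chromosome}"
        )
    if not model.is_coding:
        return TranscriptLocus(region=Region.NONCODING)
    t = model.transcript_index(p0)
    if t is None:
        return TranscriptLocus(region=Region.INTRON)
    u5 = model.utr5_length
    ncds = model.cds_length
    if t < u5:
        return TranscriptLocus(region=Region.FIVE_UTR)
    if t < u5 + ncds:
        cds_offset = t - u5
        return TranscriptLocus(
            region=Region.CDS,
            cds_offset=cds_offset,
            aa_pos=cds_offset // 3 + 1,
            codon_phase=cds_offset % 3,
        )
    return TranscriptLocus(region=Region.THREE_UTR)


def transcript_protein(model: GeneModel, transcript_sequence: str) -> str:
    """Translate the CDS of a coding model, stopping at the first stop codon.

    ``transcript_sequence`` is the spliced transcript (5'->3'), so its
    length must equal the exon-union length of the model.
    """
    if not model.is_coding:
        raise ValueError(f"{model.symbol} is non-coding")
    if len(transcript_sequence) != model.length:
        raise ValueError(
            f"sequence length {len(transcript_sequence)} != transcript "
            f"length {model.length} for {model.transcript_id}"
        )
    u5 = model.utr5_length
    cds = transcript_sequence[u5 : u5 + model.cds_length].upper()
    bad = [i for i, b in enumerate(cds) if b not in "ACGT"]
    if bad:
        raise AmbiguousSequenceError(
            f"ambiguous bases in CDS of {model.transcript_id} at CDS "
            f"positions {bad}"
        )
    return str(Seq(cds).translate(to_stop=True))


# ----------------------------------------------------------------------
# GTF ingestion
# ----------------------------------------------------------------------

_GTF_DIALECTS = {"generic", "ensembl", "refseq"}


def read_gtf(path: str | Path, source_dialect: str = "generic") -> dict[str, GeneModel]:
    """Read a GTF file into one canonical GeneModel per gene, keyed by symbol.

    One transcript is selected per gene: the longest CDS among coding
    transcripts (longest exon union for wholly non-coding genes), ties
    broken by smallest transcript_id.  GTF coordinates (1-based closed)
    are converted to the internal 0-based half-open convention.
    """
    if source_dialect not in _GTF_DIALECTS:
        raise ValueError(f"unknown GTF dialect {source_dialect!r}")
    path = Path(path)
    # Validate field count up front so errors carry a line number; gffutils
    # does the attribute parsing.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise GTFParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields"
                )

    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[str, list] = defaultdict(list)
    cdss: dict[str, list] = defaultdict(list)
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS"}:
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        gid = feat.attributes.get("gene_id", [None])[0]
        if tid is None or gid is None:
            raise GTFParseError(
                f"{path}: {feat.featuretype} feature missing "
                "gene_id/transcript_id attributes"
            )
        symbol = feat.attributes.get("gene_name", [gid])[0]
        meta.setdefault(
            tid,
            {
                "gene_id": gid,
                "symbol": symbol,
                "chromosome": feat.seqid,
                "strand": feat.strand,
            },
        )
        interval = (feat.start - 1, feat.end)  # to 0-based half-open
        (exons if feat.featuretype == "exon" else cdss)[tid].append(interval)

    # group transcripts by gene, pick the canonical one
    by_gene: dict[str, list[str]] = defaultdict(list)
    for tid, info in meta.items():
        by_gene[info["gene_id"]].append(tid)

    models: dict[str, GeneModel] = {}
    for gid, tids in by_gene.items():
        candidates = []
        for tid in tids:
            if tid not in exons:
                warnings.warn(f"transcript {tid} of {gid} has no exons; skipped")
                continue
            cds_len = sum(e - s for s, e in cdss.get(tid, []))
            exon_len = sum(e - s for s, e in exons[tid])
            candidates.append((cds_len, exon_len, tid))
        if not candidates:
            warnings.warn(f"gene {gid} has no transcript with exons; skipped")
            continue
        candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
        cds_len, _, tid = candidates[0]
        info = meta[tid]
        ex = sorted(exons[tid])
        if info["strand"] == "-":
            ex = ex[::-1]
        kwargs: dict = {}
        if cds_len > 0:
            kwargs["is_coding"] = True
            kwargs["cds_start"] = min(s for s, _ in cdss[tid])
            kwargs["cds_end"] = max(e for _, e in cdss[tid])
        model = GeneModel(
            gene_id=gid,
            symbol=info["symbol"],
            chromosome=info["chromosome"],
            strand=info["strand"],
            exons=ex,
            transcript_id=tid,
            **kwargs,
        )
        models[model.symbol] = model
    return models
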