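"""WGS discordant-read-pair validation of RNA-derived fusion calls.

A fusion called from RNA-seq is corroborated by genomic evidence when
enough WGS read pairs straddle the two partner loci: one mate maps near
the 5' partner gene, the other near the 3' partner.  "Near" means within
the gene span extended by a flank (default 100 kb up- and downstream),
and both mates must be confidently mapped (MAPQ >= 20 by default).  At
least ``min_pairs`` such pairs (default 3) validate the call; samples
without WGS are NOT_EVALUABLE and excluded from the validation rate.

Discordance is defined purely by window membership, not by SAM
proper-pair flags, so low-pass and high-pass libraries can be mixed.
When the two partner windows overlap (genomic-neighbor partners), the
shared interval is carved out of both windows: a pair falling entirely
inside the overlap is ordinary concordant coverage and must not
self-validate the fusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .genome_model import GeneModel

VALIDATED = "VALIDATED"
NOT_VALIDATED = "NOT_VALIDATED"
NOT_EVALUABLE = "NOT_EVALUABLE"

#: (chromosome, start, end) 0-based half-open
Window = tuple[str, int, int]


@dataclass(frozen=True)
class ValidationResult:
    call_id: str
    n_discordant: int
    status: str


def partner_windows(
    gene5: str,
    gene3: str,
    models: Mapping[str, GeneModel],
    flank: int = 100_000,
) -> tuple[Window, Window]:
    """Gene spans +- flank for both partners, clipped at chromosome start."""

    def window(symbol: str) -> Window:
        try:
            m = models[symbol]
        except KeyError:
            raise KeyError(f"gene {symbol!r} absent from annotation") from None
        lo, hi = m.span
        return (m.chromosome, max(0, lo - flank), hi + flank)

    return window(gene5), window(gene3)


def _carve_overlap(w5: Window, w3: Window) -> tuple[list[Window], list[Window]]:
    """Split each window into sub-intervals excluding their mutual overlap."""
    if w5[0] != w3[0]:
        return [w5], [w3]
    lo = max(w5[1], w3[1])
    hi = min(w5[2], w3[2])
    if hi <= lo:
        return [w5], [w3]

    def minus(w: Window) -> list[Window]:
        parts = []
        if w[1] < lo:
            parts.append((w[0], w[1], lo))
        if hi < w[2]:
            parts.append((w[0], hi, w[2]))
        return parts

    return minus(w5), minus(w3)


def _in_any(chrom: str, pos: int, windows: Sequence[Window]) -> bool:
    return any(c == chrom and s <= pos < e for c, s, e in windows)


def count_discordant_pairs(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    windows: tuple[Window, Window],
    min_mapq: int = 20,
) -> int:
    """Count templates with one confidently-mapped mate in each partner window.

    ``alignments`` may be a SAM/BAM path or an iterable of records.
    Secondary and supplementary records are ignored; each template counts
    at most once; both mates must reach ``min_mapq``.  The mate's window
    membership is judged by its leftmost aligned position.
    """
    parts5, parts3 = _carve_overlap(*windows)
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            records = list(fh)
    else:
        records = list(alignments)

    # collect mate positions per template
    by_name: dict[str, list[tuple[str, int, int]]] = {}
    for rec in records:
        if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
            continue
        by_name.setdefault(rec.query_name, []).append(
            (rec.reference_name, rec.reference_start, rec.mapping_quality)
        )

    n = 0
    for mates in by_name.values():
        if len(mates) < 2:
            continue
        if any(mq < min_mapq for _, _, mq in mates[:2]):
            continue
        (c1, p1, _), (c2, p2, _) = mates[:2]
        hit5 = _in_any(c1, p1, parts5) or _in_any(c2, p2, parts5)
        hit3 = _in_any(c1, p1, parts3) or _in_any(c2, p2, parts3)
        one_each = (_in_any(c1, p1, parts5) and _in_any(c2, p2, parts3)) or (
            _in_any(c1, p1, parts3) and _in_any(c2, p2, parts5)
        )
        if hit5 and hit3 and one_each:
            n += 1
    return n


def validate_call(
    n_discordant: int,
    has_wgs: bool,
    min_pairs: int = 3,
    call_id: str = "",
) -> ValidationResult:
    """Threshold the discordant-pair count into a validation status."""
    if n_discordant < 0:
        raise ValueError("n_discordant must be >= 0")
    if not has_wgs:
        return ValidationResult(call_id, 0, NOT_EVALUABLE)
    status = VALIDATED if n_discordant >= min_pairs else NOT_VALIDATED
    return ValidationResult(call_id, n_discordant, status)


def validation_rate(results: Iterable[ValidationResult]) -> float:
    """VALIDATED / (VALIDATED + NOT_VALIDATED); non-evaluable excluded."""
    n_val = n_eval = 0
    for r in results:
        if r.status == NOT_EVALUABLE:
            continue
        n_eval += 1
        n_val += r.status == VALIDATED
    if n_eval == 0:
        raise ValueError("no evaluable validation results")
    return n_val / n_eval


def write_results_tsv(results: Iterable[ValidationResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("call_id\tn_discordant\tstatus\n")
        for r in results:
            fh.write(f"{r.call_id}\t{r.n_discordant}\t{r.status}\n")
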