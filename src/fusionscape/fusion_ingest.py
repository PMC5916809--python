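"""Parse fusion-caller output tables, harmonize them, and merge across callers.

Three tab-separated dialects are supported, modeled on the output shapes
of common RNA-seq fusion callers:

* ``STARFUSION_LIKE`` — gene pair plus ``chr:pos:strand`` breakpoints,
  junction/spanning read counts, FFPM, and library size.
* ``ERICSCRIPT_LIKE`` — split chromosome/position/strand columns with
  crossing/spanning read counts.
* ``BREAKFAST_LIKE`` — genomic breakpoints with a single read count.

All dialects carry ``sample_id``/``cancer_type`` columns so a whole
cohort can live in one file per caller.  Records merge across callers
when the ordered gene pair matches and both breakpoints agree within a
small tolerance; the surviving coordinates and counts come from the
highest-priority caller present.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

Breakpoint = tuple[str, int, str]  # (chromosome, 1-based position, strand)

STARFUSION_LIKE = "STARFUSION_LIKE"
ERICSCRIPT_LIKE = "ERICSCRIPT_LIKE"
BREAKFAST_LIKE = "BREAKFAST_LIKE"

#: merge precedence: coordinates/read counts of the merged record come
#: from the first of these callers present.
CALLER_PRIORITY = (STARFUSION_LIKE, ERICSCRIPT_LIKE, BREAKFAST_LIKE)


class DialectError(ValueError):
    """Unknown dialect or header not matching the declared dialect."""


class RowParseError(ValueError):
    """Unparseable row; message names the file line number."""


@dataclass
class FusionCall:
    """One harmonized fusion event in one sample."""

    sample_id: str
    cancer_type: str
    gene5: str
    gene3: str
    bp5: Breakpoint
    bp3: Breakpoint
    junction_reads: int
    spanning_frags: int
    total_frags: int
    ffpm: float | None = None
    callers: frozenset[str] = frozenset()
    call_id: str | None = None

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise ValueError("empty partner gene symbol")
        if min(self.junction_reads, self.spanning_frags) < 0:
            raise ValueError("negative read count")
        if self.ffpm is not None and self.ffpm < 0:
            raise ValueError("negative FFPM")
        if self.call_id is None:
            c5, p5, _ = self.bp5
            c3, p3, _ = self.bp3
            self.call_id = (
                f"{self.sample_id}|{self.gene5}--{self.gene3}|{c5}:{p5}|{c3}:{p3}"
            )

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)

    @property
    def supporting_frags(self) -> int:
        return self.junction_reads + self.spanning_frags


def compute_ffpm(supporting_frags: int, total_frags: int) -> float:
    """Fusion fragments per million total sequenced fragments."""
    if total_frags <= 0:
        raise ValueError(f"total_frags must be positive, got {total_frags}")
    return supporting_frags / total_frags * 1e6


def parse_breakpoint(text: str) -> Breakpoint:
    """Parse a ``chr:pos:strand`` breakpoint string."""
    parts = text.strip().split(":")
    if len(parts) != 3 or parts[2] not in {"+", "-"}:
        raise ValueError(f"malformed breakpoint {text!r}")
    return (parts[0], int(parts[1]), parts[2])


_DIALECT_HEADERS = {
    STARFUSION_LIKE: [
        "FusionName",
        "JunctionReadCount",
        "SpanningFragCount",
        "LeftGene",
        "LeftBreakpoint",
        "RightGene",
        "RightBreakpoint",
        "FFPM",
        "SampleID",
        "CancerType",
        "TotalFrags",
    ],
    ERICSCRIPT_LIKE: [
        "sample_id",
        "cancer_type",
        "GeneName1",
        "GeneName2",
        "chr1",
        "breakpoint1",
        "strand1",
        "chr2",
        "breakpoint2",
        "strand2",
        "crossingreads",
        "spanningreads",
        "total_reads",
    ],
    BREAKFAST_LIKE: [
        "sample",
        "cancer_type",
        "gene_5p",
        "gene_3p",
        "chrom_5p",
        "position_5p",
        "strand_5p",
        "chrom_3p",
        "position_3p",
        "strand_3p",
        "num_reads",
        "total_frags",
    ],
}


def read_caller_tsv(path: str | Path, dialect: str) -> list[FusionCall]:
    """Read one caller's TSV into harmonized :class:`FusionCall` records."""
    if dialect not in _DIALECT_HEADERS:
        raise DialectError(f"unknown dialect {dialect!r}")
    expected = _DIALECT_HEADERS[dialect]
    calls: list[FusionCall] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise DialectError(f"{path}: empty file")
        header = [h.lstrip("#") for h in header]
        if header != expected:
            raise DialectError(
                f"{path}: header does not match dialect {dialect}: {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                calls.append(_parse_row(dict(zip(header, row)), dialect))
            except (ValueError, KeyError) as exc:
                raise RowParseError(f"{path}:{lineno}: {exc}") from exc
    return calls


def _parse_row(rec: dict[str, str], dialect: str) -> FusionCall:
    if dialect == STARFUSION_LIKE:
        return FusionCall(
            sample_id=rec["SampleID"],
            cancer_type=rec["CancerType"],
            gene5=rec["LeftGene"],
            gene3=rec["RightGene"],
            bp5=parse_breakpoint(rec["LeftBreakpoint"]),
            bp3=parse_breakpoint(rec["RightBreakpoint"]),
            junction_reads=int(rec["JunctionReadCount"]),
            spanning_frags=int(rec["SpanningFragCount"]),
            total_frags=int(rec["TotalFrags"]),
            ffpm=float(rec["FFPM"]),
            callers=frozenset({STARFUSION_LIKE}),
        )
    if dialect == ERICSCRIPT_LIKE:
        return FusionCall(
            sample_id=rec["sample_id"],
            cancer_type=rec["cancer_type"],
            gene5=rec["GeneName1"],
            gene3=rec["GeneName2"],
            bp5=(rec["chr1"], int(rec["breakpoint1"]), rec["strand1"]),
            bp3=(rec["chr2"], int(rec["breakpoint2"]), rec["strand2"]),
            junction_reads=int(rec["crossingreads"]),
            spanning_frags=int(rec["spanningreads"]),
            total_frags=int(rec["total_reads"]),
            callers=frozenset({ERICSCRIPT_LIKE}),
        )
    return FusionCall(
        sample_id=rec["sample"],
        cancer_type=rec["cancer_type"],
        gene5=rec["gene_5p"],
        gene3=rec["gene_3p"],
        bp5=(rec["chrom_5p"], int(rec["position_5p"]), rec["strand_5p"]),
        bp3=(rec["chrom_3p"], int(rec["position_3p"]), rec["strand_3p"]),
        junction_reads=int(rec["num_reads"]),
        spanning_frags=0,
        total_frags=int(rec["total_frags"]),
        callers=frozenset({BREAKFAST_LIKE}),
    )


def add_ffpm(calls: Iterable[FusionCall]) -> list[FusionCall]:
    """Fill in FFPM from supporting fragments and library size where absent."""
    out = []
    for c in calls:
        if c.ffpm is None:
            c = replace(c, ffpm=compute_ffpm(c.supporting_frags, c.total_frags))
        out.append(c)
    return out


def _bp_close(a: Breakpoint, b: Breakpoint, tol: int) -> bool:
    return a[0] == b[0] and a[2] == b[2] and abs(a[1] - b[1]) <= tol


def merge_callers(
    call_lists: Sequence[Sequence[FusionCall]], bp_tolerance: int = 5
) -> list[FusionCall]:
    """Collapse the same event reported by several callers into one record.

    Two calls merge when they come from the same sample, name the same
    ordered gene pair, and both breakpoints lie within ``bp_tolerance``
    bases (same chromosome and strand).  The merged record keeps the
    coordinates and read counts of the highest-priority caller present
    and unions the ``callers`` sets.  Greedy first-match grouping: calls
    are scanned in caller-priority order, so the group anchor is always
    the best available caller's record.
    """
    prio = {name: i for i, name in enumerate(CALLER_PRIORITY)}

    def caller_rank(c: FusionCall) -> int:
        return min(prio.get(name, len(prio)) for name in c.callers)

    flat = sorted(
        (c for lst in call_lists for c in lst),
        key=lambda c: (caller_rank(c), c.sample_id, c.gene5, c.gene3, c.bp5, c.bp3),
    )
    merged: list[FusionCall] = []
    for call in flat:
        target = None
        for m in merged:
            if (
                m.sample_id == call.sample_id
                and m.gene_pair == call.gene_pair
                and _bp_close(m.bp5, call.bp5, bp_tolerance)
                and _bp_close(m.bp3, call.bp3, bp_tolerance)
            ):
                target = m
                break
        if target is None:
            merged.append(replace(call))
        else:
            target.callers = frozenset(target.callers | call.callers)
    return merged


def read_calls_tsv(path: str | Path) -> list[FusionCall]:
    """Read back the canonical TSV written by :func:`write_calls_tsv`."""
    calls = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            calls.append(
                FusionCall(
                    sample_id=rec["sample_id"],
                    cancer_type=rec["cancer_type"],
                    gene5=rec["gene5"],
                    gene3=rec["gene3"],
                    bp5=parse_breakpoint(rec["bp5"]),
                    bp3=parse_breakpoint(rec["bp3"]),
                    junction_reads=int(rec["junction_reads"]),
                    spanning_frags=int(rec["spanning_frags"]),
                    total_frags=int(rec["total_frags"]),
                    ffpm=float(rec["ffpm"]) if rec["ffpm"] else None,
                    callers=frozenset(rec["callers"].split(",")),
                    call_id=rec["call_id"],
                )
            )
    return calls


def write_calls_tsv(calls: Iterable[FusionCall], path: str | Path) -> None:
    """Serialize merged calls as a canonical TSV with a ``callers`` column."""
    cols = [
        "call_id",
        "sample_id",
        "cancer_type",
        "gene5",
        "gene3",
        "bp5",
        "bp3",
        "junction_reads",
        "spanning_frags",
        "total_frags",
        "ffpm",
        "callers",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(cols)
        for c in calls:
            writer.writerow(
                [
                    c.call_id,
                    c.sample_id,
                    c.cancer_type,
                    c.gene5,
                    c.gene3,
                    ":".join(map(str, c.bp5)),
                    ":".join(map(str, c.bp3)),
                    c.junction_reads,
                    c.spanning_frags,
                    c.total_frags,
                    "" if c.ffpm is None else f"{c.ffpm:.6g}",
                    ",".join(sorted(c.callers)),
                ]
            )
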