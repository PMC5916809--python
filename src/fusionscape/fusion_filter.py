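"""Five-rule fusion filter cascade.

Rules, evaluated in order (a call's ``failed_rule`` is the first one it
violates; the kept set itself is order-independent because the rules are
conjunctive):

R1  either partner on a curated exclusion list (uncharacterized,
    immunoglobulin, mitochondrial genes, ...);
R2  self-fusion or the partners are paralogs;
R3  unordered gene pair seen in a panel of normals;
R4  single-caller call with FFPM <= ``ffpm_min`` (calls reported by two
    or more callers are exempt from the FFPM floor);
R5  identical breakpoint pair recurring in >= ``recurrence_max`` samples
    across >= 2 cancer types, unless the gene pair is allowlisted
    (known biological recurrences stay).

R1-R4 look at one call at a time; R5 is the only cohort-level rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .fusion_ingest import Breakpoint, FusionCall

R1_EXCLUDED_GENE = "R1_EXCLUDED_GENE"
R2_SELF_OR_PARALOG = "R2_SELF_OR_PARALOG"
R3_NORMALS_PANEL = "R3_NORMALS_PANEL"
R4_FFPM = "R4_FFPM"
R5_RECURRENT_ARTIFACT = "R5_RECURRENT_ARTIFACT"
NONE = "NONE"

RULE_ORDER = (
    R1_EXCLUDED_GENE,
    R2_SELF_OR_PARALOG,
    R3_NORMALS_PANEL,
    R4_FFPM,
    R5_RECURRENT_ARTIFACT,
)


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


def _norm_pair(pair: Iterable[str]) -> frozenset[str]:
    return frozenset(_norm(g) for g in pair)


@dataclass
class FilterResources:
    """Exclusion lists, paralogs, panel of normals, allowlist, thresholds."""

    exclusion_genes: set[str] = field(default_factory=set)
    paralog_pairs: set[frozenset[str]] = field(default_factory=set)
    normals_panel: set[frozenset[str]] = field(default_factory=set)
    allowlist: set[frozenset[str]] = field(default_factory=set)
    ffpm_min: float = 0.1
    recurrence_max: int = 10

    def __post_init__(self) -> None:
        if self.ffpm_min <= 0 or self.recurrence_max <= 0:
            raise ValueError("thresholds must be positive")
        self.exclusion_genes = {_norm(g) for g in self.exclusion_genes}
        self.paralog_pairs = {_norm_pair(p) for p in self.paralog_pairs}
        self.normals_panel = {_norm_pair(p) for p in self.normals_panel}
        self.allowlist = {_norm_pair(p) for p in self.allowlist}

    @classmethod
    def from_files(
        cls,
        exclusion: str | Path | None = None,
        paralogs: str | Path | None = None,
        normals: str | Path | None = None,
        allowlist: str | Path | None = None,
        ffpm_min: float = 0.1,
        recurrence_max: int = 10,
    ) -> "FilterResources":
        """Load resources from plain-text files (one gene or pair per line)."""

        def read_genes(p):
            return {
                line.strip()
                for line in open(p)
                if line.strip() and not line.startswith("#")
            }

        def read_pairs(p):
            pairs = set()
            for line in open(p):
                if not line.strip() or line.startswith("#"):
                    continue
                a, b = line.split()[:2]
                pairs.add(frozenset({a, b}))
            return pairs

        return cls(
            exclusion_genes=read_genes(exclusion) if exclusion else set(),
            paralog_pairs=read_pairs(paralogs) if paralogs else set(),
            normals_panel=read_pairs(normals) if normals else set(),
            allowlist=read_pairs(allowlist) if allowlist else set(),
            ffpm_min=ffpm_min,
            recurrence_max=recurrence_max,
        )


@dataclass(frozen=True)
class FilterOutcome:
    call_id: str
    kept: bool
    failed_rule: str

    def __post_init__(self) -> None:
        if self.kept != (self.failed_rule == NONE):
            raise ValueError("kept flag inconsistent with failed_rule")


BreakpointKey = tuple[Breakpoint, Breakpoint]


def recurrence_index(
    calls: Sequence[FusionCall],
) -> dict[BreakpointKey, tuple[int, int]]:
    """Per exact breakpoint pair: (distinct samples, distinct cancer types)."""
    samples: dict[BreakpointKey, set[str]] = {}
    cancers: dict[BreakpointKey, set[str]] = {}
    for c in calls:
        key = (c.bp5, c.bp3)
        samples.setdefault(key, set()).add(c.sample_id)
        cancers.setdefault(key, set()).add(c.cancer_type)
    return {k: (len(samples[k]), len(cancers[k])) for k in samples}


def apply_filter_cascade(
    calls: Sequence[FusionCall],
    resources: FilterResources,
    rule_order: Sequence[str] = RULE_ORDER,
) -> list[FilterOutcome]:
    """Evaluate the filter cascade on a cohort's merged calls.

    ``rule_order`` only affects which rule gets blamed for a rejected
    call, never the kept set.  R5 needs the full multi-sample call set,
    so the cascade takes the whole cohort at once.
    """
    if set(rule_order) != set(RULE_ORDER):
        raise ValueError("rule_order must be a permutation of the five rules")
    recurrence = recurrence_index(calls)

    def violates(call: FusionCall, rule: str) -> bool:
        g5, g3 = _norm(call.gene5), _norm(call.gene3)
        if rule == R1_EXCLUDED_GENE:
            return g5 in resources.exclusion_genes or g3 in resources.exclusion_genes
        if rule == R2_SELF_OR_PARALOG:
            return g5 == g3 or frozenset({g5, g3}) in resources.paralog_pairs
        if rule == R3_NORMALS_PANEL:
            return frozenset({g5, g3}) in resources.normals_panel
        if rule == R4_FFPM:
            if len(call.callers) >= 2:
                return False
            if call.ffpm is None:
                raise ValueError(
                    f"call {call.call_id}: single-caller call without FFPM"
                )
            return call.ffpm <= resources.ffpm_min
        # R5
        n_samples, n_cancers = recurrence[(call.bp5, call.bp3)]
        if n_samples < resources.recurrence_max or n_cancers < 2:
            return False
        return frozenset({g5, g3}) not in resources.allowlist

    outcomes = []
    for call in calls:
        failed = NONE
        for rule in rule_order:
            if violates(call, rule):
                failed = rule
                break
        outcomes.append(
            FilterOutcome(call_id=call.call_id, kept=failed == NONE, failed_rule=failed)
        )
    return outcomes


def kept_calls(
    calls: Sequence[FusionCall], outcomes: Sequence[FilterOutcome]
) -> list[FusionCall]:
    """Subset of calls whose outcome is 'kept' (input order preserved)."""
    keep = {o.call_id for o in outcomes if o.kept}
    return [c for c in calls if c.call_id in keep]


def write_outcomes_tsv(
    outcomes: Iterable[FilterOutcome], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("call_id\tkept\tfailed_rule\n")
        for o in outcomes:
            fh.write(f"{o.call_id}\t{int(o.kept)}\t{o.failed_rule}\n")
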