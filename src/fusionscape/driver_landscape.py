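"""Driver-gene alteration profiles, mutual exclusivity, druggability, smoking.

Each sample is summarized into an :class:`AlterationProfile` over a
curated driver-gene list: does it carry a curated driver mutation, any
qualifying mutation in a driver gene, and/or a fusion touching a driver
gene.  Only eight variant classes count toward driver-gene mutation
status (inframe indels, missense, nonsense, nonstop, splice site,
translation start site); silent and other classes do not.  Profiles map
deterministically onto six cohort groups (driver mutation only, mutation
only, driver mutation + fusion, mutation + fusion, fusion only, none)
that partition the cohort.

Mutation-burden comparisons between groups use a two-sided Mann-Whitney
U test after removing samples with any mutation in mismatch-repair or
polymerase-proofreading genes (POLE, MLH1, MLH3, MGMT, MSH6, MSH3, MSH2,
PMS1, PMS2), whose hypermutator phenotype would otherwise confound the
comparison.

Druggability follows a curated drug-evidence table: a fusion is druggable
when some entry targets one of its genes (optionally requiring a
specific partner), with off-label entries honored on request.  The
smoking association is a 2x2 Pearson chi-square (no continuity
correction) of druggable status against smoking status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fusion_ingest import FusionCall

MMR_GENES = frozenset(
    {"POLE", "MLH1", "MLH3", "MGMT", "MSH6", "MSH3", "MSH2", "PMS1", "PMS2"}
)

#: MAF variant classes that count as driver-gene alterations
QUALIFYING_CLASSES = frozenset(
    {
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Translation_Start_Site",
        "Fusion",
    }
)

DRIVER_MUT_ONLY = "DRIVER_MUT_ONLY"
MUT_ONLY = "MUT_ONLY"
DRIVER_MUT_AND_FUSION = "DRIVER_MUT_AND_FUSION"
MUT_AND_FUSION = "MUT_AND_FUSION"
FUSION_ONLY = "FUSION_ONLY"
NO_ALTERATION = "NONE"

DRIVER_GROUPS = (
    DRIVER_MUT_ONLY,
    MUT_ONLY,
    DRIVER_MUT_AND_FUSION,
    MUT_AND_FUSION,
    FUSION_ONLY,
    NO_ALTERATION,
)

ON_LABEL = "ON_LABEL"
OFF_LABEL = "OFF_LABEL"


@dataclass
class AlterationProfile:
    sample_id: str
    cancer_type: str
    has_driver_mutation: bool
    has_driver_gene_mutation: bool
    has_driver_fusion: bool
    n_mutations: int
    mmr_mutated: bool

    def __post_init__(self) -> None:
        # a curated driver mutation is by definition a driver-gene mutation
        if self.has_driver_mutation:
            self.has_driver_gene_mutation = True


@dataclass(frozen=True)
class DrugEntry:
    gene: str
    drug: str
    label_status: str
    partner: str | None = None
    cancer_types: frozenset[str] | None = None  # None = any

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("drug entry needs a gene")
        if self.label_status not in (ON_LABEL, OFF_LABEL):
            raise ValueError(f"bad label status {self.label_status!r}")


def read_drug_table(path: str | Path) -> list[DrugEntry]:
    """DEPO-like TSV: gene, partner, cancer_types, drug, label columns."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    entries = []
    for r in df.itertuples():
        cancers = (
            frozenset(str(r.cancer_types).split(","))
            if getattr(r, "cancer_types", "")
            else None
        )
        entries.append(
            DrugEntry(
                gene=r.gene,
                partner=r.partner or None,
                cancer_types=cancers,
                drug=r.drug,
                label_status=r.label,
            )
        )
    return entries


def build_alteration_profiles(
    maf: pd.DataFrame,
    fusions: Sequence[FusionCall],
    driver_genes: Iterable[str],
    metadata: pd.DataFrame,
) -> list[AlterationProfile]:
    """Per-sample driver alteration profile from MAF rows and kept fusions.

    ``maf`` needs columns Hugo_Symbol, Tumor_Sample_Barcode,
    Variant_Classification and a boolean-ish ``is_driver`` column marking
    curated driver mutations (this curation is an input, not something
    the package infers).  ``metadata`` is indexed by sample with a
    ``cancer_type`` column and defines the cohort: samples without MAF
    rows still get a profile.  ``n_mutations`` counts all MAF rows of
    the sample; driver-gene status counts only the qualifying classes.
    """
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    missing = required - set(maf.columns)
    if missing:
        raise ValueError(f"MAF missing required columns: {sorted(missing)}")
    drivers = {g.upper() for g in driver_genes}
    fusion_samples: dict[str, bool] = {}
    for f in fusions:
        if f.gene5.upper() in drivers or f.gene3.upper() in drivers:
            fusion_samples[f.sample_id] = True

    by_sample = dict(tuple(maf.groupby("Tumor_Sample_Barcode")))
    profiles = []
    for sample_id, meta in metadata.iterrows():
        rows = by_sample.get(sample_id)
        if rows is None:
            n_mut = 0
            has_driver_mut = has_driver_gene_mut = mmr = False
        else:
            n_mut = len(rows)
            genes = rows["Hugo_Symbol"].str.upper()
            qualifying = rows["Variant_Classification"].isin(QUALIFYING_CLASSES)
            in_driver = genes.isin(drivers)
            has_driver_gene_mut = bool((qualifying & in_driver).any())
            if "is_driver" in rows.columns:
                has_driver_mut = bool(
                    (rows["is_driver"].astype(bool) & qualifying & in_driver).any()
                )
            else:
                has_driver_mut = False
            mmr = bool(genes.isin(MMR_GENES).any())
        profiles.append(
            AlterationProfile(
                sample_id=str(sample_id),
                cancer_type=str(meta["cancer_type"]),
                has_driver_mutation=has_driver_mut,
                has_driver_gene_mutation=has_driver_gene_mut,
                has_driver_fusion=fusion_samples.get(str(sample_id), False),
                n_mutations=n_mut,
                mmr_mutated=mmr,
            )
        )
    return profiles


def classify_driver_group(profile: AlterationProfile) -> str:
    """Map a profile onto the six-way cohort partition.

    The mutation-only style groups require a qualifying driver-gene
    mutation that is *not* a curated driver mutation.
    """
    fus = profile.has_driver_fusion
    if profile.has_driver_mutation:
        return DRIVER_MUT_AND_FUSION if fus else DRIVER_MUT_ONLY
    if profile.has_driver_gene_mutation:
        return MUT_AND_FUSION if fus else MUT_ONLY
    return FUSION_ONLY if fus else NO_ALTERATION


def driver_group_sizes(profiles: Sequence[AlterationProfile]) -> dict[str, int]:
    sizes = {g: 0 for g in DRIVER_GROUPS}
    for p in profiles:
        sizes[classify_driver_group(p)] += 1
    return sizes


def burden_comparison(
    profiles: Sequence[AlterationProfile],
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
) -> float:
    """Two-sided Mann-Whitney p for mutation burden between two groups.

    MMR/POLE-mutated samples are removed first.  Groups may be single
    group names or collections (to pool, e.g., all non-fusion-only
    groups).  Uses the exact U distribution when both groups are small
    and tie-free, the normal approximation otherwise.
    """
    ga = {group_a} if isinstance(group_a, str) else set(group_a)
    gb = {group_b} if isinstance(group_b, str) else set(group_b)
    clean = [p for p in profiles if not p.mmr_mutated]
    xa = [p.n_mutations for p in clean if classify_driver_group(p) in ga]
    xb = [p.n_mutations for p in clean if classify_driver_group(p) in gb]
    if not xa or not xb:
        raise ValueError("empty group after MSI exclusion")
    ties = len(set(xa + xb)) < len(xa) + len(xb)
    method = "exact" if (max(len(xa), len(xb)) <= 8 and not ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method).pvalue
    )


def exclusivity_matrix(
    fusions: Sequence[FusionCall],
    maf: pd.DataFrame,
    genes: Sequence[str],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Gene x sample table of alteration type: FUSION/MUTATION/BOTH/NONE."""
    mat = pd.DataFrame("NONE", index=list(genes), columns=list(samples))
    if len(mat.index) == 0:
        return mat
    gset = set(genes)
    mut_rows = maf[
        maf["Hugo_Symbol"].isin(gset)
        & maf["Variant_Classification"].isin(QUALIFYING_CLASSES)
    ]
    mutated = set(zip(mut_rows["Hugo_Symbol"], mut_rows["Tumor_Sample_Barcode"]))
    fused = set()
    for f in fusions:
        for g in (f.gene5, f.gene3):
            if g in gset:
                fused.add((g, f.sample_id))
    for g in genes:
        for s in samples:
            m = (g, s) in mutated
            fu = (g, s) in fused
            if m and fu:
                mat.loc[g, s] = "BOTH"
            elif fu:
                mat.loc[g, s] = "FUSION"
            elif m:
                mat.loc[g, s] = "MUTATION"
    return mat


def cooccurrence_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of FUSION / MUTATION / BOTH cells, for inspection."""
    rows = []
    for g in matrix.index:
        vals = matrix.loc[g]
        rows.append(
            {
                "gene": g,
                "n_fusion": int((vals == "FUSION").sum()),
                "n_mutation": int((vals == "MUTATION").sum()),
                "n_both": int((vals == "BOTH").sum()),
            }
        )
    return pd.DataFrame(rows)


def annotate_druggable(
    fusions: Sequence[FusionCall],
    drug_table: Sequence[DrugEntry],
    allow_off_label: bool = True,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Match fusions against the drug-evidence table.

    A fusion matches an entry when the entry's gene is one of its
    partners, the entry's required partner (if any) is the other one,
    and — unless ``allow_off_label`` — the entry is on-label for the
    sample's cancer type.  Returns (per-fusion match table, per-sample
    druggable flag).
    """
    rows = []
    druggable: dict[str, bool] = {}
    for f in fusions:
        druggable.setdefault(f.sample_id, False)
        for entry in drug_table:
            pair = {f.gene5, f.gene3}
            if entry.gene not in pair:
                continue
            other = (pair - {entry.gene}) or {entry.gene}
            if entry.partner is not None and entry.partner not in other:
                continue
            on_label = (
                entry.cancer_types is None or f.cancer_type in entry.cancer_types
            )
            effective = ON_LABEL if on_label else OFF_LABEL
            if entry.label_status == OFF_LABEL:
                effective = OFF_LABEL
            if effective == OFF_LABEL and not allow_off_label:
                continue
            rows.append(
                {
                    "call_id": f.call_id,
                    "sample_id": f.sample_id,
                    "gene": entry.gene,
                    "drug": entry.drug,
                    "label": effective,
                }
            )
            druggable[f.sample_id] = True
    return (
        pd.DataFrame(rows, columns=["call_id", "sample_id", "gene", "drug", "label"]),
        druggable,
    )


def smoking_association(
    druggable_flags: Mapping[str, bool], smoking_status: Mapping[str, str]
) -> tuple[float, float] | None:
    """Pearson chi-square of druggable-fusion status vs smoking status.

    ``smoking_status`` maps sample -> {"never", "smoker"}; samples
    missing from either mapping are dropped.  Returns (statistic, p) or
    None (with a warning) when a margin of the 2x2 table is zero.
    """
    table = np.zeros((2, 2), dtype=int)
    for sample, status in smoking_status.items():
        if sample not in druggable_flags or status not in ("never", "smoker"):
            continue
        i = 0 if status == "never" else 1
        j = 0 if druggable_flags[sample] else 1
        table[i, j] += 1
    return chi_square_2x2(table)


def chi_square_2x2(table: np.ndarray) -> tuple[float, float] | None:
    """Uncorrected chi-square on a 2x2 count table; None on a zero margin."""
    table = np.asarray(table, dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero margin in contingency table; chi-square undefined")
        return None
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)
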