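"""Expression percentiles, Tukey outliers, and fusion-expression association.

All statistics operate within one cancer type.  Expression values are
analyzed on a log2(x+1) scale; percentile ranks and Tukey fences are
monotone-invariant, so the choice of scale only matters for the t test.

A gene is "flagged for review" in a cancer type when (i) either the
Welch t test (fusion vs non-fusion expression) or a Fisher exact test
(outlier status x fusion status) survives Benjamini-Hochberg correction
across all (gene, cancer type) tests, (ii) at least three samples carry
a fusion in the gene, and (iii) the median expression percentile of the
fusion carriers sits in the top or bottom decile of the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .breakpoint_annot import AnnotatedFusion, FIVE_KINASE, THREE_KINASE

PARTNER_HIGHER = "PARTNER_HIGHER"
PARTNER_LOWER = "PARTNER_LOWER"
EQUAL = "EQUAL"

COPY_NUMBER_CATEGORIES = (
    "DEEP_DELETION",
    "LOSS",
    "NEUTRAL",
    "GAIN",
    "HIGH_AMPLIFICATION",
)


@dataclass(frozen=True)
class OutlierFences:
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def upper(self) -> float:
        return self.q3 + 1.5 * self.iqr

    @property
    def lower(self) -> float:
        return self.q1 - 1.5 * self.iqr


@dataclass
class AssociationResult:
    gene: str
    cancer_type: str
    n_fusion_samples: int
    t_p: float
    fisher_over_p: float
    fisher_under_p: float
    median_fusion_percentile: float
    t_q: float = np.nan
    fisher_over_q: float = np.nan
    fisher_under_q: float = np.nan
    flagged_for_review: bool = False


def log_expression(values: np.ndarray | pd.Series) -> np.ndarray:
    """log2(x+1), the working scale for all expression statistics."""
    return np.log2(np.asarray(values, dtype=float) + 1.0)


def expression_percentile(cohort: Sequence[float], value: float) -> float:
    """Percentile rank of a value within its cancer-type cohort, in [0,100].

    Average-rank convention rescaled so the cohort minimum maps to 0 and
    the maximum to 100; a fully tied cohort maps every sample to 50.
    ``value`` must be one of the cohort values (a sample's own entry).
    """
    arr = np.asarray(cohort, dtype=float)
    if arr.size == 0:
        raise ValueError("empty cohort")
    if arr.size == 1:
        return 50.0
    ranks = stats.rankdata(arr)  # average ranks, 1..n
    mask = arr == value
    if not mask.any():
        raise ValueError("value not found in cohort")
    r = float(ranks[mask][0])
    return (r - 1.0) / (arr.size - 1.0) * 100.0


def cohort_percentiles(values: Sequence[float]) -> np.ndarray:
    """Percentile rank of every sample in the cohort at once."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty cohort")
    if arr.size == 1:
        return np.array([50.0])
    ranks = stats.rankdata(arr)
    return (ranks - 1.0) / (arr.size - 1.0) * 100.0


def tukey_fences(values: Sequence[float]) -> tuple[OutlierFences, np.ndarray, np.ndarray]:
    """Tukey outlier fences plus per-sample over/under flags.

    Quartiles use linear interpolation between order statistics (the
    default numpy/R "type 7" rule).  Returns (fences, over, under)
    where over/under are boolean arrays: value > Q3 + 1.5 IQR, value <
    Q1 - 1.5 IQR.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 values for stable quartiles")
    q1, q3 = np.percentile(arr, [25, 75])
    fences = OutlierFences(q1=float(q1), q3=float(q3))
    return fences, arr > fences.upper, arr < fences.lower


def fusion_expression_association(
    expression: pd.DataFrame,
    fusion_samples: Mapping[str, set[str]],
    cancer_type: str,
    gene_sets: Iterable[str] | None = None,
    fdr: float = 0.05,
    min_fusion_samples: int = 3,
) -> list[AssociationResult]:
    """Test fusion status against expression, gene by gene, in one cohort.

    ``expression`` is genes x samples (linear scale) restricted to one
    cancer type; ``fusion_samples`` maps gene symbol -> carrier sample
    ids.  Genes without carriers emit no test.  BH correction is applied
    separately to the t-test family and each Fisher family, across all
    genes tested here.
    """
    samples = list(expression.columns)
    if gene_sets is not None:
        genes = [g for g in expression.index if g in set(gene_sets)]
    else:
        genes = list(expression.index)

    results: list[AssociationResult] = []
    for gene in genes:
        carriers = fusion_samples.get(gene, set()) & set(samples)
        if not carriers:
            continue
        vals = log_expression(expression.loc[gene, samples].to_numpy())
        is_carrier = np.array([s in carriers for s in samples])
        fus, rest = vals[is_carrier], vals[~is_carrier]
        if rest.size == 0:
            continue
        if fus.size >= 2 and np.ptp(vals) > 0:
            t_p = float(stats.ttest_ind(fus, rest, equal_var=False).pvalue)
        else:
            t_p = 1.0
        if np.isnan(t_p):
            t_p = 1.0
        _, over, under = tukey_fences(vals)
        fisher = {}
        for name, flags in (("over", over), ("under", under)):
            table = [
                [int((flags & is_carrier).sum()), int((flags & ~is_carrier).sum())],
                [int((~flags & is_carrier).sum()), int((~flags & ~is_carrier).sum())],
            ]
            fisher[name] = float(stats.fisher_exact(table)[1])
        pct = cohort_percentiles(vals)
        results.append(
            AssociationResult(
                gene=gene,
                cancer_type=cancer_type,
                n_fusion_samples=len(carriers),
                t_p=t_p,
                fisher_over_p=fisher["over"],
                fisher_under_p=fisher["under"],
                median_fusion_percentile=float(np.median(pct[is_carrier])),
            )
        )
    apply_fdr_and_flags(results, fdr=fdr, min_fusion_samples=min_fusion_samples)
    return results


def apply_fdr_and_flags(
    results: Sequence[AssociationResult],
    fdr: float = 0.05,
    min_fusion_samples: int = 3,
) -> None:
    """BH-correct each p-value family across results and set review flags.

    Call this once over the pooled results of all cancer types so the
    correction spans every (gene, cancer type) test.
    """
    if not results:
        return
    for attr_p, attr_q in (
        ("t_p", "t_q"),
        ("fisher_over_p", "fisher_over_q"),
        ("fisher_under_p", "fisher_under_q"),
    ):
        pvals = [getattr(r, attr_p) for r in results]
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(results, qvals):
            setattr(r, attr_q, float(q))
    for r in results:
        min_q = min(r.t_q, r.fisher_over_q, r.fisher_under_q)
        in_decile = (
            r.median_fusion_percentile >= 90 or r.median_fusion_percentile <= 10
        )
        r.flagged_for_review = (
            min_q < fdr and r.n_fusion_samples >= min_fusion_samples and in_decile
        )


def copy_number_category(
    value: float, cuts: Sequence[float] = (-2.0, -1.0, 1.0, 2.0)
) -> str:
    """Display category for a (log2-ratio-like) copy number value."""
    lo2, lo1, hi1, hi2 = cuts
    if value <= lo2:
        return "DEEP_DELETION"
    if value <= lo1:
        return "LOSS"
    if value < hi1:
        return "NEUTRAL"
    if value < hi2:
        return "GAIN"
    return "HIGH_AMPLIFICATION"


def copy_number_filter(
    fusions: Sequence[AnnotatedFusion],
    copy_table: pd.DataFrame,
    low: float = 1.0,
    high: float = 3.0,
) -> list[AnnotatedFusion]:
    """Keep fusions whose kinase gene copy number lies in [low, high].

    Removes copy-driven expression effects before the kinase-vs-partner
    comparison.  Fusions whose kinase gene or sample is absent from the
    copy table are excluded with a warning.
    """
    kept = []
    for f in fusions:
        gene = f.kinase_gene
        if gene is None:
            continue
        sample = f.call.sample_id
        try:
            cn = float(copy_table.loc[gene, sample])
        except KeyError:
            warnings.warn(
                f"no copy number for {gene}/{sample}; fusion excluded"
            )
            continue
        if np.isnan(cn):
            warnings.warn(
                f"missing copy number for {gene}/{sample}; fusion excluded"
            )
            continue
        if low <= cn <= high:
            kept.append(f)
    return kept


def kinase_partner_comparison(
    expression: pd.DataFrame,
    fusions: Sequence[AnnotatedFusion],
    equal_band: float = 5.0,
) -> pd.DataFrame:
    """Relative expression of kinase vs partner in each fusion-bearing sample.

    For each fusion (copy-number filtered upstream), both genes'
    percentile ranks within the cancer-type cohort are compared in the
    carrier sample: a difference within ``equal_band`` percentile points
    is EQUAL, otherwise PARTNER_HIGHER/PARTNER_LOWER.  Returns one row
    per fusion with the kinase's expression quantile (percentile / 100).
    ``expression`` must already be restricted to the relevant cohort.
    """
    rows = []
    for f in fusions:
        if f.kinase_role not in (FIVE_KINASE, THREE_KINASE):
            continue
        kinase = f.kinase_gene
        partner = f.call.gene3 if f.kinase_role == FIVE_KINASE else f.call.gene5
        sample = f.call.sample_id
        if partner not in expression.index or kinase not in expression.index:
            rows.append(
                {
                    "call_id": f.call.call_id,
                    "kinase_role": f.kinase_role,
                    "category": "NA",
                    "kinase_quantile": np.nan,
                }
            )
            continue
        kin_vals = log_expression(expression.loc[kinase].to_numpy())
        par_vals = log_expression(expression.loc[partner].to_numpy())
        idx = list(expression.columns).index(sample)
        kin_pct = cohort_percentiles(kin_vals)[idx]
        par_pct = cohort_percentiles(par_vals)[idx]
        diff = par_pct - kin_pct
        if abs(diff) <= equal_band:
            cat = EQUAL
        else:
            cat = PARTNER_HIGHER if diff > 0 else PARTNER_LOWER
        rows.append(
            {
                "call_id": f.call.call_id,
                "kinase_role": f.kinase_role,
                "category": cat,
                "kinase_quantile": kin_pct / 100.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["call_id", "kinase_role", "category", "kinase_quantile"]
    )


def association_results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "cancer_type": r.cancer_type,
                "n_fusion_samples": r.n_fusion_samples,
                "t_p": r.t_p,
                "t_q": r.t_q,
                "fisher_over_p": r.fisher_over_p,
                "fisher_over_q": r.fisher_over_q,
                "fisher_under_p": r.fisher_under_p,
                "fisher_under_q": r.fisher_under_q,
                "median_fusion_percentile": r.median_fusion_percentile,
                "flagged_for_review": r.flagged_for_review,
            }
            for r in results
        ]
    )
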