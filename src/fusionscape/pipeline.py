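"""End-to-end orchestration of the fusion analysis stages.

Stage order: ingest -> filter -> validate -> annotate -> expression ->
drivers/druggability -> neoepitopes.  Every stage writes its table into
the output directory and contributes counts to a JSON run summary; the
whole run is deterministic given the configured seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import (
    breakpoint_annot,
    driver_landscape,
    expression_assoc,
    fusion_filter,
    fusion_ingest,
    neoepitope,
    synthetic_data,
    wgs_validate,
)
from .breakpoint_annot import FRAMESHIFT, INFRAME, NO_FRAME

log = logging.getLogger("fusionscape")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Input paths plus every analysis threshold (defaults as published)."""

    input_dir: Path
    output_dir: Path
    seed: int = 0
    bp_tolerance: int = 5
    ffpm_min: float = 0.1
    recurrence_max: int = 10
    flank: int = 100_000
    min_mapq: int = 20
    min_pairs: int = 3
    fdr: float = 0.05
    copy_low: float = 1.0
    copy_high: float = 3.0
    equal_band: float = 5.0
    affinity_max: float = 500.0
    min_split_reads: int = 5
    run_expression: bool = True
    run_drivers: bool = True
    run_neoepitope: bool = True

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)

    def path(self, name: str, required: bool = True) -> Path | None:
        p = self.input_dir / name
        if not p.exists():
            if required:
                raise StageError(f"configuration: missing input {p}")
            return None
        return p


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns (and writes) the run summary."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "bp_tolerance",
                "ffpm_min",
                "recurrence_max",
                "flank",
                "min_mapq",
                "min_pairs",
                "fdr",
                "copy_low",
                "copy_high",
                "equal_band",
                "affinity_max",
                "min_split_reads",
            )
        },
        "stages": {},
    }

    # ------------------------------------------------------------ ingest
    dialect_files = {
        fusion_ingest.STARFUSION_LIKE: "calls_starfusion.tsv",
        fusion_ingest.ERICSCRIPT_LIKE: "calls_ericscript.tsv",
        fusion_ingest.BREAKFAST_LIKE: "calls_breakfast.tsv",
    }
    call_lists = []
    n_raw = 0
    for dialect, fname in dialect_files.items():
        p = config.path(fname, required=False)
        if p is None:
            continue
        calls = fusion_ingest.read_caller_tsv(p, dialect)
        n_raw += len(calls)
        call_lists.append(calls)
    if not call_lists:
        raise StageError("ingest: no caller output files found")
    merged = fusion_ingest.merge_callers(call_lists, bp_tolerance=config.bp_tolerance)
    merged = fusion_ingest.add_ffpm(merged)
    fusion_ingest.write_calls_tsv(merged, out / "merged_calls.tsv")
    log.info("ingest: %d raw records -> %d merged calls", n_raw, len(merged))
    summary["stages"]["ingest"] = {"n_raw": n_raw, "n_merged": len(merged)}

    # ------------------------------------------------------------ filter
    resources = fusion_filter.FilterResources.from_files(
        exclusion=config.path("exclusion.txt", required=False),
        paralogs=config.path("paralogs.tsv", required=False),
        normals=config.path("normals_panel.tsv", required=False),
        allowlist=config.path("allowlist.tsv", required=False),
        ffpm_min=config.ffpm_min,
        recurrence_max=config.recurrence_max,
    )
    outcomes = fusion_filter.apply_filter_cascade(merged, resources)
    fusion_filter.write_outcomes_tsv(outcomes, out / "filter_outcomes.tsv")
    kept = fusion_filter.kept_calls(merged, outcomes)
    rule_counts = {r: 0 for r in fusion_filter.RULE_ORDER}
    for o in outcomes:
        if not o.kept:
            rule_counts[o.failed_rule] += 1
    summary["stages"]["filter"] = {
        "n_in": len(merged),
        "n_kept": len(kept),
        "rejected_by_rule": rule_counts,
    }
    log.info("filter: kept %d of %d", len(kept), len(merged))

    # ---------------------------------------------------------- annotate
    from .genome_model import read_gtf, transcript_protein

    models = read_gtf(config.path("annotation.gtf"))
    transcripts = _read_fasta(config.path("transcripts.fa"))
    domains = breakpoint_annot.read_domain_table(config.path("domains.tsv"))
    kinase_groups = breakpoint_annot.read_kinase_table(config.path("kinases.tsv"))

    # ---------------------------------------------------------- validate
    wgs_dir = config.input_dir / "wgs"
    results = []
    for call in kept:
        sam = wgs_dir / f"{call.sample_id}.sam"
        if not sam.exists():
            results.append(
                wgs_validate.validate_call(0, has_wgs=False, call_id=call.call_id)
            )
            continue
        try:
            windows = wgs_validate.partner_windows(
                call.gene5, call.gene3, models, flank=config.flank
            )
        except KeyError as exc:
            raise StageError(f"validate: {exc}") from exc
        n = wgs_validate.count_discordant_pairs(
            sam, windows, min_mapq=config.min_mapq
        )
        results.append(
            wgs_validate.validate_call(
                n, has_wgs=True, min_pairs=config.min_pairs, call_id=call.call_id
            )
        )
    wgs_validate.write_results_tsv(results, out / "validation.tsv")
    n_eval = sum(r.status != wgs_validate.NOT_EVALUABLE for r in results)
    summary["stages"]["validate"] = {
        "n_calls": len(results),
        "n_evaluable": n_eval,
        "n_validated": sum(r.status == wgs_validate.VALIDATED for r in results),
        "validation_rate": (
            wgs_validate.validation_rate(results) if n_eval else None
        ),
    }

    annotated = []
    for call in kept:
        if call.gene5 not in models or call.gene3 not in models:
            warnings.warn(f"{call.call_id}: partner gene missing from annotation")
            continue
        annotated.append(
            breakpoint_annot.annotate_fusion(call, models, kinase_groups, domains)
        )
    ann_df = breakpoint_annot.fusions_to_frame(annotated)
    ann_df.to_csv(out / "annotated_fusions.tsv", sep="\t", index=False)
    category_counts = (
        ann_df.groupby(["region5", "region3"]).size().to_dict()
        if len(ann_df)
        else {}
    )
    kinase_table = (
        ann_df[ann_df.kinase_role != "NONE"]
        .groupby(["kinase_role", "frame", "domain_status"])
        .size()
        .to_dict()
        if len(ann_df)
        else {}
    )
    counts = breakpoint_annot.group_counts(annotated)
    if counts.to_numpy().sum() > 0:
        norm_pct = breakpoint_annot.normalized_group_percentages(counts)
        norm_pct.to_csv(out / "kinase_group_percentages.tsv", sep="\t")
        norm_dict = {
            ct: {g: float(v) for g, v in row.items()}
            for ct, row in norm_pct.iterrows()
        }
    else:
        norm_dict = {}
    summary["stages"]["annotate"] = {
        "n_annotated": len(annotated),
        "breakpoint_categories": {
            f"{a}|{b}": int(v) for (a, b), v in category_counts.items()
        },
        "kinase_profile": {
            f"{r}|{f}|{d}": int(v) for (r, f, d), v in kinase_table.items()
        },
        "kinase_group_percentages": norm_dict,
    }

    metadata = pd.read_csv(
        config.path("metadata.tsv"), sep="\t", index_col="sample_id"
    )

    # -------------------------------------------------------- expression
    if config.run_expression:
        expr_path = config.path("expression.tsv")
        expression = pd.read_csv(expr_path, sep="\t", index_col=0)
        copy_table = pd.read_csv(
            config.path("copy_number.tsv"), sep="\t", index_col=0
        )
        all_results = []
        for cancer_type, meta_ct in metadata.groupby("cancer_type"):
            cols = [s for s in meta_ct.index if s in expression.columns]
            fusion_samples: dict[str, set[str]] = {}
            for call in kept:
                if call.cancer_type != cancer_type:
                    continue
                for g in (call.gene5, call.gene3):
                    fusion_samples.setdefault(g, set()).add(call.sample_id)
            res = expression_assoc.fusion_expression_association(
                expression[cols],
                fusion_samples,
                str(cancer_type),
                fdr=config.fdr,
            )
            all_results.extend(res)
        expression_assoc.apply_fdr_and_flags(all_results, fdr=config.fdr)
        expression_assoc.association_results_frame(all_results).to_csv(
            out / "expression_association.tsv", sep="\t", index=False
        )

        comparisons = []
        for cancer_type, meta_ct in metadata.groupby("cancer_type"):
            cols = [s for s in meta_ct.index if s in expression.columns]
            kin = [
                f
                for f in annotated
                if f.call.cancer_type == cancer_type and f.kinase_gene is not None
            ]
            kin = expression_assoc.copy_number_filter(
                kin, copy_table, low=config.copy_low, high=config.copy_high
            )
            comp = expression_assoc.kinase_partner_comparison(
                expression[cols], kin, equal_band=config.equal_band
            )
            comparisons.append(comp)
        comparison = (
            pd.concat(comparisons, ignore_index=True)
            if comparisons
            else pd.DataFrame()
        )
        comparison.to_csv(out / "kinase_partner_comparison.tsv", sep="\t", index=False)
        summary["stages"]["expression"] = {
            "n_tests": len(all_results),
            "n_flagged": sum(r.flagged_for_review for r in all_results),
            "flagged_genes": sorted(
                f"{r.cancer_type}:{r.gene}"
                for r in all_results
                if r.flagged_for_review
            ),
            "kinase_partner_categories": (
                comparison["category"].value_counts().to_dict()
                if len(comparison)
                else {}
            ),
        }

    # ----------------------------------------------------------- drivers
    if config.run_drivers:
        maf = pd.read_csv(config.path("mutations.maf"), sep="\t")
        driver_genes = [
            line.strip()
            for line in open(config.path("drivers.txt"))
            if line.strip()
        ]
        profiles = driver_landscape.build_alteration_profiles(
            maf, kept, driver_genes, metadata
        )
        group_sizes = driver_landscape.driver_group_sizes(profiles)
        groups_df = pd.DataFrame(
            {
                "sample_id": [p.sample_id for p in profiles],
                "group": [
                    driver_landscape.classify_driver_group(p) for p in profiles
                ],
                "n_mutations": [p.n_mutations for p in profiles],
                "mmr_mutated": [p.mmr_mutated for p in profiles],
            }
        )
        groups_df.to_csv(out / "driver_groups.tsv", sep="\t", index=False)
        try:
            burden_p = driver_landscape.burden_comparison(
                profiles,
                driver_landscape.FUSION_ONLY,
                (
                    driver_landscape.DRIVER_MUT_ONLY,
                    driver_landscape.MUT_ONLY,
                    driver_landscape.DRIVER_MUT_AND_FUSION,
                    driver_landscape.MUT_AND_FUSION,
                ),
            )
        except ValueError:
            burden_p = None
        altered_genes = sorted(
            {
                g
                for call in kept
                for g in (call.gene5, call.gene3)
                if g in set(driver_genes)
            }
        )
        matrix = driver_landscape.exclusivity_matrix(
            kept, maf, altered_genes, list(metadata.index)
        )
        matrix.to_csv(out / "exclusivity_matrix.tsv", sep="\t")
        drug_table = driver_landscape.read_drug_table(config.path("drugs.tsv"))
        matches, druggable = driver_landscape.annotate_druggable(
            kept, drug_table, allow_off_label=True
        )
        matches.to_csv(out / "druggable_matches.tsv", sep="\t", index=False)
        for s in metadata.index:
            druggable.setdefault(str(s), False)
        smoking = driver_landscape.smoking_association(
            druggable, metadata["smoking_status"].to_dict()
        )
        summary["stages"]["drivers"] = {
            "group_sizes": group_sizes,
            "fusion_only_burden_p": burden_p,
            "druggable_fraction": sum(druggable.values()) / len(druggable),
            "smoking_chi2": (
                {"statistic": smoking[0], "p": smoking[1]} if smoking else None
            ),
        }

    # -------------------------------------------------------- neoepitope
    if config.run_neoepitope:
        predictor = synthetic_data.toy_affinity_model(config.seed)
        proteins: dict[str, neoepitope.FusionProtein] = {}
        wildtype: dict[str, list[str]] = {}
        alleles: dict[str, list[str]] = {}
        junction_reads: dict[str, int] = {}
        frame_of: dict[str, str] = {}
        for f in annotated:
            call = f.call
            utr_swap = (
                f.frame == NO_FRAME
                and f.category == ("FIVE_UTR", "FIVE_UTR")
            )
            if f.frame == NO_FRAME and not utr_swap:
                continue
            try:
                proteins[call.call_id] = neoepitope.translate_fusion(
                    f, transcripts, models
                )
            except ValueError as exc:
                warnings.warn(str(exc))
                continue
            wts = []
            for g in (call.gene5, call.gene3):
                m = models[g]
                if m.is_coding:
                    wts.append(transcript_protein(m, transcripts[g]))
            wildtype[call.call_id] = wts
            hla = metadata.loc[call.sample_id, "hla_alleles"]
            alleles[call.call_id] = str(hla).split(";")
            junction_reads[call.call_id] = call.junction_reads
            frame_of[call.call_id] = f.frame
        epitope_calls = neoepitope.call_neoantigens(
            proteins,
            wildtype,
            predictor,
            alleles,
            junction_reads,
            affinity_max=config.affinity_max,
            min_split_reads=config.min_split_reads,
        )
        pd.DataFrame(
            [
                {
                    "call_id": c.call_id,
                    "peptide": c.peptide,
                    "allele": c.allele,
                    "affinity_nM": c.affinity_nM,
                    "is_neoantigen": c.is_neoantigen,
                }
                for c in epitope_calls
            ]
        ).to_csv(out / "neoepitopes.tsv", sep="\t", index=False)
        counts = neoepitope.neoantigen_counts(epitope_calls)
        by_frame: dict[str, list[int]] = {INFRAME: [], FRAMESHIFT: []}
        for call_id, protein in proteins.items():
            if junction_reads.get(call_id, 0) < config.min_split_reads:
                continue
            fr = frame_of[call_id]
            if fr in by_frame:
                by_frame[fr].append(counts.get(call_id, 0))
        summary["stages"]["neoepitope"] = {
            "n_fusions_scored": len(
                [
                    c
                    for c in proteins
                    if junction_reads.get(c, 0) >= config.min_split_reads
                ]
            ),
            "n_neoantigens": int(sum(counts.values())),
            "mean_neoantigens_inframe": (
                float(np.mean(by_frame[INFRAME])) if by_frame[INFRAME] else None
            ),
            "mean_neoantigens_frameshift": (
                float(np.mean(by_frame[FRAMESHIFT]))
                if by_frame[FRAMESHIFT]
                else None
            ),
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
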