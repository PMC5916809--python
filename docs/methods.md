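# Methods

## Coordinate model and breakpoint convention

Every gene is represented by one canonical transcript (when several are
available in a GTF, the longest CDS wins, ties broken by smallest
transcript id). Exons are stored 0-based half-open in transcript
(5′→3′) order; GTF input (1-based closed) and all emitted breakpoints
(1-based, `chr:pos:strand`) are converted at the boundary.

A breakpoint coordinate is read as the *junction base*: the first base
3′ of the junction on that partner's transcript. For the 3′ partner
this is the first retained base; for the 5′ partner, the first excluded
base. The convention makes one quantity serve both sides:
`cds_offset`, the number of coding bases strictly 5′ of the breakpoint,
equals the retained coding bases of a 5′ partner and the discarded
coding bases of a 3′ partner. The reading frame of the 3′ gene survives
iff those two counts are congruent mod 3; a junction outside both CDSs
has no frame. Breakpoints reported on exon edges classify as exonic;
positions between exons are intronic; all positions in non-coding genes
are non-coding. The protein residue containing a CDS breakpoint is
`aa_pos = cds_offset // 3 + 1`.

## Filter cascade

The five rules are conjunctive, so the kept set is independent of
evaluation order; only the rule blamed for a rejection
(`failed_rule` = first violated in R1→R5 order) depends on it, which a
test asserts. Choices where the rules underdetermine behavior:

- Exclusion (R1) matches if *either* partner is listed; list matching is
  case-normalized.
- Paralog and normals matching (R2, R3) is on unordered gene pairs —
  panel-of-normals breakpoints vary run to run, gene pairs do not.
- The FFPM floor (R4, default 0.1) applies to calls seen by exactly one
  caller, whichever it is; agreement between two callers is treated as
  sufficient evidence regardless of support depth.
- Recurrence (R5) groups calls by exact equality of *both* breakpoints
  (not gene pairs). Removal requires the ≥ 10 samples to span ≥ 2 cancer
  types: a recurrence confined to one cancer type is plausible biology
  (TMPRSS2–ERG style) and kept, and allowlisted pairs survive
  regardless.

Cross-caller merging requires the same sample, same ordered gene pair,
and both breakpoints within ±5 bp (configurable; callers that realign
to genomic coordinates can be a few bases off exon edges). The merged
record takes coordinates and read counts from the best caller present
(STAR-Fusion-like > EricScript-like > Breakfast-like).

## WGS validation

A candidate is supported by a read pair when one mate falls in each
partner gene's span ± 100 kb, both mates have MAPQ ≥ 20 (the stricter
both-mates reading), and secondary/supplementary records are ignored;
≥ 3 such pairs validate the call. Discordance is defined purely by
window membership rather than SAM proper-pair flags so that mixed
low-/high-pass libraries behave identically. When the two windows
overlap (genomic-neighbor partners), the shared interval is removed
from both before counting: pairs wholly inside the overlap are ordinary
local coverage and must not self-validate the event. Samples without
WGS are excluded from the validation-rate denominator.

## Kinase annotation

Domain retention is assessed on the annotated catalytic-domain interval
[d_start, d_end] (1-based residues, boundary-inclusive — the boundary
residue's codon is complete):

- 5′-kinase: intact iff the junction residue is ≥ d_end or the
  breakpoint is in the kinase's 3′UTR. The partner's frame is
  irrelevant; the kinase ORF portion lies upstream of the junction.
- 3′-kinase: intact iff the whole ORF rides along (breakpoint in the
  kinase 5′UTR — the promoter-swap case) or the junction residue is
  ≤ d_start *and* the fusion is in frame.
- Genes with several domain rows are intact if any row is intact.
- Both-kinase fusions with exactly one intact domain are reassigned to
  that side; otherwise they stay both-kinase.

Per cancer type, the count of fused kinase genes in group *g* is
divided by the pan-cancer share *p₉* of that group and the results
rescaled to sum to 100 (`n₉/Σn₉`), which compares each cancer type
against the pan-cancer background instead of raw group sizes. Groups
with zero pan-cancer count are dropped before normalization; a cancer
type with no kinase fusions is omitted with a warning.

## Expression statistics

All expression statistics run within one cancer type on a log2(x+1)
scale (percentiles and fences are rank-based and therefore
scale-invariant; the t test is not). Percentile ranks use average ranks
rescaled by (rank − 1)/(n − 1) × 100, so a cohort maximum scores 100, a
fully tied cohort scores 50 everywhere, and the cohort mean is exactly
50. Quartiles for Tukey fences use linear interpolation between order
statistics (numpy/R type 7, the common default; configurable
convention was considered out of scope). Fences require n ≥ 4.

Association testing per fused gene: Welch's two-sided t test (fusion
vs non-fusion samples) and Fisher exact tests of outlier × fusion
status, run separately for over- and under-outliers since the two
directions answer different questions. Benjamini–Hochberg correction
("stringent FDR", q < 0.05 by default) is applied per test family
across all (gene, cancer type) tests in the run. A gene is flagged for
review when a corrected test passes, the fusion is seen in ≥ 3 samples,
and the carriers' median percentile is in the top or bottom decile.

The kinase-vs-partner comparison first restricts to fusions whose
kinase gene has 1–3 copies (inclusive) in the carrier sample, removing
amplification-driven expression, then compares the two genes'
percentile ranks in that sample; differences within ±5 percentile
points are "equal". Copy-number display categories use cut points
−2/−1/+1/+2 on a log2-ratio-like scale and are annotations, not
filters.

## Driver landscape

Only eight variant classes qualify as driver-gene alterations (inframe
indels, missense, nonsense, nonstop, splice site, translation start
site, plus fusions); silent and UTR classes contribute to the burden
only. Which mutations are *driver mutations* is an input annotation
column on the MAF, not something the package infers. A driver fusion is
any kept fusion touching a driver-gene list member. The six cohort
groups partition every sample. Burden comparisons remove samples with
any mutation in POLE, MLH1, MLH3, MGMT, MSH6, MSH3, MSH2, PMS1 or PMS2
first (hypermutator confounding), then apply a two-sided Mann-Whitney U
test — exact when both groups are ≤ 8 and tie-free, asymptotic
otherwise; both pairwise and pooled group comparisons are supported.
The smoking association is an uncorrected Pearson chi-square on the
2×2 druggable × smoking table (at n ≈ 500 the continuity correction is
immaterial; the published inequality holds either way); a zero margin
yields NA with a warning.

Drug matching: an evidence entry matches a fusion when its gene is a
partner, its required partner (if any) is the other one, and the entry
is on-label for the sample's cancer type — otherwise it counts only
when off-label use is allowed (the default, mirroring the
"regardless of cancer type" reading).

## Neoepitopes

The fusion protein is the translation of (5′ transcript up to the
junction) + (3′ transcript from the junction), starting at the 5′
gene's start codon and stopping at the first stop. In-frame products
carry the wild-type 3′ suffix; frameshift products carry a novel tail;
a 5′UTR→5′UTR swap yields the unaltered 3′ protein (junction index 0).
Candidate peptides are all full-length 8–11-mers containing the
junction's flanking residues, plus every tail k-mer for frameshift
products (default on — the whole tail is tumor-specific; a
junction-only mode exists). Peptides found verbatim in either partner's
wild-type protein are removed before prediction; the minimal
two-protein reading of "absent from wild type" is the default, with a
whole-proteome check available by supplying more sequences. A
peptide-allele pair is a neoantigen at ≤ 500 nM. Fusions with < 5
junction reads are skipped. Predictor failures produce NA calls, not
aborts.

The affinity predictor is a contract (deterministic peptide × allele →
nM in (0, 50000]); the bundled `ToyAffinityPredictor` is a seeded
hash, not a binding model. Its affinity is 50000·u² for hash-uniform u,
giving a ~10 % marginal binder rate so that epitope-count contrasts are
resolvable on cohorts of tens of fusions, and designated motifs can be
forced under 500 nM for tests.

## Synthetic cohort

The generator emulates: multi-exon gene models (2–5 exons, both
strands, CDS a multiple of 3 with proper start/stop, 80–160 codons)
laid out with ≥ 250 kb spacing so validation windows of distinct genes
never collide; log-normal expression (per-gene location 4–9 and scale
0.6–1.2 in log2 units) with fusion carriers shifted by ±5 gene-level
SDs for outlier events; mostly copy-neutral copy numbers with one
deliberately amplified carrier to exercise the 1–3 filter; MAF-like
mutations with Poisson(8) background burden, configurable driver and
driver-gene mutation fractions (0.45/0.25), and an MSI subpopulation
(10 % of samples) carrying an MMR mutation plus Poisson(80) extra
burden; per-sample SAM files with the configured number of qualifying
discordant pairs plus concordant and MAPQ-10 decoys; and toy HLA
metadata. Default cohort: two cancer-type labels × 50 samples, 48 genes
of which 16 are kinases (two per group). The truth set contains ten
kept events spanning every frame/side/domain combination the annotator
distinguishes, one decoy per filter rule, and one allowlisted recurrent
event.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: read-level sequencing noise and alignment
artifacts, isoform diversity and alternative splicing, correlated
expression structure, realistic HLA binding, germline variation, and
cancer-type-specific mutation spectra. Truth-recovery rates of 100 %
on this cohort demonstrate the pipeline's rules are implemented as
specified, not that real-data sensitivity/specificity would match.

## Problem sizes and determinism

All randomness flows from one integer seed through
`numpy.random.default_rng`; identical seed and config give
byte-identical generator output and pipeline reports. Test and
acceptance runs use desk-scale sizes chosen to exercise every code
path: 100-sample cohorts, 450 random fusions for the frame oracle
(9 phase combinations × 50), 100 replicates for outlier-recovery
rates, and 1000 simulations for Mann-Whitney calibration.

## Known limitations

- One canonical transcript per gene; breakpoints that are intronic on
  that transcript lose frame information even if another isoform would
  rescue it.
- The CDS genomic span includes the stop codon; GTFs that exclude stop
  codons from CDS features will shift 3′UTR boundaries by 3 bases.
- Merging is greedy (first match in caller-priority order); pathological
  chains of calls each within tolerance of the next could merge
  transitively.
- The exact-breakpoint reading of recurrence (R5) will not group
  recurrent events whose reported coordinates jitter between samples.
- `expression_percentile` requires the queried value to be a cohort
  member (a sample's own entry), by design.
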