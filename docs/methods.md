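# Methods

`fracseq` implements the downstream analysis of a subcellular
fractionation-then-sequencing study: given paired cytoplasmic and nuclear
RNA-seq quantifications from a panel of cell lines, plus a tumor/adjacent
cohort, it identifies long noncoding RNAs (lncRNAs), finds the subset that is
up-regulated in tumors by consensus differential expression, classifies each
gene's subcellular fraction bias against a housekeeping-calibrated reference
range, and characterizes the resulting nuclear-enriched disease-associated
candidates (promoter marks, preimplantation expression, survival,
co-expression partners). Because the real inputs for such a study are
controlled-access cohorts and in-house libraries, the package ships a
synthetic study generator that reproduces the statistical structure of those
inputs with recorded ground truth; every stage and the end-to-end run are
validated against that truth.

## Transcript catalogs and class codes

Transcripts are exon-structured models with 0-based half-open coordinates
internally; GTF I/O converts from/to the 1-based inclusive convention.
Transcript equivalence everywhere (assembly intersection, per-sample assembly
support) is **intron-chain identity** on the same chromosome and strand:
internal splice junctions are reproducible across assemblers while terminal
exon ends are not. Mono-exonic transcripts have no intron chain and are
matched only on an exact exon span; they are accepted by the data model but
removed by the lncRNA filter, which considers multi-exonic transcripts only.

Each assembled transcript receives one transfrag class code against the
reference annotation, decided in a fixed precedence order:

| code | relation |
|------|----------|
| `=`  | identical intron chain, same strand |
| `c`  | intron chain is a contiguous sub-chain of a reference chain, span contained |
| `j`  | shares at least one splice junction, same strand |
| `i`  | span entirely inside a reference intron (either strand) |
| `x`  | exonic overlap only on the opposite strand |
| `o`  | any same-strand exonic overlap |
| `u`  | intergenic |

The precedence order makes the decision total and deterministic; the test
suite checks every code against an independent brute-force oracle that works
on explicit per-base sets rather than interval arithmetic.

Assembly support counts, per condition (tumor/adjacent), the per-sample
assemblies containing a transcript under the same equivalence. It is monotone
in the sample set by construction.

## lncRNA identification

Candidate transcripts must pass five commuting filters: ≥ 2 exons, spliced
length strictly greater than 200 nt, known strand, expression above 1 TPM,
and no exonic overlap with the repeat mask (threshold configurable, default
zero tolerance). The expression criterion uses the **maximum** TPM across
samples by default (a mean-based mode is available); "length" is spliced
(summed-exon) length, the standard lncRNA definition, not genomic span.

Surviving transcripts are partitioned by class code: exact matches (`=`)
inherit the reference biotype — lincRNA/antisense become annotated lncRNAs,
protein_coding becomes mRNA, anything else is rejected. All other codes are
unannotated; an unannotated transcript is kept as a lncRNA only when **every**
required coding-potential predictor labels it noncoding. Predictors are
pluggable label tables; the built-in ORF predictor (coding iff the longest
ATG-initiated, stop-terminated open reading frame in the three sense frames is
≥ 100 amino acids) is a deliberately simple stand-in that lets synthetic runs
proceed without external tools, not a reimplementation of any published
classifier.

## Consensus differential expression

External DE methods are consumed as result tables with either an
FDR-style rule (|log2FC| > 1 and BH-adjusted p < 0.01, strict inequalities)
or a posterior-style rule (|log2FC| > 1 and PPDE > 0.99). The built-in method
— so the pipeline runs standalone — scales counts to a common library size,
computes log2 fold changes on condition means with a 0.5 pseudocount, and
tests each transcript with a two-sided Mann-Whitney U (exact for small
tie-free samples, tie-corrected normal approximation otherwise),
BH-adjusting across transcripts.

The consensus set is the intersection of all methods' significant calls with
**consistent direction**; transcripts significant everywhere but with
conflicting signs are excluded and logged (a transcript cannot be both up-
and down-regulated, so direction consistency is required even though an
intersection over identifiers alone would be weaker).

The dysregulated set is validated by clustering samples (average linkage on
1 − Pearson distance over per-feature-standardized log2(TPM+1)) into two
groups and testing the 2×2 cluster-by-status table with a chi-square test of
independence (1 df, no continuity correction). Note that correlation distance
only separates groups when the feature set contains both up- and
down-regulated genes — a one-directional signature yields near-constant
standardized profiles — which the generator reflects by planting
down-regulated lncRNAs alongside the up-regulated candidates.

## Fraction enrichment (core statistic)

Both fractions of all cell lines are normalized jointly by median-of-ratios
size factors (per-gene geometric mean over libraries computed on genes
positive everywhere; per-library factor = median gene/geometric-mean ratio).
Joint estimation over all fraction libraries is the default; note that it
anchors the absolute ratio scale to the gene-population median, so only
relative geometry (distances from the housekeeping band) is identifiable —
which is all the classification uses.

Per gene and cell line, log2(FPKM_cyto/FPKM_nuc) is defined only when both
fractions are ≥ 0.1 FPKM. The reference range for "normal" fraction bias is
the 5th–95th percentile interval (linear interpolation between order
statistics; nearest-rank available) of the per-gene **mean** ratio over
housekeeping genes (at least 30 evaluable required). A gene is
nuclear-enriched when its ratio falls strictly below the lower limit in ≥ 4
cell lines, cytoplasmic-enriched symmetrically above; boundary values are
non-fraction-specific ("below"/"exceeding" are strict). With the required
line count above half the panel, the two enriched statuses are mutually
exclusive by counting. Marker genes of known localization (GAPDH and RPS14
cytoplasmic, MALAT1 nuclear) are checked against their expected calls after
classification.

## Characterization

* **Promoter marks**: a transcript is associated with an active promoter in
  an epigenome when an H3K4me3 peak shares ≥ 1 base with the window
  [TSS − 1000, TSS + 1000] (inclusive endpoints, clipped at zero; TSS is the
  leftmost base on plus-strand, rightmost on minus-strand transcripts).
  Counts are reported per epigenome category (ESC, ESC-derived, iPSC,
  cancer).
* **Preimplantation expression**: per stage, a gene is *expressed* when ≥ 2
  embryos contain ≥ 1 cell with TPM > 1, and *lineage-specific* when some
  embryo has ≥ 2 expressing cells covering < 67% of its cells. The two
  clauses are evaluated independently and both are reported; a stage with
  fewer than two embryos is non-evaluable. "≥ 2 embryos" counts embryos
  within one stage, matching per-stage reporting.
* **Survival**: patients are split at the median expression of the gene
  (ties to the low group — the most common convention; the split point is
  configurable). Kaplan-Meier curves and the two-group log-rank statistic
  (Σ(O−E))²/ΣV with p from chi-square, 1 df, come from lifelines; the test
  suite verifies the statistic against a hand-tabulated O/E/V computation.
  Raw p-values are reported (the screening criterion is p < 0.05
  uncorrected), with a BH-adjusted column emitted alongside for transparency.
* **Report**: one row per candidate merges all evidence; a gene is flagged
  "not expressed" when its cell-line FPKM is below 0.5 in ≥ 5 lines.

## Co-expression

Genes expressed in < 20% of tumor samples are removed (fraction compared
inclusively). Pairwise Pearson correlations between each candidate and all
other genes are computed on log2(TPM+1) (transform configurable); p-values
come from the t transform with n−2 df. Partners satisfy PCC ≥ 0.6 (inclusive)
and p < 0.05; the rule is signed — only positive correlations qualify — with
an absolute-value mode behind a flag. Candidates are then clustered on their
partner-PCC rows (missing entries 0) by average-linkage hierarchical
clustering with Euclidean distance, cut into k = 3 clusters. Full weighted
network construction (soft thresholds, topological overlap, module
eigengenes) is deliberately not implemented: the analysis reported is plain
pairwise-correlation thresholding, and that is what the module does.

## Synthetic study generator

The generator emulates the study's statistical structure with one seeded
random generator per stream; equal configurations produce byte-identical
files. Default conditions: 2,000 genes (200 housekeeping, 300 lncRNA), 8
cell lines, 50 tumor/adjacent pairs (the end-to-end tests and acceptance run
use 10 pairs to keep the run small), 100 planted nuclear and 100 planted
cytoplasmic genes, 50 planted DE transcripts, 8 candidate genes planted with
both up-regulation and nuclear enrichment.

* **Fraction matrices**: per-gene mean ratio by class — neutral mRNA
  N(0, 0.6); housekeeping N(1.0, 1.3), a cytoplasm-shifted band whose
  5th/95th percentiles land near the asymmetric limits the calibration is
  meant to produce; background lncRNAs N(−1.0, 0.6) (nuclear-shifted as a
  population, without per-gene truth); planted genes at band-center − 3.5
  (nuclear) and + 5.0 (cytoplasmic), i.e. beyond the band. Per-line noise is
  N(0, 0.5); per-library depth factors U(0.6, 1.6) are applied so
  normalization has real work to do.
* **Tumor cohort**: negative-binomial counts (dispersion 0.05) with planted
  fold changes of ±2 log2 units; candidates draw their baseline from a
  moderately-expressed band so a 4-fold change is detectable at 10 pairs
  (undetectable candidates would be removed by the TPM filter anyway).
  Per-sample assembly catalogs include each transcript with probability
  saturating in its counts; candidate transcripts never enter adjacent
  catalogs (tumor-specific), and realized support counts are recorded as
  truth.
* **External DE tables**: one FDR-style and one posterior-style table are
  simulated from the truth with noisy fold changes; planted transcripts are
  confidently significant, null transcripts are not, leaving the built-in
  Mann-Whitney test as the power-limiting member of the consensus.
* **Survival**: a latent binary risk state drives both an exponential hazard
  (× hazard ratio 3 when high-risk) and the expression of prognostic genes,
  so a median split on any prognostic gene recovers the risk groups; 20%
  uniform censoring.
* **Co-expression**: a separate tumor-only panel (60 samples) where candidate
  lncRNAs and their planted partner mRNAs share latent factors with loading
  1.5 over N(0, 0.5) noise (pairwise r ≈ 0.9); the panel is separate from
  the DE counts, as in a design where co-expression uses the full tumor
  cohort rather than the matched pairs.
* **Embryo single-cell TPM**: 7 stages × 3 embryos × 8 cells; candidates
  express in 2–3 cells per embryo (≥ 2 cells, < 67%) from the 4-cell stage
  onward.
* **Peaks**: 27 epigenomes (8 ESC, 9 ESC-derived, 5 iPSC, 5 cancer);
  candidates carry a TSS-proximal peak in every stem-cell epigenome and in
  half the cancer ones; other genes are marked per epigenome with
  probability 0.3.
* **Catalogs**: three-exon gene models on two chromosomes; the reference is
  engineered per gene so that every class code occurs among unannotated
  lncRNAs in roughly the proportions a reference comparison produces
  (j-heavy, then u and i); five extra transcripts each violate exactly one
  candidate filter.

What the generator does **not** emulate: isoform complexity (one expressed
transcript per gene), positional correlation between neighbouring genes,
GC/length biases in quantification, multi-factor clinical confounding, or
assembly artifacts beyond presence/absence. Passing tests therefore show the
decision rules and statistics behave correctly under the assumed model, not
that the pipeline is robust to quantification artifacts in real data.

## Recovery metrics and numerical choices

Enrichment "recovery" is scored over the planted nuclear and cytoplasmic
genes (≥ 95% expected at default effect sizes, with zero
nuclear↔cytoplasmic confusions), plus the requirement that the bulk (≥ 75%)
of housekeeping genes classify as non-fraction-specific. Unplanted neutral
genes are not counted as errors: 10% of housekeeping genes lie outside their
own 5th–95th percentile band by definition, and a neutral mRNA whose true
mean ratio genuinely falls beyond the calibrated limits is being classified
correctly, not mistakenly.

Other numerical choices: percentile convention is linear interpolation
(configurable); zero-variance features are dropped with a log entry before
clustering, and a degenerate two-cluster cut returns chi-square 0 with p = 1;
Pearson r is clamped to [−1, 1] against rounding; transcripts missing from
an expression matrix are treated as zero expression and logged; all-zero
genes are ignored for size-factor estimation but preserved in normalized
output; ties in hierarchical clustering follow scipy's deterministic merge
order.

## Pipeline

`fracseq run` executes the stages in dependency order, communicating through
plain-text files in the output directory. Every stage writes a marker with a
hash of its parameters and input bytes; unchanged stages are skipped on
rerun, and two runs with the same seed produce byte-identical output trees.
A funnel log records the count after every filtering step (assembled →
filter survivors → lncRNAs → consensus DE → nuclear-enriched → candidates).
All thresholds are surfaced in `PipelineConfig` with the analysis' decision
rules as defaults, so a bare run applies exactly those rules.

## Known limitations

* The built-in DE test is rank-based and underpowered relative to
  model-based methods at small n; it is the limiting member of the consensus
  by design.
* The class-code comparator implements the seven codes above, not the full
  set a reference comparator emits (no p/e/s/r equivalents).
* The ORF-length coding-potential rule is a stand-in with no claim of
  accuracy on real sequence.
* Joint median-of-ratios normalization across fractions assumes most genes
  are not fraction-biased; a per-line normalization mode would be preferable
  if that assumption failed badly (the housekeeping calibration absorbs
  moderate violations).
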