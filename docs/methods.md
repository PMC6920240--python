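# Methods

## The procedure

The pipeline characterizes transcription factors (TFs) behind a disease
gene signature — a curated list of genes split into up- and down-regulated
sublists, each gene optionally flagged as belonging to an injury/repair
expression program. Four analysis stages run in order, each consuming the
previous stage's output:

1. **TF profiling.** A gene counts as a TF if its symbol occurs in any set
   of a TF catalog (union semantics — the catalog's sets are alternative
   curations, not independent evidence). The profile is partitioned on the
   injury flag, and the headline summary reports the injury percentage
   rounded to the nearest integer.
2. **Target enrichment.** For each TF-target set (one set per TF per
   experiment, ChEA-style) and each signature direction list, the
   representation factor RF = x·N/(n·D) compares the observed overlap x to
   the n·D/N expected under independence. A TF is called enriched when any
   of its experiment sets has RF strictly above 1. Keeping experiments as
   separate rows (rather than pooling per TF) preserves cell-line-specific
   evidence. Target sets are intersected with the universe before n is
   counted so x ≤ n ≤ N holds structurally. RF carries no p-value by
   default; a hypergeometric tail per row is available behind
   `with_pvalues=True`. Pathway overrepresentation (ORA) of target genes
   is the hypergeometric upper tail P(X ≥ k) with Benjamini–Hochberg FDR
   across categories restricted to sizes 2–700, significant at
   adjusted p ≤ 0.05.
3. **Peak-to-target mapping.** Peaks from multiple ChIP-seq studies are
   pooled and single-linkage merged per chromosome on ≥ 1 bp interval
   overlap (a deliberate, simple cross-study "same peak" rule — the
   sources define none). A cluster's intensity is the max over members;
   clusters survive when intensity ≥ 10 *and* they appear in ≥ 2 distinct
   studies. A gene is assigned to a cluster when its TSS lies in
   [start − 10 kb, end + 10 kb) — i.e. within 10 kb of the nearer peak
   end. The TSS (not the gene body) anchors assignment because the stage
   feeds promoter qPCR design. Assignments are restricted to signature
   genes and ranked by intensity, ties broken by study support then
   symbol. Proposed qPCR regions: the binding site is the cluster
   envelope; the negative control is a same-length interval centered 5 kb
   5′ of the TSS (strand-aware), shifted further 5′ until disjoint from
   the binding site and clipped at zero (falling back to 3′ placement if
   clipping would re-create an overlap).
4. **qPCR statistics.** ΔCt = Ct_target − mean(housekeeping Ct) per
   sample; the arithmetic mean on the Ct scale is exactly the geometric
   mean of linear-scale 2^−Ct abundances, which avoids a common
   implementation bug. Per assay and timepoint, a 2×2
   genotype × treatment ANOVA with interaction uses Type II sums of
   squares — each main effect adjusted for the other, the standard choice
   for unbalanced factorials (cells thin out at late timepoints when
   animals die), implemented directly on least-squares residual sums and
   cross-checked against statsmodels in the tests. Significance tiers on
   raw p: high < 0.0005, medium < 0.005, low < 0.05, else none (strict
   cuts; p = 0.05 is not significant). No cross-timepoint multiplicity
   correction by default, matching tier-style reporting; `fdr=True` adds
   BH columns without changing tiers. ChIP enrichment is percent input:
   adjusted_input = input_ct − log2(1/input_fraction), then
   100·2^(adjusted_input − ip_ct); the input fraction defaults to 1%.
   Binding comparisons run a two-way antibody × region ANOVA on raw
   percent-input with Tukey–Kramer all-pairs adjusted p (studentized
   range on pooled within-cell variance, Kramer correction for unequal
   sizes), starred at < 0.05 / < 0.01 / < 0.001.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `rf_threshold` | 1.0 (strict >) | ratio | enrichment = more overlap than chance |
| `min_intensity` | 10 | peak score | reproducible-signal floor, inclusive |
| `min_studies` | 2 | studies | "more than one study" reproducibility |
| `window` | 10,000 | bp | TSS-to-peak assignment distance |
| `control_offset` | 5,000 | bp | negative-control placement 5′ of TSS |
| ORA size window | 2–700 | genes | excludes trivial and uninformative categories |
| `alpha` | 0.05 | — | ORA significance on BH-adjusted p |
| tier cuts | 0.0005/0.005/0.05 | raw p | three-shade significance reporting |
| `input_fraction` | 0.01 | fraction | 1% input, the common ChIP dilution |

## What the synthetic generators emulate — and what they do not

The generators are first-class, tested code; their defaults are the study
conditions, not tuning knobs. `generate_signature_world` builds a
10,271-gene universe with a 775-up/740-down signature, ~6% of signature
genes planted as TFs and ~35% of those injury-flagged — the scale of the
real signature. `generate_target_db` plants sets drawing 60% of members
from the up-list (expected RF ≈ 0.6·N/D_up ≈ 8) against uniform null sets
(expected RF ≈ 1). `generate_peak_studies` lays genes 50 kb apart on one
synthetic chromosome; true sites recur in ≥ 2 of 3 studies with ±100 bp
boundary jitter (half-width 300 bp keeps ≥ 1 bp overlap) and intensity in
[10, 100]; noise is either sub-threshold intensity confined to intergenic
midzones or high-intensity but single-study, so the default filter removes
it deterministically and planted-recovery is exact by construction.
`generate_ct_dataset` adds planted genotype/treatment/interaction shifts
(ΔCt units) plus a per-sample plate offset and Gaussian noise of 0.3
cycles — a realistic replicate-level qPCR spread — at 6 replicates per
cell; housekeeping assays receive offset and noise only, so ΔCt
normalization cancels the offset exactly. `generate_chip_dataset` plants
an 8-fold target-at-binding enrichment over a 0.1% background with
lognormal noise at 20% CV and back-computes IP Ct values, defaulting to
n = 3 ChIPs.

Not emulated: genomic sequence, read-level data, gene–gene correlation,
amplification-efficiency differences, batch structure beyond a scalar
plate offset, and cross-study intensity scale differences. Passing the
planted-recovery tests therefore demonstrates the correctness of the
arithmetic and the filter logic under the stated noise models, not
robustness to real-data pathologies such as antibody cross-reactivity or
peak-caller disagreement.

## Numerical conventions and degenerate inputs

- Zero total variance in an ANOVA cell set: F = 0, p = 1 for every effect
  (a stated convention, not a limit).
- An empty design cell drops the interaction term (reported as absent)
  rather than failing; single-level factors are errors.
- Undetermined or out-of-range Ct ([0, 45]) is missing, never imputed;
  samples with no housekeeping signal are dropped with a warning.
- RF is undefined when n = 0 or D = 0 after universe intersection; such
  rows are skipped with a logged warning rather than emitted as 0.
- Sorting is stable everywhere with documented tie-breaks, and all tables
  render floats at 6 significant digits, so identical inputs give
  byte-identical outputs.
- Coordinates are 0-based half-open throughout; a peak's `end` is the
  first base past the signal, and the right-side TSS distance is
  tss − end (so a TSS exactly `window` past the end is excluded).

## Design choices that were genuinely open

- "Within 10 kb of both ends of the peak" admits a strict reading (within
  10 kb of *each* end simultaneously); the envelope-extension reading
  (within 10 kb of the nearer end) was chosen because the strict one
  excludes genes adjacent to wide peaks, contradicting the observation
  that binding sites generally overlap promoters.
- The arithmetic expression for RF can be parsed as x/(n·D·N); the verbal
  observed/expected definition is authoritative, giving x·N/(n·D).
- The universe N is an explicit input (defaulting to the supplied list)
  rather than a hard-coded constant, for portability across organisms.
- Type II (not I/III) sums of squares is a documented package choice for
  unbalanced cells, not a claim about any upstream analysis.
- No TF symbol alias/synonym resolution is attempted; identity is the
  upper-cased symbol.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run everything at sizes chosen
to make the statistical assertions sharp while staying quick on one CPU:
profile/overlap counts at full study scale (universe 10,271), peak-chain
recovery over 20–50 seeds of the 200-gene/3-study world, ANOVA null
calibration over 500–2,000 simulated datasets, Tukey equivalence against a
100,000-draw studentized-range simulation, and ChIP null/power over
100–200 seeds. Monte-Carlo bands are 3·SE per comparison with at most one
excursion allowed across a batch of independent comparisons (the expected
miss rate of a 3·SE band).

## Known limitations

- Single-linkage clustering can chain distinct nearby binding events into
  one cluster; no summit-based splitting is attempted.
- Cluster intensity is a max over member peaks with no cross-study
  normalization; studies on different intensity scales will bias ranking.
- The ORA universe choice (expression-detected vs annotated genes) changes
  p-values materially and is left to the caller.
- The 2×2 ANOVA does not model repeated measures or animal-level random
  effects; timepoints are analyzed independently by design.
- Percent-input assumes equal amplification efficiency between IP and
  input reactions; no standard-curve correction is implemented.
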