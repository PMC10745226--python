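# Methods

## Problem and model

ADAR enzymes deaminate adenosine to inosine in double-stranded RNA; since
sequencers read inosine as guanosine, editing appears in RNA-seq variant
calls as `A>G` substitutions on plus-strand transcripts and `T>C` on
minus-strand ones. The package starts where an upstream pipeline
(alignment, transcript assembly, haplotype calling, SnpEff annotation)
stops: per-sample VCFs whose records carry allelic depths (`AD`/`DP`) and
`ANN` functional annotations. Everything upstream of the VCF, and the
internals of SnpEff/SIFT, are out of scope by design — annotations and
scores are consumed, not recomputed.

Editing inference is rule-based, not probabilistic: a record is a putative
A-to-I event iff it is a biallelic `A>G`/`T>C` SNV, has no dbSNP rsID, and
its (transcript, site) key recurs in at least `min_samples = 2` samples of a
group. The recurrence key includes the transcript because consequence
annotation is transcript-resolved; a site-only key and cohort-wide scope are
available by flags (`include_transcript=False`, `per_group=False`). The
counting unit for event totals and 2×2 tables is the unique
(sample, site, transcript) tuple; when one record carries several
annotations for the same transcript only the highest-impact one is kept
(HIGH > MODERATE > LOW > MODIFIER) so category tables never double-count a
variant.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_samples` | 2 | recurrence threshold, distinct samples per (transcript, site) key within a group |
| `min_depth` | 100 reads | minimum total depth for a site to enter rate analyses |
| `sift_cutoff` | 0.05 | SIFT score at or below which a variant is deleterious (inclusive boundary) |
| `enrich_min_genes` | 10 | minimum query genes in a pathway for reporting |
| `enrich_min_fraction` | 0.10 | minimum fraction of the query list in the pathway |
| `enrich_alpha` | 0.05 | BH-FDR reporting threshold |
| `delta_cutoff` | 0.20 | group editing-level difference flag, in absolute percentage points |

The 20-point cutoff is interpreted as percentage points of editing level
(0.20 on the [0,1] rate scale), not a 20% relative change; the relative
reading is the main alternative and callers can rescale `delta` themselves
if they want it.

## Editing levels and shared sites

Rate = edited reads / total reads, with edited reads taken from the alt
allelic depth and total from `DP` (falling back to `AD` ref+alt). Records
without `AD` join event calling but never rate computation. The shared-site
matrix admits a site only when a depth-passing entry exists in every sample;
no imputation is attempted, matching the "shared across all samples"
construction. Group means are unweighted means of per-sample rates —
samples, not reads, are the replication unit — with pooled-read aggregation
deliberately not the default. A caller emits no record without
alternate-allele support, so a sample that observed zero edited reads at a
site has no VCF line there; the shared-site analysis therefore conditions on
sites putatively edited in all samples, which is the construction used for
cross-group rate comparison.

## Enrichment

The overrepresentation p-value is the exact binomial upper tail
`P(X ≥ k), X ~ Bin(n, K/N)` computed via `scipy.stats.binom.sf`, with BH
adjustment (`statsmodels`) across all pathways that share at least one gene
with the query. The universe defaults to all distinct genes in the GMT
annotation; a user-supplied background (e.g., all expressed genes) replaces
it. "At least 10 genes" is read as at least 10 *query* genes in the
pathway (k ≥ 10), consistent with reporting pathway percentages as k/n;
the alternative reading (pathway size ≥ 10) would change K-side filtering
only and is not implemented as a flag because k-side filtering is what the
percentage-based reporting uses. Ensembl version suffixes are stripped at
load; symbol case-folding is optional.

## Group statistics

Pearson χ² on 2×2 tables without Yates correction (a flag enables it);
zero-margin tables are rejected as degenerate rather than returning 0/1.
Mann–Whitney uses the exact null distribution when the data are tie-free and
C(nA+nB, nA) ≤ 20,000, otherwise the tie-corrected normal approximation.
Kruskal–Wallis is tie-corrected; an all-identical input returns H = 0,
p = 1 with a degeneracy flag instead of an error. p-values from any given
cohort are descriptive; the tests are validated by oracle equivalence
(closed form, full enumeration, exact summation) and by type-I-error
calibration on synthetic nulls, not by reproducing any particular cohort's
p-values.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- per-site read depth ~ negative binomial (gamma–Poisson, mean and
  dispersion; `dispersion=None` gives Poisson) — RNA-seq coverage is
  overdispersed, hence the default;
- edited reads ~ Binomial(depth, group rate) at each planted site, with the
  site's strand deciding the `A>G` vs `T>C` orientation;
- germline contaminants carry rsIDs and allele fractions near 0.5 or 1.0,
  so only the dbSNP filter — not the allele-fraction distribution — removes
  them, which is exactly what the end-to-end contaminant-removal property
  tests;
- non-editing substitution classes (`C>T`, `G>A`, …) exercise the class
  filter;
- every record carries an `ANN` annotation over a synthetic
  gene/transcript/pathway universe, with impact drawn once per site from a
  categorical distribution and a configurable fraction of HIGH sites also
  flagged as NMD transcripts.

Reproducibility: one master RNG seeded from the config generates the site
and contaminant catalogues; each sample draws from its own
deterministically derived substream, so identical config + seed gives
byte-identical VCFs, and partial re-runs with the same sample order are
stable. Expression tables are gamma-distributed around per-group mean TPM
with a configurable coefficient of variation (0 gives exact means, useful
for degenerate-case tests).

What the generator does *not* emulate: alignment artifacts, strand
bleed-through, positional read biases, Alu clustering of editing sites,
linkage between sites, or multi-allelic complexity beyond simple splitting.
Passing tests on simulated cohorts therefore demonstrates the correctness of
the filtering/quantification logic under the stated sampling model, not
robustness to real-data artifacts upstream of the VCF.

The synthetic supplementary-style workbook
(`write_synthetic_s1_workbook`) reproduces only the published list
*arithmetic* — 737 genes / 7827 transcripts, 302 up + 402 down disjoint DE
genes (704 unique), 38 genes shared with the disease list — with synthetic
identifiers; it exists so the list-algebra operations can be exercised end
to end without the original workbook, and is labelled synthetic everywhere.

## Numerical and scale choices

Acceptance-style computations use desk-scale problem sizes chosen to give
the properties under test adequate resolution: 200 planted sites and 50
contaminants per sample for filter correctness; 120 sites × 4 samples at
depths 100/1000/10000 for rate recovery (binomial SE at the deepest setting
≈ 0.002, well below the recovery tolerance); 500 replicates for χ²
calibration, giving a binomial 99% CI of ±2.5 points around the 5% nominal
rate; 1000 random tables and all nA, nB ≤ 8 for the statistical oracles.
Chi-square agreement with the closed form is asserted to 1e-9, Mann–Whitney
against enumeration and the binomial tail against exact rational summation
to 1e-12.

## Known limitations

- No site-level statistical test for differential editing; group deltas are
  descriptive, as in the analysis this package supports.
- The recurrence rule's scope (within-group vs cohort-wide) changes gene
  lists; within-group is the default and the flag is explicit.
- SIFT scores are joined per transcript with no cross-transcript
  reconciliation.
- The Pre/Post-type within-patient design is analysed unpaired, matching the
  named tests (χ², Mann–Whitney); no paired alternative is provided.
- No multiple-testing correction across families of 2×2 comparisons.
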