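# Methods

## Problem and model

`poolscan` implements a case/control differentiation scan for pooled
whole-genome sequencing (pool-seq), followed by an expression-anchored
enrichment analysis and two regulatory follow-up steps.  The design it
targets is one case pool of `n_SE = 22` diploid individuals sequenced
together, compared against four control pools of 10 individuals each at a
mean depth of ~30x.

**Pool allele frequencies.** With pooled DNA there are no genotypes; the
alternate-allele frequency of pool *k* at a biallelic SNP is estimated
directly from the allelic depths of a multi-sample VCF:

    p_k = R_alt / (R_ref + R_alt)

A pool with missing genotype (`./.`) or zero total depth is *not called* at
that locus; it contributes nothing rather than a frequency of 0.

**Virtual control pool.** The called control pools at a locus are merged
into a single virtual pool: `p_CO` is the *unweighted mean* of their
frequencies and `n_CO` the sum of their individual counts (10 each, up to
40).  A locus is eligible when the case pool and at least one control pool
are called.

**FST.** The per-locus fixation index between the case pool and the
virtual control pool is

    pbar = (n_SE * p_SE + n_CO * p_CO) / (n_SE + n_CO)
    FST  = [ pbar(1-pbar) - (n_SE p_SE(1-p_SE) + n_CO p_CO(1-p_CO)) / (n_SE + n_CO) ]
           / [ pbar(1-pbar) ]

Weights are individual counts, not chromosome counts.  The implementation
computes the numerator through the algebraically identical two-group
variance decomposition `n_SE n_CO (p_SE - p_CO)^2 / (n_SE + n_CO)^2`, which
avoids catastrophic cancellation and makes the corner values exact: FST is
0 whenever `p_SE = p_CO` and 1 exactly at a fixed difference.  Concavity of
`p(1-p)` confines the statistic to [0, 1].  Loci with `pbar` in {0, 1}
(monomorphic overall) have an undefined FST and are dropped with a logged
count.  One published variant of this formula prints the `pbar` denominator
as a product of the two pool sizes; with sizes 22 and 40 that quantity is
not a frequency and the statistic escapes [0, 1], so the sum is used and
the discrepancy is documented here.

Candidate loci are those with `FST >= threshold`, inclusive.  The default
threshold is 0.95; 0.9 is also in common use for downstream annotation, and
both are plain parameters.

## Proximity annotation and DEG-window enrichment

Gene models come from GFF3 (read via `gffutils`); all internal arithmetic
is 0-based half-open, converting VCF/GFF coordinates on the way in and out.
A variant is classified against every gene within `max_dist` (default
5 kbp, the usual effect-predictor window): `exon_variant` or
`intron_variant` inside the gene (distance 0), otherwise
`upstream_gene_variant`/`downstream_gene_variant` resolved by gene strand,
with the 1-based gap to the nearest gene boundary as the distance (a
variant adjacent to the gene is 1 bp away).

Differentially expressed genes (DEGs) are extended by a 200 kbp flank on
both sides; overlapping windows are merged and clipped to chromosome ends.
The enrichment statistic compares the number of distinct high-FST variant
positions observed inside the merged windows with the uniform expectation

    expected = n_variants * coverage_bp / genome_length_bp

The headline fold divides the observed count by the expectation *rounded to
the nearest integer* — matching how such numbers are usually reported — and
the unrounded fold is emitted alongside.  Both the distinct-position count
and the variant-gene pair count are reported, since one variant can sit in
the windows of several genes.  The genome length defaults to the sum of
chromosome lengths in the annotation and is overridable, as assembled
lengths differ between annotation releases.

## Expression filters

From one DE results table (gene, log2FC, p, adjusted p — e.g. DESeq2
output) three sets are derived with strict inequalities:

| set        | rule                      | role                        |
|------------|---------------------------|-----------------------------|
| strict     | abs(log2FC) > 1, p-adj < 0.001 | candidate DEGs for windows |
| relaxed    | abs(log2FC) > 1, p < 0.01 | clustering / network genes  |
| background | abs(log2FC) < 0.5         | motif-enrichment background |

Rows lacking the value a filter tests (adjusted p set to NA by independent
filtering) are excluded from that filter and counted, so
pass + fail + missing = input for every filter.  Strict is nested in
relaxed whenever `p-adj >= p`, which holds for standard adjustments.

## Promoter motif scan and gene-coverage enrichment

JASPAR-format PFMs (parsed with `Bio.motifs`) are turned into log-odds
matrices with a pseudocount of 0.8 split by the background composition
(uniform by default).  Promoters span -1500/+500 bp around the TSS; both
strands are scored at every offset and rescaled to a relative score in
[0, 1] between the matrix's minimum and maximum; windows at or above the
threshold (default 0.8) are hits, and windows containing N are skipped.

Gene-coverage enrichment tests whether a larger fraction of target-gene
promoters than background-gene promoters carries at least one hit: a
two-sided Fisher exact test on the 2x2 table, with
`log2((a/A)/(b/B))` as the effect size (infinite values are flagged, never
raised).  The commercial scanner this step approximates does not publish
its scoring internals; the log-odds scan with the parameters above is a
standard, fully documented stand-in, and its enrichment values should not
be expected to reproduce any specific tool's output numerically.

Co-regulation networks: the edge list is first restricted to the relaxed
DEG set, then connected components with fewer than 4 nodes are discarded
(restriction before the size rule, so components may dissolve when non-DEG
nodes drop out).  Self-loops are ignored with a count.

## Synthetic study generator

The generator emulates the study design the analysis assumes, not real
sequence content:

* **Frequencies** follow the Balding-Nichols model: ancestral `p0 ~
  U(0.05, 0.95)` per locus; each pool's population frequency `~
  Beta(p0(1-F)/F, (1-p0)(1-F)/F)`, so `F` is the expected pairwise
  fixation index.  All five pools diverge from a common ancestor with a
  common default `F` (the case pool can be given its own); whether real
  control pools diverge from each other is unknowable from the design, and
  a shared `F` is the neutral choice.
* **Reads**: pool sample counts are binomial over `2N` chromosomes, depth
  is Poisson(30), alternate reads binomial(depth, sample frequency); the
  AD field carries exactly these counts.  There is no sequencing-error
  model by default (an optional symmetric error rate exists), so planted
  fixed differences give FST = 1 exactly whenever called.
* **Fixed differences**: case frequency 1, controls 0.  Default 50 loci.
* **Monomorphic draws are rejected** and redrawn, since a variant caller
  would not emit an invariant site; this keeps "records = configured loci".
* **Genes** occupy one equal-width slot each (non-overlap by construction),
  with 2-5 exons and random strand; the DE table gives planted DEGs
  `|log2FC| ~ U(2, 6)` with p-values below 1e-9 (passing the strict filter
  after Benjamini-Hochberg by a wide margin) and null genes
  `log2FC ~ N(0, 0.3)`, `p ~ U(0, 1)`.
* **Co-location** is planted by planning genes first and pinning a
  configured fraction of the fixed-difference loci at uniform positions
  inside the +/-200 kbp windows of planted DEGs.  (Placing genes around
  already-drawn uniform loci cannot reach large fractions: a 400 kbp window
  in a 40 Mbp genome holds less than one uniform locus on average.)
* **Promoters** are i.i.d. sequences at configurable GC with the motif
  consensus inserted at recorded offsets in a configurable fraction of
  target promoters; the edge list contains one clique of planted DEGs
  (size min(6, planted)) plus random noise edges.

Everything is a pure function of the configuration: the same seed gives
byte-identical files.

What the generator deliberately lacks — linkage disequilibrium, indels and
multi-allelic sites, mapping artefacts, depth heterogeneity along the
genome, realistic promoter composition — bounds what green tests mean:
they validate the estimator, the interval statistics and the plumbing
under the stated sampling model, not robustness to alignment or calling
artefacts in real data.

## Default problem sizes

The simulated genome is 4 chromosomes x 10 Mbp with 5,000 loci, 200 genes
and 10 planted DEGs.  This keeps window coverage near 10% of the genome —
a deliberately scaled-down analogue of the study-scale geometry (~26 Mbp
of windows over ~2.4 Gbp, about 1%) — and a full pipeline run around one
second, so the whole suite exercises every stage end to end.  Divergence
recovery uses F in {0.01, 0.05, 0.2, 0.4}; note the per-locus two-pool
statistic averages well below the simulated F (the virtual control mean
shrinks the between-pool variance), so recovery is asserted as ordering,
not equality.

## Numerical choices and edge cases

* FST at monomorphic `pbar`: NaN internally, row dropped with a count —
  never a division by zero.
* Expected counts are rounded half-away-from-zero; an expectation that
  rounds to 0 flags the fold as infinite instead of dividing.
* Fisher p-values come from `scipy.stats.fisher_exact`; tests cross-check
  them against direct hypergeometric enumeration.
* Interval membership uses sorted merged intervals and binary search;
  merging is idempotent and order-invariant.
* Ties in PWM scores at the threshold count as hits (`>=`).

## Design choices where the design was open

* The pipeline has no resume/checkpoint mode: a full synthetic rerun is
  deterministic and takes about a second, so re-running is simpler and
  safer than resuming from partial state.
* Thresholds (0.95 vs 0.9 for the scan, strict vs relaxed DE sets) are
  parameters with documented defaults rather than constants.
* `p_CO` averages control pools unweighted by depth; depth-weighting is a
  plausible alternative but changes the estimator's meaning (it would
  weight sequencing effort, not individuals), so the plain mean is kept.

## Known limitations

* The FST estimator is the study's weighted two-pool form; it carries no
  pool-size bias correction of the kind pool-seq-specific estimators
  apply, and per-locus values at 30x depth are noisy — filtering at 0.95
  selects near-fixed differences, which is its intended use.
* The consequence classifier covers proximity classes only (upstream,
  downstream, intron, exon, intergenic); it is not a transcript-aware
  effect predictor.
* The motif step is an approximation at the scan level; only its planted
  signals on synthetic data, its internal oracle equivalences and its
  Fisher arithmetic are claims this package tests.
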