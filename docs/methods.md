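# Methods

## Windows, anchors, and coordinate conventions

Detection operates on a set of fixed-length sequence windows, one per
gene, aligned on an anchor base and stored in a common orientation.
Offsets are signed integers with 0 at the anchor; negative offsets lie
upstream on the gene's sense axis.

* **5' side** (TSS anchor): windows are stored 5'→3' on the coding
  strand; reverse-strand genes are reverse-complemented.  Genes without
  an annotated 5'-UTR are excluded because their TSS is unreliable.
* **3' side** (TTS anchor): all windows are standardized to the
  *antisense* orientation (forward-strand genes are reverse-
  complemented), so that in storage the end farthest from the gene again
  comes first.  Stored offset *s* maps back to the sense TTS axis as
  −*s*; every reported 3' coordinate (preferential position, functional
  window) is on the sense axis.  Genes without an annotated 3'-UTR are
  excluded.

Published interval notation such as [−1000; +500] is read as inclusive
at both ends (1501 positions).  When a gene has several transcripts the
anchor is the most extreme annotated TSS (5'-most) / TTS (3'-most); the
choice matters little for well-annotated genes and keeps the rule
transcript-selection-free.  Windows overrunning a chromosome end are
dropped and counted.  `N` letters are preserved and never match any
motif: a k-window containing an `N` is skipped in the tally.

Species presets fix the published extents — Arabidopsis 5' [−1000, +500]
and 3' [−500, +1000], maize 5' [−1500, +500] and 3' [−500, +1500] — and
the positional group intervals below.

## The detector

For each k-mer (4–8 by default; the full catalog has
Σ<sub>k=4..8</sub> 4<sup>k</sup> = 87,296 motifs) the per-offset
occurrence count over all windows is compared against a linear baseline
with a prediction band:

* **Neutral region** — the 500 stored positions most distal from the
  anchor (both sides start their stored windows at the distal end, so
  this is always the first 500 positions).  An OLS line of counts vs
  offset is fitted there; the residual standard deviation uses n−2
  degrees of freedom.
* **Band** — the upper limit of the two-sided 99% *prediction* interval
  for a single new count.  A prediction band (rather than a
  mean-response band) is deliberate: the test compares one observed
  count per offset against the band, and a mean-response band would
  shrink with the neutral sample size and flag ubiquitous noise.  The
  confidence level is configurable; 0.99 is the default.
* **Call** — exceedance offsets in the study region (everything outside
  the neutral region) form the set E; the preferential position
  maximizes count − band over E with ties broken toward the smallest
  stored offset (determinism), the functional window is the maximal
  contiguous run of E containing the peak, and the score is the peak
  exceedance.  One PLM per motif per side; PLMs with score ≤ 2 are
  discarded by default (strict inequality).
* Matching is strictly single-strand: a motif and its reverse complement
  are independent catalog entries.

The catalog-scale path vectorizes the fit/band/call over one dense
(4<sup>k</sup> × offsets) count table per motif length; the per-motif
functions define the reference semantics and the two paths are tested
against each other.  Count tables are int32 and sharded per k, keeping a
full 4–8-mer tally under ~1 GB for genome-scale inputs.

## Positional groups and composition

Preferential positions are binned into the published per-species group
schemes (e.g. Arabidopsis 5': G1 [−200, −50[, G2 [−50, −10[, G3
[−10, +20[), stored internally as inclusive integer intervals.
Positions upstream of all groups are labelled `Us`, downstream `Ds`, and
gaps between non-juxtaposed groups `NA`.  Nucleotide composition reports
pooled letter frequencies over motif strings of a PLM subset.

## Redundancy

Nested pairs (one motif a strict substring of the other) are flagged
when the functional-window Jaccard (computed on inclusive integer offset
sets) is ≥ 0.5 and the containing-gene-set Jaccard is ≥ 0.9.  The member
proposed for removal is the lower-score one (tie → shorter motif).
Collapsing is off by default: at genome scale nested redundancy affects
a sub-percent fraction of PLMs, so the pair report is informational.

## Assignment

* **PWM matching.** A PLM's one-hot matrix is compared to each library
  PWM by the minimum over all ≥4-column ungapped alignments (both
  orientations) of the mean per-column Euclidean distance.  Significance
  uses an exact empirical null: every same-length k-mer is scored
  against the PWM and p = (1 + #{k-mers at least as close}) / (1 +
  4^k).  This null is enumerable for k ≤ 8, deterministic, and
  oracle-testable; it replaces the approximate null models of external
  motif-comparison services.  P-values are BH-adjusted jointly over all
  (PLM, matrix) tests of a run; tPLM evidence requires q < 0.05 for at
  least one PWM, or an exact match in a curated k-mer library (matched
  in the given orientation only, mirroring the catalog's strand
  convention).
* **miRNA matching.** Only 8-bp PLMs are compared (mature miRNAs are
  19–24 nt; longer probes are pointless for an 8-mer catalog).  A PLM is
  a miPLM when found verbatim in a U→T-converted mature miRNA; the
  match position is recorded 1-based.  The substring step uses the given
  orientation only; full-length validation then slides the whole miRNA
  *and* its reverse complement over every ungapped placement covering
  the site and accepts ≤ 5 Hamming mismatches.  Coverage profiles
  report, per miRNA base, the fraction of matches covering it, with the
  5'-seed (bases 2–8) and cleavage site (10–11) as reference landmarks.
* **Footprints.** A PLM is positionally supported when an external
  interval (BED, converted to inclusive 1-based coordinates) has its
  midpoint (or, configurably, any overlap) inside the functional window
  extended by 30 bp, mapped to genomic coordinates per containing gene;
  bounds are inclusive.

## Enrichment

One-sided hypergeometric over-representation, P(X ≥ k), per flat
annotation term, BH-corrected, significant at adjusted p < 0.05.  The
reference list is by convention the genes retained for detection on the
same side; genes outside it are ignored on both sides of the test.  No
ontology propagation is performed — parent terms must be pre-expanded by
the annotation provider.  "Specific" terms for a PLM class are those
significant for that class's gene set and no other (set difference).

## Network inference

The incidence matrix has TF families in rows and target genes in
columns; entry 1 means at least one tPLM of that family occurs in the
gene's proximal region.  The Bernoulli latent block model is fitted with
mean-field variational EM: coordinate updates of row/column membership
posteriors and closed-form M-steps (posterior-weighted block means), so
the variational bound is non-decreasing; convergence at bound change
< 1e-6 or 500 iterations.  Probabilities are clamped to [1e-9, 1−1e-9].
Restarts (default 20) are seeded deterministically; the first start
initializes from independent k-means clusterings of rows and columns,
the rest from random hard partitions — pure near-uniform random
initializations collapse into the symmetric fixed point.  Ties on the
final bound go to the lowest start index.  Model dimensions are chosen
by the integrated completed likelihood: the completed log-likelihood at
hard max-posterior assignments minus (Q−1)/2·log n + (L−1)/2·log d +
QL/2·log(nd).  Hard assignments always come from max posteriors;
fitted modules left empty by them are reported with a warning.
All-zero rows/columns are retained but flagged.

## Synthetic data

The generator emulates exactly the assumption the detector relies on:
i.i.d. order-0 background letters with motifs overwritten at a planted
offset (uniform jitter ± radius) in a Bernoulli-selected fraction of
sequences, with a truth table of every realized plant.  Overlapping
plants within a sequence are skipped and logged so the truth stays
unambiguous.  It does **not** emulate dinucleotide composition biases,
compositional gradients along promoters, repeat structure, or motif
co-occurrence grammar — so passing recovery tests demonstrates
correctness of the statistical machinery, not performance on real
chromatin.  Block-matrix and flat-annotation generators mirror the
models of the network and enrichment stages the same way.

## Problem sizes and calibration regime

The test suite and the acceptance script run at desk scale, chosen to
exercise every code path in minutes: planted-motif recovery uses 500
windows of 1501 bases (20 seeds for the recovery rate); band calibration
uses two replicates of 8,000 background windows scanning five dimers
over ~1,000 study offsets each (≈10,000 draws); block-model recovery
uses 60×40 incidences with 3×3 planted blocks (0.9 within-pattern vs
0.1) over 10 seeds with ICL selection across Q, L ∈ 1..4.

Calibration is assessed with dimers at n = 8,000 because the band is a
normal-theory construction: with per-offset means around 500 the count
distribution is effectively Gaussian and the empirical exceedance rate
matches the nominal 0.5% within binomial error.  For rare motifs (large
k and/or few genes, per-offset means below ~20) the Poisson skewness of
counts makes the band slightly permissive — measured exceedance around
0.7–0.8% instead of 0.5% — which is a known property of applying a
Gaussian prediction band to low counts.  At genome scale (≈20,000–26,000
genes) 4–6-mers sit comfortably in the calibrated regime, while 8-mers
(mean ≈ 0.3–0.4 per offset) rely on the score > 2 filter to suppress the
resulting weak excess of marginal calls.

## Known limitations

* Exact k-mers only: no PWM-style degenerate motif discovery, no
  dinucleotide background correction, single peak per motif.
* The empirical PWM null scores all k-mers of the query's length, not a
  shuffled-motif null; q-values are therefore comparable within a run
  but not with external motif-comparison tools.
* Full-length miRNA validation is ungapped Hamming distance — no G:U
  wobble or bulge scoring.
* The LBM assumes Bernoulli blocks without degree correction; highly
  heterogeneous family marginals can masquerade as modules.
* GFF3 only (no GTF); UTR presence is taken from annotation, so
  annotation errors propagate to gene retention.
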