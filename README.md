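# plmkit

Genome-wide, *de novo* detection and characterization of **preferentially
located motifs (PLMs)** — short DNA k-mers that accumulate at a fixed
distance from gene anchors (the transcription start site, TSS, or the
transcription termination site, TTS).  Canonical examples are the
TATA-box near −35 from the TSS and the polyadenylation elements upstream
of the TTS.  plmkit is written for plant regulatory genomicists who want
to map this positional *cis*-regulatory landscape from nothing but a
genome FASTA and its GFF3 annotation, and then ask what the detected
motifs are: transcription-factor binding sites (tPLMs), miRNA-matching
motifs (miPLMs), or unassigned candidates (uPLMs) worth following up.

## Method

For every non-degenerate k-mer *m* (4 ≤ k ≤ 8; 87,296 motifs) and every
offset *x* in a set of anchor-aligned, equally oriented gene-proximal
windows, plmkit counts the number of genes whose window carries *m*
starting at *x*, giving a positional occurrence distribution
*N<sub>m</sub>(x)*.  A linear baseline is fitted by ordinary least
squares over the **neutral region** — the 500 window positions most
distal from the anchor, where no positional signal is expected:

    N_m(x) ≈ a + b·x,   x ∈ neutral region.

In the remaining study region, the motif is compared against the upper
bound of the two-sided 99% **prediction band** for a new observation,

    U(x) = a + b·x + t_{0.995, n−2} · s · sqrt(1 + 1/n + (x − x̄)² / Sxx),

where *s* is the residual standard deviation of the fit.  A motif is a
PLM when *N<sub>m</sub>(x) > U(x)* somewhere in the study region; it is
summarized by its **preferential position** (offset of maximal
exceedance), its **functional window** (the contiguous exceeding run
around the peak), and its **score** *N<sub>m</sub>(pp) − U(pp)*.  Only
PLMs with score > 2 are retained by default.

Downstream stages are: redundancy screening of nested motif pairs
(Jaccard ≥ 0.9 on gene sets, ≥ 0.5 on windows); assignment against PWM
libraries (minimum per-column Euclidean distance over ≥4-column
alignments, exact empirical null over all same-length k-mers,
Benjamini–Hochberg q < 0.05), exact ChIP-derived k-mer matches, and
mature miRNA substrings with full-length 0–5-mismatch validation;
footprint support from BED intervals within a ±30 bp flank of the
functional window; hypergeometric term enrichment of PLM-containing gene
sets; and co-clustering of the TF-family × target-gene incidence matrix
with a Bernoulli latent block model (variational EM, ICL model
selection).

## Worked example

Everything runs end-to-end on synthetic data with a known ground truth —
no downloads needed.  Plant the TATA-like 8-mer `TATAAATA` at offset
−35 ± 2 bp in 30% of 500 background windows spanning [−1000, +500]
around a mock TSS, then detect:

```python
import plmkit as pk

regions, truth = pk.generate_regions(
    n=500, upstream_extent=1000, downstream_extent=500,
    plants=[pk.PlantSpec("TATAAATA", center_offset=-35,
                         jitter_radius=2, fraction=0.3)],
    seed=42,
)
plms = pk.find_plms(regions, pk.enumerate_kmers(4, 8),
                    scheme=pk.GROUP_SCHEMES["at5p"])
hit = next(p for p in plms if p.motif == "TATAAATA")
print(hit.preferential_position, round(hit.score, 2),
      len(hit.gene_set), hit.group_label)
```

prints

```
-34 30.87 126 G2
```

i.e. the planted motif is recovered at −34 (within the ±2 bp jitter of
the planted −35), its occurrence count exceeds the 99% band by ≈31
genes, it occurs in-window in the 126 genes that actually received a
planted copy, and its peak falls in positional group G2 — the
TATA-box region of the 5' group scheme.

The same flow is available from the shell:

```bash
plm simulate --n 500 --upstream 1000 --downstream 500 \
    --plant TATAAATA:-35:2:0.3 --seed 42 --out sim
plm detect --regions sim.regions.tsv --groups preset:at5p --out run
plm filter --plms run.plms.tsv --genes run.genes.tsv --pairs-out pairs.tsv
```

Real-genome runs replace `--regions` with `--genome genome.fa --gff
annotation.gff3` and a species preset (`--preset at5p|at3p|zm5p|zm3p`),
which fixes the published window extents and positional group
intervals.

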