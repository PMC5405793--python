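# dangertrack

Not all parts of a reference genome can be trusted equally: repetitive
sequence confuses read mapping, and regions dense in structural variation
(SV) are exactly where a linear reference misrepresents real genomes.
Variant calls (SNPs in particular) made in such regions are unreliable,
yet standard pipelines score them the same as calls in clean sequence.
`dangertrack` computes a per-window *danger score* in [0, 1] over any
genome — 0 for a unique, easy-to-assess region, 1 for a repetitive,
SV-enriched one — and writes it as BED/bedGraph genome-browser tracks, so
downstream analyses can weight or filter calls by local reliability. It is
aimed at people running variant-calling or population-genomics pipelines
who want an automatic, organism-agnostic alternative to manually curated
blacklists.

## Method

The genome is tiled into fixed windows of size *W* (default 5 kb). Two
kinds of per-window features, each in [0, 1], are combined:

**SV breakpoint density.** Every SV record in a VCF contributes two
breakpoints (start and end; an insertion's two coincide; a breakend
record contributes its own position and its mate's). Per-window breakpoint
counts *c_i* are normalized by the genome-wide 99% quantile count
*q* (nearest-rank, zero-count windows included):

    f_i = min(c_i / q, 1)

**Uniqueness.** A base-resolution mappability track assigns each base
*m* = 1 / (number of exact genome matches of the k-mer starting there);
the window feature is one minus the mean:

    u_i = 1 − mean(m over window i)

so u = 0 is fully unique sequence. Tracks can be read from bedGraph/wiggle
files (e.g. reference alignability tracks with k = 50 and k = 100), or
computed exactly from a FASTA with the built-in k-mer counter for small
genomes.

**Score.** With features *f¹ … f^J* (classically four: two SV call sets
plus k = 50 and k = 100 uniqueness) and non-negative weights *w_j*
(uniform by default),

    D_i = Σ_j w_j f^j_i  ∈ [0, 1].

For evaluation, a curated region list (an ENCODE-style blacklist, GRC
issue regions) is binned onto the same grid as per-window covered
fraction, and compared with the score by Pearson correlation (with seeded
subsampling of windows) and by threshold-based overlap summaries.

## Worked example

The built-in simulator generates a toy study with known ground truth: ten
50 kb chromosomes (100 windows of 5 kb), ten "trouble" windows each
carrying a planted 1 kb exact repeat plus an SV hotspot of 40 breakpoints
in each of two call sets, 30 background SVs per call set, and a blacklist
marking the trouble windows:

```sh
dangertrack simulate --seed 7 --out-dir demo
dangertrack score \
    --chrom-sizes demo/genome.chrom.sizes \
    --sv demo/sv_callset_a.vcf,demo/sv_callset_b.vcf \
    --mappability demo/mappability_k50.bedgraph,demo/mappability_k100.bedgraph \
    --out-prefix demo/danger
dangertrack compare \
    --score demo/danger.bedgraph --chrom-sizes demo/genome.chrom.sizes \
    --regions demo/blacklist.bed --threshold 0.3 --out-prefix demo/vs_blacklist
```

which prints

```
scored 100 windows from 4 features -> demo/danger.bedgraph
correlation (pearson, n=100): 0.9969; 10/100 windows >= 0.3
```

`demo/danger.bedgraph` holds one line per window; background windows score
near 0 (a little residual SV density and edge effects), while the ten
planted windows score ≈ 0.57 — SV density saturates at 1 in both call
sets, and the 1 kb repeat inside the 5 kb window contributes ≈ 0.1
uniqueness per mappability track:

```
chr1    0       5000    0.0844
chr1    5000    10000   0.0000
...
chr2    35000   40000   0.5842    <- planted trouble window
```

The Pearson correlation of 0.9969 between score and blacklist track, and
the exact recovery of the 10 planted windows above the 0.3 cutoff, are the
expected outcome when the blacklist marks truly score-relevant regions.
`demo/danger.provenance.json` records inputs (with checksums), weights and
the per-call-set normalization quantiles.

The same computation is available as a library
(`dangertrack.pipeline.compute_danger_track`), and each stage separately
(`windows`, `sv_breakpoints`, `mappability`, `scoring`,
`blacklist_compare`, `fixtures`).

## Limitations

The exact k-mer mappability calculator is for toy/small genomes (counts
exact matches only, no mismatch tolerance); for large genomes use
precomputed alignability tracks. Scores are per-window, not per-base, and
weights are fixed, not learned. See `docs/methods.md` for modelling
details and design choices.
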