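# Methods

## Model

`dangertrack` scores genome reliability per fixed-size window by averaging
two kinds of evidence that a region is hard to assess with short-read
mapping: the local density of structural-variant breakpoints, and the
non-uniqueness of the sequence itself. The underlying assumptions are
that (i) windows where many SV breakpoints from population- or
benchmark-scale call sets accumulate are windows where the linear
reference is a poor model of real genomes, and (ii) windows of low k-mer
mappability cannot be genotyped confidently regardless of the sample.
The two signals are deliberately combined by a plain weighted mean rather
than a fitted model: the score is descriptive, not calibrated to any
particular caller's error rate.

## Coordinates and windows

All internal coordinates are 0-based half-open (BED convention); VCF
(1-based) and wiggle (1-based) inputs are converted at their parser
boundaries. Chromosome order as given in the chrom.sizes/.fai input is
canonical for every track. Windows tile each chromosome from 0 to its
length; the final window is truncated, never dropped or extended, so that
every base belongs to exactly one window and chromosome ends are still
scored. Chromosome names are matched exactly; the CLI's `--chr-prefix
add|strip` performs explicit `chr`-prefix harmonization, because silent
aliasing of names is a classic source of coordinate bugs (population VCFs
and browser tracks disagree on the prefix).

## SV breakpoint features

Each VCF record yields exactly two breakpoints. For non-breakend records
the end coordinate is resolved in priority order: `INFO/END` (1-based
inclusive), then `start + |SVLEN|`, then `start + len(REF) − 1`. This
order covers archive-style records (symbolic ALT + END), caller output
(SVLEN only), and explicit-sequence records. Insertions are the
exception: their SVLEN measures the inserted sequence, not a reference
span, so the SVLEN rule is skipped and both breakpoints coincide at the
insertion point — which keeps the invariant Σ counts = 2 × records
testable on any fully-in-layout call set. Breakend (BND) records
contribute their own position plus the mate coordinate parsed from the
ALT string; mate pairs are not deduplicated (no pairing rule is imposed,
and per-record independence keeps counting order-invariant).
Multi-allelic records contribute one pair from the first ALT (SV VCFs are
near-universally bi-allelic; occurrences are logged). Records are not
filtered on FILTER by default; `--pass-only` enables it. Records on
chromosomes outside the layout are skipped and tallied; a breakpoint
falling individually outside (e.g. a BND mate) is dropped and tallied.

Counts are normalized by the genome-wide empirical q-quantile (default
q = 0.99) computed over **all** windows, zeros included, with the
nearest-rank estimator (smallest value whose cumulative proportion ≥ q;
`numpy.quantile(..., method="inverted_cdf")`). Nearest-rank avoids
interpolation ambiguity across platforms. Ratios above 1 are clipped to 1
**before** combination — with uniform weights this is the only clipping
point that guarantees the combined score stays in [0, 1] — and a `clipped`
flag is carried in provenance. If the quantile is 0 (sparse call sets on
small genomes), any window with ≥ 1 breakpoint gets feature value 1.

## Mappability and uniqueness

A mappability track assigns each base m = 1/n where n is the number of
genome matches of the k-mer starting at that base (left-anchored, the
fixedStep-wiggle convention of reference alignability tracks). The
built-in calculator counts **exact** matches only, forward strand by
default (`count_reverse_complement=True` adds reverse-complement matches,
guarding against double-counting palindromic k-mers); k-mers containing
non-ACGT characters and start positions within k−1 of a chromosome end
are undefined. It is intended for genomes up to ~10 Mb; it makes no
attempt to reproduce mismatch-tolerant alignability of published
reference tracks.

Window uniqueness is u = 1 − mean(m). Bases absent from a track are
controlled by a missing policy. The default, `missing_as_zero`, treats
them as m = 0: in real tracks the uncovered bases are assembly gaps and N
runs, which are precisely regions a reliability score should flag.
`missing_excluded` averages over covered bases only (a fully uncovered
window gets u = 1). Aggregation is interval-wise; per-base arrays are
materialized only in tests/oracles.

## Score combination and serialization

Features are combined as D = Σ w_j f_j with w ≥ 0 normalized to sum to 1;
"uniform weighting" (w_j = 1/J) is the default and the documented recipe
uses four features (two SV call sets, k = 50 and k = 100 uniqueness), but
any J ≥ 1 is accepted. bedGraph output prints the authoritative 0–1 value
to 4 decimals (fixed precision for reproducible diffs; round-trip error
≤ 5 × 10⁻⁵). BED5 output maps the score to the UCSC 0–1000 integer
convention with round-half-even. Outputs are byte-deterministic for
identical inputs; provenance (inputs, checksums, weights, quantiles, clip
flags, version) is written as JSON alongside.

## Blacklist concordance

Curated region lists are merged on load and binned onto the grid as the
covered fraction of each window (the closer analogue of how the score
itself is binned) or binarized. Concordance uses Pearson correlation by
default — Spearman behind a flag — optionally over a without-replacement
subsample of windows with an explicit, recorded seed, since a subsampled
correlation is otherwise irreproducible. A constant vector yields an
explicit "undefined" result rather than NaN. The threshold-based overlap
summary (windows with D ≥ t, their overlap with the region list,
per-chromosome counts) exposes the cutoff as a parameter; no canonical
threshold is claimed.

## Synthetic data generator

The `fixtures` module generates complete studies with analytic ground
truth: random A/C/G/T genomes with exact repeat copies planted by
copy-paste (so k-mer occurrence counts, hence mappability, are known;
optionally the base sequence is redrawn until no k-mer of a chosen order
repeats, making planted copies the only repeats), SV VCFs whose
breakpoints are placed per an explicit hotspot/background plan with truth
counts tallied by the generator itself, and blacklists marking chosen
windows with bounded endpoint jitter. All generators are pure functions
of the spec (seed included): repeated calls are byte-identical.

The reference study condition (`default_fixture_spec`) uses ten 50 kb
chromosomes (100 windows at the standard 5 kb), one trouble window per
chromosome carrying a 1 kb exact repeat and a 40-breakpoint hotspot in
each of two call sets, 30 background records per call set, 200 bp
blacklist jitter, and k ∈ {50, 100} mappability. Forty breakpoints per
window was chosen as an unambiguous hotspot: in real genome-scale data,
windows with more than ~20 breakpoints are rare outliers. The toy scale
keeps the full pipeline (including exact k-mer counting of a 500 kb
genome) to seconds while leaving a wide score margin between planted
(≈ 0.57) and background (≲ 0.1) windows.

What the fixtures do **not** emulate: realistic SV size/type
distributions, sequencing or caller noise, mismatch-tolerant mappability,
assembly gaps, or inter-caller disagreement. Passing tests therefore
demonstrate correctness of the method's arithmetic and plumbing on known
truth, not performance on real genomes.

## Numerical and degenerate-input choices

Quantile ties are resolved by nearest rank (no interpolation). Clipping
is pre-combination (see above). Scores are clipped to [0, 1] after
combination only to absorb float round-off. Empty breakpoint lists give
all-zero features; empty region lists give zero coverage everywhere and
an undefined correlation against a constant score. BED score rounding is
round-half-even. Window size 1 is legal (used in tests to make per-window
and per-element arithmetic coincide).

## Known limitations

- The exact k-mer counter is memory/CPU-bound past ~10 Mb genomes.
- One feature per input VCF: no merging/consensus of call sets.
- Per-window resolution only; a breakpoint at a window edge credits one
  window, not its neighbour.
- Weights are user-set, not learned; the uniform default is a convention,
  not an optimum.
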