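# Methods

## Problem and model

A diploid genome sequenced at total depth C yields a read k-mer spectrum
with three regimes: sequencing-error k-mers concentrated at very low
multiplicity, heterozygous k-mers (content carried by one haplotype)
near C<sub>k</sub>/2, and homozygous k-mers near the full k-mer depth
C<sub>k</sub> = C·(L−k+1)/L·(1−e)<sup>k</sup>. When an assembler fails
to collapse a heterozygous region, both haplotype copies enter the
assembly: the region's k-mers then have assembly copy number 2 while
their read multiplicity remains that of single-copy genome content. The
pipeline identifies scaffolds dominated by this signature and removes
those that are redundant with a longer scaffold.

## Spectrum decomposition

The read spectrum histogram is fitted with a sum of 2–4 Gaussian
components by bounded least squares (`scipy.optimize.least_squares`,
trust-region reflective). Histogram-level fitting was chosen over
per-k-mer EM because it is deterministic, runs in milliseconds at any
data size, and the downstream consumer needs only the location and
spread of the homozygous component. Details:

- **Error cutoff**: the first local minimum of the histogram scanning up
  from multiplicity 1 (errors decay, signal rises); fallback 3 when the
  histogram is monotone. Only mass above the cutoff is fitted, over
  multiplicities up to 4× the histogram mode m̂.
- **Initialization**: component means at m̂/2, m̂, 2m̂, 3m̂ (het, hom,
  repeat doublings), σ at √μ (Poisson-like), weights from the local
  histogram height. The histogram is normalized by its maximum before
  fitting so the fit is exactly scale-equivariant; weights are rescaled
  afterwards.
- **Homozygous component**: the fitted component with mean nearest m̂.
  Components whose weight collapses below 10⁻⁹ of the total are dropped
  (e.g. the repeat component on a repeat-free genome).
- **Homozygous band**: μ ± 3σ of the homozygous component, clipped below
  at the error cutoff and truncated at the density crossing with the
  adjacent component on each side, so heterozygous or repeat mass does
  not leak in. A degenerate σ < 0.5 widens to (μ−1, μ+1).

The default of 3 components (het, hom, one repeat multiple) suits
moderately heterozygous genomes; use 2 for repeat-poor or haploid data.

## K-mer machinery

k is capped at 31 so canonical k-mers pack into 64-bit codes (A<C<G<T,
first base most significant, canonical = min of forward and
reverse-complement codes; numeric order equals lexicographic order).
Counting is a single rolling pass (numba) followed by `np.unique` on
~48 Mb chunks; tables are sorted code arrays, so lookups and
intersections are binary searches. N-containing windows are skipped
entirely. Default k = 27 balances specificity against error-induced
k-mer loss at short-read error rates; it is a surfaced, recorded
parameter on every interface.

Per-scaffold medians use the lower middle value for even-sized window
multisets, keeping medians integral so the flagging predicate
`median_asm_copy == 2` is exact. The GC/coverage screening table uses
median read k-mer multiplicity as its coverage proxy rather than read
alignment depth — a deliberate simplification that avoids an external
aligner and affects only the screening table, not deduplication.

## Containment alignment

The removal rule asks whether a flagged scaffold is contained in a
strictly longer one at ≥ 75% identity over ≥ 25% of its length
(thresholds inclusive; coverage is of the query, the shorter sequence —
the only reading under which removing the query is sensible). Rather
than a full aligner, the implementation uses:

- **Anchors**: canonical (k_a = 15, w = 10) minimizers, indexed over all
  scaffolds; minimizers occurring > 200 times are treated as repetitive
  and skipped.
- **Chaining**: shared anchors are grouped by target and relative
  strand, then clustered on the alignment diagonal (anti-diagonal for
  reverse-strand matches) with a 500 bp band — the gap-difference bound
  for colinearity. Bands with ≥ 4 anchors are chains; same-strand chains
  separated by < 1 kb on both sequences are merged. Query coverage is
  the union of chained query intervals over query length.
- **Identity**: per chained span, infix edit-distance alignment (edlib)
  of the query span against the matching target window (± 200 bp pad);
  identity = 1 − d/span, averaged over chains weighted by span. Pure
  anchor statistics were rejected for this role: the expected fraction
  of bases inside exact ≥ 15 bp matches falls to ~0.83 at true identity
  0.95 and ~0.35 at 0.90, so an anchor-based ratio is biased far below
  truth exactly in the regime the 0.75 threshold probes, while
  edit-distance identity stays within ±0.05 down to ≤ 0.85 identity
  (verified by the calibration tests).

Ties among qualifying hits are broken by identity × coverage, then
identity, then target id, making removal deterministic. Removal is
single-pass: targets are all strictly longer scaffolds regardless of
their own flagged/removed status, so no order-dependent cascades arise.

## Synthetic data generator

The generator reproduces the haplotig pathology with full truth labels.
Haplotype A is i.i.d. with a target GC fraction; haplotype B applies
Bernoulli(het) substitutions. The genome is cut into
exponential-length segments (mean 50 kb, truncated to [5 kb, 10× mean]);
every segment yields a haplotype-A primary contig, and a fraction of
variant-bearing segments also emit a random 30–90% sub-interval of the
haplotype-B copy as a planted haplotig. Reads are single-end, uniform
start positions, depth/2 per haplotype, uniform substitution errors.
All stages draw from independent streams derived from (seed, stage), so
outputs are pure functions of the spec.

Defaults are the study conditions exercised throughout the tests:
5 Mb genome, GC 0.32 (AT-rich, typical of insect genomes), 1%
heterozygosity, 30% haplotig fraction, 40× depth of 100 bp reads at
0.5% error. What the generator does **not** model: indels (in variants
or reads), paired ends, quality profiles, assembler chimeras/misjoins,
and realistic repeat landscapes (the genome is i.i.d., so the only
k-mer duplications are the planted ones). Passing tests therefore
demonstrate correctness of the detection logic under the intended
signature, not robustness to repeat-rich real genomes, where the
copy-2 predicate intentionally leaves exact repeats untouched.

## Validation accounting and a known limitation

`validate_dedup` compares (copy, multiplicity) matrices before/after:
duplicated homozygous mass (copy ≥ 2, multiplicity in band) must not
increase, and newly missing in-band mass (copy 0) must stay ≤ 0.5% of
band mass. One caveat is intrinsic to matrix-only accounting: a removed
haplotig's variant-spanning k-mers are heterozygous alternate-allele
content whose multiplicity distribution (mean ≈ C<sub>k</sub>/2) has a
tail reaching above the lower homozygous bound (the het/hom density
crossing, ≈ 1.1 het standard deviations above the het mean under the
default conditions). Those leaked k-mers are counted as "lost in-band
content" although no homozygous content was lost — truth-aware
decomposition on the synthetic datasets shows the newly missing in-band
k-mers are 100% alternate-allele content. Under the default study
conditions this leakage amounts to ~0.5–0.9% of band mass depending on
the realized haplotig load, i.e. it can exceed the 0.5% budget while
genuine homozygous loss is exactly zero. The strict matrix-only bound
is kept as the validation contract; the integration tests additionally
assert the truth-aware property (zero homozygous loss).

## Problem sizes and numerical choices

The test and acceptance workloads use 5 Mb genomes for the end-to-end
runs (about 100 contigs at the 50 kb contig scale, 2 M reads) and
500 kb genomes for the 20-run spectrum-recovery grid — the package's
choice of desk-scale sizes at which every statistical property under
test is comfortably resolved. Counting is exact (no sketching), so
results at larger scales differ only in runtime and memory (~16 bytes
per distinct k-mer). Degenerate inputs are handled explicitly:
spectra with no mass above the error cutoff raise a fit error advising
deeper coverage; scaffolds shorter than k are profiled with zero
windows and never flagged; empty assemblies or read sets are parameter
errors.
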