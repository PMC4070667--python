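# Methods

## The model

OTN semi-alignment replaces base-level alignment with a positional
trinucleotide code. For a pool of primer-stripped reads, the frequency of
each of the 64 trinucleotides is tallied per 0-based start offset. Because
homologous amplicons keep conserved motifs at nearly constant offsets, these
per-trinucleotide profiles are strongly peaked; each peak marks a region
where the same trinucleotide is expected to descend from a common ancestral
position. An OTN is the pair *(trinucleotide, bin around one of its peaks)*,
and each read is reduced to the binary vector of OTNs it carries.

Distances assume neutral decay of shared characters: a trinucleotide
character survives one generation of one lineage with probability
`1 − rate`, so the expected shared fraction after `gen` generations
separating two profiles is `(1 − rate)^gen`, giving the estimator

    gen = [ln(shared) − ln(total)] / ln(1 − rate).

Two readings of `shared`/`total` exist. Taken literally (`shared = |A∩B|`,
`total = |A| + |B|`), identical profiles receive the nonzero distance
`ln 2 / |ln(1 − rate)|`. The package's default counts each shared OTN once
per profile (`shared = 2·|A∩B|`), which preserves the decay model and makes
identity map to zero — a requirement for a distance that feeds neighbor
joining. The literal reading remains available (`GenParams(literal_shared=True)`).

Key assumptions, and where they bite:

- **Neutral, homogeneous rates.** `rate` (default `0.5×10⁻⁹` per
  trinucleotide per generation, the neutral 16S per-position estimate) is a
  single constant; lineage-specific rate variation rescales distances but
  not their ordering. A `per_position_x3` mode treats the figure as
  per-position and multiplies by the three positions of a trinucleotide:
  with one substitution disrupting up to three overlapping trinucleotides,
  the truth lies between the two conventions, and because `gen ∝ 1/rate`
  the choice is a pure rescaling of the time axis, not of topologies.
- **Positional stability.** Binning assumes indels do not shift motifs
  across bin boundaries. Within-read 454 homopolymer indels are handled by
  the discharge rule; accumulated evolutionary indels are not modelled
  (long-range shift correction via conserved anchors is out of scope).
- **Profiles over a common column set.** Distances are only meaningful for
  OTN matrices built from one pooled histogram; the pipeline enforces this.

## Pipeline stages and parameters

**Cleaning** (`io_prep`). Modified-Mott trimming keeps the contiguous
segment maximizing `Σ(limit − pᵢ)` over per-base error probabilities
(`limit` = 0.05); reads with more than 2 ambiguous bases or shorter than
300 nt are discarded; primers (V3–V4 pair by default) must match exactly,
in either orientation, anchored within 5 nt of the read ends (tolerating
454 key remnants); all libraries are subsampled without replacement to a
common depth (default: the smallest library) with a seeded generator. The
length cutoff applies to the read before primer removal by default; a
`post_primer` switch applies it to the bare insert instead, since either
reading of the protocol is defensible.

**Histogram and peaks** (`otn_core`). Counts are kept as a 64×Lmax matrix
plus a coverage vector (reads long enough, and N-free, at each offset);
relative frequencies divide by coverage rather than total read count so that
read-length attrition does not fake decay at long offsets. Peaks come from
an alternating-extrema prominence scan: a running maximum is emitted once
the series drops by at least `delta` below it (symmetrically for minima).
`delta` defaults to 0.1 × the row's maximum relative frequency — the
published analyses name the detector but not its threshold, so the value is
chosen to be scale-free per trinucleotide; an absolute mode exists. Peaks
below `min_peak_freq` = 0.01 are discarded as noise. Bin boundaries sit at
`ceil((p₁+p₂)/2)` between consecutive peaks (each offset joins its nearest
peak; an equidistant offset joins the following bin), with the outer bins
closed by 0 and Lmax; a valley-based boundary mode (boundary at the
between-peak minimum) is available.

**Tabulation and discharge.** Every occurrence of trinucleotide `t` at
offset `p` sets the cell for the bin of `t` containing `p`; occurrences of
trinucleotides without bins carry no positional information and are
ignored (counted in the run log). If *any* read carries `t` twice within
one bin, that OTN column is deleted globally — repeated trinucleotides in
one window are exactly what homopolymer over/under-calls produce, and a
character that cannot be placed uniquely carries no phylogenetic signal.
Identical OTN bit-vectors collapse to patterns (the method's OTUs); by
default patterns observed once are dropped before ecological statistics, as
probable sequencing errors or chimeras. The singleton count also yields the
heuristic per-position accuracy `1 − singletons/(patterns × read length)` —
a rough error-rate gauge, reported for orientation only.

**Trees** (`phylo`). Saitou–Nei neighbor joining, with the minimal-Q pair
chosen at the lowest index on ties (deterministic for a given input order)
and negative branch lengths clamped to zero and counted in the log. Pairs
sharing no OTN have undefined (infinite) distance; the default is an error
naming the pairs, with optional capping at 1.1 × the largest finite entry
for exploratory trees. Bootstrap support resamples OTN **columns** with
replacement — the natural unit of the character matrix, given that sequence
positions are not retained in the binary profile — recomputes the distance
matrix (via column multiplicities) and NJ per replicate, and reports the
percentage of replicates containing each internal bipartition of the
full-data tree; replicates with undefined pairs are dropped, and more than
20% dropped is an error.

**Ecology** (`ecology`). Shannon–Wiener H uses natural logarithms and
Simpson's index the inverse form `1/Σpᵢ²`: published values of H ≈ 5.5 and
D in the 70–150 range for thousands of OTUs are only consistent with nats
and effective-species counts, so these variants are fixed and recorded in
the output metadata. The Mann–Whitney U test enumerates all
`C(n_A+n_B, n_A)` labelings of midranked data — with triplicate libraries
this is 20 labelings, making the one-sided `p = 0.05` of completely
separated groups exact rather than asymptotic. Chord distance is the
Euclidean distance between unit-normalized abundance vectors (range
`[0, √2]`). PCA centers columns, decomposes by SVD, and retains the
smallest number of components whose variance fractions sum to at least 50%;
component signs follow the largest-|loading|-positive convention so scores
are reproducible.

## The simulator, and what it does not emulate

`synthetic_data` separates evolutionary signal from sequencing error. An
ancestral insert (default 460 nt, V3–V4-like) evolves along a tree with
edge lengths in generations — supplied, or random with edges uniform on
[10⁸, 10⁹], matching the divergence range over which the decay model is
informative (pairs beyond ≈5×10⁹ generations approach signal saturation);
each position substitutes with probability `1 − (1−r)^g` to a uniformly
chosen different base. Reads then receive primers, ±1-base indels per
homopolymer tract (≥3 identical bases) at a configurable per-read rate, and
error probabilities rising linearly from 0.001 to 0.01 along the read.
Substitution-only inheritance keeps positional ground truth exact, which is
what makes pattern- and bin-level assertions possible.

Deliberately not modelled: flowgram-level 454 noise, chimeras, inherited
indels, secondary-structure rate heterogeneity, and taxonomic abundance
skew (every taxon gets equal depth). Passing tests therefore demonstrate
correctness of the algorithms under the stated model — positional binning,
discharge, decay inversion, tree and support recovery — not robustness to
every artifact of real pyrosequencing data; in particular the published
soil dataset's headline counts (8,000 reads/sample, 740 peaks, 8,072
patterns) depend on that dataset and an unstated peak threshold and are not
reproduced here.

## Numerical choices

- `gen` is evaluated as `log1p((shared−total)/total) / log1p(−rate)`:
  both logarithms are near zero (near-identical profiles; rates ~10⁻⁹), and
  the naive `ln(shared) − ln(total)` form loses up to six digits to
  cancellation. The implementation agrees with 50-digit arithmetic to
  ~10⁻¹⁵ relative error over random (shared, total, rate) triples.
- Ties: Kadane trimming keeps the first maximal segment; NJ joins the
  lowest-index minimal-Q pair; midranks handle U-test ties; equidistant
  histogram offsets join the right-hand bin.
- Degenerate inputs fail loudly: empty read sets, all-zero abundance
  vectors, constant matrices in PCA, non-symmetric distance matrices,
  disjoint profiles under `undefined="error"`.
- Two-taxon trees (below the usual NJ minimum) are supported as a single
  split with the distance shared evenly, so minimal end-to-end runs remain
  expressible.

## Problem sizes

The test suite and the acceptance script run on desk-scale data by design:
six taxa × 20 reads of 460 nt for pipeline round trips, 10,000-column
profiles × 200 replicates for parameter recovery, 100 random 4–12-taxon
trees for NJ recovery, 1,000 random series for the peak-detection oracle,
and 100 bootstrap replicates. These sizes give the statistical assertions
comfortable margins (binomial 3-SE coverage, exact enumeration) while the
whole suite completes in seconds.

## Known limitations

Bins are derived from the pooled dataset, so adding samples can move
boundaries and change OTN identities; comparisons are only valid within one
pipeline run. Very deep divergences saturate (few shared OTNs, undefined
pairs); very shallow ones quantize (distances change only in steps of whole
shared columns). The discharge rule trades signal for robustness: at high
homopolymer error rates it removes many informative columns, which widens
distance variance before it biases it. Read lengths below ~300 nt leave too
few OTN columns for stable trees — the method is designed for long-amplicon
data.
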