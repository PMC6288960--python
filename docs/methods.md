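# Methods

## Problem and approach

Given shotgun read sets from samples of known continental origin (the
reference panel) and read sets of unknown origin (queries), the pipeline
assigns each query a continent by K-nearest-neighbors on a matrix of
alignment-free k-mer dissimilarities, and reports how significant and how
stable that assignment is. No alignment, assembly or marker selection is
involved; the only per-sample summary is the k-mer count vector and a
Markov model of the sample's own composition.

## Dissimilarity measures

Let `X_w` be the count of word `w ∈ {A,C,G,T}^k` in a sample's reads
(windows taken within reads only; windows containing N skipped; with the
default `strand="both"` policy each read's reverse complement is counted
too, making profiles strand-invariant), `N = Σ_w X_w`, and `f_w = X_w/N`.

The m-th order Markov background model is fitted from the same reads:
transitions `P(a|u) = C(ua)/Σ_b C(ub)` from (m+1)-mer counts, initial
probabilities `q(u)` from m-mer counts (for m = 0 there is a single empty
context with `q ≡ 1`). A word's null probability is the chain-rule product
`p_w = q(w_1..w_m) Π_i P(w_i | w_{i−m}..w_{i−1})`; an unobserved context or
transition makes `p_w = 0`. Centered counts are `X̃_w = X_w − N p_w`.

- Manhattan `Σ_w |f_{X,w} − f_{Y,w}|` (range [0, 2]) and Euclidean
  `√Σ_w (f_{X,w} − f_{Y,w})²` (range [0, √2]).
- d2 = `½(1 − cos(X, Y))` on raw counts.
- d2\* = `½(1 − D₂*/(√Σ X̃²/(N_X p_X) · √Σ Ỹ²/(N_Y p_Y)))` with
  `D₂* = Σ_w X̃_w Ỹ_w / √(N_X p_{X,w} N_Y p_{Y,w})`.
- d2s = same shape with per-word scale `r_w = √(X̃_w² + Ỹ_w²)`:
  `D₂s = Σ X̃ Ỹ / r`, normalizers `√Σ X̃²/r`, `√Σ Ỹ²/r`.
- CVTree: composition vectors `a_w = (X_w − E_w)/E_w`,
  `E_w = X(w_1..w_{k−1}) X(w_2..w_k) / X(w_2..w_{k−1})` (0 if the
  denominator vanishes); dissimilarity `½(1 − cos(a, b))`. Structurally
  this is an order-(k−2) null without a fitted transition model.

Zero-probability conventions (these pin the exact variant implemented):
d2\* sums run over words with `p_w > 0` in **both** samples, excluded from
the cross term and from both self-normalizers alike; d2s sums run over all
words with `X̃_w, Ỹ_w` not both zero and apply no positivity mask (a word
with `p_w = 0` simply contributes its raw count as its centered count). No
pseudocounts are added anywhere. With these conventions all four
normalized measures are exactly 0 for a sample against itself and reach 1
for perfectly anti-correlated centered profiles; values are clipped to
[0, 1] against ~1e-16 rounding. Accumulation is in double precision with
numpy's pairwise summation; the test suite requires agreement within 1e-9
with independent full-alphabet reference loops.

Defaults: k = 12, m = 10, or the `k = m + 2` pairing when only one is
given — the pairing at which the background-adjusted statistics are known
to perform well on short-read data. The Markov order is a configuration
parameter; no order-estimation procedure is included. Profiles are dense
numpy vectors over the 4^k alphabet, which is the right trade-off for
k ≤ 12 (≤ 16.8M doubles) and makes every measure a handful of vectorized
array operations.

## Classification and confidence

KNN operates directly on the matrix: the K nearest labeled references by
dissimilarity, majority vote. Determinism is guaranteed by explicit tie
rules: distance ties break by ascending sample id; vote ties go to the
tied label seen earliest in the neighbor ranking (the label owning the
nearest neighbor), with smallest summed distance as a final fallback.
Accuracy tables average over uniform, unstratified train/test splits
(default 100); a split whose training set lacks a continent is kept — that
label simply cannot be predicted there. `train_size = n − 1` reduces to
leave-one-out.

- **RC (reference-confidence)**: resample the reference panel with
  replacement B times (default 1000; a sample drawn twice legitimately
  occupies two neighbor slots), re-predict, and report the fraction of
  resamples agreeing with the full-panel prediction, per K.
- **NC (NGS-confidence)**: partition the query's reads into disjoint
  subsets (default 10), run the whole profile → dissimilarity → KNN chain
  on each, and report the fraction agreeing with the modal prediction
  (modal ties broken by the subset with the smallest nearest-neighbor
  distance).

## Significance and geography

The intra- vs inter-continental contrast uses the Mann–Whitney U counting
pairs where an inter-continental dissimilarity exceeds an intra-continental
one (ties count ½), computed by rank sums. For a single continent c, intra
pairs are within c and inter pairs oppose c to the rest; the pooled "ALL"
statistic is the sum of the three per-continent U values. The null
distribution permutes continent labels jointly across samples, leaving the
matrix untouched, which preserves the dependence among pairwise entries.
The p-value is the add-one estimator `(1 + #{U_perm ≥ U_obs})/(B + 1)` —
it can never be 0, its floor is 1/(B+1), and counting ties with ≥ is
conservative. Desk default B = 10⁴; larger values are configuration.

PCoA is classical metric MDS: Gower double-centering
`B = −½ J (D∘D) J`, eigendecomposition, coordinates `v√λ` for positive
eigenvalues sorted descending. Negative eigenvalues (the k-mer measures
are not Euclidean) are dropped without Cailliez/Lingoes correction and
their count and mass reported; variance fractions are over positive
eigenvalues only.

Great-circle distances use the haversine formula on the IUGG mean radius
6371.0088 km. The geography analysis reports Pearson and Spearman
coefficients over all n(n−1)/2 (dissimilarity, distance) pairs; constant
input yields NaN with a warning rather than an error.

## Synthetic cohorts

The simulator emulates the study design, not oak biology: an i.i.d. root
genome (GC content configurable), continent ancestors derived by
independent per-site substitution at rate δc, individuals from their
ancestor at rate δi, and shotgun reads with uniform start positions,
uniform strand and independent per-base substitution errors at rate ε.
`inject_errors` adds further substitution noise (default 5%) on top of
whatever the reads carry, composing multiplicatively by sequential
application. Sample coordinates scatter (Gaussian, in km) around fixed
continent centers (40N 95W / 48N 10E / 45N 125E) so geographic analyses
have signal.

Two phylogenies: `star` (default) makes continents exchangeable;
`chain` links them serially with branch lengths scaled by the
great-circle separation of consecutive centers, producing
isolation-by-distance structure for the geography correlation.

The desk-scale preset — L = 200 kb, 3 continents × 12 individuals,
δc = 0.02, δi = 0.002, 100 bp reads, 200 kb/sample, ε = 0.001, analyzed at
k = 8, m = 2 — is a deliberately scaled stand-in for a ~0.8 Gb genome,
92 samples, 50–300 Mbp/sample and k = 12, m = 10. These sizes keep the
whole test battery and the acceptance script in the minutes range on one
CPU while preserving the regime that matters (≈1× coverage, between-group
divergence an order of magnitude above within-group divergence, both well
above the error rate).

What the simulator does **not** emulate: recombination or coalescent
genealogies (it is a star/chain tree with independent substitutions, so
within-continent diversity has no shared polymorphism structure), indels,
repeat content and GC heterogeneity of real plant genomes, paired-end
structure, quality scores, or platform-specific error profiles. Passing
tests therefore demonstrate the correctness and calibration of the
machinery — measures, classifier, tests, confidence scores — under the
assumed divergence hierarchy, not field performance on real herbarium or
wood samples.

## Reads, down-sampling, metadata

FASTA/FASTQ (plain or gzipped) are read via Biopython in file order;
quality strings are discarded (no quality filtering), reads containing N
are kept (N handling happens at counting), and paired-end mates are
treated as independent reads. Down-sampling draws whole reads uniformly
without replacement until the running total first reaches the target, so
the output total lies in [target, target + max read length); reads are
never trimmed, preserving read-internal k-mer structure. Partitioning
permutes once and fills parts greedily; an incomplete trailing part is
dropped with a warning. Requesting more bases than a sample has raises an
insufficient-data error.

Continent labels derive from metadata with country checked first (United
States/Canada → NA at any longitude), then longitude against the 60°E
Europe/Asia split. The metadata table is TSV with columns `sample_id,
country, latitude, longitude, continent`; a blank continent is derived, the
literal `UNKNOWN` marks queries. Note `NA` is a continent label, so the
reader disables pandas' default NA-string handling.

## Pipeline reproducibility

Every stochastic stage consumes a sub-seed derived from the master seed as
`(seed · 0x9E3779B1 + crc32(stage_name)) mod 2³¹`, so stages can be rerun
in isolation. A run directory contains the matrix (PHYLIP square + TSV),
nearest-neighbor links, accuracy table, permutation results, PCoA
coordinates and eigenvalues, geography correlation, per-sample RC scores,
and a `manifest.json` recording the configuration, version and all stage
seeds; an `INCOMPLETE` marker is removed only when every stage finished.

## Known limitations

- Dense 4^k storage is deliberate but memory-hungry beyond k = 12; k = 14+
  would need the sparse or disk-backed counting this package does not do.
- The RC score's "literal resampling" reading means panels smaller than a
  few samples per continent can lose a whole continent in a bootstrap
  draw; RC < 1 then reflects panel size, not query ambiguity.
- The permutation test permutes all labels jointly; per-continent tests
  are not conditioned on the continent's size remaining fixed beyond what
  joint permutation implies.
- d2s normalization conventions differ across the literature by constant
  factors; the variant here is fixed by the self-zero and [0, 1]
  properties and the reference-loop tests, and stated above.
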