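# Methods

This note records the models, the numerical choices, and the reasoning
behind the places where the design was genuinely open. Parameter names in
code are given in backticks.

## Input processing

Intrachromosomal contact maps are read from dense whitespace text or sparse
`bin_i bin_j count` triplets (0-based indices, either triangle, mirrored on
read). Matched rows/columns whose fraction of zero entries strictly exceeds
`zero_fraction` (default 0.99) are removed before anything else; the
original coordinates stay recoverable through the retained-bin mask. Only
autosomes are processed unless asked otherwise (chromosomes named
X/Y/M(T) are skipped by default).

Balancing uses Knight–Ruiz (inner–outer Newton iteration, target row sums
1, `tol = 1e-6` on the row-sum coefficient of variation, `max_iter = 3000`);
on non-convergence the pipeline falls back to vanilla coverage
`A_ij / (r_i r_j)` automatically and records which normalization was
applied. Binomial read thinning (`downsample`) is defined on raw integer
counts only, per upper-triangle cell, so that symmetry and the thinning
model stay exact.

Contact density is the fraction of non-zero entries of the upper triangle
including the diagonal: the matrix is symmetric, so each bin pair is counted
once; the convention is stated because nothing forces it.

## Step 1 — compartment domain calling

For bin sizes below 40 kb, every 10 columns are summed (`aggregate_columns`)
to reduce sparsity; at 40 kb and coarser the matrix is used as is. Pearson
correlations of the rows, then correlations of the columns of that
correlation matrix, give `rho2A`; `sA = arctanh(rho2A)` after clipping
|r| at `1 - 1e-6`. Zero-variance bins produce undefined correlations; these
are set to 0 before the transform. Fisher's z is used because it amplifies
strong correlations far more than weak ones, sharpening the plaid contrast.

Boundaries are called in two stages on `sA`:

* **Stage 1 (TopDom-style).** The bin-signal of a gap is the mean of `sA`
  over the `window_bins x window_bins` diamond spanning the gap (default
  window 5). Candidates are local minima of the signal; each must pass a
  one-sided Wilcoxon rank-sum test of the diamond values against the
  off-diagonal values of the two flanking within-blocks (p < `p_cut`,
  default 0.05). Candidates are admitted weakest-signal-first, skipping any
  that would create a domain shorter than `min_domain_bins` (default 2).
* **Stage 2 (domain-level support).** Cell-level rank-sum statistics are
  unreliable here: `sA` cells are strongly dependent (rows move together)
  and the flanks sit at shorter genomic distances where similarity is
  systematically higher, so window-level tests endorse essentially every
  local minimum, including dips produced by correlated noise. Each
  candidate therefore must also pass a paired test on the
  distance-centered similarity (per-diagonal mean subtracted): every bin of
  the two `4 x window_bins` flanks contributes one difference — its mean
  similarity to its own side minus its mean similarity across the gap — and
  a one-sided Wilcoxon signed-rank test asks whether these per-bin
  differences are positive (p < `p_cut`). Pairing per bin cancels the
  distance composition and collapses the dependence to the unit that
  actually carries boundary information. Candidates closer than
  `2 x window_bins` to a chromosome end are not called (the centering is
  dominated by too few cells there).

On planted plaid maps (500 bins, 10 domains, design seeds distinct from the
test seeds) the two stages give boundary precision 0.9–1.0 at recall
0.9–1.0. A degenerate (constant) similarity matrix yields a single domain
with a warning.

## Step 2 — sub-compartment hierarchy

The k domains are summarized by a mean contact matrix `M` computed on the
observed/expected map (`domain_mean_contacts`, `distance_normalized=True`):
the trend comparisons below ask whether contacts are *enriched*, and raw
means are dominated by genomic distance rather than compartment preference
(on planted maps, raw means cost ~20 points of A/B agreement). For each lag
m and sliding pair (j, j+m), the binary trend matrix records per domain i
whether `M(i, j+m) > M(i, j)` (ties are 0); blocks for m = 1..`m_max` are
stacked. `m_max` defaults to all available lags when k <= 32 and to 4
otherwise: the marginal value of additional lags is negligible for the
hundreds of domains of a real chromosome but material when k is small.

Pearson correlations of the trend columns, Fisher-z transformed with the
same clipping, give `sT`. Before the PCA the scores are winsorized at
`|z| = arctanh(0.95)`: identical binary fingerprints (frequent at small k)
reach the numerical clip `arctanh(1 - 1e-6) ≈ 7.25` and would otherwise
dominate the component directions. The first `n_pcs = 10` principal
components are kept, PC1 weighted 1 and the rest 0.25; PC1 is the
compartment axis, and its arbitrary sign is fixed by requiring positive
correlation with gene density (a per-domain density vector from a user
BED/GTF; no bundled annotation, and a missing annotation is an error rather
than a silent default).

Divisive clustering recursively 2-means-splits the weighted coordinates
until every domain is alone; each split runs 10 seeded Lloyd restarts
(seeds derived from the master seed and the node id) and keeps the best
within-cluster sum of squares, so the tree is fully deterministic.

Ordering: a LOESS fit of PC2 on PC1 (statsmodels lowess, span 0.75,
locally linear — the fit only orders points along the major axis, where
local-linear vs local-quadratic is immaterial) is evaluated densely by
linear interpolation; each domain projects to the nearest curve vertex, and
z is the cumulative arc length along the curve (z = 0 for the first
domain). Weighted PC1/PC2 coordinates are used for the curve — weighting
shrinks the noise of the second coordinate fourfold and measurably
stabilizes the ordering. Every sibling pair is flipped so the right branch
has the greater mean z; flips change no clade, so the clustering topology
is untouched. With fewer than 3 domains the order is PC1 order.

Labels come from the top three split levels: B (left) / A (right), then
X.2 (left) / X.1 (right) twice, giving `B.2.2 … A.1.1`; a leaf reached
above depth 3 repeats its extreme side (a bare rightmost leaf becomes
A.1.1). Ranks are `o/k` along the leaf order from the B end — chosen over
`(o-1)/(k-1)` as the literal normalization by the number of domains; the
two are monotone-equivalent for every downstream analysis.

### Small-k identifiability

With only ~10 domains spread over 8 planted activity classes, the depth-3
partition of the inferred tree must cut exactly at the class-grid
midpoints to reproduce the planted labels. The binary-fingerprint →
correlation → 2-means chain does not guarantee that: duplicated-class
domains form zero-distance clusters that 2-means isolates preferentially,
and the embedding warps the activity axis. On noise-free expected-contact
matrices the chain recovers planted 8-class labels at ARI ~0.67–0.91
depending on the random class layout — the limit is identifiability at
small k, not sampling noise. Boundary recovery, the A/B split, and the
rank ordering (Spearman vs planted activity ≥ 0.95) are unaffected. For
real chromosomes with hundreds of domains per class the regime is far more
favourable.

## Step 3 — nested subdomains

Contacts between two sibling subdomains are modelled as a mixture of a
point mass at zero (weight `alpha`) and a log-normal for positive values.
The MLE is closed form: `alpha` is the zero fraction, `mu`/`sigma` the mean
and population SD of the log of the positive values, with
`sigma_min = 1e-3` flooring the SD so the density stays proper for
constant samples. The dendrogram likelihood is the sum over sibling pairs
of the between-children log-likelihood at the MLE; dynamic programming over
intervals finds the maximizing genome-anchored tree in O(n^3) (2D prefix
sums of zero counts, log sums and squared-log sums make each node term
O(1); a 200-bin domain fits in ~2 s). Every interval of at least
`2 x min_bins` bins is split (`min_bins = 2`; domains under 4 bins skip the
step); likelihood ties break toward the more balanced split, then leftmost.
The DP is verified against exhaustive enumeration over all Catalan(n-1)
genome-anchored trees for n <= 8. The DP runs on the balanced matrix, for
normalization-independence; nothing in the model requires raw counts.

Trimming walks the tree top-down on the observed/expected matrix. For a
split of parent [i, j] at s, the between-children rectangle is divided by
its anti-diagonal (the line joining the children's off-diagonal corners):
the half containing the parent's corner (i, j) is region A, the rest is B;
C and D are the children's within-triangles excluding the diagonal. A split
is accepted iff A > B and C > B and D > B, each by a one-tailed Wilcoxon
rank-sum test with p < 0.05 **and** mean difference > 0.1 (the
expected O/E mean is 1, so 0.1 is a 10% relative difference). Regions with
fewer than 3 finite values reject the split. Raising the mean-difference
floor never accepts a previously rejected split (monotone). The exact
region geometry is one of several readings of "the triangle delimited by
the corners"; the chosen index sets are documented in code and pinned by a
hand-drawn test case.

## Cross-sample analytics

* **Entropy**: `S_b = -(1/ln 8) Σ P_j ln P_j` over the 8-class label
  frequencies of bin b across samples, `0·ln 0 := 0`, missing labels
  excluded; S is 0 iff one label is observed and 1 iff all 8 are equally
  frequent. The null permutes each sample's label vector across bins
  independently, 1000 times by default, pooling per-bin entropies (or
  returning per-permutation means for empirical p-values).
* **Boundary levels**: first differing digit of the two flanking labels
  (A/B switch = level 1), `gt3` for identical labels, `nested` overriding
  for subdomain boundaries; symmetric in its arguments.
* **Boundary overlap**: fraction of one set with a partner strictly closer
  than the distance cutoff, greedy nearest matching without reuse; an empty
  query set is reported as missing, not zero.
* **A-B index**: per bin, mean distance-corrected (O/E) contact with A bins
  minus with B bins; boundaries at sign switches after interior
  single-bin sign runs are discarded as noise (runs merge iteratively).
* **Marker enrichment**: log2 of the median per-domain mean within a label
  over the overall median of domain means.
* **Region/state enrichment**: regions inherit the overlapping domain's
  label; multi-domain regions take the least active label (closest to
  B.2.2) and the mean rank; observed counts are divided by expected counts
  from bin-weighted genome-wide label frequencies.
* **Compartment count**: track values are ln(x+1)-transformed and averaged
  per domain; for each sibling pair, the effect size Δμ is the largest
  shift that keeps the higher side significantly above the lower
  (one-tailed Welch t-test, α = 0.001), found by bisection to 1e-6 —
  Welch because nothing guarantees equal variances; the bisection root
  equals the closed-form `μX − μY − t_{1−α} SE` since shifting does not
  change the variance. A level passes when every sibling pair's median Δμ
  across chromosomes exceeds the progressive threshold γ (0.05 for 2 and 4
  compartments, 0.1 for 8, 0.2 beyond); the count right before the first
  failing level is returned.
* **Sample clustering**: pairwise label-Hamming distance over commonly
  covered bins (pairwise-complete; a pair with no common bins is an error),
  average-linkage; the distance metric is an assumption, stated as such.
* **Interdomain contact shift**: per label group of stable domains, the
  distribution of mean O/E contact with a target domain in each condition,
  summarized by medians.
* **Panel assembly** resamples per-sample BED annotations onto a common
  40 kb grid: bp-majority label per grid bin, ties to the least active
  label, overlap-weighted mean rank.

## Synthetic data

`simulate_contact_map` draws Poisson counts with intensity
`λ_ij ∝ (1+|i−j|)^(−decay_exponent) · exp(κ (1 − |a_i − a_j|))`, scaled so
the expected upper-triangle total equals `sequencing_depth`; `a` is the
per-bin activity from the planted domains. Defaults: 500 bins of 40 kb, 10
domains with a minimum length, all 8 classes represented when possible and
adjacent domains always of distinct classes (so every planted boundary is a
real compartment switch), activities at class midpoints of an equal grid on
[0, 1], `κ = 1.5`, decay exponent 1.0, depth 2×10⁶ reads (≈16 reads per
cell, comparable to a deeply sequenced 40 kb map), zero inflation 0.05
(mappability dropouts), Poisson noise (a gamma-mixing `overdispersion`
parameter is available but off by default, keeping the counting model
analytically transparent).

`nested_fraction` defaults to 0: planted nested splits (×1.5 within-child
intensity) create genuine discontinuities in whole-chromosome similarity
that are indistinguishable from weak compartment boundaries, so maps used
to score compartment-boundary recovery are generated without them and the
subdomain fixtures plant them explicitly.

What the generator does **not** emulate: loops and loop anchors,
TAD-scale insulation unrelated to compartments, copy-number and
translocation artifacts, mappability structure beyond uniform zero
inflation, and interchromosomal contacts. Passing tests on these maps
demonstrate correct recovery of plaid compartment structure under Poisson
sampling — not performance on the full complexity of real Hi-C.

`simulate_track` (signal = effect · activity + Gaussian noise, truncated at
0; a log-scale variant makes the ln(1+x) class means exactly
effect/8 apart), `simulate_genes` (Poisson gene counts increasing with
activity, for PC1 orientation), `simulate_panel` (per-sample label
repositioning to adjacent classes at class-specific rates) and
`planted_hierarchy` (the ground-truth dendrogram implied by planted labels;
a synthetic reference object, not an inference result) complete the
fixtures.

## Determinism and degenerate inputs

Every stochastic step consumes a seed derived from the master seed (per
chromosome via a CRC of its name; per clustering node via the node id), so
identical configurations produce byte-identical outputs. Degenerate cases
are defined, not accidental: constant similarity → one domain with a
warning; k = 1 → single-leaf hierarchy with rank 1; all-zero mixture
samples → `alpha = 1` with the zero component only; tied trend comparisons
→ 0; PC1 uncorrelated with gene density → unchanged sign with a warning.

## Problem sizes used in tests

The shipped tests and the acceptance script run on synthetic chromosomes of
120–500 bins with 3–40 domains and (0.5–2)×10⁶ reads, 20-sample panels of
400 bins, and 1000-permutation nulls — sizes at which every statistical
contrast the tests assert is comfortably powered while the whole suite
stays fast.
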