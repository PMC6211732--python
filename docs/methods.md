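# Methods

## Model

A nonnegative matrix (rows = samples, columns = variables) divided by its
grand total is a discrete bivariate probability distribution P = [p_ij].
The grade transformation maps each margin onto [0, 1] proportionally to
marginal mass, giving cumulative breakpoints S_0 = 0, S_i = p_1·+…+p_i·,
and T_j likewise. The induced copula density is piecewise constant,
h_ij = p_ij/(p_i· p_·j) on the rectangle [S_{i−1},S_i) × [T_{j−1},T_j);
it equals 1 everywhere under independence and integrates to 1 over the
unit square. All statistics are functionals of this representation:

* ρ*(P) = 3 Σ_ij (S_{i−1}+S_i−1)(T_{j−1}+T_j−1) p_ij — grade Spearman.
* τ(P) = 2 Σ_{i<r,j<s} (p_ij p_rs − p_rj p_is) — grade Kendall.
* ar(r:i) = Σ_{j<s}(p_ij p_rs − p_rj p_is)/(p_r· p_i·) — the
  differentiation (variance) coefficient between normalised rows; the
  decompositions τ = 2 Σ_{i<r} p_i· p_r· ar(r:i) and
  ρ* = 3 Σ_{i<r} (S_r + S_{r−1} − S_i − S_{i−1}) p_i· p_r· ar(r:i) hold as
  identities and are verified to 1e−10 in the tests.
* τ_abs — τ with absolute values; the attainable ceiling for |τ| under any
  row/column permutation. reg = τ_max/τ_abs ∈ [0, 1].

Assumptions: all values finite and ≥ 0; every row and column has positive
mass (zero-marginal rows/columns are rejected by name rather than silently
dropped, because the formulas divide by marginals and silent dropping
shifts every downstream index). Both coefficients are invariant to positive
rescaling of the raw matrix.

The one-dimensional grade transform F*(u, x) is exposed for empirical
distributions with atoms (left/right CDF limits from a sorted sample). Its
defining property — E_X[F*(u, X)] = u for every u — is what the tests
assert; no continuous-copula machinery is built beyond this discrete case.

## GCA search

One sweep: place each row at its conditional grade mean
Σ_j (p_ij/p_i·)(T_{j−1}+T_j)/2, stable-sort rows by these positions, then
do the same for columns. A half-sweep is accepted only if it does not
lower the objective, so the objective is nondecreasing within a restart;
sweeps stop when the improvement falls below `tol` (default 1e−12) or
after `max_iter` (default 100) sweeps. The sweep finds local maxima, so it
is restarted from seeded random permutations (`restarts`, default 20);
restart 0 is always the identity so a well-ordered input is never
degraded. Ties in the stable sort preserve the current order —
reproducibility over arbitrariness. The returned arrangement is
canonically oriented (ρ*/τ are invariant under reversing both axes; of
the two orientations the one whose first row has the smaller original
index is returned). Objective default is ρ*; τ is available everywhere.

`brute_force_max` enumerates all n!·k! arrangements (guarded at 1e7) and
is the oracle in the tests: with 50 restarts the search attains the
enumerated maximum on random matrices up to 5×5, and recovers planted
noiseless monotone orderings exactly (up to full reversal) at 10×10 and
30×30.

## GCCA segmentation

Clusters are contiguous runs of the ordered axes. The criterion is τ (or
ρ*) of the Kr × Kc table of block sums — by the decomposition above this
is the mass-weighted sum of pairwise between-cluster variance
coefficients. Key computational fact: with the other axis fixed, the
criterion is *additive over segments* — a segment (l, r] contributes
φ(l, r) = 2 Σ_c [C_c(r) cC_c(l) − C_c(l) cC_c(r)] for τ (C = cumulative
column profile, cC its prefix over the fixed-axis blocks), and
3 (S(r)+S(l)−1)(m(r)−m(l)) for ρ*. Each axis is therefore solved *exactly*
by 1-D dynamic programming over cut positions; row and column DPs
alternate (≤ 20 rounds) until the criterion stops improving, which it must
since each DP step is a coordinate-wise exact maximisation. Ties in the DP
break toward the earliest cut.

For very long axes the DP's quadratic table is bounded by subsampling
candidate cut positions to an even grid (`max_candidates`, default 4096);
axes shorter than the budget are solved exactly, which covers every
optimality test. Probability tables aggregate by sum (mass-preserving);
display/downstream profiles aggregate by median of the raw values
(midpoint convention for even counts). Cluster counts are user choices —
scree curves of criterion vs K are provided (nondecreasing in K on
ordered input; the elbow is the user's read-off), with 6 × 6 as the CLI
default, matching the scale of patient/gene groupings this workflow
targets.

## Case statistics

* Differential selection: per gene, a = group-A summary, b = group-B
  summary (median of the member clusters' aggregated medians; mean
  optional), ratio = max(a/b, b/a). Genes with ratio ≥ threshold (default
  1.3) are kept — the boundary survives, since only strictly smaller
  differences are omitted — labelled UP/DOWN by the sign of a − b. The
  "difference factor" is read as a plain ratio of summaries, not a
  log-scale fold; genes with nonpositive summaries are excluded with a
  logged reason rather than silently dropped.
* Compatibility: the percentage of items with the same cluster index in
  two assignments, overall and per cluster, complement reported as
  non-compatibility. Raw indices are compared by default (both runs'
  contiguous labels share the leftmost/topmost = 1 convention); a
  Hungarian best-match relabelling is available behind an explicit flag.
  CUR or any other subset-selection method is external — the comparison
  accepts any assignment mapping.

## Synthetic data

`generate_monotone(n, k, strength, noise, seed)` plants latent scores
a_i = i/(n+1), b_j = j/(k+1), cell means exp(strength·a_i·b_j),
multiplicative log-normal noise exp(noise·ε), then shuffles rows and
columns with seeded permutations recorded as ground truth. Log-normal
noise keeps values positive and right-skewed like expression intensities;
it does not model probe-level platform effects, background correction or
normalisation, so passing recovery tests demonstrate the algorithms, not
robustness to raw-array artefacts. τ under the true ordering grows with
strength in the moderate range (the grid 0–4 is asserted); at extreme
strength the exponential concentrates the mass in one corner and τ falls
again, which is a property of the generator, not of the search.
`generate_blocks` produces piecewise-constant matrices with labelled
blocks for segmentation tests. All randomness flows through NumPy's
default PCG64 generator; a seed reproduces a matrix bit-for-bit.

Default desk-scale fixture: 32 × 200, strength 6, noise 0.3 — a
patients-by-probes table at a size where every property is checkable in
seconds. The pipeline smoke test runs 256 × 50,000 (the full
patients-by-probes scale) with 2 restarts and 10 sweeps, which completes
in about two minutes and under 2 GB on one CPU.

## Numerical choices

* "Sums to 1" and equivalence tolerances: 1e−9 absolute (double-precision
  accumulation over ≤ 1e7 cells); identity checks between alternative
  formulas use 1e−10.
* τ and ρ* are O(nk) via prefix sums; the quartic definitions live only in
  the test oracles. τ_abs sorts each row pair by the ratio key
  u_j/(u_j+v_j), making all 2×2 determinants one sign so the absolute sum
  telescopes — O(min(n,k)² · max(n,k) log) overall; it is a diagnostic,
  not a pipeline stage.
* regularity_index treats τ_abs ≤ 1e−12 as zero (exact independence
  produces rounding dust, not signal) and raises rather than divide.
* Overrepresentation maps draw every rectangle exactly (true grade widths)
  up to 4·10⁵ cells; larger maps are rasterised by sampling the step
  function on a pixel grid, since drawing 10⁷ polygons is not viable.
  Rendering never mutates the fitted objects.

## Limitations

* The multistart sweep has no optimality guarantee beyond the sizes where
  enumeration verifies it; heavily tied or near-independent matrices have
  flat objectives with many equivalent arrangements.
* Joint row × column segmentation alternates two exact 1-D solves; the
  alternation converges but may stop at a coordinate-wise optimum of the
  joint problem.
* Layer/outlier decomposition of irregular matrices is out of scope, as
  are preprocessing (background correction, normalisation), functional
  enrichment and CUR decomposition itself.
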