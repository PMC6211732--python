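# gradeca

Grade Correspondence Analysis (GCA) and Grade Correspondence-Cluster
Analysis (GCCA) for nonnegative data matrices — seriation by grade
correlation, overrepresentation maps, contiguous biclustering, and the
downstream differential-selection and cluster-comparison statistics used in
transcriptomic profiling.

## The problem

A bulk expression study produces a matrix of *n* samples (patients) by *k*
nonnegative variables (probes/genes). Treating the matrix, divided by its
grand total, as a discrete bivariate probability distribution
P = [p_ij] turns every question about structure into a question about
dependence: the *grade transformation* places rows and columns on the unit
interval proportionally to their marginal mass (S_i = p_1· + … + p_i·, and
likewise T_j), and the ratio

    h(u, v) = p_ij / (p_i· p_·j)   on   R_ij = [S_{i−1}, S_i) × [T_{j−1}, T_j)

is a piecewise-constant copula density: 1 everywhere iff rows and columns
are independent, > 1 where the joint mass is overrepresented. Drawn on the
unit square with marginal-proportional rectangles, this is the
**overrepresentation map**.

**GCA** permutes rows and columns to maximise a grade correlation of P —
Spearman's

    ρ* = 3 Σ_ij (S_{i−1} + S_i − 1)(T_{j−1} + T_j − 1) p_ij

by default, or Kendall's

    τ = 2 Σ_{i<r} Σ_{j<s} (p_ij p_rs − p_rj p_is),

so that similar samples and similarly-behaving genes end up adjacent and
the dominant monotone trend runs down the diagonal of the map. The search
alternates stable sorts of each axis by its conditional grade mean
(reciprocal-averaging style sweeps) inside a seeded Monte-Carlo multistart.

**GCCA** then cuts the ordered axes into a chosen number of *contiguous*
clusters maximising τ of the aggregated block table — τ decomposes into
pairwise between-group variance coefficients
ar(r:i) = Σ_{j<s}(p_ij p_rs − p_rj p_is)/(p_r· p_i·) weighted by group
masses, so this is exactly between-cluster differentiation. Both axes are
solved by exact dynamic programming and alternated. Cluster-level gene
profiles are medians of the raw values; a fold-difference filter (factor
1.3 by default) extracts the genes separating extreme patient clusters,
and a compatibility percentage compares cluster memberships across runs
(e.g. against a CUR-selected or random probe subset).

Diagnostics include the total variance τ_abs (τ with absolute values, the
ceiling for any arrangement) and the regularity index reg = τ_max / τ_abs.

## Worked example

```python
from gradeca import GCA, GroupContrast, differential_selection, generate_monotone

truth = generate_monotone(n=32, k=200, strength=6.0, noise=0.3, seed=1)
res = GCA(truth.matrix).fit(restarts=10, seed=0)
print(res.summary())
```

```
Grade Correspondence Analysis Results
=============================================
No. rows (samples):                        32
No. columns (variables):                  200
Objective:                                rho
Achieved value:                      0.225967
rho* (ordered):                      0.225967
tau (ordered):                       0.152397
tau_abs:                             0.268200
regularity index:                    0.568220
Restarts:                                  10
Total sweeps:                              63
Converged:                               True
=============================================
```

The generator planted a monotone trend and shuffled it; the fit recovers an
arrangement with ρ* ≈ 0.226 — the trend's strength after noise — and the
regularity index says the best monotone arrangement captures ~57 % of the
matrix's total variance. Continue with clustering and gene selection:

```python
clusters = res.segment(Kr=6, Kc=6)
print(clusters.summary())
profile = clusters.median_profile()                      # 6 x 200 medians
sel = differential_selection(profile, GroupContrast((1, 2), (5, 6), threshold=1.3))
print(len(sel.records), "genes differ by a factor >= 1.3")
```

```
Grade Correspondence-Cluster Analysis Results
=================================================
Matrix:                     32 x 200
Row clusters:               6  sizes [2, 2, 3, 5, 6, 14]
Column clusters:            6  sizes [5, 13, 22, 26, 40, 94]
Criterion (tau of blocks):  0.143766
=================================================
189 genes differ by a factor >= 1.3
```

Cluster widths vary because cuts maximise between-cluster differentiation,
not evenness. `clusters.plot_map("map.png")` renders the grayscale
overrepresentation map with bold cluster separators (darker = larger
ratio). With `strength=6` nearly every gene separates the extreme patient
clusters; at `strength=0` the selection is empty.

The same workflow from the shell:

```sh
gca synth monotone --n 32 --k 200 --strength 6 --noise 0.3 --seed 1 --out synth.tsv
gca run --input synth.tsv --outdir results/ --restarts 10 --seed 0
```

writes `ordering.json`, `clusters.json`, `profiles.tsv`, `genes.tsv`,
`map.png` and a provenance record `run.json`.

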