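# Methods

## The model

`miract` infers miRNA activity from its downstream footprint: when a miRNA
acts through mRNA degradation, the genes carrying its predicted 3'UTR target
sites are collectively down-regulated wherever the miRNA is active. The
method therefore never looks at miRNA expression itself; it couples two
measurements of the same genes — a nonnegative genes × samples expression
matrix and a genes × miRNAs table of predicted target-site counts — and asks
which contrasts in the first table co-vary with site-count profiles in the
second. miRNAs acting through translational repression leave no such
footprint and are invisible to this analysis by construction.

## Ordination conventions

Every analysis is a weighted SVD of a duality-diagram triple `(Z, D_r, D_c)`.

**Non-symmetric correspondence analysis.** For a nonnegative table `X`
(genes × samples or genes × miRNAs) with `P = X / ΣX`, row masses
`ρ_i = Σ_j P_ij` and column masses `γ_j = Σ_i P_ij`:

    Z_ij = c · (P_ij / ρ_i − γ_j),   D_r = diag(ρ),   D_c = (1/c) I.

NSCA asymmetrically decomposes how well the rows predict the columns; the
total inertia `Σ_i ρ_i Σ_j γ_wj Z_ij²` equals `c` times the numerator of the
Goodman–Kruskal τ. The `×c` profile scaling with uniform `1/c` column weights
follows the ade4 `dudi.nsc` lineage, so eigenvalue magnitudes are comparable
with the R implementations most users of this method know. Zero row or
column sums are rejected by name: a gene with no expression, or a miRNA with
no predicted targets among the measured genes, has no profile.

**Decomposition.** The triple is decomposed through the thin SVD of
`A = D_r^{1/2} Z D_c^{1/2}` (numpy's LAPACK driver evaluates this through the
smaller dimension, so tall-thin gene-by-sample matrices cost nothing extra).
Eigenvalues are squared singular values; column axes are `D_c`-orthonormal;
row coordinates `Z D_c a_k` have `D_r`-weighted variance `λ_k`. Axes with
`λ_k < tol · λ_1` are discarded (default `tol = 1e-9`, configurable); an
all-zero table yields a valid rank-0 result rather than an error. Axis signs
are fixed by making the largest-magnitude loading positive — a display/test
stabilisation only, since the supervised ranking re-orients axis 1 by the
target group.

**Coupling (co-inertia).** Two triples sharing rows and row weights are
coupled through the SVD of `D_cX^{1/2} Z_X^T D_r Z_Y D_cY^{1/2}`. The
singular values `s_k` are the covariances achieved by the successive axis
pairs (so self-coupling reproduces the single-table spectrum, `s_k = λ_k`),
and

    RV = Σ_k s_k² / sqrt(Σ_k λ_Xk² · Σ_k λ_Yk²)  ∈ [0, 1].

Because CIA is undefined without a shared row metric and the two raw tables
have different row masses, the expression-derived gene masses are imposed on
the target-table transform: row profiles are computed from the target table's
own masses, but the reference column profile is recomputed as the
imposed-weight average, keeping every column centred under the shared metric.
A `row_weight_mode="uniform"` option recomputes both transforms under `1/g`
weights instead.

**Supervision (between-group analysis).** The sample-side triple is condensed
to group centroids — each group column is the column-weight-weighted mean of
its samples' columns, with group weight equal to the summed sample weights —
then centred by the grand centroid so `k` groups leave at most `k − 1` axes.
Condensation is applied to the expression triple *before* coupling
(condense-then-couple); with two groups this yields exactly one non-null axis
and hence a single ranked vector of miRNA coordinates. Identical group
centroids produce a degenerate result (`s_1 = 0`) with a logged warning
rather than an exception; ranking such a result raises.

**Orientation and ranking.** Axis 1 is flipped if needed so the target
group's coordinate is strictly positive. Genes up-regulated in the *other*
group may carry sites for miRNAs active in the target group, so active
miRNAs accumulate at the negative end: miRNAs are ranked by ascending
coordinate, ties broken lexicographically by id (deterministic across
platforms; published rankings exhibit no ties).

**Consensus.** Prediction programs disagree substantially, so per-program
rankings are aggregated: a miRNA is retained when at least `min_programs = 2`
programs rank it within the top `K = 20`, and scored by the arithmetic mean
of exactly those ranks — ranks beyond K are treated like absences (blank in
the exported table, excluded from the mean), which is what makes the rule
reproduce the published worked examples. Sorting is by average rank, ties by
more supporting programs, then id. Averages are displayed at two decimals,
round-half-to-even.

## Input handling

Expression matrices must be nonnegative (the NSC profile requires it);
negative entries — common in two-colour log-intensities — are rejected unless
an explicit `allow_shift` opt-in subtracts the global minimum. Probe-level
matrices are collapsed by dropping probes that map to more than one gene and
averaging the remaining probes per gene (unweighted mean per sample); probes
absent from the probe map are dropped with a logged count. Target predictions
arrive as generic long-format TSV (`mirna_id, gene_id[, site_count]`), with
site counts summed over duplicate records; a `binarize` flag reduces counts
to presence/absence for programs whose multiple-site calls are unreliable,
and an optional alias map can merge family motifs (no merging by default).
Before analysis the two tables are restricted to their shared genes, in
expression-matrix order (authoritative everywhere downstream); miRNA columns
that lose all their targets are dropped with a warning, and an intersection
below 3 genes is an error.

## The simulator

`simulate_dataset` emulates the mechanism the method assumes, nothing more:

* target counts: each (gene, miRNA) cell is occupied with probability
  `p_target = 0.2` and then carries `1 + Poisson(λ_sites − 1)` sites with
  `λ_sites = 1.5` — roughly the per-miRNA target fraction and the
  one-to-two-sites-per-target regime of seed-based prediction programs;
* expression: gene baselines `Normal(8, 1.5)` on an RMA-like log2 scale with
  residual noise `Normal(0, σ)`, `σ = 0.5` by default;
* the planted signal: in group-A samples only, each gene is lowered by
  `δ · (its total site count over the active miRNAs)` — a linear
  dose–response with no saturation, the simplest mechanism consistent with
  degradation; `δ = 0.5` by default, `δ = 0` giving an exchangeable null;
* the default problem size (500 genes, 6 samples per group, 30 miRNAs, 3
  active) is the reference configuration used by the recovery and
  calibration checks throughout the tests and the acceptance script.

Rows or columns that violate the table invariants (a gene with no sites, an
all-zero expression row after flooring at 0) are redrawn from the same
stream. All randomness flows from one seed through child streams spawned in
a fixed order (counts, baselines, noise), so identical configurations are
bit-identical across platforms. `perturb_target_table` emulates program
disagreement by toggling cells (nonzero→0, zero→1) with a given probability,
reverting one toggle per zeroed row/column so invariants survive.

What the simulator does *not* model: translational repression (undetectable
by design), probe-level effects, two-colour dye biases, correlated target
structure between miRNA families, and expression-dependent prediction bias.
Passing the recovery tests therefore shows the pipeline recovers the assumed
degradation footprint under realistic noise — not that any particular real
dataset will yield correct biology.

## Calibration

With the reference configuration and five perturbed program tables
(flip rate 0.1), all three planted miRNAs reach the consensus with average
rank ≤ 5 in ≥ 90% of simulations (observed 100% over 50 seeds). Under the
null (`δ = 0`), the per-miRNA probability of entering the consensus top 3 is
calibrated at its chance level `3/m` (observed mean frequency 0.10 at
`m = 30`, with no bias toward sparse target columns); note that the *maximum*
over all `m` empirical frequencies at 200 replicates is a multiple-comparisons
statistic with visible sampling noise around that level.

## Numerical choices and limitations

* Rank tolerance `1e-9` relative to the leading eigenvalue; oracle-facing
  tests use `1e-14` to compare full spectra.
* Weighted sums use `einsum`/BLAS; no sparse path — the intended problem
  sizes (≲ 50k genes, ≲ 1k miRNAs) are comfortably dense.
* Exports are plain TSV; plots are best-effort (a rendering failure logs a
  warning and never fails a run).
* Only two-group supervision yields a single ranked vector; more groups give
  `k − 1` axes and no canonical one-dimensional ranking.
* Multi-table coupling (more than one prediction program *simultaneously*),
  permutation tests for RV, and rank-aggregation statistics beyond the top-K
  mean are out of scope.
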