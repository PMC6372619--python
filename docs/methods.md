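# Methods

## Preprocessing: rank-based robust z response profiles

Raw expression (genes × samples) is converted per sample into ascending
within-sample gene ranks (rank 1 = lowest; ties receive the average
rank). Ranking makes the pipeline invariant to any strictly monotone
per-sample distortion, which is what makes profiles from different
platforms or normalisation pipelines comparable. Each gene's rank in a
treated sample is then robust-z-scored against the control samples:

    z = (rank − median(control ranks)) / NIQR,
    NIQR = IQR(control ranks) × c,   c = 0.7413 by default.

`c = 0.7413 = 1/1.349` makes the NIQR consistent with a normal standard
deviation; it is a configuration knob (`niqr_constant`) because other
conventions exist. Quartiles use linear interpolation between order
statistics (the numpy default); with few control samples the quantile
rule visibly changes z, so it is fixed and documented rather than left to
chance. Genes whose control IQR is zero cannot be scaled: their z is set
to 0 and they are reported, rather than dropped, so gene indices stay
aligned between training and held-out sets. Control columns are excluded
from the output by default (`keep_controls=True` retains them,
z-scored). At least two control samples are required; all-degenerate
controls are a hard error.

A bypass path accepts any user-supplied differential matrix (log fold
change, moderated t, …) directly as the response-profile matrix; the
decomposition is agnostic to how `D` was obtained as long as the origin
means "no effect".

## Decomposition

1. **Total strength.** `lᵢ = ‖dᵢ‖₂` per sample; `D′ = D·T⁻¹` has unit
   columns. Strength (how hard the sample was perturbed) and direction
   (what the perturbation did) are analysed separately; an all-zero
   column is a hard error naming the sample.
2. **Mirror selection.** The `lᵢ` are screened by an iterative one-sided
   (upper-tail) Grubbs test: while the largest norm's statistic
   `G = (max − mean)/sd` exceeds the critical value
   `G_crit = ((n−1)/√n)·√(t²/(n−2+t²))` (with `t` the upper `α/n`
   Student-t quantile at `n−2` df), that sample is removed and the test
   repeated. Only large norms are tested — the concern is samples whose
   response is too extreme to be assumed reversible. Default `α = 0.05`;
   every iteration (statistic, critical value, n) is recorded in an audit
   trail. Fewer than 3 survivors is a hard error. Note the test assumes
   roughly normal norms; on skewed (e.g. lognormal) strength
   distributions it will occasionally also remove a legitimate tail
   sample — acceptable, since removal only shrinks the mirror set, it
   does not drop the sample from `D′` or the scores.
3. **Mirror concatenation.** `DM = [D′ | −P′]`, where `P′` is the kept
   columns. With no removals the column mean of `DM` is exactly zero;
   with removals the residual centroid is `(Σ removed d′)/(N+m)` — small
   by construction since removed samples are few.
4. **Component extraction.** `DM` is decomposed by SVD *without
   re-centring*: the mirror anchors the centroid at the biological
   origin, and re-centring would silently shift it whenever samples were
   removed. When nothing is removed, uncentred SVD and mean-centred PCA
   coincide exactly (tested). Component `j`'s contribution ratio is
   `σⱼ²/Σσ²`; the smallest leading set whose cumulative contribution
   reaches `cum_threshold` is retained, with ties broken toward
   inclusion. Zero-σ components are never retained. Default threshold
   0.8; 0.9 is the conventional choice for small sample sets.
5. **Varimax rotation.** The retained components are rotated by
   maximising the raw varimax criterion
   `V = Σⱼ [Σᵢ λᵢⱼ⁴ − (Σᵢ λᵢⱼ²)²/n]` with pairwise Jacobi sweeps (each
   pair's optimal angle in closed form via `¼·atan2`), stopping when a
   sweep improves `V` by less than `varimax_tol` (1e−8) or after
   `varimax_max_iter` (1000) sweeps; non-convergence returns the
   best-so-far rotation with a warning flag in the metadata. No Kaiser
   row-normalisation is applied: the rows are genes of orthonormal
   vectors, not differently-scaled variables. `k = 1` skips rotation.
   Correctness is pinned by a grid-search oracle at `k = 2`
   (0.001-radian scan) plus orthogonality and criterion-ascent
   invariants for general k.
6. **Ordering and signs.** Post-rotation contributions are recomputed
   from the rotation matrix and the singular spectrum
   (`Σₗ Qₗⱼ²·σₗ²/Σσ²`), the factors renamed `P1…Pk` in descending order,
   and each factor's largest-|loading| gene made positive. Sign is a
   mathematical indeterminacy; the canonical rule keeps runs comparable,
   and analysts can flip a factor when the negative pole is the
   interpretable one (e.g. antagonists scoring negative).
7. **Scores.** `S = R·D′` exactly. Each score column is the projection
   of a unit vector onto orthonormal rows, so its squared sum is ≤ 1, and
   `Rᵀ·S` equals the orthogonal projection of `D′` onto the retained
   subspace.

## Signatures, enrichment, validation

* **Top-fraction genes**: `floor(fraction·n_genes)` genes (min 1) by
  squared loading, sign-blind, boundary ties by gene id. With 11,911
  genes and fraction 0.01 this is 119 genes.
* **Signature**: genes in descending contribution (squared loading /
  total squared mass) until the cumulative contribution reaches the
  cutoff (default 0.9); the crossing gene is included. A cumulative sum
  landing exactly on the cutoff terminates the list (a 1e−12 float guard
  implements the tie).
* **Enrichment**: one-sided hypergeometric p per (factor top-gene list,
  gene set) with the analysed matrix's genes as the universe;
  Benjamini–Hochberg across all factor × set pairs jointly (the
  `per_factor_min` family — BH over each factor's minimum p — is
  available where a factor-level family is preferred). A factor is
  significant if any set has q < α (default 0.05); SEGR is the fraction
  of significant factors.
* **Validation**: Spearman ρ between a signature's loading values and
  each test sample's response values over the gene-id intersection
  (coverage reported, < 3 shared genes is an error). Spearman's rank
  invariance makes per-sample monotone scaling of the test set
  irrelevant, so no normalisation is applied to it.

## Synthetic data generator

`SyntheticSpec` plants `k` sparse orthonormal gene programs (disjoint
gene blocks when sparsity permits, QR-orthonormalised otherwise),
heavy-tailed Laplace activities per factor with geometrically decaying
scales (ratio 0.7, giving the steep contribution spectra real screens
show), i.i.d. Gaussian gene noise, lognormal per-sample strengths, and
optionally a minority of outlier samples with multiplied strengths.
Column `j` of `D` is the unit direction of `W·sⱼ + εⱼ` times the
sample's strength.

Defaults — 2000 genes, 150 samples, k = 6, sparsity 0.05, leading
activity scale 5 (robust-z units), noise sd 0.1, strengths
lognormal(μ=3.7, σ=0.3) — are fixed study conditions, not tuning dials.
The activity scale is set so a responding sample moves its ~100 program
genes by roughly half a z-unit against the 0.1 background jitter, which
keeps even the weakest program's singular value above the noise bulk's
leading singular value; at much smaller scales the sixth program is
mathematically indistinguishable from noise and no method could recover
it. Strengths of order 40 match the magnitude of an L2 norm of robust-z
profiles over 2000 genes.

What the generator does **not** emulate: gene–gene correlation outside
the planted programs, platform/batch structure, non-linear or
combinatorial effects, dose series, or missing values. Passing the
recovery suite therefore shows the algebra and the estimator are
correct under the linear-mixture model the method assumes — not that
real screens satisfy that model.

Recovery is scored by optimal (Hungarian) assignment on the absolute
cosine matrix between planted and recovered loadings; planted factors
beyond the retained count score 0. Score recovery is measured against
the planted activities divided by the per-column raw norms, since the
estimated scores live in the unit-normalised profile space.

## Numerical conventions and edge cases

* Rank ties: average (mid-rank) throughout, including Spearman.
* Retention tie at the threshold: toward inclusion (≥, with a 1e−12
  guard).
* Rank direction ascending; flipping it only flips the global sign of
  `D`, absorbed by the sign canonicalisation.
* Degenerate inputs: all-identical profiles collapse to one factor with
  equal scores; rank-deficient `DM` succeeds (zero-σ components
  dropped); duplicate ids, non-numeric cells, non-finite values, unknown
  control ids, and gene-set mismatches between `R` and a score matrix
  are hard errors with the offending names in the message.
* Determinism: every stage is deterministic given inputs and
  configuration; the generator is deterministic given its seed.

## Problem sizes

The test and reproduction suites run the full pipeline on 2000 × 150
matrices (seconds per run), the varimax grid oracle on 100 random
500-gene pairs, the Grubbs power check on 100 replicates of 20 samples,
and enrichment oracles on universes up to 200 genes — sizes at which
every brute-force oracle is exact and fast while the pipeline still
operates in its intended regime.

## Known limitations

* Linear separation only: effects that combine non-linearly land in
  unseparated or noise factors.
* The Grubbs gate assumes near-normal strength distributions; heavy
  right-skew inflates removals (harmless for the mirror, but the audit
  trail should be inspected).
* The number of factors is governed by a variance heuristic (cumulative
  contribution), not a model-selection criterion; factors beyond the
  planted/biological ones are noise-dominated and should be triaged by
  enrichment and score inspection.
* Factor labelling (what a factor *means*) remains the analyst's job;
  the package produces the rankings, signatures and enrichments that
  labelling consumes.
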