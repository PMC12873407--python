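# Methods

This note documents the models implemented in `funcmap`, the choices made
where the procedure admitted more than one reasonable reading, and what the
synthetic-data experiments do and do not establish.

## Orthonormal projective NMF

The item-response matrix is oriented items × subjects so the dictionary `W`
lives on items. The objective is the projective form

    J(W) = ‖X − W WᵀX‖²_F,   W ≥ 0,

minimized by the multiplicative update `W ← W ⊙ (AW) ⊘ (W WᵀAW + ε)` with
`A = XXᵀ` and `ε = 1e-12`. Orthonormality is promoted implicitly — at a
minimum of the projective objective `WᵀW ≈ I` — rather than enforced per
iteration; columns are L2-normalized once after convergence and loadings
recomputed as `H = WᵀX`.

Two numerical guards stabilize the plain update:

- **Global rescaling.** J is not scale-invariant, and the optimal scale has
  the closed form `s² = tr(WᵀAW)/tr((WᵀW)(WᵀAW))` for `W → sW`. Every
  iterate (and the initializer) is rescaled to this optimum; this costs
  nothing extra because both traces are already needed for the objective.
- **Damped step rejection.** The one-term multiplicative step can overshoot
  early on. The objective is monitored; an increasing step is retried with a
  halved exponent (`W ⊙ ratio^η`, η = 1, ½, ¼, …) and only abandoned — with a
  warning — if no damping descends. In practice damping triggers only in the
  first few iterations from an SVD start.

Initialization is NNDSVD-ar computed from the eigendecomposition of `A`
(symmetric PSD, so its eigenvectors are left singular vectors of `X`), with
zeros filled by small seeded random values; a seeded multi-start random
initializer is available. Defaults: `tol = 1e-6` relative objective change,
`max_iter = 2000` (the multiplicative update approaches fixed points slowly;
500 iterations routinely stops short of the 1e-6 tolerance on 29 × 300
matrices, so the cap was raised rather than the tolerance loosened). A fit
that hits the cap is returned with `converged=False` and a warning.

## Split-half rank selection

Per split, subjects are randomly divided into two disjoint halves and both
halves are fit at every candidate rank. Agreement is scored by the adjusted
Rand index and variation of information of the two item assignments and by
the concordance index of the dictionaries — mean cosine similarity of columns
after optimal one-to-one matching (Hungarian assignment); generalizability by
`ΔRE`, the increase in Frobenius reconstruction error when one half's
dictionary reconstructs the other half's data, normalized by `‖X_half‖_F` and
averaged over both transfer directions. The winning rank has the best mean
rank over the four criteria (aRI↑, CI↑, VI↓, ΔRE↓), ties to the smaller rank.

Half-sample fits use `tol = 1e-5`, `max_iter = 500`: item assignments and
dictionary cosines are insensitive to the last decades of objective decrease,
and the split loop runs thousands of fits. The default 200 splits (50 in the
bundled experiments) is far below 10,000, which the `paper` preset restores;
metric medians on 29-item data stabilize well below that. The concordance
index is cosine-based after optimal matching — a documented assumption, since
"concordance between dictionaries" admits several formulas.

## Subject loadings

Loadings are `(WᵀX)ᵀ`. Published per-subject loadings of order 0.01–0.08
suggest a per-subject normalization, so the default mode divides each
subject's loadings by their total response sum ("subject-sum"); raw
within-factor response sums are always returned alongside, and every
downstream correlation-based result is invariant to the choice. Internal
consistency is the mean pairwise Pearson correlation among a factor's items,
bootstrapped over subjects (mean and 95% percentile interval).

## Fuzzy subtyping

Loadings are residualized on age, sex (0/1), education years, suicidal
ideation (0/1) and suicide attempt (0/1) by OLS; residuals are centered and
exactly orthogonal to each covariate. Fuzzy C-means uses fuzzifier `m = 2`
(the community default; it also makes the equidistant-point membership
exactly ½) and 20 seeded restarts keeping the best objective, since FCM is
initialization-sensitive. Validity indices over c = 2–6:

- SI — Campello–Hruschka fuzzy silhouette: crisp silhouettes of modal labels
  weighted by the margin `u_(1) − u_(2)`;
- XB — `Σ u² d² / (n · min ‖c_p − c_q‖²)` (+∞ for coincident centroids);
- PE — mean membership entropy, in `[0, ln c]`.

Consensus is by mean rank (SI↑, XB↓, PE↓), ties to smaller c.

The core-membership cutoff scans τ ∈ [0.70, 0.90] in steps of 0.01. For each
τ, "explained variance" is the between-cluster over total sum of squares of
the core subjects (max membership ≥ τ) under modal labels — the quantity is
named but not defined in the source methodology, so this SS-ratio reading is
a documented choice. The elbow is the grid point of maximum perpendicular
distance from the chord joining the curve's endpoints (kneedle-style);
cutoffs that empty a cluster are excluded, and a linear curve (no elbow)
falls back to the grid midpoint with a warning. Subjects at or above τ are
core members of their modal cluster; the rest form the ambiguous
("non-specific") group. Cluster display names follow the dominant centroid
coordinate so that "factor-1-dominant"-style labels are stable across seeds.

## Connectivity and the edge model

Connectivity is the Pearson correlation of ROI time series pushed through
Fisher's r-to-z, with r clipped at `±(1 − 1e-7)` so duplicated series stay
finite; diagonals are zero and matrices are vectorized in row-major
upper-triangle order (a pure function of R). Preprocessing of raw BOLD data
is out of scope; the module ingests clean time series or ready matrices.

With a univariate behavioral target, the L2-penalized canonical direction
over edges reduces exactly to the ridge solution `w ∝ (EᵀE + λI)⁻¹Eᵀy`
(solved in primal or dual form, whichever is smaller); the subject's FC score
is the projection of their standardized edge vector onto `w`. The pipeline:

- **Edge ranking**: mean |Pearson r| with the target over bootstrap
  subsamples (default 95% of subjects, 100 replications), ties broken by edge
  id; zero-variance edges contribute r = 0.
- **Nested CV**: k-fold outer loop (default 10-fold = 90% training folds)
  repeated with re-randomized folds; per training fold, 10 random draws of
  (λ log-uniform on [1, 10], N_features uniform on [100, 400]) scored by mean
  inner-fold correlation; constant inner predictions score −1. Standardization,
  ranking and tuning all happen strictly inside the training fold. A
  subject's FC score is their held-out prediction averaged over repeats, and
  the canonical r is the Pearson correlation of those scores with the target.
  How repeated predictions are aggregated into one r is a documented choice
  (per-subject averaging before correlating).
- **Consensus edges**: edges selected in more than half of the outer fits,
  with fit-averaged weights. The >50% rule is a documented choice.
- **Permutation test**: each iteration permutes raw targets and reruns the
  whole nested pipeline, with outer repeats reduced (default 5; 1 in the
  bundled experiments) to keep B iterations tractable;
  `p = (1 + #{null ≥ observed})/(1 + B)`. Permuting covariate-aligned targets
  is available via manual pre-residualization; raw-target permutation is the
  default.
- **Edge association maps** use raw within-factor score sums (not model
  loadings), partial Pearson controlling the five covariates, BH-FDR across
  all edges at q < 0.001, signs retained.
- **Region contributions** credit |weight| of each selected edge to both
  endpoint regions and normalize to proportions (scale-invariant, sum 1).
- **Subtype contrasts**: two-sample t per edge on covariate-residualized
  values for each subtype pair, BH-FDR within each contrast.

## Group statistics

Pearson chi-square is computed without continuity correction — the printed
contingency statistics of the motivating tables (0.47, 3.11, 1.83, …) match
the uncorrected formula exactly, which fixes the dialect. Partial Pearson
correlates OLS residuals with `df = n − #covariates − 2`. ANOVA is the
classical decomposition with Tukey HSD post-hocs; a residualized-ANOVA mode
exists for covariate-adjusted comparisons but is off by default, because
summary-level recomputation shows the published F statistics are not plainly
reproducible either way. FDR families are per analysis battery.

## Synthetic data: what it emulates, and what it does not

The generator plants exactly the structure the analysis assumes: a sparse
non-negative item dictionary with one dominant factor per row (blocks of
14 + 15 items, cross-loadings capped at half the dominant entry even after
column normalization); non-negative subject scores from softplus-transformed
correlated Gaussians — the softplus attenuates correlation, so the latent
correlation is calibrated by a 1-D root search on a large fixed sample to hit
the target (−0.75 by default) after transformation; Likert rendering by
round-and-clip of the scaled signal plus Gaussian item noise (SD 0.3 by
default, auto-scaled so the 97.5th signal percentile maps to the top level);
covariates on the cohort's inclusion ranges (age uniform 16–25, male rate
0.2, SI 0.8, SA 0.58) with a small linear age tilt on the scores
(`covariate_effect = 0.05` per SD); a loading-space point cloud with two core
clusters and a 15% boundary mass on centroid chords; and symmetric zero-
diagonal z-matrices where planted edges follow
`baseline + effect · standardized score + noise` (effect 0.6, noise SD 1.0,
baseline 0.25) and all other edges are noise. Defaults use 64 regions (2016
edges) rather than 224 (24,976) to keep routine runs fast; 224 is available
by config. All generators are bit-reproducible given (config, seed), with
stage seeds spawned from one `SeedSequence`.

None of this emulates raw BOLD acquisition, head motion, preprocessing
artifacts, item-level response distributions of a real instrument, or
diagnosis-dependent effects. Passing recovery tests therefore demonstrates
the *correctness and calibration of the procedures* — that rank selection
finds a genuinely two-dimensional structure, that the cutoff flags genuinely
ambiguous members, that the nested CV does not leak (pure-noise targets score
|r| ≤ 0.15 and the permutation test rejects at ~5% under the null) — not that
any particular cohort-level estimate would replicate.

## Problem sizes in the bundled experiments

The test suite and the acceptance script run at sizes chosen for desk-scale
turnaround: 20-seed rank-recovery experiments at 50 splits; nested CV at
5 outer folds × 2 repeats with 3 × 3 inner search and 20-rep ranking; 200
permutations for the planted-signal p; 100 pure-noise replicate experiments
at 19 permutations each for type-I calibration; 200 simulations for FDR
control. The `paper` preset restores the full-fidelity settings (10,000
split-halves, 100 × 10-fold CV, 100-rep ranking, 10,000 permutations) for
users with the compute budget.

## Known limitations

- The one-term multiplicative update needs damping guards and converges
  slowly near fixed points; alternative NMF flavors (KL, sparse) are out of
  scope.
- Rank-selection behavior is characterized on planted-structure data; on weak
  or continuous factor structure the four criteria can disagree, and the mean
  rank hides that disagreement (the full per-criterion table is returned).
- The ambiguity cutoff depends on the SS-ratio elbow definition; other
  explained-variance readings shift τ by a few grid steps.
- With a univariate target the "canonical" correlation is a ridge regression
  in disguise; multivariate (k > 1) CCA is not implemented.
- Permutation iterations reuse reduced outer repeats; at very small B or very
  small n the null resolution is coarse (a warning fires below B = 100).
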