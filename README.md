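# funcmap

Factor discovery, fuzzy subtyping, and connectivity-based brain–behavior
mapping for self-injury function questionnaires.

## The problem

Non-suicidal self-injury (NSSI) serves different psychological functions in
different patients — regulating internal states versus influencing the social
environment — and treating a clinically heterogeneous sample as one group
obscures both risk profiles and neural correlates. `funcmap` implements a
three-stage analysis for questionnaire + resting-state fMRI studies of this
kind:

1. **Factor discovery.** The subjects-by-items Likert matrix (e.g. the 29-item
   function subscale of the Ottawa Self-Injury Inventory, items scored 0–4) is
   factorized with *orthonormal projective non-negative matrix factorization*
   (OPNMF): `X ≈ W WᵀX` with a non-negative item dictionary `W` (items × k,
   unit-norm columns). The rank k is chosen by split-half stability — adjusted
   Rand index, variation of information and dictionary concordance between
   half-sample fits, plus the out-of-sample increase in reconstruction error
   `ΔRE = ‖X_B − W_A W_AᵀX_B‖/‖X_B‖ − ‖X_B − W_B W_BᵀX_B‖/‖X_B‖`.
2. **Fuzzy subtyping.** Subject factor loadings, residualized on age, sex,
   education, suicidal ideation and suicide attempt, are soft-clustered with
   fuzzy C-means. The cluster count is picked by consensus over the fuzzy
   silhouette, Xie–Beni and partition-entropy indices (c = 2–6), and a
   membership cutoff τ ∈ [0.70, 0.90], chosen at the elbow of the core
   explained-variance curve, separates core subtype members from ambiguous
   ("non-specific") cases.
3. **Brain–behavior mapping.** Region-pair Fisher-z connectivity values
   (`z = atanh(r)`) are vectorized into edges; a ridge-regularized canonical
   direction `w ∝ (EᵀE + λI)⁻¹Eᵀy` predicts factor loadings from
   bootstrap-ranked top edges inside a nested cross-validation
   (λ ∈ [1, 10], N_features ∈ [100, 400], 10 random search draws per training
   fold), and the out-of-sample canonical correlation is tested by permuting
   the target through the whole pipeline. Edge-wise partial correlations with
   raw factor scores are mapped at an FDR threshold, and selected-edge weight
   mass is apportioned to regions.

Because cohort data of this kind are not public, the package ships a
first-class synthetic-data generator that plants known structure — a two-factor
item dictionary (14 + 15 items), negatively correlated factor scores
(r = −0.75), a three-group soft cluster layout, and factor-coupled
connectivity edges — so every stage is verifiable by parameter recovery.

## A worked example

```python
import funcmap as fm

ds = fm.generate_dataset(fm.SyntheticConfig(n_subjects=300, seed=42,
                                            n_regions=8, planted_edges_per_factor=2))
X = ds.responses.T.astype(float)                      # items x subjects
report = fm.split_half_stability(X, k_range=(2, 3, 4, 5, 6), n_splits=50, seed=0)
print(fm.select_rank(report)["medians"].round(3))
```

prints the median stability metrics per candidate rank:

```
     ari     ci     vi  delta_re
k
2  1.000  0.999  0.000     0.002
3  0.706  0.638  0.457     0.002
4  0.480  0.469  0.813     0.001
5  0.300  0.368  1.121     0.000
6  0.199  0.378  1.353    -0.000
```

Rank 2 is maximally stable (half-sample fits agree perfectly on the item
assignment: aRI = 1, VI = 0, dictionary concordance 0.999), so `select_rank`
returns k = 2. Fitting at that rank recovers the planted 14/15 item split
exactly:

```python
model = fm.fit_opnmf(X, 2, seed=0)
labels = fm.assign_items(model).labels               # -> 14 items on factor 1, 15 on factor 2
fm.adjusted_rand(labels, ds.true_item_assignment)    # -> 1.0
```

The `examples/` directory has one short script per capability: factor
discovery, fuzzy subtyping (recovers the planted 15% boundary mass as the
ambiguous group), connectivity mapping (out-of-sample canonical r ≈ 0.96
against 0.02 for a pure-noise target), group statistics, and the one-config
full pipeline. A thin CLI wraps the same pipeline:

```bash
funcmap run --preset desk --seed 1 --out-dir my_run
funcmap report --out-dir my_run
```

Presets `test`, `desk` and `paper` expand to increasing resampling fidelity
(`paper` = 10,000 split-halves, 100×10-fold nested CV, 10,000 permutations).

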