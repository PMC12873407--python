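"""Regularized canonical-correlation mapping from connectivity edges to
behavioral factor loadings.

With a one-dimensional behavioral target, the L2-penalized canonical
direction over the edge features reduces to the ridge solution
``w ∝ (EᵀE + λI)⁻¹ Eᵀ y``; a subject's FC score is the projection of their
(standardized) edge vector onto ``w``, and the canonical correlation is the
Pearson correlation between out-of-sample FC scores and the observed target.
Feature selection (top bootstrap-ranked edges) and the hyperparameters
(λ, N_features) are tuned inside a nested cross-validation so the reported
correlation is honestly out-of-sample; significance comes from permuting the
target and re-running the whole pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import solve
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RccConfig",
    "RccResult",
    "rank_edges_bootstrap",
    "fit_rcc",
    "RidgeDirection",
    "nested_cv_predict",
    "permutation_test",
    "edge_association_map",
    "region_contributions",
    "subtype_contrast_edges",
]


@dataclass
class RccConfig:
    """Search space and resampling plan for the edge-to-loading model.

    λ is drawn log-uniformly on [lambda_min, lambda_max] and the feature
    count uniformly on [n_features_min, n_features_max]; each outer training
    fold runs ``inner_search_iters`` random draws scored by inner-CV mean
    correlation.  ``perm_outer_repeats`` bounds the outer repeats used inside
    each permutation iteration to keep the null tractable.
    """

    lambda_min: float = 1.0
    lambda_max: float = 10.0
    n_features_min: int = 100
    n_features_max: int = 400
    outer_folds: int = 10
    outer_repeats: int = 100
    inner_folds: int = 10
    inner_search_iters: int = 10
    bootstrap_reps: int = 100
    bootstrap_fraction: float = 0.95
    n_permutations: int = 10000
    perm_outer_repeats: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.lambda_min <= 0 or self.lambda_max < self.lambda_min:
            raise ValueError("need 0 < lambda_min <= lambda_max")
        if self.n_features_min < 1 or self.n_features_max < self.n_features_min:
            raise ValueError("invalid feature-count grid")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")


@dataclass
class RccResult:
    fc_scores: np.ndarray            # per-subject out-of-sample score, repeat-averaged
    canonical_r: float
    selected_edges: np.ndarray       # consensus edge ids (>50% selection frequency)
    edge_weights: np.ndarray         # mean weight per consensus edge
    selection_frequency: np.ndarray  # per edge, over outer fits
    chosen_hyperparams: list         # (repeat, fold, lambda, n_features, inner_r)
    permutation_p: float | None = None
    null_r: np.ndarray | None = None
    config: RccConfig | None = None


def _column_correlations(E: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of E with y; zero-variance columns give 0."""
    Ec = E - E.mean(axis=0)
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    se = np.sqrt((Ec**2).sum(axis=0))
    denom = se * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ec.T @ yc) / denom
    r[~np.isfinite(r)] = 0.0
    return r


def rank_edges_bootstrap(
    edges: np.ndarray,
    target: np.ndarray,
    reps: int = 100,
    fraction: float = 0.95,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank edges by mean |Pearson r| with the target over subsamples.

    Each replication draws ``fraction`` of the subjects without replacement;
    an edge with zero variance inside a subsample contributes r = 0 for that
    replication.  Returns ``(order, scores)`` with ties broken by edge id.
    """
    E = np.asarray(edges, dtype=float)
    y = np.asarray(target, dtype=float)
    n = E.shape[0]
    if n < 20:
        raise ValueError("need at least 20 subjects to rank edges")
    rng = np.random.default_rng(seed)
    size = max(2, int(round(fraction * n)))
    acc = np.zeros(E.shape[1])
    for _ in range(reps):
        idx = rng.choice(n, size=size, replace=False)
        acc += np.abs(_column_correlations(E[idx], y[idx]))
    scores = acc / reps
    order = np.lexsort((np.arange(E.shape[1]), -scores))
    return order, scores


@dataclass
class RidgeDirection:
    """Penalized canonical direction for a univariate target.

    Columns are standardized with statistics stored from the fitting data;
    ``w = (EᵀE + λI)⁻¹ Eᵀ y`` is solved in whichever of the primal/dual
    forms is smaller.
    """

    lam: float
    w: np.ndarray = None
    mean_: np.ndarray = None
    scale_: np.ndarray = None

    def fit(self, E: np.ndarray, y: np.ndarray) -> "RidgeDirection":
        E = np.asarray(E, dtype=float)
        y = np.asarray(y, dtype=float)
        self.mean_ = E.mean(axis=0)
        sd = E.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        Z = (E - self.mean_) / self.scale_
        yc = y - y.mean()
        n, p = Z.shape
        if p <= n:
            self.w = solve(Z.T @ Z + self.lam * np.eye(p), Z.T @ yc, assume_a="pos")
        else:
            alpha = solve(Z @ Z.T + self.lam * np.eye(n), yc, assume_a="pos")
            self.w = Z.T @ alpha
        return self

    def score_subjects(self, E_new: np.ndarray) -> np.ndarray:
        Z = (np.asarray(E_new, dtype=float) - self.mean_) / self.scale_
        return Z @ self.w


def fit_rcc(selected_edges: np.ndarray, target: np.ndarray, lam: float) -> RidgeDirection:
    """Fit the penalized direction on a pre-selected edge subset."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return RidgeDirection(lam=lam).fit(selected_edges, target)


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list:
    perm = rng.permutation(n)
    return [fold for fold in np.array_split(perm, n_folds)]


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def nested_cv_predict(
    edges: np.ndarray,
    target: np.ndarray,
    config: RccConfig,
    _collect_hyperparams: bool = True,
) -> RccResult:
    """Out-of-sample FC scores and canonical correlation via nested CV.

    Per outer repeat and fold, edges are bootstrap-ranked and (λ, N_features)
    tuned on the training portion only — ``inner_search_iters`` random draws
    scored by mean inner-fold correlation (constant predictions score −1) —
    then the best model is refit on the whole training fold and applied to
    the held-out subjects.  Each subject's FC score is their held-out
    prediction averaged over repeats; the canonical r is the Pearson
    correlation of those scores with the observed target.  The consensus
    edge set collects edges selected in more than half of the outer fits.
    """
    E = np.asarray(edges, dtype=float)
    y = np.asarray(target, dtype=float)
    n, n_edges = E.shape
    if n < 50:
        warnings.warn(f"n={n} subjects is small for nested CV", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    preds = np.zeros((config.outer_repeats, n))
    sel_counts = np.zeros(n_edges)
    weight_sums = np.zeros(n_edges)
    n_fits = 0
    hyper = []
    for rep in range(config.outer_repeats):
        folds = _fold_indices(n, config.outer_folds, rng)
        for fold_id, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx, assume_unique=False)
            E_tr, y_tr = E[train_idx], y[train_idx]
            rank_seed = int(rng.integers(0, 2**31))
            order, _ = rank_edges_bootstrap(
                E_tr, y_tr, reps=config.bootstrap_reps,
                fraction=config.bootstrap_fraction, seed=rank_seed,
            )
            best = None
            inner_rng = np.random.default_rng(int(rng.integers(0, 2**31)))
            for _ in range(config.inner_search_iters):
                lam = float(
                    np.exp(
                        inner_rng.uniform(
                            np.log(config.lambda_min), np.log(config.lambda_max)
                        )
                    )
                )
                nf = int(
                    inner_rng.integers(config.n_features_min, config.n_features_max + 1)
                )
                nf = min(nf, n_edges)
                cols = order[:nf]
                inner_folds = _fold_indices(len(train_idx), config.inner_folds, inner_rng)
                fold_rs = []
                for in_test in inner_folds:
                    in_train = np.setdiff1d(np.arange(len(train_idx)), in_test)
                    if in_train.size < 3 or in_test.size < 3:
                        continue
                    model = fit_rcc(E_tr[np.ix_(in_train, cols)], y_tr[in_train], lam)
                    p = model.score_subjects(E_tr[np.ix_(in_test, cols)])
                    r = _safe_pearson(p, y_tr[in_test])
                    fold_rs.append(-1.0 if np.isnan(r) else r)
                crit = float(np.mean(fold_rs)) if fold_rs else -1.0
                if best is None or crit > best[0]:
                    best = (crit, lam, nf, cols)
            crit, lam, nf, cols = best
            model = fit_rcc(E_tr[:, cols], y_tr, lam)
            preds[rep, test_idx] = model.score_subjects(E[np.ix_(test_idx, cols)])
            sel_counts[cols] += 1
            weight_sums[cols] += model.w
            n_fits += 1
            if _collect_hyperparams:
                hyper.append((rep, fold_id, lam, nf, crit))
    fc_scores = preds.mean(axis=0)
    canonical_r = _safe_pearson(fc_scores, y)
    freq = sel_counts / n_fits
    consensus = np.flatnonzero(freq > 0.5)
    with np.errstate(invalid="ignore"):
        mean_w = np.where(sel_counts > 0, weight_sums / np.maximum(sel_counts, 1), 0.0)
    return RccResult(
        fc_scores=fc_scores,
        canonical_r=float(canonical_r),
        selected_edges=consensus,
        edge_weights=mean_w[consensus],
        selection_frequency=freq,
        chosen_hyperparams=hyper,
        config=config,
    )


def permutation_test(
    edges: np.ndarray,
    target: np.ndarray,
    config: RccConfig,
    observed_r: float,
    n_permutations: int | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for the canonical correlation.

    Each iteration permutes the target across subjects and re-runs the full
    nested pipeline (at ``perm_outer_repeats`` outer repeats, logged in the
    returned config); ``p = (1 + #{null >= observed}) / (1 + B)``.
    """
    B = config.n_permutations if n_permutations is None else int(n_permutations)
    if B < 100:
        warnings.warn(f"only {B} permutations: coarse p-value resolution", stacklevel=2)
    y = np.asarray(target, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    null_cfg = replace(config, outer_repeats=config.perm_outer_repeats)
    null_r = np.empty(B)
    for b in range(B):
        perm = rng.permutation(y.size)
        cfg_b = replace(null_cfg, seed=int(rng.integers(0, 2**31)))
        res = nested_cv_predict(edges, y[perm], cfg_b, _collect_hyperparams=False)
        null_r[b] = res.canonical_r
    p = (1.0 + float(np.sum(null_r >= observed_r))) / (1.0 + B)
    return p, null_r


def _residualize_on(Z: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residuals of columns of M on covariates Z (with intercept)."""
    n = M.shape[0]
    D = np.column_stack([np.ones(n), Z]) if Z is not None and Z.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(D, M, rcond=None)
    return M - D @ beta


def edge_association_map(
    edges: np.ndarray,
    raw_scores: np.ndarray,
    covariates=None,
    fdr_threshold: float = 0.001,
) -> pd.DataFrame:
    """Edge-wise partial correlations with a raw factor score, BH-corrected.

    Per edge: Pearson correlation of covariate-residualized edge values with
    the covariate-residualized score; p from the t distribution with
    ``df = n - n_cov - 2``; Benjamini-Hochberg adjustment across all edges;
    the significance mask thresholds the adjusted p.  Signs are retained.
    """
    E = np.asarray(edges, dtype=float)
    y = np.asarray(raw_scores, dtype=float)
    if covariates is None:
        Z = np.empty((E.shape[0], 0))
    elif isinstance(covariates, pd.DataFrame):
        Z = covariates.drop(columns=["subject"], errors="ignore").to_numpy(dtype=float)
    else:
        Z = np.asarray(covariates, dtype=float)
    n = E.shape[0]
    Er = _residualize_on(Z, E)
    yr = _residualize_on(Z, y[:, None])[:, 0]
    r = _column_correlations(Er, yr)
    df = n - Z.shape[1] - 2
    r_cl = np.clip(r, -0.9999999, 0.9999999)
    t = r_cl * np.sqrt(df / (1.0 - r_cl**2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "edge": np.arange(E.shape[1]),
            "r": r,
            "p": p,
            "q": q,
            "sign": np.sign(r).astype(int),
            "significant": q < fdr_threshold,
        }
    )


def region_contributions(
    edge_ids: np.ndarray,
    weights: np.ndarray,
    edge_map: pd.DataFrame,
    parcellation: pd.DataFrame | None = None,
    top_k: int = 5,
) -> pd.DataFrame:
    """Per-region share of the selected-edge weight mass.

    Each selected edge credits ``|weight|`` to both endpoint regions; the
    proportions normalize total endpoint credit to 1 and are invariant to
    global weight rescaling.
    """
    edge_ids = np.asarray(edge_ids, dtype=int)
    weights = np.asarray(weights, dtype=float)
    if edge_ids.size == 0:
        warnings.warn("empty selected edge set: no region contributions", stacklevel=2)
        return pd.DataFrame(columns=["region", "credit", "proportion"])
    lookup = edge_map.set_index("edge")
    n_regions = int(max(lookup["i"].max(), lookup["j"].max())) + 1
    credit = np.zeros(n_regions)
    for e, w in zip(edge_ids, weights):
        i, j = int(lookup.loc[e, "i"]), int(lookup.loc[e, "j"])
        credit[i] += abs(w)
        credit[j] += abs(w)
    total = credit.sum()
    prop = credit / total if total > 0 else credit
    out = pd.DataFrame({"region": np.arange(n_regions), "credit": credit, "proportion": prop})
    if parcellation is not None:
        named = parcellation.set_index(parcellation["id"] - 1)
        out["name"] = out["region"].map(named["name"])
        if "macro_region" in named:
            out["macro_region"] = out["region"].map(named["macro_region"])
    out = out.sort_values("proportion", ascending=False).reset_index(drop=True)
    out.attrs["top_k"] = out.head(top_k)
    return out


def subtype_contrast_edges(
    edges: np.ndarray,
    subtype_labels,
    edge_subset: np.ndarray | None = None,
    covariates=None,
    q_threshold: float = 0.05,
) -> dict:
    """Two-sample t contrasts of edge values between each pair of subtypes.

    Edges are covariate-residualized first; each subtype pair gets its own
    BH-FDR family.  Pairs with fewer than two subjects in a group are skipped
    (recorded under ``"skipped"``).  Signed t-values are retained.
    """
    E = np.asarray(edges, dtype=float)
    labels = np.asarray(subtype_labels)
    if edge_subset is not None:
        subset = np.asarray(edge_subset, dtype=int)
        E = E[:, subset]
    else:
        subset = np.arange(E.shape[1])
    if covariates is None:
        Z = np.empty((E.shape[0], 0))
    elif isinstance(covariates, pd.DataFrame):
        Z = covariates.drop(columns=["subject"], errors="ignore").to_numpy(dtype=float)
    else:
        Z = np.asarray(covariates, dtype=float)
    Er = _residualize_on(Z, E)
    groups = [g for g in pd.unique(labels)]
    results = {}
    skipped = []
    for a_i in range(len(groups)):
        for b_i in range(a_i + 1, len(groups)):
            ga, gb = groups[a_i], groups[b_i]
            A, B = Er[labels == ga], Er[labels == gb]
            if A.shape[0] < 2 or B.shape[0] < 2:
                skipped.append((ga, gb))
                continue
            t, p = sps.ttest_ind(A, B, axis=0)
            t = np.nan_to_num(t)
            p = np.nan_to_num(p, nan=1.0)
            _, qv, _, _ = multipletests(p, method="fdr_bh")
            results[(ga, gb)] = pd.DataFrame(
                {"edge": subset, "t": t, "p": p, "q": qv, "significant": qv < q_threshold}
            )
    results["skipped"] = skipped
    return results
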