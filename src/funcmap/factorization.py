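"""Orthonormal projective NMF of item-response data.

Approximates a non-negative items x subjects matrix ``X`` by ``W @ W.T @ X``
with a non-negative item dictionary ``W`` (items x k).  The projective form
makes item-to-factor assignment deterministic (row-wise argmax of ``W``), and
the multiplicative update drives ``W`` toward near-orthonormal columns, giving
sparse, non-redundant factors.  Model order is chosen by split-half stability:
the sample is repeatedly halved, both halves are factorized, and agreement
between the two solutions (adjusted Rand index, variation of information,
dictionary concordance) plus out-of-sample reconstruction error are compared
across candidate ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "FactorModel",
    "ItemAssignment",
    "StabilityReport",
    "ConsistencyReport",
    "fit_opnmf",
    "assign_items",
    "adjusted_rand",
    "variation_of_information",
    "concordance_index",
    "split_half_stability",
    "select_rank",
    "bootstrap_consistency",
    "subject_loadings",
]

_EPS = 1e-12


@dataclass
class FactorModel:
    """Fitted OPNMF model.

    Attributes
    ----------
    W : ndarray, shape (n_items, k)
        Non-negative dictionary; columns are L2-normalized.
    H : ndarray, shape (k, n_subjects)
        Subject loadings, ``W.T @ X`` on the fitting data.
    k : int
        Number of factors.
    objective : float
        Final value of ``||X - W W.T X||_F^2``.
    n_iter : int
    converged : bool
    """

    W: np.ndarray
    H: np.ndarray
    k: int
    objective: float
    n_iter: int
    converged: bool


@dataclass
class ItemAssignment:
    labels: np.ndarray  # item -> factor index, 1-based
    ties: list = field(default_factory=list)


@dataclass
class StabilityReport:
    """Long-format split-half stability metrics.

    ``records`` has columns (k, split, metric, value) with metrics
    ``ari``, ``vi``, ``ci``, ``delta_re``.
    """

    records: pd.DataFrame
    k_range: tuple
    n_splits: int
    seed: int


@dataclass
class ConsistencyReport:
    """Bootstrap internal consistency per factor.

    ``summary`` has one row per factor: mean within-factor inter-item Pearson
    correlation plus a 95% percentile interval over bootstrap resamples;
    factors with fewer than two items are reported with NaN entries.
    """

    summary: pd.DataFrame
    samples: dict
    n_boot: int


def _check_nonnegative(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D array")
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def _nndsvd_init(A: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """NNDSVD-ar initialization of W from the item Gram matrix A = X X.T.

    A is symmetric PSD, so its eigenvectors double as left singular vectors
    of X; zeros left by the sign-splitting step are filled with small random
    values (the 'ar' variant) to avoid locked entries under multiplicative
    updates.
    """
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    sigma = np.sqrt(vals)  # singular values of X
    W = np.zeros((A.shape[0], k))
    for j in range(k):
        u = vecs[:, order[j]]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        # symmetric case: right singular vector == left, so pick the
        # dominant sign branch by norm
        if np.linalg.norm(up) >= np.linalg.norm(un):
            w = up
        else:
            w = un
        nrm = np.linalg.norm(w)
        if nrm > 0:
            W[:, j] = np.sqrt(sigma[j]) * w / nrm
    mean_scale = A.mean() ** 0.25 if A.mean() > 0 else 1.0
    zeros = W <= 0
    W[zeros] = rng.uniform(0, 1, size=int(zeros.sum())) * mean_scale / 100.0
    return W


def _objective(A: np.ndarray, W: np.ndarray, trA: float) -> float:
    # ||X - W W^T X||_F^2 = tr(A) - 2 tr(W^T A W) + tr((W^T W)(W^T A W))
    WtAW = W.T @ A @ W
    WtW = W.T @ W
    return float(trA - 2.0 * np.trace(WtAW) + np.sum(WtW * WtAW))


def _rescale(W: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Globally rescale W to the closed-form optimal scale of the projective
    objective: for W -> sW, obj(s) is minimized at
    s^2 = tr(W'AW) / tr((W'W)(W'AW)).  Keeps the direction, never increases
    the objective, and pins columns near unit norm as the fit orthogonalizes.
    """
    WtAW = W.T @ A @ W
    WtW = W.T @ W
    num = float(np.trace(WtAW))
    den = float(np.sum(WtW * WtAW))
    if den <= 0 or num <= 0:
        return W
    return W * (num / den) ** 0.25


def fit_opnmf(
    X: np.ndarray,
    k: int,
    init_mode: str = "nndsvdar",
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 1,
) -> FactorModel:
    """Fit projective NMF by multiplicative updates.

    Parameters
    ----------
    X : ndarray, shape (n_items, n_subjects)
        Non-negative data; items index rows so the dictionary lives on items.
    k : int
        Number of factors, ``k < min(X.shape)``.
    init_mode : {"nndsvdar", "random"}
        Deterministic SVD-based init (default) or seeded random init; with
        ``n_restarts > 1`` random restarts are run and the best objective kept.

    Notes
    -----
    The update ``W <- W * (A W) / (W W.T A W + eps)`` with ``A = X X.T``
    decreases ``||X - W W.T X||_F^2``; the objective is monitored and an
    increasing step is rejected (with a warning).  Orthonormality is promoted
    implicitly by the projective update; columns are normalized once at the
    end and loadings recomputed as ``W.T X``.
    """
    X = _check_nonnegative(X)
    if np.any(X.sum(axis=1) == 0):
        raise ValueError("X has all-zero item rows; drop them before fitting")
    if not 1 <= k < min(X.shape):
        raise ValueError(f"k={k} must satisfy 1 <= k < min(X.shape)={min(X.shape)}")

    A = X @ X.T
    trA = float(np.trace(A))
    rng = np.random.default_rng(seed)

    starts = []
    if init_mode == "nndsvdar":
        starts.append(_nndsvd_init(A, k, rng))
    elif init_mode == "random":
        scale = A.mean() ** 0.25 if A.mean() > 0 else 1.0
        for _ in range(max(1, n_restarts)):
            starts.append(rng.uniform(0.1, 1.0, size=(X.shape[0], k)) * scale)
    else:
        raise ValueError(f"unknown init_mode {init_mode!r}")

    def _evaluate(Wc):
        """Optimal global rescale + objective, sharing the expensive products."""
        AWc = A @ Wc
        WtAW = Wc.T @ AWc
        WtW = Wc.T @ Wc
        num = float(np.trace(WtAW))
        den = float(np.sum(WtW * WtAW))
        s2 = num / den if den > 0 and num > 0 else 1.0
        s = s2**0.5
        obj = float(trA - 2.0 * s2 * num + s2 * s2 * den)
        return s * Wc, s * AWc, s2 * WtAW, obj

    best = None
    for W in starts:
        W, AW, WtAW, obj = _evaluate(W)
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            ratio = AW / (W @ WtAW + _EPS)
            # the multiplicative step can overshoot; reject an increasing
            # step and retry it damped (halved exponent) until it descends
            eta = 1.0
            stepped = False
            while eta >= 1.0 / 1024:
                cand = W * ratio if eta == 1.0 else W * ratio**eta
                W_new, AW_new, WtAW_new, obj_new = _evaluate(cand)
                if obj_new <= obj + 1e-8 * max(obj, 1.0):
                    stepped = True
                    break
                eta /= 2.0
            if not stepped:
                warnings.warn(
                    f"objective increased at iteration {n_iter}; step rejected",
                    RuntimeWarning,
                    stacklevel=2,
                )
                break
            delta = abs(obj - obj_new) / max(obj, _EPS)
            W, AW, WtAW, obj = W_new, AW_new, WtAW_new, obj_new
            if delta < tol or obj <= 1e-12 * trA:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"OPNMF did not converge in {n_iter} iterations (k={k})",
                RuntimeWarning,
                stacklevel=2,
            )
        if best is None or obj < best[1]:
            best = (W, obj, n_iter, converged)

    W, obj, n_iter, converged = best
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    H = W.T @ X
    return FactorModel(W=W, H=H, k=k, objective=_objective(A, W, trA), n_iter=n_iter, converged=converged)


def assign_items(model: FactorModel, allow_zero_rows: bool = False) -> ItemAssignment:
    """Label each item by its dominant dictionary column (1-based).

    Ties break to the lowest factor index and are recorded; an all-zero row
    is an error unless ``allow_zero_rows``.
    """
    W = model.W
    row_max = W.max(axis=1)
    if np.any(row_max == 0) and not allow_zero_rows:
        bad = np.flatnonzero(row_max == 0).tolist()
        raise ValueError(f"items {bad} have all-zero dictionary rows; cannot assign")
    labels = np.argmax(W, axis=1) + 1
    ties = [
        int(i)
        for i in range(W.shape[0])
        if row_max[i] > 0 and np.sum(np.isclose(W[i], row_max[i], rtol=0, atol=1e-12)) > 1
    ]
    return ItemAssignment(labels=labels, ties=ties)


def adjusted_rand(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D with equal length")
    if a.size < 2:
        raise ValueError("need at least two elements")
    return float(adjusted_rand_score(a, b))


def variation_of_information(labels_a, labels_b) -> float:
    """Partition distance H(A) + H(B) - 2 I(A,B), in nats."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D with equal length")
    n = a.size
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    joint = np.zeros((ua.size, ub.size))
    np.add.at(joint, (ia, ib), 1.0)
    p = joint / n
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    def _H(q):
        q = q[q > 0]
        return -np.sum(q * np.log(q))
    mask = p > 0
    mi = np.sum(p[mask] * (np.log(p[mask]) - np.log(np.outer(pa, pb)[mask])))
    vi = _H(pa) + _H(pb) - 2.0 * mi
    return float(vi) if vi > 1e-12 else 0.0


def concordance_index(W_a: np.ndarray, W_b: np.ndarray) -> float:
    """Mean cosine similarity of optimally matched dictionary columns.

    Columns are matched one-to-one to maximize total cosine similarity
    (Hungarian assignment), then the matched cosines are averaged.
    """
    W_a = np.asarray(W_a, dtype=float)
    W_b = np.asarray(W_b, dtype=float)
    if W_a.shape != W_b.shape:
        raise ValueError("dictionaries must share shape (items x k)")
    na = np.linalg.norm(W_a, axis=0)
    nb = np.linalg.norm(W_b, axis=0)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    C = (W_a / na).T @ (W_b / nb)
    rows, cols = linear_sum_assignment(-C)
    return float(C[rows, cols].mean())


def _reconstruction_error(W: np.ndarray, X: np.ndarray) -> float:
    # ||X - W W^T X||_F normalized by ||X||_F
    R = X - W @ (W.T @ X)
    return float(np.linalg.norm(R) / max(np.linalg.norm(X), _EPS))


def split_half_stability(
    X: np.ndarray,
    k_range=(2, 3, 4, 5, 6),
    n_splits: int = 200,
    seed: int = 0,
    fit_tol: float = 1e-5,
    fit_max_iter: int = 500,
    **fit_kwargs,
) -> StabilityReport:
    """Split-half stability and generalizability across candidate ranks.

    For each split, subjects are randomly divided into two disjoint halves
    and OPNMF is fit on each half at every ``k``.  Agreement between the two
    solutions is scored by the adjusted Rand index and variation of
    information of the item assignments and the concordance of the
    dictionaries; generalizability by the out-of-sample increase in
    normalized reconstruction error, averaged over both transfer directions.
    """
    X = _check_nonnegative(X)
    n_items, n_sub = X.shape
    if n_sub < 20:
        raise ValueError("need at least 20 subjects for split-half analysis")
    k_range = tuple(int(k) for k in k_range)
    if any(not 2 <= k <= min(n_items, n_sub // 2) - 1 for k in k_range):
        raise ValueError("k_range outside [2, min(dims)-1] for half-samples")

    rng = np.random.default_rng(seed)
    rows = []
    for split in range(n_splits):
        perm = rng.permutation(n_sub)
        half = n_sub // 2
        idx_a, idx_b = perm[:half], perm[half:]
        Xa, Xb = X[:, idx_a], X[:, idx_b]
        for k in k_range:
            with warnings.catch_warnings():
                # half-sample fits that stop at max_iter still yield stable
                # assignments; don't spam per-split convergence warnings
                warnings.simplefilter("ignore", RuntimeWarning)
                ma = fit_opnmf(Xa, k, seed=seed, tol=fit_tol, max_iter=fit_max_iter, **fit_kwargs)
                mb = fit_opnmf(Xb, k, seed=seed, tol=fit_tol, max_iter=fit_max_iter, **fit_kwargs)
            la = assign_items(ma, allow_zero_rows=True).labels
            lb = assign_items(mb, allow_zero_rows=True).labels
            ari = adjusted_rand(la, lb)
            vi = variation_of_information(la, lb)
            ci = concordance_index(ma.W, mb.W)
            d_ab = _reconstruction_error(ma.W, Xb) - _reconstruction_error(mb.W, Xb)
            d_ba = _reconstruction_error(mb.W, Xa) - _reconstruction_error(ma.W, Xa)
            dre = 0.5 * (d_ab + d_ba)
            rows.extend(
                [
                    (k, split, "ari", ari),
                    (k, split, "vi", vi),
                    (k, split, "ci", ci),
                    (k, split, "delta_re", dre),
                ]
            )
    records = pd.DataFrame(rows, columns=["k", "split", "metric", "value"])
    return StabilityReport(records=records, k_range=k_range, n_splits=n_splits, seed=seed)


def select_rank(report: StabilityReport) -> dict:
    """Choose the rank with the best mean rank over four stability criteria.

    Candidates are ranked on median adjusted Rand (higher better), median
    concordance (higher better), median variation of information (lower
    better) and median out-of-sample reconstruction-error increase (lower
    better); ties go to the smaller rank.
    """
    rec = report.records
    if rec.empty:
        raise ValueError("empty stability report")
    med = rec.groupby(["k", "metric"])["value"].median().unstack()
    table = pd.DataFrame(index=med.index)
    table["ari"] = med["ari"]
    table["ci"] = med["ci"]
    table["vi"] = med["vi"]
    table["delta_re"] = med["delta_re"]
    ranks = pd.DataFrame(index=med.index)
    ranks["ari"] = (-table["ari"]).rank(method="min")
    ranks["ci"] = (-table["ci"]).rank(method="min")
    ranks["vi"] = table["vi"].rank(method="min")
    ranks["delta_re"] = table["delta_re"].rank(method="min")
    mean_rank = ranks.mean(axis=1)
    best = mean_rank.min()
    selected = int(min(k for k in mean_rank.index if mean_rank[k] == best))
    note = "single-candidate" if len(mean_rank) == 1 else ""
    return {
        "selected_k": selected,
        "medians": table,
        "ranks": ranks,
        "mean_rank": mean_rank,
        "note": note,
    }


def bootstrap_consistency(
    X: np.ndarray, model: FactorModel, n_boot: int = 1000, seed: int = 0
) -> ConsistencyReport:
    """Bootstrap internal consistency of each factor.

    For each subject resample (with replacement), the mean pairwise Pearson
    correlation among the items assigned to a factor is recorded; the report
    carries the mean and a 95% percentile interval per factor.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X = _check_nonnegative(X)
    labels = assign_items(model).labels
    rng = np.random.default_rng(seed)
    n_sub = X.shape[1]
    samples = {f: [] for f in range(1, model.k + 1)}
    for _ in range(n_boot):
        idx = rng.integers(0, n_sub, size=n_sub)
        Xb = X[:, idx]
        for f in range(1, model.k + 1):
            items = np.flatnonzero(labels == f)
            if items.size < 2:
                samples[f].append(np.nan)
                continue
            sub = Xb[items]
            sd = sub.std(axis=1)
            if np.any(sd == 0):
                keep = sd > 0
                sub = sub[keep]
                if sub.shape[0] < 2:
                    samples[f].append(np.nan)
                    continue
            C = np.corrcoef(sub)
            iu = np.triu_indices_from(C, k=1)
            samples[f].append(float(C[iu].mean()))
    rows = []
    for f, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        ok = arr[~np.isnan(arr)]
        if ok.size == 0:
            rows.append((f, np.nan, np.nan, np.nan, int((labels == f).sum())))
        else:
            rows.append(
                (f, float(ok.mean()), float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5)), int((labels == f).sum()))
            )
    summary = pd.DataFrame(rows, columns=["factor", "mean_r", "ci_lo", "ci_hi", "n_items"])
    return ConsistencyReport(summary=summary, samples=samples, n_boot=n_boot)


def subject_loadings(
    model: FactorModel, X_new: np.ndarray, normalization_mode: str = "subject-sum"
) -> tuple[np.ndarray, np.ndarray]:
    """Project new subjects onto the fitted dictionary.

    Returns ``(loadings, raw_scores)``: loadings are ``(W.T X_new).T``,
    optionally normalized per subject; raw factor scores are plain sums of a
    subject's responses over the items assigned to each factor.

    normalization_mode : {"none", "subject-sum", "mean"}
        "subject-sum" divides each subject's loadings by that subject's total
        response sum (zero-total subjects are left at zero); "mean" divides
        by the item count.
    """
    X_new = _check_nonnegative(X_new)
    if X_new.shape[0] != model.W.shape[0]:
        raise ValueError("item dimension mismatch with dictionary")
    loadings = (model.W.T @ X_new).T
    if normalization_mode == "none":
        pass
    elif normalization_mode == "subject-sum":
        totals = X_new.sum(axis=0)
        safe = np.where(totals > 0, totals, 1.0)
        loadings = loadings / safe[:, None]
    elif normalization_mode == "mean":
        loadings = loadings / model.W.shape[0]
    else:
        raise ValueError(f"unknown normalization_mode {normalization_mode!r}")
    labels = assign_items(model, allow_zero_rows=True).labels
    raw = np.stack(
        [X_new[labels == f].sum(axis=0) for f in range(1, model.k + 1)], axis=1
    )
    return loadings, raw
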