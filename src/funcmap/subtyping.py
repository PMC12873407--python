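"""Fuzzy functional subtyping of subjects from factor loadings.

Loadings are first residualized on nuisance covariates (age, sex, education,
suicidal ideation, suicide attempt), then soft-clustered with fuzzy C-means.
The number of clusters is chosen by consensus over three validity indices
(fuzzy silhouette, Xie-Beni, partition entropy), and a membership cutoff
separating core members from ambiguous ("non-specific") cases is picked by
the elbow of an explained-variance curve over candidate cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr
from sklearn.metrics import silhouette_samples

__all__ = [
    "ResidualizedLoadings",
    "FuzzyPartition",
    "ValidityReport",
    "SubtypeAssignment",
    "residualize",
    "fuzzy_cmeans",
    "validity_indices",
    "select_c",
    "elbow_cutoff",
    "assign_subtypes",
]


@dataclass
class ResidualizedLoadings:
    residuals: np.ndarray       # subjects x k, column-centered
    coefficients: np.ndarray    # (1 + n_cov) x k, intercept first
    covariate_names: list
    excluded_rows: list = field(default_factory=list)


@dataclass
class FuzzyPartition:
    U: np.ndarray           # subjects x c memberships, rows sum to 1
    centroids: np.ndarray   # c x k
    m: float
    objective: float
    n_iter: int


@dataclass
class ValidityReport:
    table: pd.DataFrame     # columns: c, si, xb, pe


@dataclass
class SubtypeAssignment:
    frame: pd.DataFrame     # subject, modal_cluster, max_membership, status
    cutoff: float
    cluster_names: dict
    counts: dict


def residualize(loadings: np.ndarray, covariates: pd.DataFrame) -> ResidualizedLoadings:
    """Remove linear covariate effects from factor loadings by OLS.

    Rows with missing covariates are excluded (and recorded); residuals are
    returned centered (the intercept stays off).  A rank-deficient design
    raises an error naming the collinear columns.
    """
    loadings = np.asarray(loadings, dtype=float)
    cov = covariates.drop(columns=["subject"], errors="ignore")
    names = list(cov.columns)
    mask = cov.notna().all(axis=1).to_numpy()
    excluded = np.flatnonzero(~mask).tolist()
    Z = cov.to_numpy(dtype=float)[mask]
    Y = loadings[mask]
    n = Z.shape[0]
    D = np.column_stack([np.ones(n), Z])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        _, _, piv = qr(D, mode="economic", pivoting=True)
        dropped = sorted(piv[rank:].tolist())
        bad = [("intercept" if j == 0 else names[j - 1]) for j in dropped]
        raise ValueError(f"covariate matrix is rank-deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    res = Y - D @ beta
    res = res - res.mean(axis=0)
    return ResidualizedLoadings(
        residuals=res, coefficients=beta, covariate_names=names, excluded_rows=excluded
    )


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; handles coincident points."""
    zero = d2 <= 1e-300
    U = np.zeros_like(d2)
    any_zero = zero.any(axis=1)
    if any_zero.any():
        U[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    rest = ~any_zero
    if rest.any():
        power = d2[rest] ** (-1.0 / (m - 1.0))
        U[rest] = power / power.sum(axis=1, keepdims=True)
    return U


def fuzzy_cmeans(
    data: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_restarts: int = 20,
    seed: int = 0,
) -> FuzzyPartition:
    """Fuzzy C-means by alternating membership/centroid updates.

    Memberships follow ``u_ij proportional to d_ij^(-2/(m-1))`` and centroids
    are ``u^m``-weighted means; iteration stops when the maximum centroid
    shift falls below ``tol``.  The best of ``n_restarts`` seeded random
    initializations (by the objective ``J_m``) is returned.
    """
    X = np.asarray(data, dtype=float)
    n, k = X.shape
    if c < 2:
        raise ValueError("c must be >= 2")
    if n <= c:
        raise ValueError("need more points than clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(max(1, n_restarts)):
        rng = np.random.default_rng(child)
        centroids = X[rng.choice(n, size=c, replace=False)].copy()
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            d2 = ((X[:, None, :] - centroids[None]) ** 2).sum(axis=2)
            U = _fcm_memberships(d2, m)
            Um = U**m
            new_centroids = (Um.T @ X) / np.maximum(Um.sum(axis=0)[:, None], 1e-300)
            shift = np.abs(new_centroids - centroids).max()
            centroids = new_centroids
            if shift < tol:
                break
        d2 = ((X[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        U = _fcm_memberships(d2, m)
        J = float(np.sum(U**m * d2))
        if best is None or J < best.objective:
            best = FuzzyPartition(U=U, centroids=centroids, m=m, objective=J, n_iter=n_iter)
    return best


def validity_indices(data: np.ndarray, partition: FuzzyPartition) -> tuple:
    """Fuzzy silhouette (SI), Xie-Beni (XB), and partition entropy (PE).

    SI is the Campello-Hruschka fuzzy silhouette: crisp silhouettes of the
    modal labels weighted by the margin between the largest and second
    membership.  XB is compactness over separation,
    ``sum(u^2 d^2) / (n * min_pq ||c_p - c_q||^2)`` (infinite when centroids
    coincide).  PE is the mean membership entropy, in [0, ln c].
    """
    X = np.asarray(data, dtype=float)
    U, C = partition.U, partition.centroids
    n, c = U.shape
    labels = U.argmax(axis=1)
    if np.unique(labels).size < 2:
        si = -1.0
    else:
        s = silhouette_samples(X, labels)
        Us = np.sort(U, axis=1)
        weights = Us[:, -1] - Us[:, -2]
        si = float(np.sum(weights * s) / max(weights.sum(), 1e-300))
    d2 = ((X[:, None, :] - C[None]) ** 2).sum(axis=2)
    sep = ((C[:, None, :] - C[None]) ** 2).sum(axis=2)
    sep[np.diag_indices(c)] = np.inf
    min_sep = sep.min()
    xb = float(np.sum(U**2 * d2) / (n * min_sep)) if min_sep > 0 else float("inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        logu = np.where(U > 0, np.log(U), 0.0)
    pe = float(-np.sum(U * logu) / n)
    return si, xb, pe


def select_c(report: ValidityReport) -> dict:
    """Consensus cluster count by mean rank over SI (max), XB and PE (min)."""
    t = report.table.set_index("c")
    if t.empty:
        raise ValueError("empty validity report")
    ranks = pd.DataFrame(index=t.index)
    ranks["si"] = (-t["si"]).rank(method="min")
    ranks["xb"] = t["xb"].rank(method="min")
    ranks["pe"] = t["pe"].rank(method="min")
    mean_rank = ranks.mean(axis=1)
    best = mean_rank.min()
    selected = int(min(cc for cc in mean_rank.index if mean_rank[cc] == best))
    return {"selected_c": selected, "ranks": ranks, "mean_rank": mean_rank}


def _explained_variance(X: np.ndarray, labels: np.ndarray) -> float:
    """Between-cluster over total sum of squares for crisp labels."""
    mu = X.mean(axis=0)
    total = float(((X - mu) ** 2).sum())
    if total <= 0:
        return 1.0
    between = 0.0
    for g in np.unique(labels):
        sel = labels == g
        between += sel.sum() * float(((X[sel].mean(axis=0) - mu) ** 2).sum())
    return between / total


def _chord_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Perpendicular distance of each curve point from the endpoint chord."""
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    nrm = np.linalg.norm(chord)
    if nrm == 0:
        return np.zeros(len(x))
    pts = np.column_stack([x, y]) - p0
    return np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / nrm


def elbow_cutoff(
    U: np.ndarray,
    data: np.ndarray,
    tau_grid=None,
) -> dict:
    """Elbow-selected membership cutoff on the core explained-variance curve.

    For each candidate cutoff, core subjects (max membership >= tau) are
    given their modal label and the between/total sum-of-squares ratio is
    computed over them; the elbow is the grid point with maximum
    perpendicular distance from the chord joining the curve endpoints.
    Cutoffs that empty a cluster are excluded from the search; a strictly
    linear curve has no elbow and falls back to the grid midpoint with a
    warning.
    """
    U = np.asarray(U, dtype=float)
    X = np.asarray(data, dtype=float)
    if tau_grid is None:
        tau_grid = np.round(np.arange(0.70, 0.90 + 1e-9, 0.01), 2)
    tau_grid = np.asarray(tau_grid, dtype=float)
    c = U.shape[1]
    maxmem = U.max(axis=1)
    modal = U.argmax(axis=1)
    curve = []
    flagged = []
    for tau in tau_grid:
        core = maxmem >= tau
        labels = modal[core]
        if core.sum() < 2 or np.unique(labels).size < c:
            flagged.append(float(tau))
            curve.append(np.nan)
            continue
        curve.append(_explained_variance(X[core], labels))
    curve = np.asarray(curve)
    ok = ~np.isnan(curve)
    frame = pd.DataFrame({"tau": tau_grid, "explained_variance": curve, "valid": ok})
    usable = np.flatnonzero(ok)
    if usable.size < 3:
        warnings.warn("too few valid cutoffs for an elbow; falling back to grid midpoint", stacklevel=2)
        return {"tau": float(np.median(tau_grid)), "curve": frame, "flagged": flagged, "elbow_found": False}
    x = tau_grid[usable]
    y = curve[usable]
    dists = _chord_distances(x, y)
    interior = dists[1:-1]
    if interior.size == 0 or interior.max() <= 1e-12:
        warnings.warn("explained-variance curve is linear: no elbow; using grid midpoint", stacklevel=2)
        return {"tau": float(np.median(tau_grid)), "curve": frame, "flagged": flagged, "elbow_found": False}
    best = 1 + int(np.argmax(interior))
    return {"tau": float(x[best]), "curve": frame, "flagged": flagged, "elbow_found": True}


def assign_subtypes(U: np.ndarray, tau: float, names=None, centroids=None) -> SubtypeAssignment:
    """Split subjects into core subtype members and an ambiguous group.

    A subject whose maximum membership reaches ``tau`` is a core member of
    its modal cluster; everyone else is "ambiguous" (non-specific).  Cluster
    display names default to ``cluster_<j>`` or, when centroids are given,
    ``factor<j>-dominant`` by the largest centroid coordinate so names are
    stable across seeds.
    """
    U = np.asarray(U, dtype=float)
    n, c = U.shape
    if not (1.0 / c) < tau <= 1.0:
        raise ValueError(f"tau must lie in (1/c, 1]; got {tau} with c={c}")
    modal = U.argmax(axis=1)
    maxmem = U.max(axis=1)
    status = np.where(maxmem >= tau, "core", "ambiguous")
    if names is None:
        if centroids is not None:
            centroids = np.asarray(centroids)
            names = {j: f"factor{int(np.argmax(centroids[j])) + 1}-dominant" for j in range(c)}
        else:
            names = {j: f"cluster_{j + 1}" for j in range(c)}
    frame = pd.DataFrame(
        {
            "subject": np.arange(1, n + 1),
            "modal_cluster": modal + 1,
            "cluster_name": [names[j] for j in modal],
            "max_membership": maxmem,
            "status": status,
        }
    )
    counts = {
        "core": {int(j + 1): int(((modal == j) & (status == "core")).sum()) for j in range(c)},
        "ambiguous": int((status == "ambiguous").sum()),
        "total": n,
    }
    return SubtypeAssignment(frame=frame, cutoff=float(tau), cluster_names=names, counts=counts)
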