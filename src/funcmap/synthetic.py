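"""Synthetic questionnaire, covariate, subtype, and connectivity data.

The generators plant known structure matching the statistical assumptions of
the analysis stages: two negatively correlated non-negative latent factors
rendered to 0-4 Likert items through a sparse non-negative dictionary, small
linear covariate effects, a three-group soft cluster structure in loading
space (two core groups plus a boundary mass), and symmetric Fisher-z
connectivity matrices in which a planted edge subset depends linearly on the
factor scores.  Every generator is bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dictionary",
    "generate_subject_scores",
    "render_likert",
    "generate_covariates",
    "generate_subtype_loadings",
    "generate_connectivity",
    "generate_roi_timeseries",
    "generate_dataset",
]


@dataclass
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    Defaults mirror the study design: 29 Likert items (0-4) loading on two
    factors of 14 and 15 items whose subject scores correlate at -0.75, a
    young-adult covariate profile, and connectivity matrices with a small set
    of factor-coupled edges.  ``n_regions`` defaults to 64 (2016 edges) for
    fast tests; set 224 to match whole-brain parcellation scale.
    """

    n_subjects: int = 304
    n_items: int = 29
    n_factors: int = 2
    items_per_factor: tuple = (14, 15)
    loading_correlation: float = -0.75
    likert_levels: int = 5
    item_noise_sd: float = 0.3
    cross_loading: float = 0.1
    n_regions: int = 64
    n_timepoints: int = 200
    planted_edges_per_factor: int = 25
    edge_effect_size: float = 0.6
    edge_noise_sd: float = 1.0
    edge_baseline: float = 0.25
    covariate_effect: float = 0.05
    sex_rate: float = 0.2
    subtype_centroids: tuple = ((1.6, 0.4), (0.4, 1.6), (0.6, 0.6))
    boundary_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.n_items, self.n_factors, self.n_regions) < 1:
            raise ValueError("all counts must be >= 1")
        if any(m < 2 for m in self.items_per_factor):
            raise ValueError("items_per_factor entries must be >= 2")
        if sum(self.items_per_factor) > self.n_items:
            raise ValueError("items_per_factor sums beyond n_items")
        if self.likert_levels < 2:
            raise ValueError("likert_levels must be >= 2")
        if not -1 < self.loading_correlation < 1:
            raise ValueError("loading_correlation must lie in (-1, 1)")
        if self.edge_noise_sd <= 0:
            raise ValueError("edge_noise_sd must be positive")


@dataclass
class SyntheticDataset:
    responses: np.ndarray          # subjects x items, integers in [0, L-1]
    true_dictionary: np.ndarray    # items x k
    true_scores: np.ndarray        # subjects x k, non-negative
    true_item_assignment: np.ndarray  # item -> factor, 1-based
    covariates: pd.DataFrame
    true_memberships: np.ndarray   # subjects x c
    connectivity: list             # per-subject R x R symmetric z-matrices
    planted_edge_index: dict       # factor -> list of (i, j), i < j
    config: SyntheticConfig = None


def generate_dictionary(
    n_items: int,
    n_factors: int,
    items_per_factor,
    cross_loading: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sparse non-negative dictionary with one dominant factor per item.

    Items are partitioned into blocks of the requested sizes (leftover items
    are assigned round-robin); each item's primary loading is drawn from
    U(0.5, 1) and its cross-loadings are scaled so the primary entry stays at
    least twice any other entry in the row, even after the final per-column
    L2 normalization.
    """
    items_per_factor = tuple(int(m) for m in items_per_factor)
    if cross_loading < 0:
        raise ValueError("cross_loading must be >= 0")
    if len(items_per_factor) != n_factors or sum(items_per_factor) > n_items:
        raise ValueError("infeasible item counts for the requested factors")
    rng = np.random.default_rng(seed)
    assignment = np.concatenate(
        [np.full(m, f) for f, m in enumerate(items_per_factor)]
    )
    leftover = n_items - assignment.size
    if leftover:
        assignment = np.concatenate([assignment, np.arange(leftover) % n_factors])
    W = np.zeros((n_items, n_factors))
    primary = rng.uniform(0.5, 1.0, size=n_items)
    W[np.arange(n_items), assignment] = primary
    if cross_loading > 0 and n_factors > 1:
        cross = cross_loading * rng.uniform(0.0, 1.0, size=(n_items, n_factors))
        cross[np.arange(n_items), assignment] = 0.0
        W = W + np.minimum(cross, 0.45 * primary[:, None])
    # normalize columns, then shrink any cross entry the rescaling pushed
    # above half its row's dominant entry
    for _ in range(20):
        W = W / np.linalg.norm(W, axis=0)
        dom = W[np.arange(n_items), assignment]
        cap = 0.5 * dom[:, None]
        over = W > cap
        over[np.arange(n_items), assignment] = False
        if not over.any():
            break
        W[over] = 0.95 * np.broadcast_to(cap, W.shape)[over]
    return W


def _softplus(x):
    return np.logaddexp(0.0, x)


def _post_transform_corr(rho: float, z: np.ndarray, mu: float, sigma: float) -> float:
    z1, z2 = z
    y2 = rho * z1 + np.sqrt(1.0 - rho**2) * z2
    a = _softplus(mu + sigma * z1)
    b = _softplus(mu + sigma * y2)
    return float(np.corrcoef(a, b)[0, 1])


def generate_subject_scores(
    n_subjects: int,
    n_factors: int = 2,
    loading_correlation: float = -0.75,
    seed: int = 0,
    mu: float = 1.0,
    sigma: float = 1.0,
) -> np.ndarray:
    """Non-negative subject scores with a target inter-factor correlation.

    Correlated Gaussians are pushed through a softplus map to enforce
    non-negativity; because the monotone transform attenuates correlation,
    the latent Gaussian correlation is calibrated by a 1-D root search on a
    large fixed calibration sample so the post-transform sample correlation
    hits the target.
    """
    if n_factors != 2:
        raise ValueError("a scalar correlation target requires exactly 2 factors")
    if not -1 < loading_correlation < 1:
        raise ValueError("|loading_correlation| must be < 1")
    rng = np.random.default_rng(seed)
    if abs(loading_correlation) < 1e-12:
        rho = 0.0
    else:
        cal = np.random.default_rng(12345).standard_normal((2, 200000))
        f = lambda r: _post_transform_corr(r, cal, mu, sigma) - loading_correlation
        lo, hi = (-0.999999, 0.0) if loading_correlation < 0 else (0.0, 0.999999)
        rho = brentq(f, lo, hi, xtol=1e-6)
    z1, z2 = rng.standard_normal((2, n_subjects))
    y2 = rho * z1 + np.sqrt(1.0 - rho**2) * z2
    scores = np.column_stack(
        [_softplus(mu + sigma * z1), _softplus(mu + sigma * y2)]
    )
    return scores


def render_likert(
    scores: np.ndarray,
    dictionary: np.ndarray,
    item_noise_sd: float = 0.3,
    likert_levels: int = 5,
    seed: int = 0,
    scale: float | None = None,
) -> np.ndarray:
    """Render latent scores to an integer Likert response matrix.

    ``responses = round(clip(scores @ dictionary.T * scale + noise, 0, L-1))``.
    With ``scale=None`` the signal is auto-scaled so its 97.5th percentile
    maps to the top level, keeping the histogram spread over the scale.
    """
    scores = np.asarray(scores, dtype=float)
    dictionary = np.asarray(dictionary, dtype=float)
    if scores.shape[1] != dictionary.shape[1]:
        raise ValueError("scores and dictionary factor dimensions differ")
    rng = np.random.default_rng(seed)
    signal = scores @ dictionary.T
    if scale is None:
        hi = np.percentile(signal, 97.5) if signal.size else 0.0
        scale = (likert_levels - 1) / hi if hi > 0 else 1.0
    noisy = signal * scale + rng.normal(0.0, item_noise_sd, size=signal.shape)
    return np.clip(np.rint(noisy), 0, likert_levels - 1).astype(int)


def generate_covariates(
    n_subjects: int,
    seed: int = 0,
    sex_rate: float = 0.2,
    si_rate: float = 0.8,
    sa_rate: float = 0.58,
) -> pd.DataFrame:
    """Covariate table: age, sex, education years, suicidal ideation/attempt.

    Ages are uniform on the 16-25 inclusion range; sex, suicidal ideation
    (SI) and suicide attempt (SA) are 0/1 Bernoulli draws at rates matching
    an inpatient adolescent cohort; education is an integer year count tied
    loosely to age.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    age = rng.uniform(16.0, 25.0, size=n_subjects)
    sex = (rng.uniform(size=n_subjects) < sex_rate).astype(int)
    education = np.clip(np.rint(age - 6.0 + rng.normal(0, 1.0, n_subjects)), 6, 18).astype(int)
    si = (rng.uniform(size=n_subjects) < si_rate).astype(int)
    sa = (rng.uniform(size=n_subjects) < sa_rate).astype(int)
    return pd.DataFrame(
        {
            "subject": np.arange(1, n_subjects + 1),
            "age": age,
            "sex": sex,
            "education": education,
            "si": si,
            "sa": sa,
        }
    )


def generate_subtype_loadings(
    n_subjects: int,
    centroids,
    within_sd: float = 0.15,
    boundary_fraction: float = 0.15,
    seed: int = 0,
):
    """Loading-space point cloud with core clusters and a boundary mass.

    Core subjects are Gaussian around their centroid; boundary subjects sit
    on random convex combinations (0.35-0.65 mixing) of two centroids, where
    fuzzy memberships are intrinsically ambiguous.  Returns
    ``(points, true_labels, is_boundary)`` with labels 1-based and boundary
    subjects labeled by their nearest centroid.
    """
    centroids = np.asarray(centroids, dtype=float)
    c, k = centroids.shape
    rng = np.random.default_rng(seed)
    n_boundary = int(round(boundary_fraction * n_subjects))
    n_core = n_subjects - n_boundary
    core_labels = rng.integers(0, c, size=n_core)
    core = centroids[core_labels] + rng.normal(0, within_sd, size=(n_core, k))
    pairs = rng.integers(0, c, size=(n_boundary, 2))
    same = pairs[:, 0] == pairs[:, 1]
    pairs[same, 1] = (pairs[same, 0] + 1) % c
    t = rng.uniform(0.35, 0.65, size=n_boundary)[:, None]
    boundary = (
        t * centroids[pairs[:, 0]]
        + (1 - t) * centroids[pairs[:, 1]]
        + rng.normal(0, within_sd / 2, size=(n_boundary, k))
    )
    points = np.vstack([core, boundary])
    d_boundary = np.linalg.norm(boundary[:, None, :] - centroids[None], axis=2)
    labels = np.concatenate([core_labels + 1, np.argmin(d_boundary, axis=1) + 1])
    is_boundary = np.concatenate(
        [np.zeros(n_core, dtype=bool), np.ones(n_boundary, dtype=bool)]
    )
    perm = rng.permutation(n_subjects)
    return points[perm], labels[perm], is_boundary[perm]


def _plant_edges(rng, n_regions, n_factors, per_factor):
    n_edges = n_regions * (n_regions - 1) // 2
    if n_factors * per_factor > n_edges:
        raise ValueError("more planted edges requested than edges exist")
    iu = np.triu_indices(n_regions, k=1)
    chosen = rng.choice(n_edges, size=n_factors * per_factor, replace=False)
    planted = {}
    for f in range(n_factors):
        ids = chosen[f * per_factor : (f + 1) * per_factor]
        planted[f + 1] = [(int(iu[0][e]), int(iu[1][e])) for e in ids]
    return planted


def generate_connectivity(
    true_scores: np.ndarray,
    n_regions: int,
    planted_edge_index: dict,
    edge_effect_size: float = 0.6,
    edge_noise_sd: float = 1.0,
    baseline: float = 0.25,
    seed: int = 0,
) -> list:
    """Per-subject symmetric z-matrices with factor-coupled planted edges.

    A planted edge of factor f follows
    ``z = baseline + effect * standardized_score_f + noise``; every other
    edge is pure noise around the baseline.  Matrices are symmetric with a
    zero diagonal.
    """
    scores = np.asarray(true_scores, dtype=float)
    n_sub, k = scores.shape
    all_edges = [e for edges in planted_edge_index.values() for e in edges]
    if len(set(all_edges)) != len(all_edges):
        raise ValueError("planted edge sets overlap across factors")
    for i, j in all_edges:
        if not 0 <= i < j < n_regions:
            raise ValueError(f"planted edge ({i},{j}) out of range or not i<j")
    rng = np.random.default_rng(seed)
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    z_scores = (scores - scores.mean(axis=0)) / sd
    iu = np.triu_indices(n_regions, k=1)
    n_edges = iu[0].size
    edge_pos = {(int(a), int(b)): e for e, (a, b) in enumerate(zip(*iu))}
    mats = []
    vals = baseline + rng.normal(0.0, edge_noise_sd, size=(n_sub, n_edges))
    for f, edges in planted_edge_index.items():
        cols = [edge_pos[e] for e in edges]
        vals[:, cols] += edge_effect_size * z_scores[:, [f - 1] * len(cols)]
    for s in range(n_sub):
        M = np.zeros((n_regions, n_regions))
        M[iu] = vals[s]
        M = M + M.T
        mats.append(M)
    return mats


def generate_roi_timeseries(
    target_correlation_matrix: np.ndarray,
    n_timepoints: int,
    seed: int = 0,
    diagonal_loading: float = 1e-6,
) -> np.ndarray:
    """Gaussian T x R series whose sample correlation converges to a target.

    The target is diagonally loaded and Cholesky-factored; a clear error is
    raised if it is not positive definite after loading.
    """
    C = np.asarray(target_correlation_matrix, dtype=float)
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("target correlation matrix must be symmetric")
    R = C.shape[0]
    loaded = C + diagonal_loading * np.eye(R)
    try:
        L = np.linalg.cholesky(loaded)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "target correlation matrix is not positive definite after "
            f"diagonal loading ({diagonal_loading}); increase loading or fix the target"
        ) from err
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_timepoints, R)) @ L.T


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full synthetic bundle driven by one config and one seed.

    Stage seeds are spawned deterministically from ``config.seed`` so each
    component is reproducible in isolation.  Covariates add a small linear
    tilt (``covariate_effect`` per standardized age) to the scores before
    rendering, and true soft memberships are fuzzy-membership weights of the
    score vectors relative to the configured subtype centroids.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    W = generate_dictionary(
        config.n_items,
        config.n_factors,
        config.items_per_factor,
        cross_loading=config.cross_loading,
        seed=seeds[0],
    )
    scores = generate_subject_scores(
        config.n_subjects,
        config.n_factors,
        config.loading_correlation,
        seed=seeds[1],
    )
    covariates = generate_covariates(
        config.n_subjects, seed=seeds[2], sex_rate=config.sex_rate
    )
    age_z = (covariates["age"] - covariates["age"].mean()) / covariates["age"].std()
    tilted = np.clip(scores + config.covariate_effect * age_z.to_numpy()[:, None], 0.0, None)
    responses = render_likert(
        tilted,
        W,
        item_noise_sd=config.item_noise_sd,
        likert_levels=config.likert_levels,
        seed=seeds[3],
    )
    centroids = np.asarray(config.subtype_centroids, dtype=float)
    d2 = np.maximum(
        ((scores[:, None, :] - centroids[None]) ** 2).sum(axis=2), 1e-12
    )
    inv = 1.0 / d2
    memberships = inv / inv.sum(axis=1, keepdims=True)
    rng_e = np.random.default_rng(seeds[4])
    planted = _plant_edges(
        rng_e, config.n_regions, config.n_factors, config.planted_edges_per_factor
    )
    connectivity = generate_connectivity(
        scores,
        config.n_regions,
        planted,
        edge_effect_size=config.edge_effect_size,
        edge_noise_sd=config.edge_noise_sd,
        baseline=config.edge_baseline,
        seed=seeds[5],
    )
    labels = np.concatenate(
        [np.full(m, f + 1) for f, m in enumerate(config.items_per_factor)]
    )
    leftover = config.n_items - labels.size
    if leftover:
        labels = np.concatenate([labels, (np.arange(leftover) % config.n_factors) + 1])
    return SyntheticDataset(
        responses=responses,
        true_dictionary=W,
        true_scores=scores,
        true_item_assignment=labels,
        covariates=covariates,
        true_memberships=memberships,
        connectivity=connectivity,
        planted_edge_index=planted,
        config=config,
    )
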