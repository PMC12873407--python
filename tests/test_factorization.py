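"""OPNMF fitting, partition metrics (against brute-force oracles), and
split-half rank selection."""

import itertools
import math
import warnings

import numpy as np
import pytest

import funcmap as fm
from funcmap.factorization import (
    StabilityReport,
    _objective,
    adjusted_rand,
    concordance_index,
    select_rank,
    variation_of_information,
)

# ---------------------------------------------------------------------------
# independent oracles


def set_partitions(items):
    """All set partitions of a sequence (restricted growth strings)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def partition_to_labels(partition, n):
    labels = np.empty(n, dtype=int)
    for g, block in enumerate(partition):
        for i in block:
            labels[i] = g
    return labels


def ari_pair_counting(a, b):
    """Hubert-Arabie adjusted Rand from explicit pair enumeration."""
    n = len(a)
    pairs = list(itertools.combinations(range(n), 2))
    together_a = sum(a[i] == a[j] for i, j in pairs)
    together_b = sum(b[i] == b[j] for i, j in pairs)
    together_both = sum((a[i] == a[j]) and (b[i] == b[j]) for i, j in pairs)
    total = len(pairs)
    expected = together_a * together_b / total
    maximum = 0.5 * (together_a + together_b)
    if maximum == expected:
        return 1.0
    return (together_both - expected) / (maximum - expected)


def vi_direct(a, b):
    """Variation of information from the joint label distribution."""
    n = len(a)
    joint = {}
    for x, y in zip(a, b):
        joint[(x, y)] = joint.get((x, y), 0) + 1
    pa, pb = {}, {}
    for (x, y), c in joint.items():
        pa[x] = pa.get(x, 0) + c
        pb[y] = pb.get(y, 0) + c
    h_a = -sum(c / n * math.log(c / n) for c in pa.values())
    h_b = -sum(c / n * math.log(c / n) for c in pb.values())
    mi = sum(
        c / n * math.log((c / n) / (pa[x] / n * pb[y] / n)) for (x, y), c in joint.items()
    )
    return h_a + h_b - 2 * mi


# ---------------------------------------------------------------------------


class TestOpnmf:
    def test_rank_one_data_fit_exactly(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.uniform(0.1, 1, 10), rng.uniform(0.1, 1, 30))
        model = fm.fit_opnmf(X, 1, seed=0)
        assert model.objective <= 1e-6 * np.sum(X**2)

    def test_block_diagonal_communities_recovered(self):
        X = np.zeros((6, 40))
        X[:3, :20] = 1.0
        X[3:, 20:] = 2.0
        model = fm.fit_opnmf(X, 2, seed=0)
        labels = fm.assign_items(model).labels
        assert adjusted_rand(labels, [1, 1, 1, 2, 2, 2]) == 1.0

    def test_synthetic_item_assignment_recovery(self, small_dataset, fitted_model):
        _, model = fitted_model
        labels = fm.assign_items(model).labels
        assert adjusted_rand(labels, small_dataset.true_item_assignment) >= 0.9

    def test_dictionary_invariants(self, fitted_model):
        _, model = fitted_model
        assert np.all(model.W >= 0)
        assert np.allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-8)
        assert model.objective >= 0

    def test_objective_not_worse_than_init(self, fitted_model):
        X, model = fitted_model
        A = X @ X.T
        # a fresh unit-scaled random start is an upper bound on the final fit
        rng = np.random.default_rng(1)
        W0 = rng.uniform(0.1, 1.0, size=(X.shape[0], 2))
        W0 /= np.linalg.norm(W0, axis=0)
        assert model.objective <= _objective(A, W0, np.trace(A))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            fm.fit_opnmf(np.array([[1.0, -0.5], [0.2, 0.3], [0.1, 0.4]]), 1)

    def test_assignment_invariant_to_rescaling(self, small_dataset):
        X = small_dataset.responses.T.astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = fm.assign_items(fm.fit_opnmf(X, 2, seed=0)).labels
            b = fm.assign_items(fm.fit_opnmf(3.7 * X, 2, seed=0)).labels
        assert adjusted_rand(a, b) == 1.0


class TestAssignItems:
    def test_argmax_and_tie_rules(self):
        W = np.array([[0.9, 0.1], [0.5, 0.5], [0.0, 1.0]])
        model = fm.FactorModel(W=W, H=None, k=2, objective=0.0, n_iter=1, converged=True)
        assign = fm.assign_items(model)
        assert assign.labels.tolist() == [1, 1, 2]
        assert assign.ties == [1]

    def test_identity_dictionary_is_bijection(self):
        W = np.eye(3)
        model = fm.FactorModel(W=W, H=None, k=3, objective=0.0, n_iter=1, converged=True)
        labels = fm.assign_items(model).labels
        assert sorted(labels.tolist()) == [1, 2, 3]

    def test_zero_row_rejected(self):
        W = np.array([[0.0, 0.0], [1.0, 0.0]])
        model = fm.FactorModel(W=W, H=None, k=2, objective=0.0, n_iter=1, converged=True)
        with pytest.raises(ValueError):
            fm.assign_items(model)


class TestPartitionMetrics:
    def test_identical_and_relabeled_partitions(self):
        a = [1, 1, 2, 2, 3]
        assert adjusted_rand(a, a) == 1.0
        assert adjusted_rand(a, [2, 2, 3, 3, 1]) == 1.0
        assert variation_of_information(a, a) == 0.0

    def test_crossed_partition_example(self):
        a, b = [1, 1, 2, 2], [1, 2, 1, 2]
        assert adjusted_rand(a, b) == pytest.approx(ari_pair_counting(a, b))
        assert variation_of_information(a, b) == pytest.approx(vi_direct(a, b))

    def test_vi_closed_form_extremes(self):
        n = 6
        ones = [1] * n
        singletons = list(range(n))
        assert variation_of_information(ones, singletons) == pytest.approx(math.log(n))

    def test_against_bruteforce_on_all_partitions(self):
        # every pair of set partitions of 5 items
        parts = [partition_to_labels(p, 5) for p in set_partitions(range(5))]
        for a in parts:
            for b in parts:
                assert adjusted_rand(a, b) == pytest.approx(ari_pair_counting(a, b), abs=1e-12)
                assert variation_of_information(a, b) == pytest.approx(vi_direct(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            variation_of_information([1, 2], [1, 2, 3])


class TestConcordance:
    def test_column_permutation_recovered(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(0, 1, size=(10, 3))
        assert concordance_index(W, W[:, [2, 0, 1]]) == pytest.approx(1.0)

    def test_orthogonal_replacement_halves_score(self):
        W_a = np.zeros((4, 2))
        W_a[0, 0] = 1.0
        W_a[1, 1] = 1.0
        W_b = W_a.copy()
        W_b[:, 1] = [0.0, 0.0, 1.0, 0.0]  # orthogonal to both columns of W_a
        assert concordance_index(W_a, W_b) == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_bruteforce_over_permutations(self, k):
        rng = np.random.default_rng(k)
        W_a = rng.uniform(0, 1, size=(8, k))
        W_b = rng.uniform(0, 1, size=(8, k))
        na = W_a / np.linalg.norm(W_a, axis=0)
        nb = W_b / np.linalg.norm(W_b, axis=0)
        C = na.T @ nb
        brute = max(
            np.mean([C[i, p[i]] for i in range(k)])
            for p in itertools.permutations(range(k))
        )
        assert concordance_index(W_a, W_b) == pytest.approx(brute)


class TestSplitHalf:
    def test_noiseless_two_factor_data_fully_stable(self):
        cfg = fm.SyntheticConfig(
            n_subjects=200, item_noise_sd=0.0, seed=3, n_regions=6, planted_edges_per_factor=2
        )
        ds = fm.generate_dataset(cfg)
        X = ds.responses.T.astype(float)
        report = fm.split_half_stability(X, k_range=(2,), n_splits=50, seed=0)
        rec = report.records
        assert rec.loc[rec.metric == "ari", "value"].median() == 1.0
        assert rec.loc[rec.metric == "vi", "value"].median() == 0.0

    def test_delta_re_nonnegative_in_expectation(self, small_dataset):
        X = small_dataset.responses.T.astype(float)
        report = fm.split_half_stability(X, k_range=(2,), n_splits=50, seed=1)
        dre = report.records.query("metric == 'delta_re'")["value"]
        assert dre.mean() >= 0

    def test_seeded_repeat_identical(self, small_dataset):
        X = small_dataset.responses.T.astype(float)
        a = fm.split_half_stability(X, k_range=(2, 3), n_splits=5, seed=4)
        b = fm.split_half_stability(X, k_range=(2, 3), n_splits=5, seed=4)
        assert a.records.equals(b.records)

    def test_sensitivity_to_item_deletion(self, small_dataset):
        # dropping an item subset must not break the two-factor structure
        X = small_dataset.responses.T.astype(float)
        keep = np.setdiff1d(np.arange(29), [0, 5, 17, 28])
        report = fm.split_half_stability(X[keep], k_range=(2, 3, 4), n_splits=30, seed=2)
        assert select_rank(report)["selected_k"] == 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = fm.fit_opnmf(X[keep], 2, seed=0)
        labels = fm.assign_items(model).labels
        truth = small_dataset.true_item_assignment[keep]
        assert adjusted_rand(labels, truth) >= 0.9


def _report_from_medians(medians):
    import pandas as pd

    rows = []
    for k, (ari, ci, vi, dre) in medians.items():
        rows += [(k, 0, "ari", ari), (k, 0, "ci", ci), (k, 0, "vi", vi), (k, 0, "delta_re", dre)]
    return StabilityReport(
        records=pd.DataFrame(rows, columns=["k", "split", "metric", "value"]),
        k_range=tuple(medians),
        n_splits=1,
        seed=0,
    )


class TestSelectRank:
    def test_dominating_rank_selected(self):
        report = _report_from_medians({2: (0.9, 0.9, 0.1, 0.01), 3: (0.5, 0.6, 0.8, 0.05)})
        assert select_rank(report)["selected_k"] == 2

    def test_exact_tie_prefers_smaller_rank(self):
        report = _report_from_medians({2: (0.7, 0.7, 0.3, 0.02), 3: (0.7, 0.7, 0.3, 0.02)})
        assert select_rank(report)["selected_k"] == 2

    def test_single_candidate_noted(self):
        report = _report_from_medians({2: (0.7, 0.7, 0.3, 0.02)})
        out = select_rank(report)
        assert out["selected_k"] == 2
        assert out["note"] == "single-candidate"


class TestConsistency:
    def test_factor_items_sharing_signal_are_consistent(self, small_dataset, fitted_model):
        X, model = fitted_model
        report = fm.bootstrap_consistency(X, model, n_boot=200, seed=0)
        assert (report.summary["mean_r"] >= 0.6).all()

    def test_independent_items_are_not(self):
        X = np.random.default_rng(0).integers(0, 5, size=(29, 300)).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = fm.fit_opnmf(X, 2, seed=0)
        report = fm.bootstrap_consistency(X, model, n_boot=200, seed=0)
        assert report.summary["mean_r"].abs().max() <= 0.1

    def test_seeded_repeat_identical(self, fitted_model):
        X, model = fitted_model
        a = fm.bootstrap_consistency(X, model, n_boot=100, seed=5)
        b = fm.bootstrap_consistency(X, model, n_boot=100, seed=5)
        assert a.summary.equals(b.summary)


class TestSubjectLoadings:
    def test_raw_scores_are_within_factor_sums(self, fitted_model):
        _, model = fitted_model
        labels = fm.assign_items(model).labels
        x = np.zeros(29)
        x[labels == 1] = 4.0
        _, raw = fm.subject_loadings(model, x[:, None])
        assert raw[0, 0] == 4.0 * (labels == 1).sum()
        assert raw[0, 1] == 0.0

    def test_zero_subject_zero_everything(self, fitted_model):
        _, model = fitted_model
        loadings, raw = fm.subject_loadings(model, np.zeros((29, 1)))
        assert np.all(loadings == 0) and np.all(raw == 0)

    def test_loadings_track_true_scores(self):
        cfg = fm.SyntheticConfig(
            n_subjects=300, item_noise_sd=0.0, seed=9, n_regions=6, planted_edges_per_factor=2
        )
        ds = fm.generate_dataset(cfg)
        X = ds.responses.T.astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = fm.fit_opnmf(X, 2, seed=0)
        loadings, _ = fm.subject_loadings(model, X, normalization_mode="none")
        labels = fm.assign_items(model).labels
        truth = ds.true_item_assignment
        # match fitted factors to true factors through the item assignment
        for f in (1, 2):
            true_f = np.argmax([np.sum((labels == g) & (truth == f)) for g in (1, 2)]) + 1
            r = np.corrcoef(loadings[:, true_f - 1], ds.true_scores[:, f - 1])[0, 1]
            assert r >= 0.95

    def test_unknown_mode_rejected(self, fitted_model):
        _, model = fitted_model
        with pytest.raises(ValueError):
            fm.subject_loadings(model, np.zeros((29, 1)), normalization_mode="bogus")
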