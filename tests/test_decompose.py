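"""Factorization core: SIMPLISMA selection, MCR-ALS, NMF, PCA, VAF.

Independent oracles: brute-force purity scan for SIMPLISMA, scipy's
Lawson–Hanson NNLS (the in-package solver enumerates active sets), an
alternating per-column scipy-NNLS loop for the MCR-ALS objective, and a
singular-value decomposition for PCA.
"""

import numpy as np
import pytest
from scipy import optimize
from sklearn.base import clone

from synergykit._matching import match_columns, mean_matched_cc
from synergykit.decompose import (
    MCRALS,
    StoppingRule,
    SynergyNMF,
    SynergyPCA,
    _nnls_columns,
    mcr_als,
    nmf,
    pca_synergy,
    select_order,
    simplisma_select,
    vaf,
)
from synergykit.errors import ArgumentError, DegeneracyError, UndefinedMetricError


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def _scipy_nnls_columns(C, D):
    return np.column_stack([optimize.nnls(C, D[:, j])[0] for j in range(D.shape[1])])


def _simplisma_bruteforce(D, r, alpha):
    """Literal purity scan: explicit loops and explicit determinants."""
    m, n = D.shape
    mu = D.mean(axis=0)
    sigma = D.std(axis=0)
    offset = alpha * mu.max()
    lam = np.sqrt(mu**2 + (sigma + offset) ** 2)
    Y = D / np.where(lam > 0, lam, 1.0)
    selected = []
    for j in range(r):
        best, best_p = -1, -np.inf
        for i in range(n):
            if i in selected:
                continue
            if j == 0:
                omega = 1.0
            else:
                cols = np.column_stack([Y[:, i]] + [Y[:, s] for s in selected])
                omega = max(np.linalg.det((cols.T @ cols) / m), 0.0)
            p = omega * sigma[i] / (mu[i] + offset)
            if p > best_p:
                best, best_p = i, p
        selected.append(best)
    return selected


# ---------------------------------------------------------------------------
# SIMPLISMA
# ---------------------------------------------------------------------------

class TestSimplisma:
    def test_matches_bruteforce_oracle(self, noiseless_day1):
        D = noiseless_day1[0].values[:, :1200]  # keep the scan affordable
        state = simplisma_select(D, 2, alpha=0.03)
        assert state.selected.tolist() == _simplisma_bruteforce(D, 2, 0.03)

    def test_selected_columns_are_single_synergy_samples(
        self, noiseless_truth, noiseless_day1
    ):
        D = noiseless_day1[0].values
        state = simplisma_select(D, 2, alpha=0.03)
        S = noiseless_truth.S_true
        for idx in state.selected:
            active = S[:, idx]
            # exactly one synergy carries the sample
            assert np.sort(active)[-1] > 0
            assert np.sort(active)[0] <= 0.05 * S.max()

    def test_initial_c_recovers_true_directions(
        self, noiseless_truth, noiseless_day1
    ):
        state = simplisma_select(noiseless_day1[0].values, 2)
        _, ccs = match_columns(noiseless_truth.C_true, state.C_init)
        assert np.all(ccs >= 0.99)

    def test_proportional_column_cannot_be_selected_twice(self):
        # second column is an exact multiple of the first: its determinant
        # weight vanishes once the direction is taken
        base = np.array([1.0, 2.0, 0.5])
        other = np.array([0.1, 0.1, 3.0])
        D = np.column_stack([base, 2 * base, other, 0.5 * other, base + other])
        state = simplisma_select(D, 2, alpha=0.03)
        dirs = {0: 0, 1: 0, 2: 1, 3: 1}
        picked = [dirs.get(i) for i in state.selected]
        assert picked[0] != picked[1]
        # every column collinear with the first selection is weighted out
        sel0 = state.selected[0]
        partner = {0: 1, 1: 0, 2: 3, 3: 2}[sel0]
        assert state.weights[1][sel0] < 1e-12
        assert state.weights[1][partner] < 1e-12

    def test_constant_column_has_zero_purity(self):
        D = np.column_stack(
            [np.ones(3), np.array([1.0, 0.1, 0.2]), np.array([0.2, 1.3, 0.1])]
        )
        state = simplisma_select(D, 2)
        assert state.purity[0][0] == 0.0
        assert 0 not in state.selected

    def test_rank_deficient_request_raises(self):
        col = np.array([1.0, 2.0, 3.0])
        D = np.column_stack([col, 2 * col, 3 * col, 0.5 * col])
        with pytest.raises(DegeneracyError):
            simplisma_select(D, 2)


# ---------------------------------------------------------------------------
# NNLS solver
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_active_set_nnls_matches_lawson_hanson(seed):
    rng = np.random.default_rng(seed)
    A = np.abs(rng.standard_normal((4, 3)))
    B = rng.standard_normal((4, 30))
    S_fast = _nnls_columns(A, B)
    S_ref = _scipy_nnls_columns(A, B)
    assert np.all(S_fast >= 0)
    res_fast = np.sum((B - A @ S_fast) ** 2, axis=0)
    res_ref = np.sum((B - A @ S_ref) ** 2, axis=0)
    assert np.allclose(res_fast, res_ref, rtol=1e-10, atol=1e-12)


# ---------------------------------------------------------------------------
# MCR-ALS
# ---------------------------------------------------------------------------

class TestMCRALS:
    def test_exact_factorization_recovered_noiseless(self, small_rank2):
        dec = mcr_als(small_rank2, 2)
        D = small_rank2
        assert np.linalg.norm(D - dec.C @ dec.S) < 1e-8 * np.linalg.norm(D)
        assert dec.vaf == pytest.approx(1.0, abs=1e-10)

    def test_repeated_runs_bit_identical(self, noisy_day1):
        D = noisy_day1[0].values
        a, b = mcr_als(D, 2), mcr_als(D, 2)
        assert np.array_equal(a.C, b.C)
        assert np.array_equal(a.S, b.S)

    def test_objective_trace_non_increasing(self, noisy_day1):
        dec = mcr_als(noisy_day1[0].values, 2)
        tr = dec.objective_trace
        assert np.all(np.diff(tr) <= 1e-10 * tr[0])

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_converged_objective_matches_alternating_nnls_oracle(self, seed):
        C = np.array([[1.0, 0.1], [0.7, 0.4], [0.05, 1.0]])
        t = np.linspace(0, 4 * np.pi, 50)
        S = np.vstack(
            [np.clip(np.sin(t), 0, None), np.clip(np.sin(t + np.pi), 0, None)]
        )
        rng = np.random.default_rng(seed)
        D = np.clip(C @ S + 0.05 * rng.standard_normal((3, 50)), 0, None) + 1e-6
        dec = mcr_als(D, 2, stop=StoppingRule(q_tol=1e-9, max_iter=3000))
        Cc = simplisma_select(D, 2).C_init.copy()
        for _ in range(500):
            Sc = _scipy_nnls_columns(Cc, D)
            Cc = _scipy_nnls_columns(Sc.T, D.T).T
        f_oracle = 0.5 * np.sum((D - Cc @ Sc) ** 2)
        assert dec.objective_trace[-1] == pytest.approx(f_oracle, rel=1e-6)

    def test_factors_nonnegative(self, noisy_day1):
        dec = mcr_als(noisy_day1[0].values, 2)
        assert np.all(dec.C >= 0)
        assert np.all(dec.S >= 0)

    def test_project_mode_runs(self, small_rank2):
        dec = mcr_als(small_rank2, 2, mode="project")
        assert dec.vaf > 0.99
        assert np.all(dec.C >= 0) and np.all(dec.S >= 0)

    def test_recorded_vaf_consistent_with_reconstruction(self, noisy_day1):
        D = noisy_day1[0].values
        dec = mcr_als(D, 2)
        assert dec.vaf == pytest.approx(vaf(D, dec.reconstruction()), abs=1e-12)


# ---------------------------------------------------------------------------
# NMF
# ---------------------------------------------------------------------------

class TestNMF:
    @pytest.mark.parametrize("seed", range(10))
    def test_objective_non_increasing_every_seed(self, small_rank2, seed):
        dec = nmf(small_rank2 + 1e-9, 2, seed=seed)
        tr = dec.objective_trace
        assert np.all(np.diff(tr) <= 1e-10 * (tr[0] + 1e-300))
        assert dec.n_iter <= 1000

    def test_exact_rank_r_data_fit_well_across_seeds(self, small_rank2):
        vafs = [nmf(small_rank2, 2, seed=s).vaf for s in range(10)]
        assert min(vafs) >= 0.999  # no local optimum observed at this size

    def test_stopping_rule_honored(self, noisy_day1):
        dec = nmf(noisy_day1[0].values, 2, seed=1)
        assert dec.n_iter <= 1000
        if dec.n_iter < 1000:
            tr = dec.objective_trace
            q = 100.0 * (tr[-1] - tr[-2]) / tr[-2]
            assert abs(q) <= 0.01 or tr[-1] <= 1e-20 * tr[0]

    def test_same_seed_reproducible(self, small_rank2):
        a, b = nmf(small_rank2, 2, seed=3), nmf(small_rank2, 2, seed=3)
        assert np.array_equal(a.C, b.C)

    def test_factors_nonnegative(self, noisy_day1):
        dec = nmf(noisy_day1[0].values, 2, seed=2)
        assert np.all(dec.C >= 0) and np.all(dec.S >= 0)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def test_complete_basis_reconstructs_exactly(self, noisy_day1):
        D = noisy_day1[0].values
        dec = pca_synergy(D, 3)
        assert np.allclose(dec.reconstruction(), D, atol=1e-10)
        assert dec.vaf == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalues_sorted_descending(self, noisy_day1):
        dec = pca_synergy(noisy_day1[0].values, 2)
        assert np.all(np.diff(dec.eigenvalues) <= 1e-12)

    def test_components_match_svd_oracle(self):
        D = np.abs(np.random.default_rng(2).standard_normal((3, 200)))
        dec = pca_synergy(D, 2)
        X = D - D.mean(axis=1, keepdims=True)
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        for k in range(2):
            ref = s[k] * Vt[k]
            err = min(
                np.max(np.abs(dec.S[k] - ref)), np.max(np.abs(dec.S[k] + ref))
            )
            assert err <= 1e-8 * np.max(np.abs(ref))

    def test_vaf_non_decreasing_in_k(self, noisy_day1):
        D = noisy_day1[0].values
        vafs = [pca_synergy(D, k).vaf for k in (1, 2, 3)]
        assert np.all(np.diff(vafs) >= -1e-12)

    def test_sign_convention(self, noisy_day1):
        dec = pca_synergy(noisy_day1[0].values, 3)
        for k in range(3):
            col = dec.C[:, k]
            assert col[np.argmax(np.abs(col))] > 0


# ---------------------------------------------------------------------------
# VAF and order selection
# ---------------------------------------------------------------------------

class TestVAF:
    def test_perfect_reconstruction(self, noisy_day1):
        D = noisy_day1[0].values
        assert vaf(D, D) == pytest.approx(1.0)

    def test_column_mean_baseline_is_zero(self, noisy_day1):
        D = noisy_day1[0].values
        M = np.broadcast_to(D.mean(axis=0, keepdims=True), D.shape)
        assert vaf(D, M) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # mean(D) column-wise: [[2,3],[2,3]]; den = 4, num = 1
        D = np.array([[1.0, 2.0], [3.0, 4.0]])
        M = np.array([[1.0, 2.0], [3.0, 5.0]])
        assert vaf(D, M) == pytest.approx(0.75)

    def test_constant_d_undefined(self):
        with pytest.raises(UndefinedMetricError):
            vaf(np.ones((2, 4)), np.ones((2, 4)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ArgumentError):
            vaf(np.ones((2, 4)), np.ones((2, 5)))


class TestSelectOrder:
    def test_rank_one_data(self):
        c = np.array([[1.0], [0.5], [0.2]])
        s = np.abs(np.sin(np.linspace(0, 6, 100)))[None, :]
        assert select_order(c @ s) == 1

    def test_default_fixture_needs_two(self, noisy_day1):
        assert select_order(noisy_day1[0].values) == 2

    def test_unreachable_threshold_warns_and_returns_r_max(self, noisy_day1):
        with pytest.warns(UserWarning):
            r = select_order(
                noisy_day1[0].values, method="pca", vaf_threshold=1.0
            )
        assert r == 3


# ---------------------------------------------------------------------------
# scikit-learn estimator surface
# ---------------------------------------------------------------------------

class TestEstimators:
    def test_mcrals_estimator_round_trip(self, noisy_day1):
        X = noisy_day1[0].values.T  # samples x channels
        est = MCRALS(n_synergies=2).fit(X)
        A = est.transform(X)
        assert A.shape == (X.shape[0], 2)
        # transform re-solves S against the final C (the stored
        # activations were computed one ALS half-step earlier)
        assert np.allclose(A, est.activations_, atol=1e-3)
        assert est.synergies_.shape == (3, 2)

    def test_estimators_clonable_with_params(self):
        for est in (MCRALS(alpha=0.02), SynergyNMF(random_state=4), SynergyPCA()):
            c = clone(est)
            assert c.get_params() == est.get_params()

    def test_pca_estimator_matches_function(self, noisy_day1):
        D = noisy_day1[0].values
        est = SynergyPCA(n_components=2).fit(D.T)
        dec = pca_synergy(D, 2)
        assert np.allclose(est.components_, dec.C.T, atol=1e-12)
        assert np.allclose(est.transform(D.T), dec.S.T, atol=1e-10)

    def test_nmf_estimator_seed_controls_result(self, small_rank2):
        X = small_rank2.T
        a = SynergyNMF(random_state=0).fit(X)
        b = SynergyNMF(random_state=0).fit(X)
        assert np.array_equal(a.components_, b.components_)


def test_mcr_beats_chance_on_noisy_fixture(truth, noisy_day1):
    """Noisy-day recovery: extracted synergies stay close to the truth."""
    dec = mcr_als(noisy_day1[0].values, 2)
    cc = mean_matched_cc(truth.C_true, dec.C)
    assert cc > 0.95
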