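"""Muscle-synergy extraction from envelope matrices.

The core factorization is MCR-ALS: the envelope matrix D (m channels x n
samples) is resolved as D ~= C S with C (m x r) the synergy matrix and S
(r x n) the activation coefficients, alternating exact non-negative
least-squares updates of C and S from a deterministic SIMPLISMA
pure-variable initialization.  Because the initialization has no random
state, repeated decompositions of the same data are bit-identical — the
property that makes the extracted activations usable as stable neural-
network features across sessions.  NMF (random-start multiplicative
updates) and PCA (unconstrained eigendecomposition) are provided as the
classical baselines whose non-uniqueness / sign indeterminacy MCR-ALS
removes.

Estimator classes (:class:`MCRALS`, :class:`SynergyNMF`,
:class:`SynergyPCA`) follow scikit-learn conventions (samples as rows,
``fit``/``transform``, trailing-underscore fitted attributes) so they
compose with pipelines; the module-level functions keep the field's
channels-as-rows convention for D.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ArgumentError, DataError, DegeneracyError, UndefinedMetricError
from .preprocess import EnvelopeMatrix

__all__ = [
    "SynergyDecomposition",
    "PurityState",
    "StoppingRule",
    "simplisma_select",
    "mcr_als",
    "nmf",
    "pca_synergy",
    "vaf",
    "select_order",
    "MCRALS",
    "SynergyNMF",
    "SynergyPCA",
]


@dataclass
class StoppingRule:
    """Relative-change stopping criterion shared by NMF and MCR-ALS.

    Iteration stops when the percent change of the objective between
    successive iterations, Q = 100 (f_{l+1} - f_l) / f_l, satisfies
    |Q| <= q_tol, or after max_iter iterations.
    """

    q_tol: float = 0.01   # percent
    max_iter: int = 1000

    def __post_init__(self):
        if self.q_tol <= 0:
            raise ArgumentError("q_tol must be positive")
        if self.max_iter < 1:
            raise ArgumentError("max_iter must be at least 1")


@dataclass
class SynergyDecomposition:
    """Result of one synergy extraction.

    ``C`` (m x r) holds the synergy weight vectors as columns, ``S``
    (r x n) the activation coefficient time courses as rows.  For PCA,
    ``mean`` stores the per-channel means removed before projection and
    the reconstruction is C S + mean; for the non-negative methods the
    reconstruction is C S.
    """

    C: np.ndarray
    S: np.ndarray
    method: str
    r: int
    n_iter: int
    objective_trace: np.ndarray
    vaf: float
    mean: np.ndarray | None = None
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    def reconstruction(self) -> np.ndarray:
        M = self.C @ self.S
        if self.mean is not None:
            M = M + self.mean[:, None]
        return M


@dataclass
class PurityState:
    """SIMPLISMA pure-variable selection record.

    Row j of ``purity`` / ``weights`` holds the per-candidate purity
    p_i = omega_i sigma_i / (mu_i + alpha mu_max) and determinant weight
    omega_i used for the j-th selection; ``selected`` the chosen time-
    sample indices in selection order; ``C_init`` the channel-intensity
    vectors of the selected columns.
    """

    purity: np.ndarray
    weights: np.ndarray
    alpha: float
    selected: np.ndarray
    C_init: np.ndarray


def _as_matrix(D) -> np.ndarray:
    if isinstance(D, EnvelopeMatrix):
        return D.values
    D = np.asarray(D, dtype=float)
    if D.ndim != 2:
        raise ArgumentError("D must be 2-D (channels x samples)")
    if not np.all(np.isfinite(D)):
        raise DataError("D contains non-finite values")
    return D


def _require_nonnegative(D: np.ndarray):
    if np.any(D < 0):
        raise DataError("D must be non-negative for this method")


# ---------------------------------------------------------------------------
# non-negative least squares
# ---------------------------------------------------------------------------

def _nnls_columns(C: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Exact solution of min_{S >= 0} ||D - C S||_F, column by column.

    For small r the optimum is found by enumerating active sets: the
    NNLS solution restricted to its support solves the unconstrained
    least-squares problem on that support, so scanning all 2^r - 1
    supports (vectorized across all n columns at once) and keeping the
    best feasible candidate is exact.  For larger r this falls back to
    scipy's Lawson–Hanson solver per column.
    """
    m, r = C.shape
    n = D.shape[1]
    if r > 8:
        S = np.empty((r, n))
        for j in range(n):
            S[:, j] = optimize.nnls(C, D[:, j])[0]
        return S

    best_res = np.sum(D * D, axis=0)  # s = 0 candidate
    best_S = np.zeros((r, n))
    for k in range(1, r + 1):
        for support in itertools.combinations(range(r), k):
            Ct = C[:, support]
            G = Ct.T @ Ct
            B = Ct.T @ D
            try:
                St = np.linalg.solve(G, B)
            except np.linalg.LinAlgError:
                St = np.linalg.pinv(G) @ B
            resid = D - Ct @ St
            res = np.sum(resid * resid, axis=0)
            feasible = np.all(St >= 0, axis=0)
            better = feasible & (res < best_res - 1e-15 * (1 + best_res))
            if np.any(better):
                best_res[better] = res[better]
                best_S[:, better] = 0.0
                best_S[np.ix_(list(support), np.flatnonzero(better))] = St[
                    :, better
                ]
    return best_S


# ---------------------------------------------------------------------------
# SIMPLISMA pure-variable selection
# ---------------------------------------------------------------------------

def simplisma_select(D, r: int, alpha: float = 0.03) -> PurityState:
    """Select r pure time samples and form the initial synergy matrix.

    A pure variable is a time sample at which (ideally) a single synergy
    is active, so its channel-intensity vector is proportional to that
    synergy's weight vector.  Candidates are ranked by the purity
    p_i = omega_i * sigma_i / (mu_i + alpha * max(mu)), with mu_i and
    sigma_i the mean and standard deviation of column i across channels
    and alpha a small noise offset (fractions of the largest mean,
    typically 0.01-0.05).  The determinant weight omega_i — the
    determinant of the correlation-around-the-origin matrix of the
    length-scaled candidate column joined with the already-selected
    columns — suppresses candidates linearly dependent on previous
    selections (omega is identically 1 for the first pick; exact ties
    resolve to the lowest index).  The selected columns of D become the
    columns of the initial C.
    """
    D = _as_matrix(D)
    _require_nonnegative(D)
    m, n = D.shape
    if r < 1 or r > min(m, n):
        raise ArgumentError(f"r={r} must be in 1..min(m, n)={min(m, n)}")
    if alpha <= 0:
        raise ArgumentError("alpha must be positive")

    mu = D.mean(axis=0)
    sigma = D.std(axis=0)  # population sd, 1/m normalization
    mu_max = float(mu.max())
    if mu_max == 0:
        raise DegeneracyError("D is identically zero; no pure variables")
    offset = alpha * mu_max
    base_purity = sigma / (mu + offset)

    # length-scaled columns for the determinant weight
    lam = np.sqrt(mu**2 + (sigma + offset) ** 2)
    lam_safe = np.where(lam > 0, lam, 1.0)
    Y = D / lam_safe

    purity_rows = np.empty((r, n))
    weight_rows = np.empty((r, n))
    selected: list[int] = []
    for j in range(r):
        if j == 0:
            omega = np.ones(n)
        else:
            Ys = Y[:, selected]                      # m x j
            A = (Ys.T @ Ys) / m                      # j x j
            det_A = float(np.linalg.det(A))
            B = (Ys.T @ Y) / m                       # j x n
            try:
                AinvB = np.linalg.solve(A, B)
            except np.linalg.LinAlgError:
                AinvB = np.linalg.pinv(A) @ B
            a_ii = np.sum(Y * Y, axis=0) / m
            # Schur complement: det([[a_ii, b^T], [b, A]]) over candidates
            omega = np.clip(det_A * (a_ii - np.sum(B * AinvB, axis=0)), 0.0, None)
        p = omega * base_purity
        p[selected] = -np.inf
        purity_rows[j] = np.where(np.isneginf(p), 0.0, p)
        weight_rows[j] = omega
        idx = int(np.argmax(p))
        if not np.isfinite(p[idx]) or p[idx] <= 1e-12 * max(base_purity.max(), 1.0):
            raise DegeneracyError(
                f"only {j} distinguishable pure variables found "
                f"(requested r={r}); data may be rank deficient"
            )
        selected.append(idx)

    sel = np.asarray(selected, dtype=int)
    return PurityState(
        purity=purity_rows,
        weights=weight_rows,
        alpha=alpha,
        selected=sel,
        C_init=D[:, sel].copy(),
    )


# ---------------------------------------------------------------------------
# factorizations
# ---------------------------------------------------------------------------

def _objective(D, C, S) -> float:
    R = D - C @ S
    return 0.5 * float(np.sum(R * R))


def _run_als(D, C, stop, update_S, update_C):
    """Shared alternating loop with the |Q| <= q_tol stopping rule."""
    trace = []
    S = None
    converged = False
    f_prev = None
    n_iter = 0
    # exact-fit floor: an objective this far below the data energy is a
    # numerically perfect factorization and Q becomes 0/0 noise
    f_floor = 1e-24 * (0.5 * float(np.sum(D * D)) + 1e-300)
    for n_iter in range(1, stop.max_iter + 1):
        S = update_S(C)
        C = update_C(S)
        f = _objective(D, C, S)
        trace.append(f)
        if f <= f_floor:
            converged = True
            break
        if f_prev is not None:
            q = 100.0 * (f - f_prev) / f_prev
            if abs(q) <= stop.q_tol:
                converged = True
                break
        f_prev = f
    return C, S, np.asarray(trace), n_iter, converged


def mcr_als(
    D,
    r: int,
    stop: StoppingRule | None = None,
    alpha: float = 0.03,
    mode: str = "exact",
) -> SynergyDecomposition:
    """MCR-ALS synergy extraction with SIMPLISMA initialization.

    Starting from the deterministic pure-variable initial C, alternately
    solves the two conditional least-squares problems
    S = argmin ||D - C S|| and C = argmin ||D - C S|| under
    non-negativity, until the relative objective change |Q| falls below
    ``stop.q_tol`` percent or ``stop.max_iter`` iterations.

    mode="exact" (default) solves each subproblem by exact non-negative
    least squares, which makes the objective trace provably
    non-increasing.  mode="project" applies the unconstrained normal-
    equation updates C = D S^T (S S^T)^-1, S = (C^T C)^-1 C^T D and
    clips negatives to zero — cheaper, but monotonicity is no longer
    guaranteed.

    The procedure has no random state: repeated calls on identical input
    return bit-identical factors.
    """
    D = _as_matrix(D)
    _require_nonnegative(D)
    if r < 1:
        raise ArgumentError("r must be at least 1")
    stop = stop or StoppingRule()
    if mode not in ("exact", "project"):
        raise ArgumentError(f"unknown mode {mode!r}")

    state = simplisma_select(D, r, alpha)
    C0 = state.C_init
    notes = [f"simplisma pure variables at columns {state.selected.tolist()}"]

    if mode == "exact":
        update_S = lambda C: _nnls_columns(C, D)            # noqa: E731
        update_C = lambda S: _nnls_columns(S.T, D.T).T      # noqa: E731
    else:
        def update_S(C):
            G = C.T @ C
            try:
                S = np.linalg.solve(G, C.T @ D)
            except np.linalg.LinAlgError:
                S = np.linalg.pinv(G) @ (C.T @ D)
                notes.append("singular normal equations in S update")
            return np.clip(S, 0.0, None)

        def update_C(S):
            G = S @ S.T
            try:
                C = np.linalg.solve(G, S @ D.T).T
            except np.linalg.LinAlgError:
                C = (np.linalg.pinv(G) @ (S @ D.T)).T
                notes.append("singular normal equations in C update")
            return np.clip(C, 0.0, None)

    C, S, trace, n_iter, converged = _run_als(D, C0, stop, update_S, update_C)
    return SynergyDecomposition(
        C=C,
        S=S,
        method="mcr_als",
        r=r,
        n_iter=n_iter,
        objective_trace=trace,
        vaf=vaf(D, C @ S),
        converged=converged,
        notes=notes,
    )


def nmf(
    D,
    r: int,
    stop: StoppingRule | None = None,
    seed: int = 0,
) -> SynergyDecomposition:
    """Random-start NMF by multiplicative (Lee–Seung) updates.

    Minimizes f(S, C) = 1/2 ||D - C S||_F^2 from uniform(0, 1] initial
    factors drawn with ``seed``, stopping on the same |Q| <= q_tol rule
    as MCR-ALS.  Different seeds can converge to differently ordered and
    scaled factors — the non-uniqueness that motivates the deterministic
    MCR-ALS alternative.
    """
    D = _as_matrix(D)
    _require_nonnegative(D)
    if r < 1:
        raise ArgumentError("r must be at least 1")
    stop = stop or StoppingRule()
    eps = 1e-12
    rng = np.random.default_rng(seed)
    m, n = D.shape
    C = 1.0 - rng.random((m, r))   # uniform (0, 1]
    S = 1.0 - rng.random((r, n))

    trace = []
    converged = False
    f_prev = None
    n_iter = 0
    f_floor = 1e-24 * (0.5 * float(np.sum(D * D)) + 1e-300)
    for n_iter in range(1, stop.max_iter + 1):
        S *= (C.T @ D) / (C.T @ C @ S + eps)
        C *= (D @ S.T) / (C @ (S @ S.T) + eps)
        f = _objective(D, C, S)
        trace.append(f)
        if f <= f_floor:
            converged = True
            break
        if f_prev is not None:
            q = 100.0 * (f - f_prev) / f_prev
            if abs(q) <= stop.q_tol:
                converged = True
                break
        f_prev = f
    return SynergyDecomposition(
        C=C,
        S=S,
        method="nmf",
        r=r,
        n_iter=n_iter,
        objective_trace=np.asarray(trace),
        vaf=vaf(D, C @ S),
        converged=converged,
    )


def pca_synergy(D, k: int) -> SynergyDecomposition:
    """PCA baseline: top-k eigenvectors of the channel covariance.

    C's columns are the eigenvectors of the m x m covariance of the
    channel signals over time, sorted by descending eigenvalue, each
    sign-fixed so its largest-magnitude entry is positive; S = C^T
    (D - mean) are the component time courses.  No non-negativity
    constraint applies.  The reconstruction is C S + mean.
    """
    D = _as_matrix(D)
    m, n = D.shape
    if k < 1 or k > m:
        raise ArgumentError(f"k={k} must be in 1..m={m}")
    mean = D.mean(axis=1)
    X = D - mean[:, None]
    V = (X @ X.T) / max(n - 1, 1)
    evals, evecs = np.linalg.eigh(V)       # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    notes = []
    if m > 1 and np.any(
        np.isclose(evals[:-1], evals[1:], rtol=1e-10, atol=1e-14)
    ):
        notes.append(
            "repeated eigenvalues: eigenspace basis is not unique"
        )
    C = evecs[:, :k]
    # deterministic sign: largest-magnitude entry of each eigenvector > 0
    signs = np.sign(C[np.argmax(np.abs(C), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    C = C * signs
    S = C.T @ X
    M = C @ S + mean[:, None]
    dec = SynergyDecomposition(
        C=C,
        S=S,
        method="pca",
        r=k,
        n_iter=1,
        objective_trace=np.asarray([_objective(D, C, S) ]),
        vaf=vaf(D, M),
        mean=mean,
        notes=notes,
    )
    dec.eigenvalues = evals  # full spectrum, descending
    return dec


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def vaf(D, M) -> float:
    """Variance accounted for: 1 - ||D - M||_F^2 / ||D - mean(D)||_F^2.

    mean(D) replaces every column by its across-channel mean.  VAF is 1
    for a perfect reconstruction, 0 when M is the column-mean matrix,
    and can be negative for reconstructions worse than that baseline.
    """
    D = _as_matrix(D)
    M = _as_matrix(M)
    if D.shape != M.shape:
        raise ArgumentError(f"shape mismatch: {D.shape} vs {M.shape}")
    col_mean = D.mean(axis=0, keepdims=True)
    den = float(np.sum((D - col_mean) ** 2))
    if den == 0.0:
        raise UndefinedMetricError(
            "VAF undefined: D has no across-channel variance"
        )
    num = float(np.sum((D - M) ** 2))
    return 1.0 - num / den


def _decompose(D, method, r, stop=None, alpha=0.03, seed=0):
    if method in ("mcr_als", "mcr"):
        return mcr_als(D, r, stop=stop, alpha=alpha)
    if method == "nmf":
        return nmf(D, r, stop=stop, seed=seed)
    if method == "pca":
        return pca_synergy(D, r)
    raise ArgumentError(f"unknown method {method!r}")


def select_order(
    D,
    method: str = "mcr_als",
    vaf_threshold: float = 0.80,
    r_max: int | None = None,
    stop: StoppingRule | None = None,
    alpha: float = 0.03,
    seed: int = 0,
) -> int:
    """Smallest synergy count whose reconstruction VAF exceeds threshold.

    Decomposes D at r = 1, 2, ... r_max (default: the channel count) and
    returns the first r with VAF > ``vaf_threshold``.  If no candidate
    qualifies, returns r_max with a warning.
    """
    D = _as_matrix(D)
    m = D.shape[0]
    r_max = m if r_max is None else r_max
    if r_max > m:
        raise ArgumentError(f"r_max={r_max} exceeds channel count {m}")
    for r in range(1, r_max + 1):
        dec = _decompose(D, method, r, stop=stop, alpha=alpha, seed=seed)
        if dec.vaf > vaf_threshold:
            return r
    warnings.warn(
        f"no r <= {r_max} reached VAF > {vaf_threshold}; returning r_max",
        stacklevel=2,
    )
    return r_max


# ---------------------------------------------------------------------------
# scikit-learn estimators (samples as rows: X = D.T)
# ---------------------------------------------------------------------------

class _SynergyEstimator(TransformerMixin, BaseEstimator):
    """Shared plumbing: X is (n_samples, n_channels); fitted attributes
    expose the synergy matrix as ``components_`` (r x m, rows are
    synergies) plus the domain-convention ``decomposition_``."""

    def _validate(self, X, nonneg):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        if nonneg and np.any(X < 0):
            raise DataError("X must be non-negative")
        return X

    def _finish(self, dec: SynergyDecomposition):
        self.decomposition_ = dec
        self.components_ = dec.C.T.copy()
        self.activations_ = dec.S.T.copy()
        self.n_iter_ = dec.n_iter
        self.objective_trace_ = dec.objective_trace
        self.vaf_ = dec.vaf
        self.n_features_in_ = dec.C.shape[0]
        return self

    @property
    def synergies_(self) -> np.ndarray:
        """Synergy matrix C in channels x synergies layout."""
        check_is_fitted(self, "components_")
        return self.components_.T

    def fit(self, X, y=None):
        raise NotImplementedError

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.activations_.copy()


class MCRALS(_SynergyEstimator):
    """Deterministic MCR-ALS synergy transformer.

    Parameters mirror :func:`mcr_als`; ``transform`` solves the exact
    NNLS projection of new samples onto the fitted synergies.

    Examples
    --------
    >>> est = MCRALS(n_synergies=2).fit(X)     # X: samples x channels
    >>> A = est.transform(X)                   # samples x synergies
    """

    def __init__(
        self,
        n_synergies: int = 2,
        alpha: float = 0.03,
        q_tol: float = 0.01,
        max_iter: int = 1000,
        mode: str = "exact",
    ):
        self.n_synergies = n_synergies
        self.alpha = alpha
        self.q_tol = q_tol
        self.max_iter = max_iter
        self.mode = mode

    def fit(self, X, y=None):
        X = self._validate(X, nonneg=True)
        dec = mcr_als(
            X.T,
            self.n_synergies,
            stop=StoppingRule(self.q_tol, self.max_iter),
            alpha=self.alpha,
            mode=self.mode,
        )
        return self._finish(dec)

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = self._validate(X, nonneg=True)
        if X.shape[1] != self.n_features_in_:
            raise ArgumentError("channel count differs from fit")
        return _nnls_columns(self.components_.T, X.T).T


class SynergyNMF(_SynergyEstimator):
    """Random-start multiplicative-update NMF transformer."""

    def __init__(
        self,
        n_synergies: int = 2,
        q_tol: float = 0.01,
        max_iter: int = 1000,
        random_state: int = 0,
    ):
        self.n_synergies = n_synergies
        self.q_tol = q_tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = self._validate(X, nonneg=True)
        dec = nmf(
            X.T,
            self.n_synergies,
            stop=StoppingRule(self.q_tol, self.max_iter),
            seed=self.random_state,
        )
        return self._finish(dec)

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = self._validate(X, nonneg=True)
        if X.shape[1] != self.n_features_in_:
            raise ArgumentError("channel count differs from fit")
        return _nnls_columns(self.components_.T, X.T).T


class SynergyPCA(_SynergyEstimator):
    """Channel-covariance PCA baseline (no non-negativity)."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = self._validate(X, nonneg=False)
        dec = pca_synergy(X.T, self.n_components)
        self._finish(dec)
        self.mean_ = dec.mean
        self.explained_variance_ = dec.eigenvalues[: self.n_components]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = self._validate(X, nonneg=False)
        if X.shape[1] != self.n_features_in_:
            raise ArgumentError("channel count differs from fit")
        return (X - self.mean_) @ self.components_.T
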