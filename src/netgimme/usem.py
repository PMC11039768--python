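"""Unified SEM (lag-1 structural VAR) estimation for one subject.

The model for an observed p-variate time series eta_t is

    eta_t = A eta_t + Phi eta_{t-1} + zeta_t,     zeta_t ~ N(0, diag(Psi))

where A holds contemporaneous directed paths (zero diagonal) and Phi
lag-1 paths (its diagonal are the autoregressive paths).  An edge
"source -> target" means the target's equation regresses on the source,
i.e. the coefficient lives at ``A[target, source]`` (or ``Phi``).

Estimation minimises the Gaussian ML discrepancy

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^{-1}) - ln|S| - 2p

over the stacked 2p-variate covariance S of [eta_{t-1}; eta_t], with the
lagged block saturated and the innovation covariance diagonal.  Because
the likelihood factorises into a marginal part for eta_{t-1} (whose
saturated covariance estimate is simply the sample lagged block) and a
conditional part, and the optimal innovation variances given (A, Phi)
are the diagonal structural residual variances, the discrepancy
concentrates to a smooth function of the free path coefficients only:

    F(A, Phi) = sum_i ln R_ii(A, Phi) - 2 ln|det(I - A)|
                + ln|S_LL| - ln|S|,

    R = W S W',   W = [-Phi, I - A].

Each R_ii depends only on row i of (A, Phi); rows couple only through
the log-determinant term.  Gradient and Hessian are available in closed
form, which keeps both Newton-type fitting and score-test (modification
index) computation cheap even when scored over every admissible path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

#: a directed path (source ROI index, target ROI index, lag in {0, 1})
Path = tuple[int, int, int]


class SingularCovarianceError(ValueError):
    """Stacked sample covariance is (near-)singular.

    Typically the series is too short relative to the number of ROIs;
    a longer series (or fewer ROIs) is needed.
    """


# ---------------------------------------------------------------------------
# path pattern


@dataclass(frozen=True)
class PathPattern:
    """Boolean masks of which paths are free.

    ``free_A[t, s]`` frees the contemporaneous path s -> t (diagonal is
    forbidden); ``free_Phi[t, s]`` frees the lag-1 path, the diagonal
    being the autoregressive (AR) paths.
    """

    free_A: np.ndarray
    free_Phi: np.ndarray

    def __post_init__(self) -> None:
        fa = np.asarray(self.free_A, dtype=bool)
        fp = np.asarray(self.free_Phi, dtype=bool)
        if fa.shape != fp.shape or fa.ndim != 2 or fa.shape[0] != fa.shape[1]:
            raise ValueError("free_A and free_Phi must be square and same shape")
        if np.any(np.diag(fa)):
            raise ValueError("contemporaneous self-loops are not admissible")
        fa.setflags(write=False)
        fp.setflags(write=False)
        object.__setattr__(self, "free_A", fa)
        object.__setattr__(self, "free_Phi", fp)

    @property
    def p(self) -> int:
        return self.free_A.shape[0]

    @property
    def n_free(self) -> int:
        return int(self.free_A.sum() + self.free_Phi.sum())

    @classmethod
    def empty(cls, p: int) -> "PathPattern":
        return cls(np.zeros((p, p), bool), np.zeros((p, p), bool))

    @classmethod
    def ar_only(cls, p: int) -> "PathPattern":
        return cls(np.zeros((p, p), bool), np.eye(p, dtype=bool))

    def has_path(self, path: Path) -> bool:
        s, t, lag = path
        return bool((self.free_Phi if lag else self.free_A)[t, s])

    def with_paths(self, paths) -> "PathPattern":
        fa, fp = self.free_A.copy(), self.free_Phi.copy()
        for s, t, lag in paths:
            if lag == 0 and s == t:
                raise ValueError("contemporaneous self-loop")
            (fp if lag else fa)[t, s] = True
        return PathPattern(fa, fp)

    def without_paths(self, paths) -> "PathPattern":
        fa, fp = self.free_A.copy(), self.free_Phi.copy()
        for s, t, lag in paths:
            (fp if lag else fa)[t, s] = False
        return PathPattern(fa, fp)

    def free_paths(self) -> list[Path]:
        """All free paths in canonical (lag, target, source) order."""
        out: list[Path] = []
        for lag, mask in ((0, self.free_A), (1, self.free_Phi)):
            ts, ss = np.nonzero(mask)
            out.extend((int(s), int(t), lag) for t, s in zip(ts, ss))
        return sorted(out, key=path_sort_key)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PathPattern)
            and np.array_equal(self.free_A, other.free_A)
            and np.array_equal(self.free_Phi, other.free_Phi)
        )


def path_sort_key(path: Path):
    s, t, lag = path
    return (lag, t, s)


def all_candidate_paths(p: int) -> list[Path]:
    """Every admissible path: A off-diagonal plus all of Phi."""
    cands = [(s, t, 0) for t in range(p) for s in range(p) if s != t]
    cands += [(s, t, 1) for t in range(p) for s in range(p)]
    return sorted(cands, key=path_sort_key)


# ---------------------------------------------------------------------------
# sufficient statistics


@dataclass(frozen=True)
class StackedCov:
    """Sufficient statistics: stacked covariance of [eta_{t-1}; eta_t]."""

    S: np.ndarray  # (2p, 2p) sample covariance (ddof=1)
    n_eff: int  # number of stacked (lagged, current) pairs, T - 1
    p: int
    const: float  # ln|S_LL| - ln|S|, the parameter-free part of F

    @classmethod
    def from_data(cls, data: np.ndarray, standardize: bool = True) -> "StackedCov":
        X = np.asarray(data, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need a T x p matrix with T >= 3")
        p = X.shape[1]
        if standardize:
            sd = X.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                raise ValueError("constant ROI column cannot be standardized")
            X = (X - X.mean(axis=0)) / sd
        stacked = np.hstack([X[:-1], X[1:]])
        S = np.cov(stacked, rowvar=False, ddof=1)
        return cls.from_cov(S, n_eff=X.shape[0] - 1)

    @classmethod
    def from_cov(cls, S: np.ndarray, n_eff: int) -> "StackedCov":
        S = np.asarray(S, dtype=float)
        twop = S.shape[0]
        if twop % 2:
            raise ValueError("stacked covariance must be 2p x 2p")
        p = twop // 2
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0 or not np.isfinite(logdet):
            raise SingularCovarianceError(
                "stacked sample covariance is singular; a longer time series "
                "is required for this number of ROIs"
            )
        sign_l, logdet_l = np.linalg.slogdet(S[:p, :p])
        if sign_l <= 0:
            raise SingularCovarianceError("lagged covariance block is singular")
        return cls(S=S, n_eff=int(n_eff), p=p, const=float(logdet_l - logdet))


# ---------------------------------------------------------------------------
# concentrated discrepancy, gradient, Hessian

_PENALTY = 1e12


def _stacked_cols(paths, p: int) -> np.ndarray:
    """Column index of each path's coefficient within a row of W = [-Phi, I-A]."""
    return np.array([s if lag else p + s for s, t, lag in paths], dtype=int)


def _rows(paths) -> np.ndarray:
    return np.array([t for s, t, lag in paths], dtype=int)


def _build_W(A: np.ndarray, Phi: np.ndarray) -> np.ndarray:
    p = A.shape[0]
    return np.hstack([-Phi, np.eye(p) - A])


def discrepancy(A: np.ndarray, Phi: np.ndarray, data: StackedCov) -> float:
    """Concentrated ML discrepancy F(A, Phi); large penalty off-domain."""
    p = data.p
    W = _build_W(A, Phi)
    R = W @ data.S @ W.T
    r = np.diag(R)
    sign, logdet_IA = np.linalg.slogdet(np.eye(p) - A)
    if sign <= 0 or np.any(r <= 1e-300):
        return _PENALTY
    return float(np.sum(np.log(r)) - 2.0 * logdet_IA + data.const)


def _grad_hess(
    A: np.ndarray,
    Phi: np.ndarray,
    data: StackedCov,
    paths: list[Path],
    want_hess: bool = True,
):
    """Gradient (and Hessian) of F with respect to the given paths."""
    p = data.p
    S = data.S
    W = _build_W(A, Phi)
    G = W @ S  # (p, 2p); G[i, c] = (S w_i)_c
    r = np.einsum("ic,ic->i", G, W)  # R_ii
    B = np.linalg.inv(np.eye(p) - A)

    rows = _rows(paths)
    cols = _stacked_cols(paths, p)
    is_A = np.array([lag == 0 for _, _, lag in paths])
    srcs = np.array([s for s, _, _ in paths], dtype=int)

    g_vals = G[rows, cols]  # (S w_i)_{c_a} per parameter
    grad = -2.0 * g_vals / r[rows]
    if np.any(is_A):
        grad[is_A] += 2.0 * B[srcs[is_A], rows[is_A]]
    if not want_hess:
        return grad, None

    same_row = rows[:, None] == rows[None, :]
    Scc = S[np.ix_(cols, cols)]
    ri = r[rows]
    H = same_row * (
        2.0 * Scc / ri[:, None]
        - 4.0 * np.outer(g_vals / ri, g_vals / ri)
    )
    if np.any(is_A):
        ia = np.nonzero(is_A)[0]
        ja, ta = srcs[ia], rows[ia]
        # d^2(-2 ln det(I-A)) / dA_{t1 j1} dA_{t2 j2} = 2 B_{j1 t2} B_{j2 t1}
        H[np.ix_(ia, ia)] += 2.0 * B[np.ix_(ja, ta)] * B[np.ix_(ja, ta)].T
    return grad, H


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class FittedUSEM:
    """ML estimates for one subject under a fixed path pattern."""

    pattern: PathPattern
    A_hat: np.ndarray
    Phi_hat: np.ndarray
    se_A: np.ndarray
    se_Phi: np.ndarray
    z_A: np.ndarray
    z_Phi: np.ndarray
    Psi_hat: np.ndarray  # innovation variances (diagonal)
    F_ML: float
    n_eff: int
    converged: bool
    grad_max: float
    x: np.ndarray = field(repr=False)  # free-parameter vector (warm starts)

    @property
    def p(self) -> int:
        return self.A_hat.shape[0]

    def estimate(self, path: Path) -> float:
        s, t, lag = path
        return float((self.Phi_hat if lag else self.A_hat)[t, s])

    def wald_p(self, path: Path) -> float:
        s, t, lag = path
        z = (self.z_Phi if lag else self.z_A)[t, s]
        return float(2.0 * stats.norm.sf(abs(z)))


def _unpack(x: np.ndarray, paths: list[Path], p: int):
    A = np.zeros((p, p))
    Phi = np.zeros((p, p))
    for val, (s, t, lag) in zip(x, paths):
        (Phi if lag else A)[t, s] = val
    return A, Phi


def fit_usem(
    data: StackedCov,
    pattern: PathPattern,
    x0: np.ndarray | None = None,
    gtol: float = 1e-7,
    maxiter: int = 500,
    ar_start: float = 0.3,
) -> FittedUSEM:
    """Fit the uSEM by Newton-type minimisation of the concentrated F.

    Free coefficients start at zero (AR paths at ``ar_start``) unless a
    warm-start vector ``x0`` is given.  Non-convergence is flagged on
    the result, not raised.
    """
    p = data.p
    if pattern.p != p:
        raise ValueError("pattern dimension does not match data")
    free = pattern.free_paths()
    k = len(free)
    if data.n_eff - 1 <= k:
        raise ValueError("too few time points for the number of free paths")

    if k == 0:
        A = np.zeros((p, p))
        Phi = np.zeros((p, p))
        return _finalize(data, pattern, free, np.empty(0), A, Phi, True, 0.0)

    if x0 is None:
        x0 = np.array([ar_start if (lag == 1 and s == t) else 0.0 for s, t, lag in free])
    else:
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (k,):
            raise ValueError("warm start has wrong length")
        if discrepancy(*_unpack(x0, free, p), data) >= _PENALTY:
            x0 = np.array(
                [ar_start if (lag == 1 and s == t) else 0.0 for s, t, lag in free]
            )

    def fun(x):
        return discrepancy(*_unpack(x, free, p), data)

    def jac(x):
        g, _ = _grad_hess(*_unpack(x, free, p), data, free, want_hess=False)
        return g

    def hess(x):
        _, H = _grad_hess(*_unpack(x, free, p), data, free)
        return H

    res = optimize.minimize(
        fun, x0, method="trust-exact", jac=jac, hess=hess,
        options={"gtol": gtol, "maxiter": maxiter},
    )
    x = res.x
    g = jac(x)
    gmax = float(np.max(np.abs(g))) if k else 0.0
    A, Phi = _unpack(x, free, p)
    converged = bool(np.isfinite(fun(x)) and fun(x) < _PENALTY and gmax < 1e-5)
    return _finalize(data, pattern, free, x, A, Phi, converged, gmax)


def _finalize(data, pattern, free, x, A, Phi, converged, gmax) -> FittedUSEM:
    p = data.p
    W = _build_W(A, Phi)
    R = W @ data.S @ W.T
    psi = np.diag(R).copy()
    F = max(discrepancy(A, Phi, data), 0.0)

    se_A = np.full((p, p), np.nan)
    se_Phi = np.full((p, p), np.nan)
    z_A = np.full((p, p), np.nan)
    z_Phi = np.full((p, p), np.nan)
    if free:
        _, H = _grad_hess(A, Phi, data, free)
        info = (data.n_eff - 1) / 2.0 * H  # profile observed information
        try:
            cov = np.linalg.inv(info)
            var = np.diag(cov).copy()
            var[var < 0] = np.nan
        except np.linalg.LinAlgError:
            var = np.full(len(free), np.nan)
        se = np.sqrt(var)
        for se_k, (s, t, lag), val in zip(se, free, x):
            if lag:
                se_Phi[t, s] = se_k
                z_Phi[t, s] = val / se_k if se_k > 0 else np.nan
            else:
                se_A[t, s] = se_k
                z_A[t, s] = val / se_k if se_k > 0 else np.nan
    return FittedUSEM(
        pattern=pattern, A_hat=A, Phi_hat=Phi,
        se_A=se_A, se_Phi=se_Phi, z_A=z_A, z_Phi=z_Phi,
        Psi_hat=psi, F_ML=F, n_eff=data.n_eff,
        converged=converged, grad_max=gmax, x=np.asarray(x, float),
    )


# ---------------------------------------------------------------------------
# fit indices


@dataclass(frozen=True)
class FitIndices:
    chi2: float
    df: int
    chi2_null: float
    df_null: int
    CFI: float
    NNFI: float
    RMSEA: float
    SRMR: float


def implied_stacked_cov(fit: FittedUSEM, data: StackedCov) -> np.ndarray:
    """Model-implied 2p x 2p covariance at the fitted parameters."""
    p = data.p
    S_LL = data.S[:p, :p]
    B = np.linalg.inv(np.eye(p) - fit.A_hat)
    Gam = B @ fit.Phi_hat
    C = B @ np.diag(fit.Psi_hat) @ B.T
    top = np.hstack([S_LL, S_LL @ Gam.T])
    bot = np.hstack([Gam @ S_LL, Gam @ S_LL @ Gam.T + C])
    return np.vstack([top, bot])


def compute_fit_indices(fit: FittedUSEM, pattern: PathPattern, data: StackedCov) -> FitIndices:
    """CFI / NNFI / RMSEA / SRMR from the stacked covariance.

    The baseline (null) model treats all 2p variables as mutually
    uncorrelated with free variances.
    """
    p = data.p
    n1 = fit.n_eff - 1
    chi2 = max(n1 * fit.F_ML, 0.0)
    n_moments = p * (2 * p + 1)
    q = p * (p + 1) // 2 + pattern.n_free + p
    df = n_moments - q

    S = data.S
    sign, logdet = np.linalg.slogdet(S)
    F_null = float(np.sum(np.log(np.diag(S))) - logdet)
    chi2_null = max(n1 * F_null, 0.0)
    df_null = n_moments - 2 * p

    if df <= 0:
        cfi, nnfi, rmsea = 1.0, 1.0, 0.0
    else:
        num = max(chi2 - df, 0.0)
        den = max(chi2_null - df_null, chi2 - df, 0.0)
        cfi = 1.0 - num / den if den > 0 else 1.0
        null_ratio = chi2_null / df_null
        nnfi = (null_ratio - chi2 / df) / (null_ratio - 1.0) if null_ratio != 1.0 else 1.0
        rmsea = float(np.sqrt(num / (df * n1)))

    Sig = implied_stacked_cov(fit, data)
    d = np.sqrt(np.diag(S))
    resid = (S - Sig) / np.outer(d, d)
    iu = np.triu_indices(2 * p)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))

    return FitIndices(
        chi2=float(chi2), df=int(df), chi2_null=float(chi2_null),
        df_null=int(df_null), CFI=float(cfi), NNFI=float(nnfi),
        RMSEA=float(rmsea), SRMR=srmr,
    )


#: default thresholds: (CFI >=, NNFI >=, RMSEA <=, SRMR <=)
DEFAULT_FIT_THRESHOLDS = {"CFI": 0.95, "NNFI": 0.95, "RMSEA": 0.05, "SRMR": 0.05}


def n_criteria_met(idx: FitIndices, thresholds: dict | None = None) -> int:
    th = thresholds or DEFAULT_FIT_THRESHOLDS
    return int(
        (idx.CFI >= th["CFI"])
        + (idx.NNFI >= th["NNFI"])
        + (idx.RMSEA <= th["RMSEA"])
        + (idx.SRMR <= th["SRMR"])
    )


def excellent_fit(idx: FitIndices, thresholds: dict | None = None) -> bool:
    """True iff at least two of the four index thresholds are met."""
    return n_criteria_met(idx, thresholds) >= 2


# ---------------------------------------------------------------------------
# modification indices (score tests) and pruning


@dataclass(frozen=True)
class CandidateScore:
    path: Path
    mi: float
    p_value: float
    epc: float  # expected parameter change if the path were freed


def modification_indices(
    fit: FittedUSEM,
    pattern: PathPattern,
    candidates: list[Path] | None = None,
    data: StackedCov | None = None,
) -> list[CandidateScore]:
    """Univariate score (Lagrange-multiplier) tests for fixed paths.

    Each modification index estimates, on a 1-df chi-square scale, the
    drop in the model chi-square from freeing that single path.  Scores
    use the analytic gradient of the concentrated discrepancy at the
    sample covariance together with the expected information (the same
    Hessian evaluated at the model-implied covariance); the block of the
    free parameters is profiled out via a Schur complement.
    """
    if data is None:
        raise ValueError("data (StackedCov) is required")
    p = data.p
    if candidates is None:
        candidates = all_candidate_paths(p)
    candidates = [
        c for c in sorted(set(candidates), key=path_sort_key)
        if not pattern.has_path(c) and not (c[2] == 0 and c[0] == c[1])
    ]
    if not candidates:
        return []
    free = pattern.free_paths()
    nf, nc = len(free), len(candidates)
    grad, _ = _grad_hess(fit.A_hat, fit.Phi_hat, data, free + candidates, want_hess=False)
    implied = StackedCov.from_cov(implied_stacked_cov(fit, data), data.n_eff)
    _, H = _grad_hess(fit.A_hat, fit.Phi_hat, implied, free + candidates)
    g_c = grad[nf:]
    H_cc = np.diag(H)[nf:]
    if nf:
        H_ff = H[:nf, :nf]
        H_fc = H[:nf, nf:]
        try:
            X = np.linalg.solve(H_ff, H_fc)
            schur = H_cc - np.einsum("fc,fc->c", H_fc, X)
        except np.linalg.LinAlgError:
            warnings.warn("free-parameter Hessian singular; using unadjusted scores")
            schur = H_cc
    else:
        schur = H_cc

    scale = (fit.n_eff - 1) / 2.0
    out = []
    for i, path in enumerate(candidates):
        if not np.isfinite(schur[i]) or schur[i] <= 1e-12:
            warnings.warn(f"information singular for candidate {path}; skipped")
            continue
        mi = float(scale * g_c[i] ** 2 / schur[i])
        out.append(
            CandidateScore(
                path=path, mi=mi, p_value=float(stats.chi2.sf(mi, 1)),
                epc=float(-g_c[i] / schur[i]),
            )
        )
    return out


def prune_paths(
    fit: FittedUSEM,
    pattern: PathPattern,
    alpha: float = 0.05,
    protected: set[Path] | frozenset[Path] = frozenset(),
) -> PathPattern:
    """Drop free, unprotected paths whose two-sided Wald p >= alpha."""
    drop = [
        path for path in pattern.free_paths()
        if path not in protected and not (fit.wald_p(path) < alpha)
    ]
    return pattern.without_paths(drop) if drop else pattern
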