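"""Unit tests for the unified-SEM engine.

The discrepancy minimisation is checked against a brute-force numeric
minimisation of the uncentred stacked-covariance discrepancy over all
parameters (saturated lagged block included); modification indices are
checked against exact refits.
"""

import numpy as np
import pytest
from scipy import optimize

from netgimme import (
    FitIndices,
    PathPattern,
    StackedCov,
    compute_fit_indices,
    excellent_fit,
    fit_usem,
    modification_indices,
    prune_paths,
)
from netgimme.usem import SingularCovarianceError, all_candidate_paths, discrepancy

from conftest import make_var_data


def brute_force_discrepancy(data: StackedCov, pattern: PathPattern) -> float:
    """Minimise F over (V, A, Phi, Psi) with generic numeric optimisation.

    Independent of the analytic concentration used by fit_usem: the
    saturated lagged block is parameterised by its Cholesky factor and
    everything is optimised jointly.
    """
    p = data.p
    S = data.S
    free = pattern.free_paths()
    tril = np.tril_indices(p)
    _, logdet_S = np.linalg.slogdet(S)

    def unpack(theta):
        L = np.zeros((p, p))
        L[tril] = theta[: len(tril[0])]
        V = L @ L.T
        k = len(tril[0])
        A = np.zeros((p, p))
        Phi = np.zeros((p, p))
        for val, (s, t, lag) in zip(theta[k: k + len(free)], free):
            (Phi if lag else A)[t, s] = val
        psi = np.exp(theta[k + len(free):])
        return V, A, Phi, psi

    def F(theta):
        V, A, Phi, psi = unpack(theta)
        try:
            B = np.linalg.inv(np.eye(p) - A)
        except np.linalg.LinAlgError:
            return 1e10
        G = B @ Phi
        C = B @ np.diag(psi) @ B.T
        Sig = np.block([[V, V @ G.T], [G @ V, G @ V @ G.T + C]])
        sign, logdet = np.linalg.slogdet(Sig)
        if sign <= 0:
            return 1e10
        return logdet + np.trace(np.linalg.solve(Sig, S)) - logdet_S - 2 * p

    L0 = np.linalg.cholesky(S[:p, :p])
    x0 = np.concatenate(
        [
            L0[tril],
            [0.3 if (lag == 1 and s == t) else 0.0 for s, t, lag in free],
            np.zeros(p),
        ]
    )
    res = optimize.minimize(F, x0, method="Nelder-Mead",
                            options={"maxiter": 60000, "xatol": 1e-11, "fatol": 1e-14})
    res = optimize.minimize(F, res.x, method="Nelder-Mead",
                            options={"maxiter": 60000, "xatol": 1e-12, "fatol": 1e-15})
    return res.fun


class TestFit:
    def test_matches_brute_force_minimum(self, three_roi_fixture):
        data = three_roi_fixture["data"]
        pattern = three_roi_fixture["pattern"]
        fit = fit_usem(data, pattern)
        assert fit.converged
        oracle = brute_force_discrepancy(data, pattern)
        assert fit.F_ML == pytest.approx(oracle, abs=1e-6)

    def test_empty_pattern_on_identity_covariance(self):
        p = 3
        data = StackedCov.from_cov(np.eye(2 * p), n_eff=100)
        fit = fit_usem(data, PathPattern.empty(p))
        assert fit.F_ML == pytest.approx(0.0, abs=1e-12)

    def test_consistency_long_series(self):
        """Estimates approach truth as T grows (checked at T=20,000)."""
        p = 4
        A = np.zeros((p, p))
        A[1, 0], A[3, 2] = 0.5, -0.35
        Phi = np.diag([0.4, 0.3, 0.5, 0.25])
        Phi[2, 0] = 0.3
        _, data = make_var_data(A, Phi, T=20_000, seed=5)
        pattern = PathPattern.ar_only(p).with_paths([(0, 1, 0), (2, 3, 0), (0, 2, 1)])
        fit = fit_usem(data, pattern)
        assert fit.converged
        assert np.max(np.abs(fit.A_hat - A)) < 0.05
        assert np.max(np.abs(fit.Phi_hat - Phi)) < 0.05

    def test_estimates_zero_where_fixed(self, three_roi_fixture):
        fit = fit_usem(three_roi_fixture["data"], three_roi_fixture["pattern"])
        free_A = three_roi_fixture["pattern"].free_A
        free_Phi = three_roi_fixture["pattern"].free_Phi
        assert np.all(fit.A_hat[~free_A] == 0)
        assert np.all(fit.Phi_hat[~free_Phi] == 0)
        assert np.all(fit.Psi_hat > 0)
        assert np.all(fit.se_A[free_A] > 0)

    def test_singular_covariance_raises(self):
        X = np.random.default_rng(0).normal(size=(6, 3))  # T too short: 2p x 2p rank-deficient
        with pytest.raises(SingularCovarianceError):
            StackedCov.from_data(X)

    def test_nesting_monotonicity(self):
        """Freeing an extra path never increases the optimal discrepancy."""
        rng = np.random.default_rng(3)
        p = 3
        A = np.zeros((p, p))
        A[2, 0] = 0.4
        Phi = np.diag([0.3, 0.4, 0.2])
        _, data = make_var_data(A, Phi, T=300, seed=11)
        base = PathPattern.ar_only(p)
        f_base = fit_usem(data, base).F_ML
        for cand in all_candidate_paths(p):
            if base.has_path(cand):
                continue
            f_bigger = fit_usem(data, base.with_paths([cand])).F_ML
            assert f_bigger <= f_base + 1e-8

    def test_chi2_mean_tracks_nominal_df(self):
        """Under a correctly specified pattern the model chi-square has
        mean approximately equal to its degrees of freedom."""
        p = 3
        A = np.zeros((p, p))
        A[1, 0] = 0.4
        Phi = np.diag([0.4, 0.3, 0.5])
        pattern = PathPattern.ar_only(p).with_paths([(0, 1, 0)])
        chi2s = []
        df = None
        for seed in range(200):
            _, data = make_var_data(A, Phi, T=2000, seed=2000 + seed)
            fit = fit_usem(data, pattern)
            idx = compute_fit_indices(fit, pattern, data)
            chi2s.append(idx.chi2)
            df = idx.df
        assert abs(np.mean(chi2s) - df) / df < 0.15

    def test_relabeling_equivariance(self, three_roi_fixture):
        """Permuting ROI labels permutes the estimates accordingly."""
        X = three_roi_fixture["X"]
        pattern = three_roi_fixture["pattern"]
        perm = [2, 0, 1]
        Xp = X[:, perm]
        data_p = StackedCov.from_data(Xp, standardize=False)
        inv = np.argsort(perm)
        fa = pattern.free_A[np.ix_(inv, inv)]
        fp = pattern.free_Phi[np.ix_(inv, inv)]
        # relabeled pattern: position of old ROI i is inv[i]
        pat_p = PathPattern(pattern.free_A[np.ix_(perm, perm)], pattern.free_Phi[np.ix_(perm, perm)])
        fit = fit_usem(three_roi_fixture["data"], pattern)
        fit_p = fit_usem(data_p, pat_p)
        assert fit_p.F_ML == pytest.approx(fit.F_ML, abs=1e-8)
        assert np.allclose(fit_p.A_hat, fit.A_hat[np.ix_(perm, perm)], atol=1e-6)
        assert np.allclose(fit_p.Phi_hat, fit.Phi_hat[np.ix_(perm, perm)], atol=1e-6)


class TestFitIndices:
    def test_saturated_model_perfect_fit(self, three_roi_fixture):
        # recursive contemporaneous block + full lagged block: just identified
        p = 3
        data = three_roi_fixture["data"]
        full = PathPattern(np.tril(np.ones((p, p), bool), -1), np.ones((p, p), bool))
        fit = fit_usem(data, full)
        idx = compute_fit_indices(fit, full, data)
        assert idx.df == 0
        assert idx.chi2 == pytest.approx(0.0, abs=1e-6)
        assert idx.CFI == 1.0 and idx.RMSEA == 0.0
        assert idx.SRMR == pytest.approx(0.0, abs=1e-6)

    def test_independence_pattern_identity_covariance(self):
        p = 3
        data = StackedCov.from_cov(np.eye(2 * p), n_eff=200)
        fit = fit_usem(data, PathPattern.empty(p))
        idx = compute_fit_indices(fit, PathPattern.empty(p), data)
        assert idx.chi2 == pytest.approx(0.0, abs=1e-10)
        assert idx.RMSEA == 0.0

    def test_formula_oracle(self, three_roi_fixture):
        """Indices match an independent recomputation from the formulas."""
        data = three_roi_fixture["data"]
        pattern = three_roi_fixture["pattern"]
        fit = fit_usem(data, pattern)
        idx = compute_fit_indices(fit, pattern, data)
        p, S, n1 = data.p, data.S, data.n_eff - 1
        chi2 = n1 * fit.F_ML
        q = p * (p + 1) / 2 + pattern.n_free + p
        df = p * (2 * p + 1) - q
        F0 = np.sum(np.log(np.diag(S))) - np.linalg.slogdet(S)[1]
        chi20, df0 = n1 * F0, p * (2 * p + 1) - 2 * p
        assert idx.chi2 == pytest.approx(chi2, abs=1e-9)
        assert idx.df == df
        cfi = 1 - max(chi2 - df, 0) / max(chi20 - df0, chi2 - df, 0)
        nnfi = (chi20 / df0 - chi2 / df) / (chi20 / df0 - 1)
        rmsea = np.sqrt(max(chi2 - df, 0) / (df * n1))
        assert idx.CFI == pytest.approx(cfi, abs=1e-6)
        assert idx.NNFI == pytest.approx(nnfi, abs=1e-6)
        assert idx.RMSEA == pytest.approx(rmsea, abs=1e-6)
        # SRMR recomputed from the implied covariance residuals
        from netgimme.usem import implied_stacked_cov

        Sig = implied_stacked_cov(fit, data)
        d = np.sqrt(np.diag(S))
        res = (S - Sig) / np.outer(d, d)
        srmr = np.sqrt(np.mean(res[np.triu_indices(2 * p)] ** 2))
        assert idx.SRMR == pytest.approx(srmr, abs=1e-9)


def _idx(cfi, nnfi, rmsea, srmr):
    return FitIndices(chi2=1, df=1, chi2_null=10, df_null=2,
                      CFI=cfi, NNFI=nnfi, RMSEA=rmsea, SRMR=srmr)


@pytest.mark.parametrize(
    "cfi,nnfi,rmsea,srmr,expected",
    [
        (0.9615, 0.9375, 0.0678, 0.0395, True),  # cohort-average indices: exactly 2 met
        (0.95, 0.95, 0.05, 0.05, True),  # boundary inclusive
        (0.5, 0.5, 0.2, 0.2, False),
        (0.96, 0.5, 0.2, 0.2, False),  # only one criterion met
    ],
)
def test_excellent_fit_rule(cfi, nnfi, rmsea, srmr, expected):
    assert excellent_fit(_idx(cfi, nnfi, rmsea, srmr)) is expected


class TestModificationIndices:
    def test_free_and_self_candidates_excluded(self, three_roi_fixture):
        data = three_roi_fixture["data"]
        pattern = three_roi_fixture["pattern"]
        fit = fit_usem(data, pattern)
        scores = modification_indices(fit, pattern, None, data)
        paths = {s.path for s in scores}
        assert not any(pattern.has_path(p) for p in paths)
        assert not any(lag == 0 and s == t for s, t, lag in paths)
        assert all(s.mi >= 0 for s in scores)

    def test_matches_refit_chi_square_drop(self):
        """Each MI approximates the exact refit delta chi-square.

        The base model omits a single true path; the univariate score
        statistic is a local approximation and degrades when several
        paths are omitted at once.
        """
        p = 3
        A = np.zeros((p, p))
        A[1, 0], A[2, 1] = 0.5, 0.3
        Phi = np.diag([0.4, 0.3, 0.5])
        Phi[2, 0] = 0.2
        _, data = make_var_data(A, Phi, T=600, seed=9)
        base = PathPattern.ar_only(p).with_paths([(0, 1, 0), (0, 2, 1)])
        fit = fit_usem(data, base)
        for score in modification_indices(fit, base, None, data):
            refit = fit_usem(data, base.with_paths([score.path]))
            dchi = (data.n_eff - 1) * (fit.F_ML - refit.F_ML)
            # relative check at meaningful scale; tiny statistics compared absolutely
            assert score.mi == pytest.approx(dchi, rel=0.10, abs=0.15)

    def test_strong_omitted_path_ranks_first(self):
        hits = 0
        p = 3
        Phi = np.diag([0.4, 0.3, 0.5])
        A = np.zeros((p, p))
        A[1, 0] = 0.4
        base = PathPattern.ar_only(p)
        for seed in range(30):
            _, data = make_var_data(A, Phi, T=500, seed=100 + seed)
            fit = fit_usem(data, base)
            scores = modification_indices(fit, base, None, data)
            best = max(scores, key=lambda s: s.mi)
            hits += best.path == (0, 1, 0)
        assert hits >= 29  # >= 95% of replicates

    def test_epc_sign_matches_omitted_coefficient(self):
        p = 3
        A = np.zeros((p, p))
        A[1, 0] = -0.4
        _, data = make_var_data(A, np.diag([0.3, 0.3, 0.3]), T=800, seed=21)
        base = PathPattern.ar_only(p)
        fit = fit_usem(data, base)
        score = next(s for s in modification_indices(fit, base, None, data)
                     if s.path == (0, 1, 0))
        assert score.epc < 0


class TestPrune:
    def test_nothing_prunable(self, three_roi_fixture):
        data = three_roi_fixture["data"]
        pattern = three_roi_fixture["pattern"]
        fit = fit_usem(data, pattern)  # all planted paths strong at T=800
        assert prune_paths(fit, pattern, alpha=0.05) == pattern

    def test_single_nonsignificant_path_removed(self):
        p = 3
        Phi = np.diag([0.4, 0.3, 0.5])
        _, data = make_var_data(np.zeros((p, p)), Phi, T=800, seed=13)
        pattern = PathPattern.ar_only(p).with_paths([(0, 1, 0)])  # spurious
        fit = fit_usem(data, pattern)
        pruned = prune_paths(fit, pattern, alpha=0.05)
        assert not pruned.has_path((0, 1, 0))
        assert all(pruned.has_path((i, i, 1)) for i in range(p))

    def test_protected_paths_retained(self):
        p = 3
        _, data = make_var_data(np.zeros((p, p)), np.zeros((p, p)), T=500, seed=17)
        pattern = PathPattern.ar_only(p)  # AR truly zero here
        fit = fit_usem(data, pattern)
        protected = frozenset((i, i, 1) for i in range(p))
        assert prune_paths(fit, pattern, 0.05, protected) == pattern
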