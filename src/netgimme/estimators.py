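"""Estimator-style interfaces over the uSEM engine and the staged search.

``UnifiedSEM`` fits one subject's lag-1 structural VAR under a fixed (or
AR-only) path pattern; ``GIMME`` runs the full group / subgroup /
individual search over a cohort.  Both follow the scikit-learn estimator
protocol (``fit``, ``get_params`` / ``set_params``, fitted attributes
with a trailing underscore), so they compose with sklearn tooling; the
module-level functions in :mod:`netgimme.usem` and :mod:`netgimme.gimme`
remain the underlying implementation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import gimme as _gimme
from . import usem as _usem


class UnifiedSEM(BaseEstimator):
    """Unified SEM (contemporaneous + lag-1 structural VAR) for one series.

    Parameters
    ----------
    pattern : PathPattern or None
        Paths to free.  ``None`` frees only the autoregressive paths.
    standardize : bool
        z-score each ROI before fitting (recommended; makes coefficients
        comparable across subjects).
    """

    def __init__(self, pattern=None, standardize: bool = True):
        self.pattern = pattern
        self.standardize = standardize

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a T x p time-series matrix")
        data = _usem.StackedCov.from_data(X, standardize=self.standardize)
        pattern = self.pattern if self.pattern is not None else _usem.PathPattern.ar_only(data.p)
        fit = _usem.fit_usem(data, pattern)
        self.n_features_in_ = data.p
        self.data_ = data
        self.pattern_ = pattern
        self.result_ = fit
        self.A_ = fit.A_hat
        self.Phi_ = fit.Phi_hat
        self.psi_ = fit.Psi_hat
        self.discrepancy_ = fit.F_ML
        self.converged_ = fit.converged
        self.fit_indices_ = _usem.compute_fit_indices(fit, pattern, data)
        return self

    def score(self, X=None, y=None) -> float:
        """Negative ML discrepancy (higher is better), sklearn-style."""
        check_is_fitted(self, "result_")
        return -self.discrepancy_

    def modification_indices(self, candidates=None):
        check_is_fitted(self, "result_")
        return _usem.modification_indices(self.result_, self.pattern_, candidates, self.data_)


class GIMME(BaseEstimator):
    """Staged group / subgroup / individual connectivity search.

    ``fit`` takes a cohort: either a mapping of subject id to a T x p
    array, or a list of arrays (ids are generated).  The fitted
    attributes expose the group path set, the Walktrap subgrouping, the
    similarity matrix and the per-subject final models.
    """

    def __init__(
        self,
        gamma_group: float = 0.75,
        gamma_sub: float = 0.50,
        alpha: float = 0.05,
        walktrap_steps: int = 4,
        max_paths: int | None = 60,
        ar_start: bool = True,
        standardize: bool = True,
    ):
        self.gamma_group = gamma_group
        self.gamma_sub = gamma_sub
        self.alpha = alpha
        self.walktrap_steps = walktrap_steps
        self.max_paths = max_paths
        self.ar_start = ar_start
        self.standardize = standardize

    def _config(self) -> _gimme.SearchConfig:
        return _gimme.SearchConfig(
            gamma_group=self.gamma_group,
            gamma_sub=self.gamma_sub,
            alpha=self.alpha,
            walktrap_steps=self.walktrap_steps,
            max_paths=self.max_paths,
            ar_start=self.ar_start,
            standardize=self.standardize,
        )

    def fit(self, X, y=None):
        if isinstance(X, dict):
            cohort = {str(k): np.asarray(v, float) for k, v in X.items()}
        else:
            cohort = {f"sub-{i + 1:03d}": np.asarray(v, float) for i, v in enumerate(X)}
        result = _gimme.run_gimme(cohort, self._config())
        self.result_ = result
        self.subject_ids_ = list(result.subject_ids)
        self.group_paths_ = list(result.group_paths)
        self.similarity_ = result.similarity
        self.subgroup_labels_ = np.array(
            [result.subgroup_solution.assignment[s] for s in result.subject_ids]
        )
        self.subgroup_paths_ = dict(result.subgroup_paths)
        self.mean_fit_ = dict(result.mean_fit)
        self.n_features_in_ = result.group_pattern.p
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the subgroup label of each subject."""
        return self.fit(X).subgroup_labels_
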