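"""Replicated simulation studies that exercise the whole pipeline.

Each function generates fresh synthetic data from a known truth, runs
the corresponding stage of the pipeline, and returns recovery or
calibration summaries.  They are used by the validation suite and by
the reproduction script; problem sizes are arguments so desk-scale runs
stay cheap.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .atlas import default_atlas
from .density import METRICS
from .gimme import SearchConfig, detect_subgroups, group_search
from .outcomes import (
    RegressionSpec,
    apply_bonferroni,
    fit_continuous_outcome_model,
    fit_count_outcome_model,
    fit_outcome_model,
    primary_specs,
)
from .simulate import (
    OutcomeCoeffs,
    SimulationParams,
    make_true_structure,
    simulate_cohort,
    simulate_outcomes,
)
from .stability import assess_stability
from .usem import StackedCov


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# group-level search recovery


def group_recovery_study(
    n_reps: int = 20,
    seed: int = 0,
    params: SimulationParams | None = None,
    config: SearchConfig | None = None,
) -> dict:
    """Recall of true group paths on replicated default cohorts."""
    atlas = default_atlas()
    config = config or SearchConfig()
    recalls = []
    for rep_seed in _child_seeds(seed, n_reps):
        p = dataclasses.replace(params or SimulationParams(), seed=rep_seed)
        truth = make_true_structure(atlas, p)
        cohort = simulate_cohort(truth, p)
        datas = {
            sid: StackedCov.from_data(X, standardize=config.standardize)
            for sid, X in cohort.items()
        }
        _, added = group_search(datas, config)
        true_group = {(s, t, lag) for s, t, lag, _ in truth.group_paths}
        recalls.append(len(true_group & set(added)) / len(true_group))
    return {"recall_mean": float(np.mean(recalls)), "recalls": recalls, "n_reps": n_reps}


def group_null_study(
    n_reps: int = 20,
    seed: int = 0,
    n_subjects: int = 49,
    T: int = 500,
    config: SearchConfig | None = None,
) -> dict:
    """False-positive rate of the group search on AR-only cohorts."""
    atlas = default_atlas()
    config = config or SearchConfig()
    false_pos = []
    for rep_seed in _child_seeds(seed, n_reps):
        params = SimulationParams(
            n_subjects=n_subjects, T=T, seed=rep_seed,
            subgroup_sizes=(), subgroup_n_paths=(), individual_rate=0.0,
        )
        truth = make_true_structure(atlas, params)
        # strip the group paths: AR-only null dynamics
        truth = type(truth)(
            atlas=truth.atlas, group_paths=(), subgroup_paths={},
            individual_paths={sid: () for sid in truth.subject_ids},
            ar_coefficients=truth.ar_coefficients, noise_sd=truth.noise_sd,
            subgroup_assignment=truth.subgroup_assignment,
        )
        cohort = simulate_cohort(truth, params)
        datas = {
            sid: StackedCov.from_data(X, standardize=config.standardize)
            for sid, X in cohort.items()
        }
        _, added = group_search(datas, config)
        false_pos.append(len(added) > 0)
    return {"false_positive_rate": float(np.mean(false_pos)), "n_reps": n_reps}


# ---------------------------------------------------------------------------
# subgrouping and stability


def planted_similarity_study(
    n_reps: int = 20, seed: int = 0, sizes: tuple[int, int] = (39, 10),
    within_rate: float = 8.0, between_rate: float = 1.0,
) -> dict:
    """ARI of Walktrap on planted two-block count similarity matrices."""
    n1, n2 = sizes
    n = n1 + n2
    aris = []
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        sim = np.zeros((n, n), int)
        for i, j in itertools.combinations(range(n), 2):
            same = (i < n1) == (j < n1)
            w = rng.poisson(within_rate if same else between_rate)
            sim[i, j] = sim[j, i] = w
        sol = detect_subgroups(sim, [f"s{i}" for i in range(n)])
        truth = [0] * n1 + [1] * n2
        est = [sol.assignment[f"s{i}"] for i in range(n)]
        aris.append(adjusted_rand_score(truth, est))
    return {"ari_mean": float(np.mean(aris)), "n_reps": n_reps}


def stability_discrimination_study(
    n_runs: int = 20, seed: int = 0, n_reps: int = 20, alpha_step: float = 0.05
) -> dict:
    """Fraction of runs declaring strong blocks stable and noise unstable."""
    alphas = np.arange(alpha_step, 1.0 + 1e-9, alpha_step)
    n = 40
    ids = [f"s{i}" for i in range(n)]

    strong = np.zeros((n, n), int)
    for i, j in itertools.combinations(range(n), 2):
        if (i < 20) == (j < 20):
            strong[i, j] = strong[j, i] = 10
    sol_strong = detect_subgroups(strong, ids)
    stable_hits = 0
    for run_seed in _child_seeds(seed, n_runs):
        _, verdict = assess_stability(strong, sol_strong, alphas, n_reps=n_reps, seed=run_seed)
        stable_hits += verdict.stable

    unstable_hits = 0
    for run_seed in _child_seeds(seed + 1, n_runs):
        rng = np.random.default_rng(run_seed)
        noise = np.triu(rng.integers(0, 4, size=(n, n)), 1)
        noise = noise + noise.T
        sol = detect_subgroups(noise, ids)
        if sol.n_subgroups < 2:
            unstable_hits += 1
            continue
        _, verdict = assess_stability(noise, sol, alphas, n_reps=n_reps, seed=run_seed)
        unstable_hits += not verdict.stable

    return {
        "stable_fraction_strong": stable_hits / n_runs,
        "unstable_fraction_noise": unstable_hits / n_runs,
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# outcome-model calibration


def _density_frame(n: int, rng: np.random.Generator) -> pd.DataFrame:
    dens = pd.DataFrame(0.0, index=[f"s{i}" for i in range(n)], columns=list(METRICS))
    dens["SN-SN_pos"] = rng.uniform(0.2, 0.3, n)
    dens["DMN-FPN_pos"] = rng.uniform(0.02, 0.10, n)
    dens["DMN-SN_neg"] = rng.uniform(0.0, 0.06, n)
    dens["SN-FPN_pos"] = rng.uniform(0.03, 0.14, n)
    return dens


def outcome_coverage_study(n_reps: int = 200, seed: int = 0, n: int = 200) -> dict:
    """95% Wald-CI coverage of planted count and linear coefficients."""
    coeffs = OutcomeCoeffs()
    nb_spec = RegressionSpec("slips", "negative_binomial", ("SN-SN_pos", "DMN-FPN_pos"))
    lin_spec = RegressionSpec(
        "craving_treatment", "gaussian_log_outcome", ("DMN-SN_neg", "SN-FPN_pos")
    )
    nb_cover = lin_cover = nb_used = 0
    for rep_seed in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(rep_seed)
        dens = _density_frame(n, rng)
        out = simulate_outcomes(dens, coeffs, seed=rep_seed + 1)

        res = fit_count_outcome_model(nb_spec, dens, out)
        if res.converged:
            nb_used += 1
            b = res.coefficients.loc["SN-SN_pos"]
            if b["b"] - 1.96 * b["se"] <= coeffs.slips_sn_sn_pos <= b["b"] + 1.96 * b["se"]:
                nb_cover += 1

        res = fit_continuous_outcome_model(lin_spec, dens, out)
        b = res.coefficients.loc["DMN-SN_neg"]
        if b["b"] - 1.96 * b["se"] <= coeffs.craving_dmn_sn_neg <= b["b"] + 1.96 * b["se"]:
            lin_cover += 1
    return {
        "nb_coverage": nb_cover / max(nb_used, 1),
        "linear_coverage": lin_cover / n_reps,
        "n_reps": n_reps,
    }


def familywise_error_study(n_reps: int = 200, seed: int = 0, n: int = 200) -> dict:
    """Familywise error of the six Bonferroni-corrected models under the null."""
    null_coeffs = OutcomeCoeffs(
        slips_sn_sn_pos=0.0, slips_dmn_fpn_pos=0.0, craving_dmn_sn_neg=0.0,
        craving_sn_fpn_pos=0.0, cue_dmn_sn_neg=0.0, cue_sn_fpn_pos=0.0, ftnd_beta=0.0,
    )
    metrics = ["SN-SN_pos", "DMN-FPN_pos", "DMN-SN_neg", "SN-FPN_pos"]
    hits = 0
    for rep_seed in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(rep_seed)
        dens = _density_frame(n, rng)
        out = simulate_outcomes(dens, null_coeffs, seed=rep_seed + 1)
        specs = primary_specs(metrics)
        pvals = []
        for spec in specs:
            if not spec.predictors:
                continue
            res = fit_outcome_model(spec, dens, out)
            if res.converged and np.isfinite(res.model_p):
                pvals.append(res.model_p)
        flags, _ = apply_bonferroni(pvals, m=6)
        hits += any(flags)
    return {"familywise_error": hits / n_reps, "n_reps": n_reps}
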