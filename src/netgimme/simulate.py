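"""Synthetic cohort generation from a known uSEM ground truth.

A cohort is generated from a three-level truth: group paths shared by
everyone, subgroup paths shared within blocks of subjects, and
idiosyncratic individual paths, mirroring the layered structure that the
connectivity search is meant to recover.  The default group map places
contemporaneous paths within the SN (2), FPN (4) and DMN (1) and between
SN-FPN (1) and SN-DMN (2), lag-1 paths within the FPN (2) and DMN (1),
and an autoregressive path on every ROI.

Each subject's series follows the reduced form

    eta_t = (I - A)^(-1) (Phi eta_{t-1} + zeta_t),  zeta_t ~ N(0, diag)

and is kept only if the composite system is stationary (spectral radius
of (I - A)^(-1) Phi below 1); coefficient draws are rejection-resampled
otherwise.

Clinical outcomes are coupled to the *true* density profiles: slips are
negative-binomial with a log link on positive SN-SN and positive DMN-FPN
density, and the two craving outcomes are log-scale linear in negative
DMN-SN and positive SN-FPN density, with demographic covariates drawn
from distributions matching the study cohort's descriptives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import NetworkAtlas
from .usem import Path

#: directed path with its true coefficient
CoefPath = tuple[int, int, int, float]


class StationarityError(RuntimeError):
    """No stationary coefficient draw found within the rejection budget."""


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class OutcomeCoeffs:
    """Ground-truth coefficients linking true densities to outcomes.

    Signs follow the directions reported for this cohort: higher
    positive SN-SN density means more slips, higher positive DMN-FPN
    density fewer slips; more negative DMN-SN density lowers craving and
    more positive SN-FPN density raises it.  Density metrics live on a
    0-0.3 scale, hence the large slopes.
    """

    slips_intercept: float = -2.5
    slips_sn_sn_pos: float = 20.0
    slips_dmn_fpn_pos: float = -20.0
    slips_theta: float = 2.0  # NB dispersion: var = mu + mu^2 / theta
    craving_intercept: float = 1.1
    craving_dmn_sn_neg: float = -5.0
    craving_sn_fpn_pos: float = 5.0
    craving_sigma: float = 0.3
    cue_intercept: float = 0.4
    cue_dmn_sn_neg: float = -2.0
    cue_sn_fpn_pos: float = 2.0
    cue_sigma: float = 0.4
    cue_shift: float = 1.0  # cue outcome = exp(linear + noise) - shift
    # covariate effects on the slips log-mean / craving log-scale
    age_beta: float = 0.0
    sex_beta: float = 0.0
    ftnd_beta: float = 0.05
    treatment_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.slips_theta <= 0:
            raise ValueError("negative-binomial dispersion theta must be positive")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic cohort; defaults emulate the study design."""

    n_subjects: int = 49
    T: int = 500
    burn_in: int = 200
    ar_range: tuple[float, float] = (0.2, 0.6)
    group_range: tuple[float, float] = (0.2, 0.4)
    subgroup_range: tuple[float, float] = (0.2, 0.4)
    individual_range: tuple[float, float] = (0.2, 0.4)
    positive_fraction: float = 0.75  # sign mix of non-AR paths
    subgroup_sizes: tuple[int, ...] = (39, 10)
    subgroup_n_paths: tuple[int, ...] = (6, 18)
    individual_rate: float = 2.0  # Poisson mean of extra paths per subject
    noise_sd: float = 1.0
    max_rejections: int = 200
    outcome_coeffs: OutcomeCoeffs = field(default_factory=OutcomeCoeffs)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subgroup_sizes) != len(self.subgroup_n_paths):
            raise ValueError("subgroup_sizes and subgroup_n_paths must align")
        if self.subgroup_sizes and sum(self.subgroup_sizes) not in (0, self.n_subjects):
            raise ValueError("subgroup sizes must sum to n_subjects (or be empty)")


#: group-level contemporaneous path counts per unordered network pair
DEFAULT_GROUP_CONTEMP = {
    frozenset({"SN"}): 2,
    frozenset({"FPN"}): 4,
    frozenset({"DMN"}): 1,
    frozenset({"SN", "FPN"}): 1,
    frozenset({"SN", "DMN"}): 2,
}
#: group-level lag-1 (non-AR) path counts per unordered network pair
DEFAULT_GROUP_LAGGED = {
    frozenset({"FPN"}): 2,
    frozenset({"DMN"}): 1,
}


# ---------------------------------------------------------------------------
# truth


@dataclass(frozen=True)
class TrueStructure:
    """Ground-truth paths at every level plus noise scales."""

    atlas: NetworkAtlas
    group_paths: tuple[CoefPath, ...]
    subgroup_paths: dict[int, tuple[CoefPath, ...]]
    individual_paths: dict[str, tuple[CoefPath, ...]]
    ar_coefficients: np.ndarray
    noise_sd: np.ndarray
    subgroup_assignment: dict[str, int]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.individual_paths)

    def matrices_for(self, subject_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Composite (A, Phi) for one subject; A[target, source]."""
        p = self.atlas.n_rois
        A = np.zeros((p, p))
        Phi = np.diag(self.ar_coefficients).astype(float)
        paths = list(self.group_paths)
        sg = self.subgroup_assignment.get(subject_id)
        if sg is not None and sg in self.subgroup_paths:
            paths += list(self.subgroup_paths[sg])
        paths += list(self.individual_paths.get(subject_id, ()))
        for s, t, lag, coef in paths:
            (Phi if lag else A)[t, s] = coef
        return A, Phi

    def paths_for(self, subject_id: str, level: str | None = None) -> list[CoefPath]:
        if level == "group":
            return list(self.group_paths)
        if level == "subgroup":
            sg = self.subgroup_assignment.get(subject_id)
            return list(self.subgroup_paths.get(sg, ()))
        if level == "individual":
            return list(self.individual_paths.get(subject_id, ()))
        return (
            self.paths_for(subject_id, "group")
            + self.paths_for(subject_id, "subgroup")
            + self.paths_for(subject_id, "individual")
        )


def spectral_radius(A: np.ndarray, Phi: np.ndarray) -> float:
    B = np.linalg.inv(np.eye(A.shape[0]) - A)
    return float(np.max(np.abs(np.linalg.eigvals(B @ Phi))))


def is_stationary(A: np.ndarray, Phi: np.ndarray, tol: float = 0.999) -> bool:
    try:
        return spectral_radius(A, Phi) < tol
    except np.linalg.LinAlgError:
        return False


def _network_pair_slots(atlas: NetworkAtlas, pair: frozenset, lag: int) -> list[Path]:
    nets = atlas.networks_of_indices()
    p = atlas.n_rois
    slots = []
    for s in range(p):
        for t in range(p):
            if s == t:
                continue
            if frozenset({nets[s], nets[t]}) == pair:
                slots.append((s, t, lag))
    return slots


def _draw_coef(rng: np.random.Generator, rng_range, positive_fraction: float) -> float:
    mag = rng.uniform(*rng_range)
    sign = 1.0 if rng.random() < positive_fraction else -1.0
    return sign * mag


def make_true_structure(atlas: NetworkAtlas, params: SimulationParams) -> TrueStructure:
    """Draw a layered ground truth; rejection-resampled until stationary."""
    master = np.random.default_rng(params.seed)
    for _attempt in range(params.max_rejections):
        rng = np.random.default_rng(master.integers(2**31))
        structure = _draw_structure(atlas, params, rng)
        ok = all(
            is_stationary(*structure.matrices_for(sid))
            for sid in structure.subject_ids
        )
        if ok:
            return structure
    raise StationarityError(
        f"no stationary draw in {params.max_rejections} attempts; "
        "reduce coefficient ranges or path counts"
    )


def _draw_structure(atlas: NetworkAtlas, params: SimulationParams, rng) -> TrueStructure:
    p = atlas.n_rois
    subject_ids = [f"sub-{i + 1:03d}" for i in range(params.n_subjects)]
    ar = rng.uniform(*params.ar_range, size=p)

    taken: set[Path] = set()

    def admissible(slot: Path) -> bool:
        # reciprocal contemporaneous pairs are excluded from the truth:
        # their joint effect is nearly unidentifiable from one stationary run
        s, t, lag = slot
        if slot in taken:
            return False
        return not (lag == 0 and (t, s, 0) in taken)

    group: list[CoefPath] = []
    for table, lag in ((DEFAULT_GROUP_CONTEMP, 0), (DEFAULT_GROUP_LAGGED, 1)):
        for pair, count in table.items():
            for _ in range(count):  # one at a time: picks constrain later picks
                slots = [s for s in _network_pair_slots(atlas, pair, lag) if admissible(s)]
                if not slots:
                    raise ValueError(f"not enough slots for {set(pair)} lag {lag}")
                path = slots[rng.integers(len(slots))]
                taken.add(path)
                group.append((*path, _draw_coef(rng, params.group_range, params.positive_fraction)))

    all_slots = [
        (s, t, lag)
        for lag in (0, 1)
        for s in range(p)
        for t in range(p)
        if s != t
    ]

    subgroup_paths: dict[int, tuple[CoefPath, ...]] = {}
    assignment: dict[str, int] = {}
    if params.subgroup_sizes:
        idx = 0
        for sg_id, (size, n_paths) in enumerate(
            zip(params.subgroup_sizes, params.subgroup_n_paths), start=1
        ):
            for sid in subject_ids[idx: idx + size]:
                assignment[sid] = sg_id
            idx += size
            chosen = []
            for _ in range(n_paths):
                avail = [s for s in all_slots if admissible(s)]
                path = avail[rng.integers(len(avail))]
                taken.add(path)
                chosen.append(path)
            subgroup_paths[sg_id] = tuple(
                (*path, _draw_coef(rng, params.subgroup_range, params.positive_fraction))
                for path in chosen
            )
    else:
        assignment = {sid: 1 for sid in subject_ids}

    individual: dict[str, tuple[CoefPath, ...]] = {}
    for sid in subject_ids:
        n_extra = int(rng.poisson(params.individual_rate)) if params.individual_rate > 0 else 0
        own: list[CoefPath] = []
        own_slots: set[Path] = set()
        for _ in range(n_extra):
            avail = [
                s for s in all_slots
                if admissible(s) and s not in own_slots
                and not (s[2] == 0 and (s[1], s[0], 0) in own_slots)
            ]
            if not avail:
                break
            path = avail[rng.integers(len(avail))]
            own_slots.add(path)
            own.append(
                (*path, _draw_coef(rng, params.individual_range, params.positive_fraction))
            )
        individual[sid] = tuple(own)

    return TrueStructure(
        atlas=atlas,
        group_paths=tuple(group),
        subgroup_paths=subgroup_paths,
        individual_paths=individual,
        ar_coefficients=ar,
        noise_sd=np.full(p, params.noise_sd),
        subgroup_assignment=assignment,
    )


# ---------------------------------------------------------------------------
# time-series simulation


def simulate_var(
    A: np.ndarray,
    Phi: np.ndarray,
    T: int,
    seed,
    burn_in: int = 200,
    noise_sd=1.0,
) -> np.ndarray:
    """T x p draw from the reduced form of a (A, Phi) uSEM."""
    if not is_stationary(A, Phi):
        raise StationarityError("composite system is not stationary")
    p = A.shape[0]
    B = np.linalg.inv(np.eye(p) - A)
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=noise_sd, size=(T + burn_in, p))
    eta = np.zeros(p)
    out = np.empty((T + burn_in, p))
    for t in range(T + burn_in):
        eta = B @ (Phi @ eta + noise[t])
        out[t] = eta
    return out[burn_in:]


def simulate_subject_timeseries(
    structure: TrueStructure,
    subject_id: str,
    T: int,
    seed,
    burn_in: int = 200,
) -> np.ndarray:
    """Simulate one subject's T x p matrix via the reduced form."""
    A, Phi = structure.matrices_for(subject_id)
    try:
        return simulate_var(A, Phi, T, seed, burn_in=burn_in, noise_sd=structure.noise_sd)
    except StationarityError as err:
        raise StationarityError(f"{subject_id}: {err}") from None


def simulate_cohort(
    structure: TrueStructure, params: SimulationParams
) -> dict[str, np.ndarray]:
    """One series per subject, child seeds derived from the master seed."""
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(len(structure.subject_ids))
    return {
        sid: simulate_subject_timeseries(
            structure, sid, params.T, child, burn_in=params.burn_in
        )
        for sid, child in zip(structure.subject_ids, children)
    }


def stationary_stacked_cov(A: np.ndarray, Phi: np.ndarray, noise_sd) -> np.ndarray:
    """Closed-form stationary covariance of [eta_{t-1}; eta_t].

    Solves the reduced-form discrete Lyapunov equation
    V = G V G' + C with G = (I-A)^(-1) Phi and C = (I-A)^(-1) Psi (I-A)^(-T).
    """
    from scipy.linalg import solve_discrete_lyapunov

    p = A.shape[0]
    B = np.linalg.inv(np.eye(p) - A)
    G = B @ Phi
    C = B @ np.diag(np.asarray(noise_sd, float) ** 2) @ B.T
    V = solve_discrete_lyapunov(G, C)
    top = np.hstack([V, V @ G.T])
    bot = np.hstack([G @ V, G @ V @ G.T + C])
    return np.vstack([top, bot])


# ---------------------------------------------------------------------------
# outcomes


def simulate_outcomes(
    density_profiles: pd.DataFrame,
    coeffs: OutcomeCoeffs,
    seed,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Clinical outcomes coupled to the true density metrics.

    ``density_profiles`` is a subjects x metrics table holding at least
    the columns ``SN-SN_pos``, ``DMN-FPN_pos``, ``DMN-SN_neg`` and
    ``SN-FPN_pos`` (as produced by the density module from true graphs).
    Covariates emulate the cohort descriptives: age ~ N(28.35, 6.36)
    truncated to 18-45, sex ~ Bernoulli(28/49), FTND ~ N(4.49, 1.86)
    clipped to 0-10, treatment ~ Bernoulli(29/49).
    """
    rng = np.random.default_rng(seed)
    n = len(density_profiles)
    age = np.clip(rng.normal(28.35, 6.36, size=n), 18, 45)
    sex = (rng.random(n) < 28 / 49).astype(int)
    ftnd = np.clip(rng.normal(4.49, 1.86, size=n), 0, 10)
    treatment = (rng.random(n) < 29 / 49).astype(int)
    baseline_cpd = np.clip(rng.normal(11.62, 5.34, size=n), 1, None)

    covar_lin = (
        coeffs.age_beta * (age - age.mean())
        + coeffs.sex_beta * sex
        + coeffs.ftnd_beta * (ftnd - ftnd.mean())
        + coeffs.treatment_beta * treatment
    )

    mu = np.exp(
        coeffs.slips_intercept
        + coeffs.slips_sn_sn_pos * density_profiles["SN-SN_pos"].to_numpy()
        + coeffs.slips_dmn_fpn_pos * density_profiles["DMN-FPN_pos"].to_numpy()
        + covar_lin
    )
    theta = coeffs.slips_theta
    slips = rng.negative_binomial(theta, theta / (theta + mu))

    craving = np.exp(
        coeffs.craving_intercept
        + coeffs.craving_dmn_sn_neg * density_profiles["DMN-SN_neg"].to_numpy()
        + coeffs.craving_sn_fpn_pos * density_profiles["SN-FPN_pos"].to_numpy()
        + covar_lin
        + rng.normal(scale=coeffs.craving_sigma, size=n)
    )

    cue = (
        np.exp(
            coeffs.cue_intercept
            + coeffs.cue_dmn_sn_neg * density_profiles["DMN-SN_neg"].to_numpy()
            + coeffs.cue_sn_fpn_pos * density_profiles["SN-FPN_pos"].to_numpy()
            + rng.normal(scale=coeffs.cue_sigma, size=n)
        )
        - coeffs.cue_shift
    )

    out = pd.DataFrame(
        {
            "subject_id": density_profiles.index,
            "slips": slips.astype(int),
            "craving_treatment": craving,
            "cue_craving": cue,
            "age": age,
            "sex": sex,
            "ftnd": ftnd,
            "treatment": treatment,
            "baseline_cpd": baseline_cpd,
        }
    ).set_index("subject_id")
    if missing_rate > 0:
        mask = rng.random(n) < missing_rate
        out.loc[mask, "craving_treatment"] = np.nan
    return out
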