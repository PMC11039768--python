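"""Three-stage data-driven model search across a cohort.

Starting from autoregressive-only person models, the search first adds
paths whose modification index is significant for at least a 75%
majority of subjects (group level), then clusters subjects on a sparse
sign-aware count similarity matrix with Walktrap and repeats the
majority search within each subgroup (threshold 50%), and finally adds
person-specific paths one at a time until the subject's model reaches
excellent fit on two of four indices.  Paths that lose significance as
others are added are pruned at each level, with lower-level paths
protected from higher-level pruning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np

from .usem import (
    CandidateScore,
    FitIndices,
    FittedUSEM,
    Path,
    PathPattern,
    StackedCov,
    all_candidate_paths,
    compute_fit_indices,
    excellent_fit,
    fit_usem,
    modification_indices,
    path_sort_key,
    prune_paths,
)


@dataclass(frozen=True)
class SearchConfig:
    """Tunables of the staged search."""

    gamma_group: float = 0.75  # majority fraction for group-level paths
    gamma_sub: float = 0.50  # majority fraction within a subgroup
    alpha: float = 0.05  # two-sided level for MI counting and pruning
    walktrap_steps: int = 4
    max_paths: int | None = 60  # per-subject safety cap on added paths
    ar_start: bool = True  # free all AR paths from the start
    standardize: bool = True
    bonferroni_candidates: bool = False  # Bonferroni alpha over candidates
    direction_refinement: bool = True  # post-search orientation check of added paths

    def __post_init__(self) -> None:
        if not (0.5 <= self.gamma_group <= 1.0):
            raise ValueError("gamma_group must be in [0.5, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class SubgroupSolution:
    subject_ids: tuple[str, ...]
    assignment: dict[str, int]  # subject -> subgroup id, contiguous from 1
    modularity: float
    n_subgroups: int
    degenerate: bool = False  # all-zero similarity: everyone a singleton

    def members(self, sg: int) -> list[str]:
        return [s for s in self.subject_ids if self.assignment[s] == sg]


@dataclass
class SubjectResult:
    subject_id: str
    pattern: PathPattern
    fit: FittedUSEM
    indices: FitIndices
    levels: dict[Path, str]  # non-AR path -> {group, subgroup, individual}
    converged: bool


@dataclass
class GimmeResult:
    subject_ids: list[str]
    group_pattern: PathPattern
    group_paths: list[Path]  # non-AR paths added at group level
    similarity: np.ndarray
    subgroup_solution: SubgroupSolution
    subgroup_paths: dict[int, list[Path]]
    subjects: dict[str, SubjectResult]
    mean_fit: dict[str, float]
    config: SearchConfig = field(default_factory=SearchConfig)


# ---------------------------------------------------------------------------
# shared majority add/prune loop


class _CohortFitter:
    """Caches warm starts while a pattern evolves over a cohort."""

    def __init__(self, datas: dict[str, StackedCov]):
        self.datas = datas
        self.values: dict[str, dict[Path, float]] = {sid: {} for sid in datas}
        self.summed_F_cache: dict[tuple, float] = {}

    def fit(self, sid: str, pattern: PathPattern) -> FittedUSEM:
        free = pattern.free_paths()
        x0 = np.array([self.values[sid].get(p, 0.0) for p in free]) if free else None
        fit = fit_usem(self.datas[sid], pattern, x0=x0)
        if fit.converged:
            self.values[sid] = dict(zip(free, fit.x))
        return fit

    def fit_all(self, pattern: PathPattern, subset=None) -> dict[str, FittedUSEM]:
        sids = subset if subset is not None else list(self.datas)
        return {sid: self.fit(sid, pattern) for sid in sids}


def _effective_alpha(config: SearchConfig, n_candidates: int) -> float:
    if config.bonferroni_candidates and n_candidates > 0:
        return config.alpha / n_candidates
    return config.alpha


def _majority_add_prune(
    fitter: _CohortFitter,
    members: list[str],
    base_pattern: PathPattern,
    gamma: float,
    config: SearchConfig,
    protected: frozenset[Path],
    max_added: int = 60,
) -> tuple[PathPattern, list[Path]]:
    """Iterative majority path addition then majority pruning.

    A candidate is added when its modification index is significant for
    at least ``gamma`` of ``members`` (ties: larger summed MI, then
    canonical path order).  Added paths that are Wald-significant for
    fewer than ``gamma`` of members are afterwards pruned, worst first.
    """
    K = len(members)
    pattern = base_pattern
    added: list[Path] = []
    p = pattern.p
    candidates_all = all_candidate_paths(p)

    def add_loop(pattern: PathPattern) -> tuple[PathPattern, int]:
        n_new = 0
        while len(added) < max_added:
            fits = fitter.fit_all(pattern, members)
            cands = [c for c in candidates_all if not pattern.has_path(c)]
            if not cands:
                break
            alpha_eff = _effective_alpha(config, len(cands))
            counts: dict[Path, int] = {c: 0 for c in cands}
            mi_sums: dict[Path, float] = {c: 0.0 for c in cands}
            for sid in members:
                fit = fits[sid]
                if not fit.converged:
                    warnings.warn(f"{sid}: non-convergence; excluded from this round's count")
                    continue
                for score in modification_indices(fit, pattern, cands, fitter.datas[sid]):
                    mi_sums[score.path] += score.mi
                    if score.p_value < alpha_eff:
                        counts[score.path] += 1
            best = max(
                cands, key=lambda c: (counts[c], mi_sums[c], [-v for v in path_sort_key(c)])
            )
            if counts[best] / K >= gamma:
                pattern = pattern.with_paths([best])
                added.append(best)
                n_new += 1
            else:
                break
        return pattern, n_new

    # a refinement pass can reorient paths and free up majority-level signal
    # that the first greedy pass absorbed, so add and refine alternate once
    for _round in range(2):
        pattern, n_new = add_loop(pattern)
        if config.direction_refinement and added:
            pattern, added = _refine_directions(fitter, members, pattern, added)
        else:
            break
        if _round > 0 or n_new == 0:
            break

    # majority pruning of the added paths (protected paths never pruned)
    while added:
        fits = fitter.fit_all(pattern, members)
        sig_counts = {
            path: sum(
                1 for sid in members
                if fits[sid].converged and fits[sid].wald_p(path) < config.alpha
            )
            for path in added
        }
        worst = min(added, key=lambda c: (sig_counts[c], path_sort_key(c)))
        if sig_counts[worst] / K < gamma:
            pattern = pattern.without_paths([worst])
            added.remove(worst)
        else:
            break

    return pattern, sorted(added, key=path_sort_key)


def _summed_F(fitter: _CohortFitter, members, pattern: PathPattern) -> float:
    key = (tuple(pattern.free_paths()), tuple(members))
    cached = fitter.summed_F_cache.get(key)
    if cached is not None:
        return cached
    total = 0.0
    for sid in members:
        fit = fitter.fit(sid, pattern)
        if not fit.converged:
            total = np.inf
            break
        total += fit.F_ML
    fitter.summed_F_cache[key] = total
    return total


def _refine_directions(
    fitter: _CohortFitter,
    members: list[str],
    pattern: PathPattern,
    added: list[Path],
) -> tuple[PathPattern, list[Path]]:
    """Orientation check of the paths added by the greedy search.

    One-path-at-a-time addition can lock in a mirrored parameterisation
    of a directed pair (most often when a contemporaneous and a lagged
    path share the same ROI pair): each mirrored path stays significant,
    yet the configuration fits worse than the correctly oriented one.
    For every ROI pair carrying added paths, the equal-complexity
    orientation variants are compared by the cohort-summed discrepancy
    and the best is kept.  Because fixing one pair changes the evidence
    for the others, sweeps repeat until no pair changes (greedy errors
    interact).  Variants that collide with existing paths are skipped;
    ties keep the current orientation.
    """
    added = list(added)
    for _sweep in range(5):
        changed = False
        pairs: dict[tuple[int, int], list[Path]] = {}
        for s, t, lag in added:
            if s == t:
                continue
            pairs.setdefault((min(s, t), max(s, t)), []).append((s, t, lag))

        for pair_paths in pairs.values():
            if len(pair_paths) > 2:
                continue  # full 2x2 already present: orientation moot
            variants = [[]]
            for s, t, lag in pair_paths:
                variants = [v + [d] for v in variants for d in ((s, t, lag), (t, s, lag))]
            candidates = []
            for variant in variants:
                if len(set(variant)) < len(variant):
                    continue
                collision = any(
                    path not in pair_paths and pattern.has_path(path) for path in variant
                )
                if collision:
                    continue
                trial = pattern.without_paths(pair_paths).with_paths(variant)
                candidates.append((variant, trial))
            if len(candidates) < 2:
                continue
            scores = [
                (_summed_F(fitter, members, trial), i)
                for i, (_, trial) in enumerate(candidates)
            ]
            original_idx = next(
                i for i, (variant, _) in enumerate(candidates)
                if set(variant) == set(pair_paths)
            )
            best_F, best_i = min(scores)
            if best_i != original_idx and best_F < scores[original_idx][0] - 1e-9:
                variant, trial = candidates[best_i]
                pattern = trial
                for old, new in zip(pair_paths, variant):
                    if old != new:
                        added.remove(old)
                        added.append(new)
                changed = True
        if not changed:
            break
    return pattern, sorted(added, key=path_sort_key)


# ---------------------------------------------------------------------------
# stage operations


def group_search(
    datas: dict[str, StackedCov], config: SearchConfig | None = None
) -> tuple[PathPattern, list[Path]]:
    """Group-level path search over the whole cohort."""
    config = config or SearchConfig()
    if len(datas) < 2:
        raise ValueError("group search needs at least two subjects")
    p = next(iter(datas.values())).p
    if any(d.p != p for d in datas.values()):
        raise ValueError("all subjects must share the same ROI set")
    base = PathPattern.ar_only(p) if config.ar_start else PathPattern.empty(p)
    ar_paths = frozenset((i, i, 1) for i in range(p))
    fitter = _CohortFitter(datas)
    cap = config.max_paths if config.max_paths is not None else 10**9
    return _majority_add_prune(
        fitter, list(datas), base, config.gamma_group, config, ar_paths, max_added=cap
    )


def build_similarity_matrix(
    datas: dict[str, StackedCov],
    group_pattern: PathPattern,
    config: SearchConfig | None = None,
) -> np.ndarray:
    """Sparse count similarity over subjects, sign-aware.

    Per subject the feature set contains (i) every non-AR group path
    tagged by the sign of that subject's estimate and (ii) every
    still-fixed candidate whose modification index is significant,
    tagged by the sign of its expected parameter change.  The (i, j)
    entry counts features shared by subjects i and j; the diagonal is 0.
    """
    config = config or SearchConfig()
    sids = list(datas)
    p = group_pattern.p
    ar = {(i, i, 1) for i in range(p)}
    group_non_ar = [c for c in group_pattern.free_paths() if c not in ar]
    features: list[set] = []
    fitter = _CohortFitter(datas)
    for sid in sids:
        fit = fitter.fit(sid, group_pattern)
        fs: set = set()
        for path in group_non_ar:
            est = fit.estimate(path)
            if est != 0:
                fs.add((path, 1 if est > 0 else -1))
        for score in modification_indices(fit, group_pattern, None, datas[sid]):
            if score.p_value < config.alpha and score.epc != 0:
                fs.add((score.path, 1 if score.epc > 0 else -1))
        features.append(fs)
    n = len(sids)
    sim = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = len(features[i] & features[j])
    return sim


def detect_subgroups(
    sim: np.ndarray,
    subject_ids,
    config: SearchConfig | None = None,
) -> SubgroupSolution:
    """Walktrap community detection on the weighted similarity graph."""
    config = config or SearchConfig()
    sim = np.asarray(sim)
    n = sim.shape[0]
    subject_ids = tuple(subject_ids)
    if sim.shape != (n, n) or len(subject_ids) != n:
        raise ValueError("similarity matrix and subject ids disagree")
    if not np.array_equal(sim, sim.T) or np.any(np.diag(sim) != 0) or np.any(sim < 0):
        raise ValueError("similarity must be symmetric, nonnegative, zero-diagonal")

    iu = np.triu_indices(n, k=1)
    mask = sim[iu] > 0
    edges = list(zip(iu[0][mask], iu[1][mask]))
    weights = sim[iu][mask].astype(float)
    if not edges:
        return SubgroupSolution(
            subject_ids=subject_ids,
            assignment={sid: i + 1 for i, sid in enumerate(subject_ids)},
            modularity=float("nan"),
            n_subgroups=n,
            degenerate=True,
        )
    g = ig.Graph(n=n, edges=edges)
    dendro = g.community_walktrap(weights=list(weights), steps=config.walktrap_steps)
    clustering = dendro.as_clustering()
    membership = clustering.membership
    # relabel contiguous from 1 in order of first appearance
    relabel: dict[int, int] = {}
    assignment = {}
    for sid, m in zip(subject_ids, membership):
        if m not in relabel:
            relabel[m] = len(relabel) + 1
        assignment[sid] = relabel[m]
    return SubgroupSolution(
        subject_ids=subject_ids,
        assignment=assignment,
        modularity=float(g.modularity(membership, weights=list(weights))),
        n_subgroups=len(relabel),
    )


def subgroup_search(
    datas: dict[str, StackedCov],
    group_pattern: PathPattern,
    solution: SubgroupSolution,
    config: SearchConfig | None = None,
) -> dict[int, list[Path]]:
    """Majority search within each subgroup of size >= 2."""
    config = config or SearchConfig()
    fitter = _CohortFitter(datas)
    protected = frozenset(group_pattern.free_paths())
    out: dict[int, list[Path]] = {}
    cap = config.max_paths if config.max_paths is not None else 10**9
    for sg in range(1, solution.n_subgroups + 1):
        members = solution.members(sg)
        if len(members) < 2:
            out[sg] = []
            continue
        _, added = _majority_add_prune(
            fitter, members, group_pattern, config.gamma_sub, config, protected,
            max_added=cap,
        )
        out[sg] = added
    return out


def individual_search(
    data: StackedCov,
    base_pattern: PathPattern,
    config: SearchConfig | None = None,
    protected: frozenset[Path] | None = None,
) -> tuple[PathPattern, FittedUSEM, FitIndices, list[Path]]:
    """Add the largest significant-MI path until excellent fit.

    Stops when two of four fit-index thresholds are met, no candidate is
    significant, or the cap is reached; then prunes non-significant
    individual-level additions (base-pattern paths are protected).
    """
    config = config or SearchConfig()
    if protected is None:
        protected = frozenset(base_pattern.free_paths())
    pattern = base_pattern
    added: list[Path] = []
    cap = config.max_paths if config.max_paths is not None else 10**9

    fit = fit_usem(data, pattern)
    idx = compute_fit_indices(fit, pattern, data)
    while len(added) < cap:
        if excellent_fit(idx):
            break
        scores = modification_indices(fit, pattern, None, data)
        sig = [s for s in scores if s.p_value < config.alpha]
        if not sig:
            break
        best = max(sig, key=lambda s: (s.mi, [-v for v in path_sort_key(s.path)]))
        pattern = pattern.with_paths([best.path])
        added.append(best.path)
        new_fit = fit_usem(data, pattern)
        if not new_fit.converged:
            warnings.warn("non-convergence during individual search; keeping last model")
            pattern = pattern.without_paths([best.path])
            added.remove(best.path)
            break
        fit = new_fit
        idx = compute_fit_indices(fit, pattern, data)

    if added:
        pruned = prune_paths(fit, pattern, config.alpha, protected)
        if pruned != pattern:
            added = [a for a in added if pruned.has_path(a)]
            pattern = pruned
            fit = fit_usem(data, pattern)
            idx = compute_fit_indices(fit, pattern, data)
    return pattern, fit, idx, sorted(added, key=path_sort_key)


def run_gimme(
    cohort: dict[str, np.ndarray],
    config: SearchConfig | None = None,
) -> GimmeResult:
    """Full staged search: group -> subgrouping -> subgroup -> individual."""
    config = config or SearchConfig()
    datas = {
        sid: StackedCov.from_data(X, standardize=config.standardize)
        for sid, X in cohort.items()
    }
    p = next(iter(datas.values())).p
    ar = {(i, i, 1) for i in range(p)}

    group_pattern, group_paths = group_search(datas, config)
    sim = build_similarity_matrix(datas, group_pattern, config)
    solution = detect_subgroups(sim, list(datas), config)
    sg_paths = subgroup_search(datas, group_pattern, solution, config)

    subjects: dict[str, SubjectResult] = {}
    for sid, data in datas.items():
        sg = solution.assignment[sid]
        own_sub = sg_paths.get(sg, [])
        base = group_pattern.with_paths(own_sub)
        pattern, fit, idx, added = individual_search(data, base, config)
        levels: dict[Path, str] = {}
        for path in pattern.free_paths():
            if path in ar:
                continue
            if path in added:
                levels[path] = "individual"
            elif path in own_sub:
                levels[path] = "subgroup"
            else:
                levels[path] = "group"
        subjects[sid] = SubjectResult(
            subject_id=sid, pattern=pattern, fit=fit, indices=idx,
            levels=levels, converged=fit.converged,
        )

    mean_fit = {
        name: float(np.mean([getattr(r.indices, name) for r in subjects.values()]))
        for name in ("CFI", "NNFI", "RMSEA", "SRMR")
    }
    return GimmeResult(
        subject_ids=list(datas),
        group_pattern=group_pattern,
        group_paths=group_paths,
        similarity=sim,
        subgroup_solution=solution,
        subgroup_paths=sg_paths,
        subjects=subjects,
        mean_fit=mean_fit,
        config=config,
    )
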