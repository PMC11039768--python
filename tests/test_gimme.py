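"""Tests of the staged group/subgroup/individual search."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from netgimme import PathPattern, StackedCov
from netgimme.gimme import (
    SearchConfig,
    build_similarity_matrix,
    detect_subgroups,
    group_search,
    individual_search,
    run_gimme,
    subgroup_search,
)
from netgimme.simulate import simulate_var

AR3 = np.diag([0.4, 0.3, 0.5])


def shared_path_cohort(n_subjects, a, T, seed0, p=3, extra=None):
    """Cohort sharing the contemporaneous path 0 -> 1 with coefficient a."""
    A = np.zeros((p, p))
    A[1, 0] = a
    if extra:
        for s, t, val in extra:
            A[t, s] = val
    Phi = np.diag([0.4, 0.3, 0.5, 0.35, 0.45][:p])
    return {
        f"s{i}": simulate_var(A, Phi, T, seed0 + i) for i in range(n_subjects)
    }


def to_datas(cohort):
    return {sid: StackedCov.from_data(X) for sid, X in cohort.items()}


class TestGroupSearch:
    def test_recovers_shared_path(self):
        datas = to_datas(shared_path_cohort(12, 0.4, 500, seed0=0))
        pattern, added = group_search(datas, SearchConfig())
        assert (0, 1, 0) in added
        assert all(pattern.has_path((i, i, 1)) for i in range(3))

    def test_null_cohort_adds_nothing(self):
        datas = to_datas(shared_path_cohort(12, 0.0, 500, seed0=50))
        _, added = group_search(datas, SearchConfig())
        assert added == []

    def test_minority_path_not_added(self):
        """A path present in 60% of subjects stays below the 75% majority."""
        p = 3
        Phi = np.diag([0.4, 0.3, 0.5])
        A1 = np.zeros((p, p))
        A1[1, 0] = 0.5
        cohort = {}
        for i in range(20):
            A = A1 if i < 12 else np.zeros((p, p))  # 60% carry the path
            cohort[f"s{i}"] = simulate_var(A, Phi, 500, 200 + i)
        _, added = group_search(to_datas(cohort), SearchConfig())
        assert (0, 1, 0) not in added

    def test_invariant_to_subject_order(self):
        cohort = shared_path_cohort(8, 0.4, 400, seed0=300)
        datas = to_datas(cohort)
        _, added1 = group_search(datas, SearchConfig())
        reordered = dict(reversed(list(datas.items())))
        _, added2 = group_search(reordered, SearchConfig())
        assert added1 == added2

    def test_monotone_in_gamma(self):
        """Raising the majority threshold never adds new paths."""
        datas = to_datas(shared_path_cohort(10, 0.35, 400, seed0=400,
                                            extra=[(1, 2, 0.3)]))
        added = {}
        for gamma in (0.5, 0.75, 1.0):
            _, paths = group_search(datas, SearchConfig(gamma_group=gamma))
            added[gamma] = set(paths)
        assert added[1.0] <= added[0.75] <= added[0.5]


class TestSimilarity:
    def test_identical_and_disjoint_subjects(self):
        # two pairs of twins with opposite-signed omitted paths
        p = 3
        Phi = np.diag([0.4, 0.3, 0.5])
        Apos = np.zeros((p, p))
        Apos[1, 0] = 0.5
        Aneg = np.zeros((p, p))
        Aneg[2, 1] = -0.5
        cohort = {
            "a1": simulate_var(Apos, Phi, 600, 1),
            "a2": simulate_var(Apos, Phi, 600, 2),
            "b1": simulate_var(Aneg, Phi, 600, 3),
            "b2": simulate_var(Aneg, Phi, 600, 4),
        }
        datas = to_datas(cohort)
        pattern = PathPattern.ar_only(p)
        sim = build_similarity_matrix(datas, pattern, SearchConfig())
        assert np.array_equal(sim, sim.T)
        assert np.all(np.diag(sim) == 0)
        # twins share their omitted-path feature; cross pairs share none of it
        assert sim[0, 1] >= 1
        assert sim[2, 3] >= 1

    def test_opposite_signs_do_not_count(self):
        """The same path with opposite estimate signs contributes nothing."""
        p = 3
        Phi = np.diag([0.4, 0.3, 0.5])
        Apos = np.zeros((p, p))
        Apos[1, 0] = 0.5
        Aneg = np.zeros((p, p))
        Aneg[1, 0] = -0.5
        cohort = {
            "pos": simulate_var(Apos, Phi, 2000, 5),
            "neg": simulate_var(Aneg, Phi, 2000, 6),
        }
        sim = build_similarity_matrix(to_datas(cohort), PathPattern.ar_only(p))
        assert sim[0, 1] == 0


class TestDetectSubgroups:
    def test_disconnected_blocks(self):
        n = 10
        sim = np.zeros((n, n), int)
        for i, j in itertools.combinations(range(5), 2):
            sim[i, j] = sim[j, i] = 4
        for i, j in itertools.combinations(range(5, 10), 2):
            sim[i, j] = sim[j, i] = 4
        sol = detect_subgroups(sim, [f"s{i}" for i in range(n)])
        assert sol.n_subgroups == 2
        labels = [sol.assignment[f"s{i}"] for i in range(n)]
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert set(labels) == {1, 2}

    def test_planted_partition_recovery(self):
        """39/10 planted blocks recovered with high ARI on average."""
        aris = []
        for rep in range(20):
            rng = np.random.default_rng(rep)
            n1, n2 = 39, 10
            n = n1 + n2
            sim = np.zeros((n, n), int)
            for i, j in itertools.combinations(range(n), 2):
                same = (i < n1) == (j < n1)
                sim[i, j] = sim[j, i] = rng.poisson(8 if same else 1)
            sol = detect_subgroups(sim, [f"s{i}" for i in range(n)])
            truth = [0] * n1 + [1] * n2
            est = [sol.assignment[f"s{i}"] for i in range(n)]
            aris.append(adjusted_rand_score(truth, est))
        assert np.mean(aris) >= 0.9

    def test_matches_max_modularity_on_small_graph(self):
        """Walktrap's chosen cut equals the exhaustive max-modularity
        partition on a small two-community graph."""
        import igraph as ig

        sim = np.array(
            [
                [0, 5, 4, 0, 0, 1],
                [5, 0, 6, 0, 0, 0],
                [4, 6, 0, 1, 0, 0],
                [0, 0, 1, 0, 7, 5],
                [0, 0, 0, 7, 0, 6],
                [1, 0, 0, 5, 6, 0],
            ]
        )
        sol = detect_subgroups(sim, list("abcdef"))
        iu = np.triu_indices(6, 1)
        mask = sim[iu] > 0
        g = ig.Graph(n=6, edges=list(zip(iu[0][mask], iu[1][mask])))
        w = list(sim[iu][mask].astype(float))

        best_q, best_parts = -1.0, None
        for labels in itertools.product(range(3), repeat=6):
            q = g.modularity(list(labels), weights=w)
            if q > best_q + 1e-12:
                best_q, best_parts = q, labels
        est = [sol.assignment[s] for s in "abcdef"]
        assert adjusted_rand_score(est, list(best_parts)) == 1.0

    def test_all_zero_matrix_gives_singletons(self):
        sol = detect_subgroups(np.zeros((4, 4), int), list("abcd"))
        assert sol.degenerate
        assert sol.n_subgroups == 4


class TestSubgroupAndIndividual:
    def test_subgroup_planted_path(self):
        """A path shared by one block only is found at subgroup level."""
        p = 3
        Phi = np.diag([0.4, 0.3, 0.5])
        A_sub = np.zeros((p, p))
        A_sub[2, 1] = 0.4
        cohort = {}
        for i in range(8):
            A = A_sub if i < 4 else np.zeros((p, p))
            cohort[f"s{i}"] = simulate_var(A, Phi, 500, 600 + i)
        datas = to_datas(cohort)
        group_pattern, _ = group_search(datas, SearchConfig())
        sim = build_similarity_matrix(datas, group_pattern)
        sol = detect_subgroups(sim, list(datas))
        sg_paths = subgroup_search(datas, group_pattern, sol, SearchConfig())
        found = set().union(*[set(v) for v in sg_paths.values()]) if sg_paths else set()
        assert (1, 2, 0) in found or group_pattern.has_path((1, 2, 0))

    def test_singleton_subgroup_empty(self):
        datas = to_datas(shared_path_cohort(3, 0.0, 300, seed0=700))
        pattern = PathPattern.ar_only(3)
        from netgimme.gimme import SubgroupSolution

        sol = SubgroupSolution(
            subject_ids=tuple(datas), assignment={s: i + 1 for i, s in enumerate(datas)},
            modularity=0.0, n_subgroups=3,
        )
        sg = subgroup_search(datas, pattern, sol, SearchConfig())
        assert all(v == [] for v in sg.values())

    def test_individual_search_early_stop(self):
        p = 3
        Phi = np.diag([0.4, 0.3, 0.5])
        X = simulate_var(np.zeros((p, p)), Phi, 500, 800)
        data = StackedCov.from_data(X)
        pattern, fit, idx, added = individual_search(data, PathPattern.ar_only(p))
        assert added == []  # AR-only truth: base model already excellent

    def test_individual_search_recovers_idiosyncratic_path(self):
        p = 4
        Phi = np.diag([0.4, 0.3, 0.5, 0.35])
        A = np.zeros((p, p))
        A[1, 0] = 0.6
        X = simulate_var(A, Phi, 500, 801)
        data = StackedCov.from_data(X)
        pattern, fit, idx, added = individual_search(data, PathPattern.ar_only(p))
        assert (0, 1, 0) in added

    def test_max_paths_zero_returns_base(self):
        p = 3
        A = np.zeros((p, p))
        A[1, 0] = 0.6
        X = simulate_var(A, np.diag([0.4, 0.3, 0.5]), 400, 802)
        data = StackedCov.from_data(X)
        base = PathPattern.ar_only(p)
        pattern, _, _, added = individual_search(data, base, SearchConfig(max_paths=0))
        assert pattern == base and added == []


@pytest.fixture(scope="module")
def small_result():
    """12-subject cohort with group, subgroup and individual structure."""
    p = 4
    Phi = np.diag([0.4, 0.3, 0.5, 0.35])
    A_group = np.zeros((p, p))
    A_group[1, 0] = 0.4
    cohort = {}
    for i in range(12):
        A = A_group.copy()
        if i < 6:
            A[3, 2] = 0.4  # subgroup block
        if i == 0:
            A[2, 0] = 0.5  # idiosyncratic
        cohort[f"s{i:02d}"] = simulate_var(A, Phi, 500, 900 + i)
    return cohort, run_gimme(cohort)


class TestRunGimme:
    def test_structural_postconditions(self, small_result):
        _, res = small_result
        group = set(res.group_paths)
        for sid, sub in res.subjects.items():
            assert sub.converged
            # group paths present in every subject's final pattern
            for path in group:
                assert sub.pattern.has_path(path)
            # level tags partition the non-AR edges
            non_ar = {
                pth for pth in sub.pattern.free_paths()
                if not (pth[2] == 1 and pth[0] == pth[1])
            }
            assert set(sub.levels) == non_ar
            sg = res.subgroup_solution.assignment[sid]
            for path in res.subgroup_paths.get(sg, []):
                assert sub.pattern.has_path(path)

    def test_group_path_recovered(self, small_result):
        _, res = small_result
        assert (0, 1, 0) in res.group_paths

    def test_deterministic(self, small_result):
        cohort, res = small_result
        res2 = run_gimme(cohort)
        assert res2.group_paths == res.group_paths
        assert np.array_equal(res2.similarity, res.similarity)
        assert res2.subgroup_solution.assignment == res.subgroup_solution.assignment
        for sid in res.subjects:
            assert res2.subjects[sid].pattern == res.subjects[sid].pattern
            assert res2.subjects[sid].levels == res.subjects[sid].levels
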