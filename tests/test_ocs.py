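import dataclasses
import itertools
import math

import numpy as np
import pytest

from layersim.ocs import (
    ContributionSolution,
    OCSProblem,
    coancestry_stats,
    frontier_endpoints,
    min_inbreeding_matings,
    random_mating,
    solve_ocs,
    truncation_select,
)


class TestTruncationSelect:
    def test_distinct_values_top_n(self):
        idx = np.array([5.0, 1.0, 4.0, 2.0, 3.0, 0.5])
        is_male = np.array([True, True, True, False, False, False])
        fem, mal = truncation_select(idx, is_male, 2, 2)
        np.testing.assert_array_equal(mal, [0, 2])
        np.testing.assert_array_equal(fem, [4, 3])

    def test_sire_dam_ratio_40(self):
        # 40 sires for 1,080 dams: ratio 1:27
        assert 1080 // 40 == 27
        assert 1080 // 120 == 9

    def test_tie_rule_matches_sort_then_cut_oracle(self):
        rng = np.random.default_rng(0)
        idx = rng.integers(0, 4, 30).astype(float)  # many duplicates
        is_male = rng.random(30) < 0.5
        fem, mal = truncation_select(idx, is_male, 5, 5)
        for rows, sel in ((np.flatnonzero(~is_male), fem), (np.flatnonzero(is_male), mal)):
            oracle = sorted(rows.tolist(), key=lambda r: (-idx[r], r))[:5]
            assert sel.tolist() == oracle

    def test_insufficient_candidates(self):
        with pytest.raises(ValueError, match="insufficient"):
            truncation_select(np.ones(4), np.array([True, True, False, False]), 3, 1)


class TestRandomMating:
    def test_equal_quota_deal(self):
        plan = random_mating(np.arange(120), np.full(120, 9), np.arange(1000, 2080), seed=1)
        counts = plan.sire_counts()
        assert set(counts.values()) == {9}
        assert sorted(plan.dams.tolist()) == list(range(1000, 2080))

    def test_single_sire_gets_all(self):
        plan = random_mating([7], [4], [1, 2, 3, 4], seed=2)
        assert plan.sire_counts() == {7: 4}

    def test_deterministic(self):
        p1 = random_mating(np.arange(5), np.full(5, 3), np.arange(15), seed=9)
        p2 = random_mating(np.arange(5), np.full(5, 3), np.arange(15), seed=9)
        np.testing.assert_array_equal(p1.dams, p2.dams)

    def test_quota_mismatch(self):
        with pytest.raises(ValueError, match="quota"):
            random_mating([1], [3], [1, 2], seed=0)


class TestMinInbreedingMatings:
    def test_unrelated_candidates_zero_progeny_f(self):
        a = np.eye(6)
        plan = min_inbreeding_matings([0, 1], [2, 2], [2, 3, 4, 5], a, seed=0)
        assert plan.mean_progeny_inbreeding == pytest.approx(0.0)

    def test_matches_exhaustive_assignment_2x4(self):
        rng = np.random.default_rng(4)
        a = np.eye(6)
        a[0, 2] = a[2, 0] = 0.5  # sire 0 related to dam 2
        a[1, 4] = a[4, 1] = 0.25
        sires, quotas, dams = [0, 1], [2, 2], [2, 3, 4, 5]
        plan = min_inbreeding_matings(sires, quotas, dams, a, seed=1)
        # brute force over all quota-respecting assignments
        best = np.inf
        for perm in itertools.permutations(dams):
            cost = (a[0, perm[0]] + a[0, perm[1]] + a[1, perm[2]] + a[1, perm[3]]) / 2
            best = min(best, cost / 4)
        assert plan.mean_progeny_inbreeding == pytest.approx(best)

    def test_never_worse_than_random(self):
        rng = np.random.default_rng(8)
        n = 12
        m = rng.random((n, n)) * 0.4
        a = (m + m.T) / 2 + np.eye(n)
        sires, quotas, dams = [0, 1, 2], [3, 3, 3], list(range(3, 12))
        mn = min_inbreeding_matings(sires, quotas, dams, a, seed=2)
        rd = random_mating(sires, quotas, dams, seed=2, a_pairs=a)
        assert mn.mean_progeny_inbreeding <= rd.mean_progeny_inbreeding + 1e-12

    def test_each_dam_once_and_quota_respected(self):
        a = np.eye(10)
        plan = min_inbreeding_matings([0, 1], [3, 3], [4, 5, 6, 7, 8, 9], a, seed=3)
        assert sorted(plan.dams.tolist()) == [4, 5, 6, 7, 8, 9]
        assert plan.sire_counts() == {0: 3, 1: 3}


def _toy_problem(nm=8, nf=6, seed=0, cap=None, sire_range=(3, 3), related=True):
    rng = np.random.default_rng(seed)
    n = nm + nf
    a = np.eye(n)
    if related:
        fam = rng.choice(nf + np.arange(nm), size=nm // 2, replace=False)
        for i in fam:
            for j in fam:
                if i != j:
                    a[i, j] = 0.5
    idx = np.concatenate([np.zeros(nf), rng.normal(1.0, 1.0, nm)])
    is_male = np.arange(n) >= nf
    return OCSProblem(
        index=idx,
        a=a,
        is_male=is_male,
        n_matings=nf,
        cap=cap if cap is not None else nf // sire_range[0],
        sire_range=sire_range,
        degrees=45.0,
    )


class TestFrontierEndpoints:
    def test_equal_index_values_gain_is_common_value(self):
        nf, nm = 4, 6
        n = nf + nm
        a = np.eye(n)
        idx = np.concatenate([np.full(nf, 2.0), np.full(nm, 2.0)])
        prob = OCSProblem(index=idx, a=a, is_male=np.arange(n) >= nf, n_matings=nf, cap=2, sire_range=(2, 2))
        sol0, _ = frontier_endpoints(prob, seed=0)
        assert sol0.gain == pytest.approx(2.0)

    def test_identity_a_unconstrained_spreads_evenly(self):
        # minimizing x'x with A = I: contributions as even as bounds allow
        nf, nm = 6, 6
        n = nf + nm
        idx = np.concatenate([np.zeros(nf), np.linspace(1, 2, nm)])
        prob = OCSProblem(index=idx, a=np.eye(n), is_male=np.arange(n) >= nf, n_matings=nf, cap=6, sire_range=(1, 6))
        _, sol90 = frontier_endpoints(prob, seed=1)
        assert sol90.sires_used == 6
        assert set(sol90.matings.tolist()) == {1}

    def test_zero_degree_equals_truncation_with_forced_quota(self):
        prob = _toy_problem(seed=3)
        sol0, _ = frontier_endpoints(prob, seed=2)
        males = np.flatnonzero(prob.is_male)
        order = np.lexsort((males, -prob.index[males]))
        top = males[order[:3]]
        x = prob.full_contributions(sol0.matings)
        gain_trunc = float(
            prob.index[top].mean() * 0.5 + prob.index[~prob.is_male].mean() * 0.5
        )
        assert sol0.gain == pytest.approx(gain_trunc)


class TestSolveOCS:
    def test_theta_zero_matches_max_gain_endpoint(self):
        prob = _toy_problem(seed=5)
        sol0, _ = frontier_endpoints(prob, seed=7)
        sol = solve_ocs(dataclasses.replace(prob, degrees=0.0), seed=7)
        assert sol.gain >= sol0.gain * (1 - 0.01) - 1e-12

    def test_theta_ninety_matches_min_coancestry_endpoint(self):
        prob = _toy_problem(seed=5)
        _, sol90 = frontier_endpoints(prob, seed=7)
        sol = solve_ocs(dataclasses.replace(prob, degrees=90.0), seed=7)
        assert sol.group_coancestry <= sol90.group_coancestry * (1 + 0.01) + 1e-12

    def test_matches_exhaustive_search_small_problem(self):
        # 6 male candidates, 3 sires at cap 2: enumerate all subsets and
        # score them with the same normalized trigonometric objective
        prob = _toy_problem(nm=6, nf=6, seed=11, sire_range=(3, 3), cap=2)
        theta = 40.0
        sol0, sol90 = frontier_endpoints(prob, seed=13)
        males = np.flatnonzero(prob.is_male)
        best = None
        for subset in itertools.combinations(range(6), 3):
            k = np.zeros(6, np.int64)
            k[list(subset)] = 2
            x = prob.full_contributions(k)
            g = float(x @ prob.index)
            c = float(x @ prob.a @ x)
            gn = (g - sol90.gain) / (sol0.gain - sol90.gain)
            cn = (sol0.group_coancestry - c) / (sol0.group_coancestry - sol90.group_coancestry)
            sc = math.cos(math.radians(theta)) * gn + math.sin(math.radians(theta)) * cn
            if best is None or sc > best[0]:
                best = (sc, g, c)
        sol = solve_ocs(dataclasses.replace(prob, degrees=theta), seed=13)
        assert sol.gain == pytest.approx(best[1], abs=1e-9)
        assert sol.group_coancestry == pytest.approx(best[2], abs=1e-9)

    def test_degenerate_endpoints_flagged(self):
        nf, nm = 4, 4
        n = nf + nm
        prob = OCSProblem(
            index=np.zeros(n), a=np.eye(n), is_male=np.arange(n) >= nf, n_matings=nf, cap=1, sire_range=(4, 4), degrees=45.0
        )
        sol = solve_ocs(prob, seed=1)
        assert sol.degenerate

    def test_deterministic(self):
        prob = _toy_problem(seed=21)
        s1 = solve_ocs(prob, seed=5)
        s2 = solve_ocs(prob, seed=5)
        np.testing.assert_array_equal(s1.matings, s2.matings)

    def test_bounds_respected(self):
        prob = _toy_problem(nm=10, nf=8, seed=2, cap=8, sire_range=(2, 6))
        for theta in (10.0, 50.0, 80.0):
            sol = solve_ocs(dataclasses.replace(prob, degrees=theta), seed=3)
            assert 2 <= sol.sires_used <= 6
            assert sol.matings.max() <= 8
            assert sol.matings.sum() == 8
            assert np.all(sol.x <= 0.5 + 1e-12)

    def test_targeted_delta_c_to_ne(self):
        # dC = 0.01 -> Ne = 50; dC = 0.0125 -> Ne = 40
        assert 1.0 / (2 * 0.01) == pytest.approx(50.0)
        assert 1.0 / (2 * 0.0125) == pytest.approx(40.0)


class TestCoancestryStats:
    def test_identity_uniform(self):
        n = 8
        x = np.full(n, 1.0 / n)
        c_now, c_next, dc, ne = coancestry_stats(x, np.eye(n), m=4)
        assert c_next == pytest.approx(1.0 / n)
        assert c_now == pytest.approx(n**2 / (4 * 16) / n)  # 1'I1/(4 m^2) = n/(4m^2)

    def test_ne_from_delta_c(self):
        x = np.array([0.5, 0.5])
        a = np.array([[1.0, 0.1], [0.1, 1.0]])
        c_now, c_next, dc, ne = coancestry_stats(x, a, m=1)
        assert c_now == pytest.approx(a.sum() / 4)
        assert c_next == pytest.approx(x @ a @ x)
        assert dc == pytest.approx((c_next - c_now) / (1 - c_now))
        if dc > 0:
            assert ne == pytest.approx(1 / (2 * dc))

    def test_random_toy_matches_formula_oracle(self):
        rng = np.random.default_rng(3)
        n = 5
        m_ = rng.random((n, n)) * 0.2
        a = (m_ + m_.T) / 2 + np.eye(n)
        x = rng.dirichlet(np.ones(n))
        c_now, c_next, dc, ne = coancestry_stats(x, a, m=3)
        assert c_next == pytest.approx(sum(x[i] * x[j] * a[i, j] for i in range(n) for j in range(n)))
        assert c_now == pytest.approx(a.sum() / 36.0)

    def test_current_coancestry_above_one_rejected(self):
        with pytest.raises(ValueError):
            coancestry_stats(np.array([1.0]), np.array([[8.0]]), m=1)


def test_frontier_monotone_and_sires_nondecreasing():
    """Gain and coancestry non-increasing in theta; UGOCS-style sire count
    does not fall as theta grows."""
    rng = np.random.default_rng(42)
    nf, nm = 12, 24
    n = nf + nm
    base = rng.normal(0, 0.15, (n, 8))
    a = base @ base.T + np.eye(n)
    d = np.sqrt(np.diag(a))
    a = a / np.outer(d, d) + np.diag(np.zeros(n))
    idx = np.concatenate([np.zeros(nf), rng.normal(1, 1, nm)])
    prob = OCSProblem(index=idx, a=a, is_male=np.arange(n) >= nf, n_matings=nf, cap=12, sire_range=(2, 12), degrees=45.0)
    gains, cos_, sires = [], [], []
    for theta in range(5, 90, 10):
        sol = solve_ocs(dataclasses.replace(prob, degrees=float(theta)), seed=9)
        gains.append(sol.gain)
        cos_.append(sol.group_coancestry)
        sires.append(sol.sires_used)
    assert all(a_ >= b - 1e-9 for a_, b in zip(gains, gains[1:]))
    assert all(a_ >= b - 1e-9 for a_, b in zip(cos_, cos_[1:]))
    assert sires[-1] >= sires[0]


def test_contribution_solution_frame():
    prob = _toy_problem(seed=13)
    sol = solve_ocs(prob, seed=1)
    df = sol.to_frame(prob)
    assert len(df) == prob.index.size
    assert df["matings"].sum() == prob.n_matings
    np.testing.assert_allclose(df["contribution"].sum(), 1.0)
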