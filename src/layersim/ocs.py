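"""Selection and mate allocation: truncation, minimum-inbreeding matings,
and optimal contribution selection on the trigonometric-penalty frontier.

Contributions are represented as integer mating counts per male candidate
(a dam is one mating), so every solution is directly realizable as a mating
plan.  The female side is fixed (truncation-selected dams with equal
contributions); optimization runs on the male side only, with the
female-female and female-male blocks of the relationship matrix entering
the group-coancestry objective as constants.

The frontier position is parameterized by "degrees" between the maximal
gain solution (0 deg) and the minimal group coancestry solution (90 deg).
A solution is scored in the plane of normalized gain and normalized
coancestry reduction (both scaled to [0, 1] between the two endpoint
solutions): an evolutionary algorithm maximizes the trigonometric blend
cos(theta) * gain + sin(theta) * coancestry-reduction, so 0 deg recovers
pure gain maximization, 90 deg pure coancestry minimization, and 45 deg
equal emphasis.  The exact angle algebra of the published method is not
public; this scalarization is our interpretation of it (it also guarantees
a monotone frontier across target degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import linear_sum_assignment

__all__ = [
    "OCSProblem",
    "ContributionSolution",
    "MatingPlan",
    "truncation_select",
    "random_mating",
    "min_inbreeding_matings",
    "frontier_endpoints",
    "solve_ocs",
    "coancestry_stats",
]


def truncation_select(index: np.ndarray, is_male: np.ndarray, n_females: int, n_males: int):
    """Top-n by index within each sex; ties broken by position (animal id).

    Returns (female_rows, male_rows) into the candidate arrays.
    """
    index = np.asarray(index, float)
    is_male = np.asarray(is_male, bool)
    males = np.flatnonzero(is_male)
    females = np.flatnonzero(~is_male)
    if females.size < n_females or males.size < n_males:
        raise ValueError(
            f"insufficient candidates: {females.size} females / {males.size} males "
            f"for {n_females} / {n_males} requested"
        )

    def top(rows, n):
        order = np.lexsort((rows, -index[rows]))
        return rows[order[:n]]

    return top(females, n_females), top(males, n_males)


@dataclass
class MatingPlan:
    """List of (sire, dam) pairs with per-pair expected progeny inbreeding."""

    sires: np.ndarray  # per mating
    dams: np.ndarray
    progeny_inbreeding: np.ndarray | None = None

    @property
    def n_matings(self) -> int:
        return self.sires.size

    def sire_counts(self):
        u, c = np.unique(self.sires, return_counts=True)
        return dict(zip(u.tolist(), c.tolist()))

    @property
    def mean_progeny_inbreeding(self) -> float:
        return float(np.mean(self.progeny_inbreeding)) if self.progeny_inbreeding is not None else float("nan")


def _expand_slots(sires, quotas):
    sires = np.asarray(sires)
    quotas = np.asarray(quotas, dtype=np.int64)
    return np.repeat(sires, quotas)


def random_mating(sires, quotas, dams, seed, a_pairs: np.ndarray | None = None) -> MatingPlan:
    """Dams permuted and dealt to sire slots (equal or given quotas)."""
    slots = _expand_slots(sires, quotas)
    dams = np.asarray(dams)
    if slots.size != dams.size:
        raise ValueError(f"quota mismatch: {slots.size} sire slots for {dams.size} dams")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dams = dams[rng.permutation(dams.size)]
    f = None if a_pairs is None else 0.5 * a_pairs[slots, dams]
    return MatingPlan(sires=slots, dams=dams, progeny_inbreeding=f)


def min_inbreeding_matings(sires, quotas, dams, a_pairs: np.ndarray, seed) -> MatingPlan:
    """Assignment of dams to sire slots minimizing mean progeny inbreeding.

    Solved exactly as a transportation problem (sires expanded to quota
    slots, Jonker-Volgenant assignment); always at least as good as random
    mating on the same inputs.  ``a_pairs[i, j]`` is the numerator
    relationship between candidate rows i and j.
    """
    slots = _expand_slots(sires, quotas)
    dams = np.asarray(dams)
    if slots.size != dams.size:
        raise ValueError(f"quota mismatch: {slots.size} sire slots for {dams.size} dams")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(dams.size)  # randomize ties deterministically
    dams_p = dams[perm]
    cost = 0.5 * a_pairs[np.ix_(slots, dams_p)]
    rows, cols = linear_sum_assignment(cost)
    order = np.argsort(rows)
    paired = dams_p[cols[order]]
    f = 0.5 * a_pairs[slots, paired]
    return MatingPlan(sires=slots, dams=paired, progeny_inbreeding=f)


# ---------------------------------------------------------------------------
# optimal contribution selection


@dataclass
class OCSProblem:
    """Candidates (fixed females + optimizable males) for one selection round.

    ``index`` and ``a`` (n x n relationship matrix) cover all candidates;
    ``is_male`` marks the optimizable half.  Females contribute 1/(2m)
    each (they are the m dams).  ``cap`` is the per-sire mating cap
    (m // n_sires for the constrained scenarios, m for the unconstrained
    one) and ``sire_range`` the allowed number of sires with x > 0.
    """

    index: np.ndarray
    a: np.ndarray
    is_male: np.ndarray
    n_matings: int
    cap: int
    sire_range: tuple
    degrees: float = 0.0
    ids: np.ndarray | None = None

    def __post_init__(self):
        self.index = np.asarray(self.index, float)
        self.a = np.asarray(self.a, float)
        self.is_male = np.asarray(self.is_male, bool)
        n = self.index.size
        if self.a.shape != (n, n):
            raise ValueError("relationship matrix must cover all candidates")
        smin, smax = self.sire_range
        nm = int(self.is_male.sum())
        if smin > smax or smax < 1:
            raise ValueError("invalid sire range")
        if nm < smin:
            raise ValueError("fewer male candidates than the minimum sire count")
        if self.cap * min(smax, nm) < self.n_matings:
            raise ValueError("infeasible: cap times max sires below the number of matings")
        if not (0.0 <= self.degrees <= 90.0):
            raise ValueError("degrees must lie in [0, 90]")

    # reduced male-side quantities ------------------------------------------
    def _pieces(self):
        m = self.n_matings
        males = np.flatnonzero(self.is_male)
        females = np.flatnonzero(~self.is_male)
        xf = np.zeros(self.index.size)
        xf[females] = 1.0 / (2.0 * m)
        a_m = self.index[males]
        amm = self.a[np.ix_(males, males)]
        cross = 2.0 * (self.a[males] @ xf)  # d co / d x_m at fixed females, times 2m scaling below
        gain_const = float(self.index @ xf)
        co_const = float(xf @ self.a @ xf)
        return males, a_m, amm, cross, gain_const, co_const

    def evaluate(self, k: np.ndarray):
        """(gain, group coancestry, sires used) for male mating counts ``k``."""
        males, a_m, amm, cross, gain_const, co_const = self._pieces()
        x = self.full_contributions(k)
        gain = float(x @ self.index)
        co = float(x @ self.a @ x)
        return gain, co, int(np.count_nonzero(k))

    def full_contributions(self, k: np.ndarray) -> np.ndarray:
        m = self.n_matings
        x = np.zeros(self.index.size)
        x[~self.is_male] = 1.0 / (2.0 * m)
        x[np.flatnonzero(self.is_male)] = np.asarray(k, float) / (2.0 * m)
        return x


@dataclass
class ContributionSolution:
    """An optimized contribution vector with its summary statistics."""

    x: np.ndarray  # contributions over all problem candidates
    matings: np.ndarray  # mating counts per male candidate
    gain: float
    group_coancestry: float
    delta_c: float
    ne: float
    sires_used: int
    degrees: float
    degenerate: bool = False

    def sire_rows(self, problem: OCSProblem):
        males = np.flatnonzero(problem.is_male)
        used = self.matings > 0
        return males[used], self.matings[used]

    def to_frame(self, problem: OCSProblem):
        """candidate_id, sex, index, contribution, matings for every candidate."""
        import pandas as pd

        males = np.flatnonzero(problem.is_male)
        matings = np.zeros(problem.index.size, np.int64)
        matings[males] = self.matings
        ids = problem.ids if problem.ids is not None else np.arange(1, problem.index.size + 1)
        return pd.DataFrame(
            {
                "candidate_id": np.asarray(ids),
                "sex": np.where(problem.is_male, "M", "F"),
                "index": problem.index,
                "contribution": self.x,
                "matings": matings,
            }
        )


def coancestry_stats(x: np.ndarray, a: np.ndarray, m: int):
    """Group coancestry statistics, exactly the printed formulas.

    Returns (current, next, delta_c, ne); ne is nan unless delta_c > 0.
    """
    x = np.asarray(x, float)
    a = np.asarray(a, float)
    c_next = float(x @ a @ x)
    c_now = float(a.sum() / (4.0 * m * m))
    if c_now >= 1.0:
        raise ValueError("current group coancestry >= 1")
    dc = (c_next - c_now) / (1.0 - c_now)
    ne = 1.0 / (2.0 * dc) if dc > 0 else float("nan")
    return c_now, c_next, dc, ne


def _greedy_max_gain(a_m: np.ndarray, m: int, cap: int, smin: int, smax: int) -> np.ndarray:
    """Exact maximizer of the linear gain under cap / sire-window / sum-m."""
    nm = a_m.size
    s = max(smin, -(-m // cap))  # ceil
    s = min(s, smax, nm)
    order = np.lexsort((np.arange(nm), -a_m))
    k = np.zeros(nm, dtype=np.int64)
    chosen = order[:s]
    k[chosen] = 1
    left = m - s
    for i in chosen:
        if left == 0:
            break
        add = min(cap - 1, left)
        k[i] += add
        left -= add
    return k


def _equal_spread(a_m: np.ndarray, m: int, cap: int, smax: int, nm: int) -> np.ndarray:
    """Equal-as-possible spread over the best min(smax, nm) candidates."""
    s = min(smax, nm, m)
    order = np.lexsort((np.arange(nm), -a_m))[:s]
    k = np.zeros(nm, dtype=np.int64)
    base, extra = divmod(m, s)
    if base + 1 > cap or (extra == 0 and base > cap):
        return _greedy_max_gain(a_m, m, cap, s, s)
    k[order] = base
    k[order[:extra]] += 1
    return k


def _greedy_min_coancestry(a_m, amm, cross, m, cap, smin, smax):
    """Greedy low-coancestry seed: spread matings equally over sires picked
    one by one to minimize the marginal group-coancestry contribution."""
    nm = a_m.size
    s = min(smax, nm, m)
    q = max(m // s, 1)
    tm = 2.0 * m
    marginal = cross / tm * q + (q / tm) ** 2 * np.diag(amm).copy()
    chosen = np.zeros(nm, bool)
    rowsum = np.zeros(nm)
    picks = []
    for _ in range(s):
        cost = marginal + 2.0 * (q / tm) ** 2 * rowsum
        cost[chosen] = np.inf
        j = int(np.argmin(cost))
        chosen[j] = True
        picks.append(j)
        rowsum += amm[:, j]
    k = np.zeros(nm, np.int64)
    base, extra = divmod(m, s)
    picks = np.asarray(picks)
    k[picks] = base
    k[picks[:extra]] += 1
    if k.max() > cap:
        return None
    return k


@njit(cache=True)
def _eval_k(k, a_m, amm, cross, gain_const, co_const, m):
    nm = k.size
    tm = 2.0 * m
    gain = gain_const
    co = co_const
    used = np.empty(nm, np.int64)
    s = 0
    for i in range(nm):
        if k[i] > 0:
            used[s] = i
            s += 1
    for ii in range(s):
        i = used[ii]
        ki = k[i]
        gain += ki * a_m[i] / tm
        co += ki * cross[i] / tm + ki * ki * amm[i, i] / (tm * tm)
        for jj in range(ii + 1, s):
            j = used[jj]
            co += 2.0 * ki * k[j] * amm[i, j] / (tm * tm)
    return gain, co, s


@njit(cache=True)
def _score(gain, co, s, mode, theta, gain0, co0, gain90, co90, smin, smax):
    if s < smin or s > smax:
        return -1.0e30
    if mode == 0:
        return gain
    if mode == 1:
        # min coancestry; gain as an infinitesimal tie-break for stability
        return -co + 1e-9 * gain
    gn = (gain - gain90) / (gain0 - gain90)
    cn = (co0 - co) / (co0 - co90)
    rad = theta * math.pi / 180.0
    return math.cos(rad) * gn + math.sin(rad) * cn


@njit(cache=True)
def _mutate(k, nm, m, cap, smin, smax):
    """One in-place feasibility-preserving move of matings between sires."""
    used = np.empty(nm, np.int64)
    s = 0
    for i in range(nm):
        if k[i] > 0:
            used[s] = i
            s += 1
    donor = used[np.random.randint(s)]
    if np.random.random() < 0.5:
        recipient = used[np.random.randint(s)]
    else:
        recipient = np.random.randint(nm)
    if recipient == donor:
        return
    if np.random.random() < 0.5:
        q = k[donor]  # full transfer (sire swap)
    else:
        q = 1 + np.random.randint(k[donor])
    room = cap - k[recipient]
    if q > room:
        q = room
    if q <= 0:
        return
    new_s = s
    if q == k[donor]:
        new_s -= 1
    if k[recipient] == 0:
        new_s += 1
    if new_s < smin or new_s > smax:
        return
    k[donor] -= q
    k[recipient] += q


@njit(cache=True)
def _repair(k, nm, m, cap, smin, smax):
    """Restore sum-to-m after crossover; returns True on success."""
    total = 0
    s = 0
    for i in range(nm):
        total += k[i]
        if k[i] > 0:
            s += 1
    guard = 0
    while total != m and guard < 20 * m + 100:
        guard += 1
        i = np.random.randint(nm)
        if total > m:
            if k[i] > 0:
                if k[i] == 1 and s - 1 < smin:
                    continue
                k[i] -= 1
                total -= 1
                if k[i] == 0:
                    s -= 1
        else:
            if k[i] < cap:
                if k[i] == 0 and s + 1 > smax:
                    continue
                k[i] += 1
                total += 1
                if k[i] == 1:
                    s += 1
    return total == m and smin <= s <= smax


@njit(cache=True)
def _ea_kernel(
    a_m,
    amm,
    cross,
    gain_const,
    co_const,
    m,
    cap,
    smin,
    smax,
    mode,
    theta,
    gain0,
    co0,
    gain90,
    co90,
    init_pop,
    mu,
    lam,
    n_gen,
    stagnation,
    seed,
):
    np.random.seed(seed)
    nm = a_m.size
    n_init = init_pop.shape[0]
    pop = np.zeros((mu, nm), np.int64)
    pop_scores = np.full(mu, -1.0e30)
    # seed population: provided individuals then mutated copies
    for i in range(mu):
        src = init_pop[i % n_init]
        for j in range(nm):
            pop[i, j] = src[j]
        if i >= n_init:
            for _ in range(1 + np.random.randint(5)):
                _mutate(pop[i], nm, m, cap, smin, smax)
        g, c, s = _eval_k(pop[i], a_m, amm, cross, gain_const, co_const, m)
        pop_scores[i] = _score(g, c, s, mode, theta, gain0, co0, gain90, co90, smin, smax)

    child = np.zeros(nm, np.int64)
    best = np.zeros(nm, np.int64)
    best_score = -1.0e30
    for i in range(mu):
        if pop_scores[i] > best_score:
            best_score = pop_scores[i]
            best[:] = pop[i]
    stale = 0
    for _gen in range(n_gen):
        improved = False
        for _c in range(lam):
            p1 = np.random.randint(mu)
            if np.random.random() < 0.25:
                p2 = np.random.randint(mu)
                for j in range(nm):
                    child[j] = pop[p1, j] if np.random.random() < 0.5 else pop[p2, j]
                if not _repair(child, nm, m, cap, smin, smax):
                    child[:] = pop[p1]
            else:
                child[:] = pop[p1]
            for _mu2 in range(1 + np.random.randint(3)):
                _mutate(child, nm, m, cap, smin, smax)
            g, c, s = _eval_k(child, a_m, amm, cross, gain_const, co_const, m)
            sc = _score(g, c, s, mode, theta, gain0, co0, gain90, co90, smin, smax)
            # replace the current worst if better
            worst = 0
            for i in range(1, mu):
                if pop_scores[i] < pop_scores[worst]:
                    worst = i
            if sc > pop_scores[worst]:
                pop[worst, :] = child
                pop_scores[worst] = sc
            if sc > best_score + 1e-14:
                best_score = sc
                best[:] = child
                improved = True
        if improved:
            stale = 0
        else:
            stale += 1
            if stale >= stagnation:
                break
    return best


def _solution_from_k(problem: OCSProblem, k: np.ndarray, degrees: float, degenerate=False) -> ContributionSolution:
    x = problem.full_contributions(k)
    gain = float(x @ problem.index)
    co = float(x @ problem.a @ x)
    # reference coancestry: equal contributions over the candidate pool
    # (identical to 1'A1/(4 m^2) when the pool is exactly the 2m parents)
    xbar = np.where(problem.is_male, 0.5 / max(problem.is_male.sum(), 1), 0.5 / max((~problem.is_male).sum(), 1))
    c_now = float(xbar @ problem.a @ xbar)
    dc = (co - c_now) / (1.0 - c_now)
    ne = 1.0 / (2.0 * dc) if dc > 0 else float("nan")
    return ContributionSolution(
        x=x,
        matings=np.asarray(k, np.int64),
        gain=gain,
        group_coancestry=co,
        delta_c=dc,
        ne=ne,
        sires_used=int(np.count_nonzero(k)),
        degrees=degrees,
        degenerate=degenerate,
    )


#: EA defaults (mu, lambda, generations, stagnation window)
EA_DEFAULTS = dict(mu=40, lam=160, n_gen=2000, stagnation=200)


def _run_ea(problem: OCSProblem, mode: int, theta: float, endpoints, seed: int, ea_params=None) -> np.ndarray:
    males, a_m, amm, cross, gain_const, co_const = problem._pieces()
    m = problem.n_matings
    smin, smax = problem.sire_range
    smax_eff = min(smax, a_m.size)
    params = dict(EA_DEFAULTS)
    if ea_params:
        params.update(ea_params)
    params.pop("penalty_per_degree", None)
    seeds = [
        _greedy_max_gain(a_m, m, problem.cap, smin, smax_eff),
        _equal_spread(a_m, m, problem.cap, smax_eff, a_m.size),
    ]
    kmin = _greedy_min_coancestry(a_m, amm, cross, m, problem.cap, smin, smax_eff)
    if kmin is not None:
        seeds.append(kmin)
    if endpoints is not None:
        seeds = [endpoints[0].matings, endpoints[1].matings] + seeds
    init = np.stack(seeds).astype(np.int64)
    if endpoints is None:
        g0 = c0 = g90 = c90 = 0.0
        gain0, co0, gain90, co90 = 1.0, 1.0, 0.0, 0.0
    else:
        gain0, co0 = endpoints[0].gain, endpoints[0].group_coancestry
        gain90, co90 = endpoints[1].gain, endpoints[1].group_coancestry
    return _ea_kernel(
        a_m,
        amm,
        cross,
        gain_const,
        co_const,
        m,
        problem.cap,
        smin,
        smax_eff,
        mode,
        theta,
        gain0,
        co0,
        gain90,
        co90,
        init,
        int(params["mu"]),
        int(params["lam"]),
        int(params["n_gen"]),
        int(params["stagnation"]),
        int(seed) % (2**31 - 1),
    )


def frontier_endpoints(problem: OCSProblem, seed: int = 0, ea_params=None):
    """(max-gain solution, min-coancestry solution) under the constraints."""
    males, a_m, amm, cross, gain_const, co_const = problem._pieces()
    smin, smax = problem.sire_range
    k0 = _greedy_max_gain(a_m, problem.n_matings, problem.cap, smin, min(smax, a_m.size))
    sol0 = _solution_from_k(problem, k0, 0.0)
    k90 = _run_ea(problem, mode=1, theta=90.0, endpoints=None, seed=seed + 1, ea_params=ea_params)
    sol90 = _solution_from_k(problem, k90, 90.0)
    return sol0, sol90


def solve_ocs(problem: OCSProblem, seed: int, ea_params=None) -> ContributionSolution:
    """Best contribution vector at the problem's target degrees.

    Deterministic given ``seed``.  When the two frontier endpoints coincide
    the common solution is returned for any target, flagged degenerate.
    """
    sol0, sol90 = frontier_endpoints(problem, seed=seed, ea_params=ea_params)
    if (
        abs(sol0.gain - sol90.gain) < 1e-12
        and abs(sol0.group_coancestry - sol90.group_coancestry) < 1e-12
    ):
        return _solution_from_k(problem, sol0.matings, problem.degrees, degenerate=True)
    theta = float(problem.degrees)
    if theta <= 0.0:
        return _solution_from_k(problem, sol0.matings, 0.0)
    if theta >= 90.0:
        return _solution_from_k(problem, sol90.matings, 90.0)
    k = _run_ea(problem, mode=2, theta=theta, endpoints=(sol0, sol90), seed=seed, ea_params=ea_params)
    return _solution_from_k(problem, k, theta)
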