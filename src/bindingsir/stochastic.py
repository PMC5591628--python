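"""Event-driven stochastic SIR simulation on configuration networks.

Finite-population oracle for the mean-field solvers: a configuration-graph
builder, an exact event-driven simulator for the static network (case I),
a Gillespie simulator with partnership dynamics (case II, optionally with
demographic turnover), and a growth-rate estimator.

The static simulator exploits the percolation representation of Markovian
SIR: draw each node's infectious period up front, draw per-directed-edge
transmission delays, and run Dijkstra from the seeds over the edges whose
delay is shorter than the source's infectious period.  This reproduces the
exact distribution of the continuous-time process and runs in
O((N + E) log N) per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .kernels import DegreeDistribution

__all__ = [
    "ContactGraph",
    "SimResult",
    "build_configuration_graph",
    "simulate_static_sir",
    "simulate_dynamic_sir",
    "estimate_growth_rate",
]

_SEED_STRIDE = 1_000_003  # replicate seeds: seed + i * stride (mod 2^31)


@dataclass
class ContactGraph:
    """Static contact network in CSR adjacency form."""

    N: int
    indptr: np.ndarray
    indices: np.ndarray
    degrees: np.ndarray
    n_erased: int  # stubs erased after the rematch rounds

    @property
    def n_edges(self) -> int:
        return self.indices.size // 2


@dataclass
class SimResult:
    """Replicate-level output of a stochastic simulation."""

    final_sizes: np.ndarray          # fraction ever infected, per replicate
    times: np.ndarray                # reporting grid
    cum_infections: np.ndarray       # (replicates, grid) cumulative counts
    cum_recoveries: np.ndarray
    free_fraction: np.ndarray | None  # (replicates, grid), dynamic case only
    N: int
    initial_infected: int
    seed: int

    def major_outbreaks(self, threshold_factor: float = 10.0) -> np.ndarray:
        """Boolean mask: final size exceeds threshold_factor * seeded fraction."""
        return self.final_sizes > threshold_factor * self.initial_infected / self.N


def build_configuration_graph(
    N: int, degree: DegreeDistribution, seed: int
) -> ContactGraph:
    """Uniform stub matching with a rematch-then-erase simplification policy.

    Self-loops and duplicate edges are broken up and their stubs rematched
    for up to 100 rounds; any still-defective stubs are then erased.
    """
    rng = np.random.default_rng(seed)
    degs = rng.choice(degree.degrees(), size=N, p=degree.probabilities())
    if degs.max() >= N:
        raise ValueError("degree must be smaller than the population size")
    if degs.sum() % 2 == 1:
        # resample one degree until the stub count is even; if the support
        # cannot fix the parity (all degrees odd), drop one stub instead
        fixed = False
        for _ in range(1000):
            i = int(rng.integers(N))
            d = int(rng.choice(degree.degrees(), p=degree.probabilities()))
            if (degs.sum() - degs[i] + d) % 2 == 0:
                degs[i] = d
                fixed = True
                break
        if not fixed:
            i = int(rng.integers(N))
            while degs[i] == 0:
                i = int(rng.integers(N))
            degs[i] -= 1
    stubs = np.repeat(np.arange(N), degs)
    rng.shuffle(stubs)
    a, b = stubs[0::2].copy(), stubs[1::2].copy()

    def defects(a, b, edge_set):
        bad = []
        seen = set()
        for k in range(a.size):
            u, v = (int(a[k]), int(b[k]))
            key = (u, v) if u < v else (v, u)
            if u == v or key in seen:
                bad.append(k)
            else:
                seen.add(key)
        return bad

    n_erased = 0
    for _ in range(100):
        bad = defects(a, b, None)
        if not bad:
            break
        pool = np.concatenate([a[bad], b[bad]])
        rng.shuffle(pool)
        a_new, b_new = pool[0::2], pool[1::2]
        a[bad], b[bad] = a_new, b_new
    else:
        bad = defects(a, b, None)
    bad = defects(a, b, None)
    if bad:
        n_erased = 2 * len(bad)
        keep = np.ones(a.size, dtype=bool)
        keep[bad] = False
        a, b = a[keep], b[keep]

    # CSR adjacency
    deg_eff = np.zeros(N, dtype=np.int64)
    np.add.at(deg_eff, a, 1)
    np.add.at(deg_eff, b, 1)
    indptr = np.zeros(N + 1, dtype=np.int64)
    np.cumsum(deg_eff, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)
    fill = indptr[:-1].copy()
    for u, v in zip(a, b):
        indices[fill[u]] = v
        fill[u] += 1
        indices[fill[v]] = u
        fill[v] += 1
    return ContactGraph(
        N=N, indptr=indptr, indices=indices, degrees=degs, n_erased=n_erased
    )


@njit(cache=True)
def _static_outbreak(indptr, indices, beta, gamma, seed_nodes, rng_seed):
    np.random.seed(rng_seed)
    N = indptr.size - 1
    if gamma > 0.0:
        rho = np.random.exponential(1.0 / gamma, N)
    else:
        rho = np.full(N, np.inf)
    t_inf = np.full(N, np.inf)
    cap = indices.size + seed_nodes.size + 16
    heap_t = np.empty(cap)
    heap_v = np.empty(cap, dtype=np.int64)
    m = 0
    for s in seed_nodes:
        t_inf[s] = 0.0
        heap_t[m] = 0.0
        heap_v[m] = s
        m += 1
        # sift up
        i = m - 1
        while i > 0:
            p = (i - 1) // 2
            if heap_t[p] <= heap_t[i]:
                break
            heap_t[p], heap_t[i] = heap_t[i], heap_t[p]
            heap_v[p], heap_v[i] = heap_v[i], heap_v[p]
            i = p
    while m > 0:
        t = heap_t[0]
        u = heap_v[0]
        m -= 1
        heap_t[0] = heap_t[m]
        heap_v[0] = heap_v[m]
        i = 0
        while True:
            l, r = 2 * i + 1, 2 * i + 2
            small = i
            if l < m and heap_t[l] < heap_t[small]:
                small = l
            if r < m and heap_t[r] < heap_t[small]:
                small = r
            if small == i:
                break
            heap_t[i], heap_t[small] = heap_t[small], heap_t[i]
            heap_v[i], heap_v[small] = heap_v[small], heap_v[i]
            i = small
        if t > t_inf[u]:
            continue  # stale entry
        if beta <= 0.0:
            continue
        for k in range(indptr[u], indptr[u + 1]):
            v = indices[k]
            delay = np.random.exponential(1.0 / beta)
            if delay < rho[u] and t + delay < t_inf[v]:
                t_inf[v] = t + delay
                if m >= cap:
                    # grow (rare: duplicates); double the arrays
                    new_cap = 2 * cap
                    nt = np.empty(new_cap)
                    nv = np.empty(new_cap, dtype=np.int64)
                    nt[:m] = heap_t[:m]
                    nv[:m] = heap_v[:m]
                    heap_t, heap_v, cap = nt, nv, new_cap
                heap_t[m] = t_inf[v]
                heap_v[m] = v
                m += 1
                i = m - 1
                while i > 0:
                    p = (i - 1) // 2
                    if heap_t[p] <= heap_t[i]:
                        break
                    heap_t[p], heap_t[i] = heap_t[i], heap_t[p]
                    heap_v[p], heap_v[i] = heap_v[i], heap_v[p]
                    i = p
    return t_inf, rho


def simulate_static_sir(
    graph: ContactGraph,
    beta: float,
    gamma: float,
    initial_infected: int,
    seed: int,
    replicates: int = 1,
    t_grid: np.ndarray | None = None,
) -> SimResult:
    """Exact event-driven SIR on a static graph (percolation/Dijkstra scheme)."""
    if not 0 < initial_infected < graph.N:
        raise ValueError("initial_infected must be in (0, N)")
    if t_grid is None:
        t_grid = np.linspace(0.0, 40.0, 81)
    R = replicates
    fs = np.empty(R)
    ci = np.empty((R, t_grid.size))
    cr = np.empty((R, t_grid.size))
    for i in range(R):
        rep_seed = (seed + i * _SEED_STRIDE) % (2**31 - 1)
        rng = np.random.default_rng(rep_seed)
        seeds = rng.choice(graph.N, size=initial_infected, replace=False).astype(
            np.int64
        )
        t_inf, rho = _static_outbreak(
            graph.indptr, graph.indices, beta, gamma,
            seeds, rep_seed,
        )
        infected = np.isfinite(t_inf)
        fs[i] = infected.sum() / graph.N
        ti = t_inf[infected]
        tr = ti + rho[infected]
        ci[i] = np.searchsorted(np.sort(ti), t_grid, side="right")
        cr[i] = np.searchsorted(np.sort(tr), t_grid, side="right")
    return SimResult(
        final_sizes=fs,
        times=t_grid,
        cum_infections=ci,
        cum_recoveries=cr,
        free_fraction=None,
        N=graph.N,
        initial_infected=initial_infected,
        seed=seed,
    )


@njit(cache=True)
def _dynamic_run(
    N, n, beta, gamma, rho_rate, sigma, mu,
    initial_infected, t_burn, t_max, grid, rng_seed,
):
    np.random.seed(rng_seed)
    S_, I_, R_ = 0, 1, 2
    n_stubs = N * n
    partner = np.full(n_stubs, -1, dtype=np.int64)
    stub_edge = np.full(n_stubs, -1, dtype=np.int64)
    free_list = np.arange(n_stubs)
    free_pos = np.arange(n_stubs)
    n_free = n_stubs
    cap_e = n_stubs // 2 + 1
    edge_a = np.empty(cap_e, dtype=np.int64)
    edge_b = np.empty(cap_e, dtype=np.int64)
    n_edges = 0
    state = np.zeros(N, dtype=np.int64)
    # S-I partnerships indexed by their susceptible-side stub
    si_list = np.empty(n_stubs, dtype=np.int64)
    si_pos = np.full(n_stubs, -1, dtype=np.int64)
    n_si = 0
    inf_list = np.empty(N, dtype=np.int64)
    inf_pos = np.full(N, -1, dtype=np.int64)
    n_inf = 0

    def free_remove(st, free_list, free_pos, n_free):
        p = free_pos[st]
        last = free_list[n_free - 1]
        free_list[p] = last
        free_pos[last] = p
        free_pos[st] = -1
        return n_free - 1

    def free_add(st, free_list, free_pos, n_free):
        free_list[n_free] = st
        free_pos[st] = n_free
        return n_free + 1

    def si_remove(st, si_list, si_pos, n_si):
        p = si_pos[st]
        if p < 0:
            return n_si
        last = si_list[n_si - 1]
        si_list[p] = last
        si_pos[last] = p
        si_pos[st] = -1
        return n_si - 1

    def si_add(st, si_list, si_pos, n_si):
        si_list[n_si] = st
        si_pos[st] = n_si
        return n_si + 1

    n_grid = grid.size
    cum_inf = np.zeros(n_grid)
    cum_rec = np.zeros(n_grid)
    free_frac = np.zeros(n_grid)
    total_inf = 0.0
    total_rec = 0.0

    # ---- burn-in: partnership dynamics only ----
    t = 0.0
    while t < t_burn:
        Rf = rho_rate * n_free * (n_free - 1) / (2.0 * n * N)
        Rs = sigma * n_edges
        Rtot = Rf + Rs
        if Rtot <= 0.0:
            break
        t += np.random.exponential(1.0 / Rtot)
        if np.random.random() * Rtot < Rf:
            i = free_list[np.random.randint(n_free)]
            j = free_list[np.random.randint(n_free)]
            if i == j or i // n == j // n:
                continue  # same stub or same owner: rejected
            partner[i] = j
            partner[j] = i
            n_free = free_remove(i, free_list, free_pos, n_free)
            n_free = free_remove(j, free_list, free_pos, n_free)
            edge_a[n_edges] = i
            edge_b[n_edges] = j
            stub_edge[i] = n_edges
            stub_edge[j] = n_edges
            n_edges += 1
        else:
            e = np.random.randint(n_edges)
            i, j = edge_a[e], edge_b[e]
            partner[i] = -1
            partner[j] = -1
            stub_edge[i] = -1
            stub_edge[j] = -1
            n_edges -= 1
            if e != n_edges:
                edge_a[e] = edge_a[n_edges]
                edge_b[e] = edge_b[n_edges]
                stub_edge[edge_a[e]] = e
                stub_edge[edge_b[e]] = e
            n_free = free_add(i, free_list, free_pos, n_free)
            n_free = free_add(j, free_list, free_pos, n_free)

    # ---- seed infection ----
    for u in range(initial_infected):
        state[u] = I_
        inf_list[n_inf] = u
        inf_pos[u] = n_inf
        n_inf += 1
    total_inf = float(initial_infected)
    for u in range(initial_infected):
        for k in range(n):
            st = u * n + k
            pt = partner[st]
            if pt >= 0 and state[pt // n] == S_:
                n_si = si_add(pt, si_list, si_pos, n_si)

    # ---- epidemic ----
    t = 0.0
    g = 0
    while True:
        Rf = rho_rate * n_free * (n_free - 1) / (2.0 * n * N)
        Rs = sigma * n_edges
        Rt = beta * n_si
        Rr = gamma * n_inf
        Rd = mu * N
        Rtot = Rf + Rs + Rt + Rr + Rd
        if Rtot <= 0.0 or (n_inf == 0 and mu == 0.0):
            break
        dt = np.random.exponential(1.0 / Rtot)
        t_new = t + dt
        while g < n_grid and grid[g] <= t_new:
            cum_inf[g] = total_inf
            cum_rec[g] = total_rec
            free_frac[g] = n_free / n_stubs
            g += 1
        t = t_new
        if t > t_max or (n_inf == 0 and mu > 0.0):
            break
        u_rand = np.random.random() * Rtot
        if u_rand < Rf:
            i = free_list[np.random.randint(n_free)]
            j = free_list[np.random.randint(n_free)]
            if i == j or i // n == j // n:
                continue
            partner[i] = j
            partner[j] = i
            n_free = free_remove(i, free_list, free_pos, n_free)
            n_free = free_remove(j, free_list, free_pos, n_free)
            edge_a[n_edges] = i
            edge_b[n_edges] = j
            stub_edge[i] = n_edges
            stub_edge[j] = n_edges
            n_edges += 1
            si_, sj_ = state[i // n], state[j // n]
            if si_ == S_ and sj_ == I_:
                n_si = si_add(i, si_list, si_pos, n_si)
            elif si_ == I_ and sj_ == S_:
                n_si = si_add(j, si_list, si_pos, n_si)
        elif u_rand < Rf + Rs:
            e = np.random.randint(n_edges)
            i, j = edge_a[e], edge_b[e]
            si_, sj_ = state[i // n], state[j // n]
            if si_ == S_ and sj_ == I_:
                n_si = si_remove(i, si_list, si_pos, n_si)
            elif si_ == I_ and sj_ == S_:
                n_si = si_remove(j, si_list, si_pos, n_si)
            partner[i] = -1
            partner[j] = -1
            stub_edge[i] = -1
            stub_edge[j] = -1
            n_edges -= 1
            if e != n_edges:
                edge_a[e] = edge_a[n_edges]
                edge_b[e] = edge_b[n_edges]
                stub_edge[edge_a[e]] = e
                stub_edge[edge_b[e]] = e
            n_free = free_add(i, free_list, free_pos, n_free)
            n_free = free_add(j, free_list, free_pos, n_free)
        elif u_rand < Rf + Rs + Rt:
            st = si_list[np.random.randint(n_si)]
            v = st // n
            state[v] = I_
            total_inf += 1.0
            inf_list[n_inf] = v
            inf_pos[v] = n_inf
            n_inf += 1
            for k in range(n):
                vst = v * n + k
                pt = partner[vst]
                if pt >= 0:
                    w = pt // n
                    if state[w] == S_:
                        n_si = si_add(pt, si_list, si_pos, n_si)
                    elif state[w] == I_:
                        n_si = si_remove(vst, si_list, si_pos, n_si)
        elif u_rand < Rf + Rs + Rt + Rr:
            v = inf_list[np.random.randint(n_inf)]
            state[v] = R_
            total_rec += 1.0
            p = inf_pos[v]
            last = inf_list[n_inf - 1]
            inf_list[p] = last
            inf_pos[last] = p
            inf_pos[v] = -1
            n_inf -= 1
            for k in range(n):
                vst = v * n + k
                pt = partner[vst]
                if pt >= 0 and state[pt // n] == S_:
                    n_si = si_remove(pt, si_list, si_pos, n_si)
        else:
            # death with replacement by a partner-free susceptible newborn
            v = np.random.randint(N)
            if state[v] == I_:
                p = inf_pos[v]
                last = inf_list[n_inf - 1]
                inf_list[p] = last
                inf_pos[last] = p
                inf_pos[v] = -1
                n_inf -= 1
            for k in range(n):
                vst = v * n + k
                pt = partner[vst]
                if pt >= 0:
                    w = pt // n
                    if state[v] == S_ and state[w] == I_:
                        n_si = si_remove(vst, si_list, si_pos, n_si)
                    elif state[v] == I_ and state[w] == S_:
                        n_si = si_remove(pt, si_list, si_pos, n_si)
                    e = stub_edge[vst]
                    partner[vst] = -1
                    partner[pt] = -1
                    stub_edge[vst] = -1
                    stub_edge[pt] = -1
                    n_edges -= 1
                    if e != n_edges:
                        edge_a[e] = edge_a[n_edges]
                        edge_b[e] = edge_b[n_edges]
                        stub_edge[edge_a[e]] = e
                        stub_edge[edge_b[e]] = e
                    n_free = free_add(vst, free_list, free_pos, n_free)
                    n_free = free_add(pt, free_list, free_pos, n_free)
            state[v] = S_
    while g < n_grid:
        cum_inf[g] = total_inf
        cum_rec[g] = total_rec
        free_frac[g] = n_free / n_stubs
        g += 1
    return total_inf, cum_inf, cum_rec, free_frac


def simulate_dynamic_sir(
    N: int,
    params,
    initial_infected: int,
    seed: int,
    replicates: int = 1,
    t_grid: np.ndarray | None = None,
    t_burn: float | None = None,
    mu: float = 0.0,
) -> SimResult:
    """Gillespie SIR with partnership dynamics (pair rate rho/(nN), separation sigma).

    The partnership process is burnt in to stationarity before infection is
    seeded.  With mu > 0, individuals additionally die at rate mu and are
    replaced by partner-free susceptible newborns (minimal case III probe).
    """
    from .dynamic_net import DynamicParams, free_fraction_dynamic

    if not 0 < initial_infected < N:
        raise ValueError("initial_infected must be in (0, N)")
    if t_grid is None:
        t_grid = np.linspace(0.0, 60.0, 121)
    relax = params.rho * free_fraction_dynamic(params.rho, params.sigma) + params.sigma
    if t_burn is None:
        t_burn = 30.0 / max(relax, 1e-6)
    R = replicates
    fs = np.empty(R)
    ci = np.empty((R, t_grid.size))
    cr = np.empty((R, t_grid.size))
    ff = np.empty((R, t_grid.size))
    for i in range(R):
        rep_seed = (seed + i * _SEED_STRIDE) % (2**31 - 1)
        total_inf, c_inf, c_rec, frfr = _dynamic_run(
            N, params.n, params.beta, params.gamma, params.rho, params.sigma,
            mu, initial_infected, t_burn, float(t_grid[-1]) + 1.0,
            np.asarray(t_grid, dtype=float), rep_seed,
        )
        fs[i] = total_inf / N
        ci[i] = c_inf
        cr[i] = c_rec
        ff[i] = frfr
    return SimResult(
        final_sizes=fs,
        times=t_grid,
        cum_infections=ci,
        cum_recoveries=cr,
        free_fraction=ff,
        N=N,
        initial_infected=initial_infected,
        seed=seed,
    )


def estimate_growth_rate(
    times: np.ndarray, series: np.ndarray, window: tuple[float, float]
) -> float:
    """Least-squares slope of log(series) on the time window."""
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    mask = (times >= window[0]) & (times <= window[1])
    if not np.any(mask):
        raise ValueError("window contains no samples")
    if np.any(series[mask] <= 0.0):
        raise ValueError("series must be positive on the window")
    return float(np.polyfit(times[mask], np.log(series[mask]), 1)[0])
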