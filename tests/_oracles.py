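"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the LP oracle
enumerates basic feasible solutions instead of calling a solver, and the
permutation oracle derives p-values from the exhaustive label-assignment
null rather than a chi-square approximation.
"""

from itertools import combinations, product

import numpy as np


def lp_max_by_vertex_enumeration(S, lb, ub, w, tol=1e-7):
    """Max of w'v over {S v = 0, lb <= v <= ub} by enumerating vertices.

    Every vertex of the (bounded) polytope is a basic solution with
    n - rank(S) variables fixed at a bound; enumerate all such partitions
    and sign patterns, keep the feasible ones, and return the best value.
    Returns None when no feasible vertex exists.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    w = np.asarray(w, dtype=float)
    m, n = S.shape
    r = np.linalg.matrix_rank(S, tol=1e-9)
    d = n - r
    best = None
    for fixed in combinations(range(n), d):
        free = [j for j in range(n) if j not in fixed]
        Sf = S[:, free]
        if free and np.linalg.matrix_rank(Sf, tol=1e-9) < len(free):
            continue
        fixed = list(fixed)
        for pattern in product((0, 1), repeat=d):
            vfix = np.array(
                [lb[j] if p == 0 else ub[j] for j, p in zip(fixed, pattern)]
            )
            if not np.all(np.isfinite(vfix)):
                continue
            v = np.zeros(n)
            v[fixed] = vfix
            if free:
                rhs = -S[:, fixed] @ vfix if fixed else np.zeros(m)
                sol, *_ = np.linalg.lstsq(Sf, rhs, rcond=None)
                v[free] = sol
            if np.abs(S @ v).max(initial=0.0) > tol:
                continue
            if (v < lb - tol).any() or (v > ub + tol).any():
                continue
            val = float(w @ v)
            if best is None or val > best:
                best = val
    return best


def logrank_statistic_direct(times, events, group):
    """Two-group log-rank (statistic, O-E for group 1), written directly
    from the risk-set definition as an independent re-derivation."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        risk = times >= t
        n = int(risk.sum())
        n1 = int((risk & (group == 1)).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & (group == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = o_minus_e**2 / var if var > 0 else 0.0
    return stat, o_minus_e


def permutation_logrank_p(times, events, group):
    """Exact permutation p-value of the log-rank statistic over all
    assignments with the observed group sizes."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    n = len(times)
    n1 = int(group.sum())
    stat_obs, _ = logrank_statistic_direct(times, events, group)
    count = 0
    total = 0
    for combo in combinations(range(n), n1):
        g = np.zeros(n, dtype=int)
        g[list(combo)] = 1
        stat, _ = logrank_statistic_direct(times, events, g)
        total += 1
        if stat >= stat_obs - 1e-12:
            count += 1
    return count / total, stat_obs


def random_toy_network(rng, n_metabolites=6, n_reactions=10):
    """A random bounded flux polytope (S, lb, ub, w) with 0 feasible."""
    while True:
        S = np.zeros((n_metabolites, n_reactions))
        for j in range(n_reactions):
            k = rng.integers(1, 3)
            rows = rng.choice(n_metabolites, size=k + 1, replace=False)
            coefs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=k + 1)
            S[rows, j] = coefs
        if np.linalg.matrix_rank(S) >= n_metabolites - 1:
            break
    lb = np.where(rng.random(n_reactions) < 0.5, -rng.integers(1, 6, n_reactions), 0.0)
    ub = rng.integers(1, 6, n_reactions).astype(float)
    w = np.zeros(n_reactions)
    w[rng.choice(n_reactions, size=2, replace=False)] = rng.integers(1, 4, 2)
    return S, lb.astype(float), ub, w
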