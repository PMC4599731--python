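"""Independent brute-force oracles used to validate the package's statistics.

Everything here is written from first principles (enumeration, closed forms,
small Newton solvers) and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
from math import comb, exp, log

import numpy as np

# --- exact test oracles -----------------------------------------------------


def binom_two_sided_p(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p: sum of all outcome probabilities not
    exceeding the observed outcome's (the minlike convention)."""
    pmf = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    ref = pmf[k] * (1 + 1e-12)
    return min(1.0, sum(q for q in pmf if q <= ref))


def signed_rank_two_sided_p(values) -> float:
    """Exact two-sided one-sample Wilcoxon p by enumerating every sign pattern
    of the rank magnitudes (no ties, no zeros)."""
    v = np.asarray(values, dtype=float)
    assert np.all(v != 0)
    ranks = np.argsort(np.argsort(np.abs(v))) + 1
    w_obs = float(ranks[v > 0].sum())
    n = len(v)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws, dtype=float)
    p = 2.0 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(1.0, p)


def ranksum_two_sided_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating every assignment of the
    pooled ranks to group A (no ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled)
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, len(pooled) + 1)
    ra = ranks[: len(a)]
    u_obs = float(ra.sum() - len(a) * (len(a) + 1) / 2)
    us = []
    for combo in itertools.combinations(range(len(pooled)), len(a)):
        rsum = sum(sorted(ranks)[i] for i in combo)
        us.append(rsum - len(a) * (len(a) + 1) / 2)
    us = np.array(us, dtype=float)
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


def fisher_two_sided_p(table) -> float:
    """Exact Fisher p by enumerating every 2x2 table with the same margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        # P(a=x | margins) hypergeometric
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a) * (1 + 1e-12)
    return min(1.0, sum(prob(x) for x in range(0, min(r1, c1) + 1) if prob(x) <= p_obs))


def kendall_tau_b(x, y) -> float:
    """Tie-corrected Kendall tau by brute-force pair counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nc = nd = tx = ty = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (nc - nd) / denom


# --- sequencing oracle ------------------------------------------------------


def maximal_run_partition(times_h, chain_km, max_gap_h=1.0, max_step_km=1.6):
    """Unique maximal-run partition of a detection string, by exhaustive
    enumeration of boundary placements for short strings.

    A partition (set of cut positions) is valid when every uncut consecutive
    pair satisfies both grouping rules; the maximal-run partition is the
    valid partition with the fewest cuts, and the enumeration asserts it is
    unique.  Returns the list of run lengths.
    """
    n = len(times_h)
    if n == 0:
        return []
    pair_ok = [
        (times_h[i + 1] - times_h[i] < max_gap_h) and (abs(chain_km[i + 1] - chain_km[i]) <= max_step_km)
        for i in range(n - 1)
    ]
    best = None
    n_best = None
    count_best = 0
    for cuts in itertools.product([0, 1], repeat=n - 1):
        if any(c == 0 and not ok for c, ok in zip(cuts, pair_ok)):
            continue
        k = sum(cuts)
        if n_best is None or k < n_best:
            best, n_best, count_best = cuts, k, 1
        elif k == n_best:
            count_best += 1
    assert count_best == 1, "maximal-run partition is not unique"
    lengths = []
    run = 1
    for c in best:
        if c:
            lengths.append(run)
            run = 1
        else:
            run += 1
    lengths.append(run)
    return lengths


# --- GLM oracles ------------------------------------------------------------


def subsets_with_marginality(mains, interactions):
    """All marginality-valid term subsets by filtering the full powerset."""
    terms = list(mains) + list(interactions)
    valid = set()
    for r in range(len(terms) + 1):
        for sub in itertools.combinations(terms, r):
            ok = all(
                all(p in sub for p in t.split(":")) for t in sub if ":" in t
            )
            if ok:
                valid.add(tuple(sorted(sub)))
    return valid


def logistic_newton(y, x, n_iter=200, tol=1e-12):
    """ML logistic fit with intercept + one predictor by damped Newton."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        W = mu * (1 - mu)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, ll


def maximal_run_partition_dp(times_h, chain_km, max_gap_h=1.0, max_step_km=1.6):
    """Minimum-cut valid segmentation by dynamic programming over segment
    spans (O(n^2)); independent of both the greedy code and the exhaustive
    enumeration, and feasible for long strings.  Returns run lengths."""
    n = len(times_h)
    if n == 0:
        return []

    def segment_ok(i, j):  # detections i..j inclusive form one valid run
        for k in range(i, j):
            if not (
                times_h[k + 1] - times_h[k] < max_gap_h
                and abs(chain_km[k + 1] - chain_km[k]) <= max_step_km
            ):
                return False
        return True

    INF = float("inf")
    best = [INF] * (n + 1)  # best[j]: min #segments covering first j detections
    prev = [-1] * (n + 1)
    best[0] = 0
    for j in range(1, n + 1):
        for i in range(j):
            if best[i] + 1 < best[j] and segment_ok(i, j - 1):
                best[j] = best[i] + 1
                prev[j] = i
    lengths = []
    j = n
    while j > 0:
        lengths.append(j - prev[j])
        j = prev[j]
    return lengths[::-1]
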