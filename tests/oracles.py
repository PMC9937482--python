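"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit Python loops and first-principles
formulas, deliberately sharing no code with the package implementation.
"""

import math


def angle_dot_oracle(lon1, lat1, lon2, lat2):
    """Great-circle angle via arccos of the dot product of unit vectors."""
    def vec(lon, lat):
        lo, la = math.radians(lon), math.radians(lat)
        return (math.cos(la) * math.cos(lo), math.cos(la) * math.sin(lo),
                math.sin(la))
    a = vec(lon1, lat1)
    b = vec(lon2, lat2)
    d = max(-1.0, min(1.0, sum(x * y for x, y in zip(a, b))))
    return math.degrees(math.acos(d))


def _run_lengths(seq):
    runs, cur = [], 0
    for v in seq:
        if v:
            cur += 1
        elif cur:
            runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return runs


def cra_oracle(R, min_line=2, min_cluster=8):
    """All nine recurrence measures by exhaustive enumeration.

    R is a 2-d 0/1 nested list or array; returns a dict with nan for
    undefined measures.
    """
    nan = float("nan")
    N = len(R)
    M = len(R[0])
    pts = [(i, j) for i in range(N) for j in range(M) if R[i][j]]
    total = len(pts)
    out = {"rec": 100.0 * total / (N * M)}
    if total == 0:
        out.update({k: nan for k in
                    ["det", "hlam", "htt", "vlam", "vtt", "corm", "clust",
                     "ent"]})
        return out

    diag_runs = []
    for k in range(-(N - 1), M):
        line = [R[i][i + k] for i in range(N) if 0 <= i + k < M]
        diag_runs += [L for L in _run_lengths(line) if L >= min_line]
    out["det"] = 100.0 * sum(diag_runs) / total

    vruns = []
    for j in range(M):
        vruns += [L for L in _run_lengths([R[i][j] for i in range(N)])
                  if L >= min_line]
    hruns = []
    for i in range(N):
        hruns += [L for L in _run_lengths([R[i][j] for j in range(M)])
                  if L >= min_line]
    out["vlam"] = 100.0 * sum(vruns) / total
    out["vtt"] = sum(vruns) / len(vruns) if vruns else nan
    out["hlam"] = 100.0 * sum(hruns) / total
    out["htt"] = sum(hruns) / len(hruns) if hruns else nan

    out["corm"] = (100.0 * sum(j - i for i, j in pts) / ((N - 1) * total)
                   if N > 1 else 0.0)

    # flood fill, 8-connectivity
    seen = set()
    clustered = 0
    ptset = set(pts)
    for p in pts:
        if p in seen:
            continue
        comp = [p]
        seen.add(p)
        stack = [p]
        while stack:
            i, j = stack.pop()
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    q = (i + di, j + dj)
                    if q in ptset and q not in seen:
                        seen.add(q)
                        comp.append(q)
                        stack.append(q)
        if len(comp) >= min_cluster:
            clustered += len(comp)
    out["clust"] = 100.0 * clustered / total

    if diag_runs:
        counts = {}
        for L in diag_runs:
            counts[L] = counts.get(L, 0) + 1
        n = len(diag_runs)
        out["ent"] = -sum((c / n) * math.log(c / n) for c in counts.values())
    else:
        out["ent"] = nan
    return out


def u_statistic(x, y):
    """Mann-Whitney U of x (number of (x_i, y_j) pairs with x_i > y_j,
    ties counting half)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def exact_u_pvalue(x, y, alternative="greater"):
    """Exact U-test p-value by exhaustive enumeration of all assignments."""
    from itertools import combinations

    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = u_statistic(x, y)
    us = []
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in comb]
        us.append(u_statistic(xs, ys))
    eps = 1e-9
    if alternative == "greater":
        return sum(u >= u_obs - eps for u in us) / len(us)
    if alternative == "less":
        return sum(u <= u_obs + eps for u in us) / len(us)
    p = 2.0 * min(sum(u >= u_obs - eps for u in us),
                  sum(u <= u_obs + eps for u in us)) / len(us)
    return min(1.0, p)
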