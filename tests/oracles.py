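"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — plain Python loops, exact
combinatorics via math.comb, direct string scans — and shares no code
path with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def binomial_tail_exact(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct summation of binomial pmf terms."""
    if k == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p**i * (1 - p) ** (n - i)
    return min(total, 1.0)


def discover_oracle(
    fg_windows: list[str],
    bg_windows: list[str],
    center_idx: int,
    p_thresh: float,
    min_occ: int,
    alphabet: str = AA_ORDER,
) -> list[tuple[str, list[tuple[int, str, float]]]]:
    """Naive re-enactment of the iterative fixing procedure on strings.

    Returns (pattern, trace) pairs where the trace lists every fixed
    (position, residue, p).  Same contract as the engine: candidate fixes
    need fg count >= min_occ and tail p < p_thresh; winner is minimum p,
    then highest fold enrichment, then lexicographic (position, residue);
    background proportions recompute from the restricted background at
    every step; matched foreground windows leave the pool after a motif
    is emitted.
    """
    width = len(fg_windows[0])
    pool = list(fg_windows)
    results = []
    while True:
        cur_fg = list(pool)
        cur_bg = list(bg_windows)
        fixed: dict[int, str] = {}
        trace: list[tuple[int, str, float]] = []
        while cur_fg and cur_bg:
            best = None
            for j in range(width):
                if j == center_idx or j in fixed:
                    continue
                for r in alphabet:
                    k = sum(1 for w in cur_fg if w[j] == r)
                    if k < min_occ:
                        continue
                    bk = sum(1 for w in cur_bg if w[j] == r)
                    p_bg = bk / len(cur_bg)
                    pv = binomial_tail_exact(k, len(cur_fg), p_bg)
                    if pv < p_thresh:
                        fold = (k / len(cur_fg)) / p_bg if p_bg > 0 else math.inf
                        cand = (pv, -fold, j, r)
                        if best is None or cand < best:
                            best = cand
            if best is None:
                break
            pv, _nf, j, r = best
            fixed[j] = r
            trace.append((j, r, pv))
            cur_fg = [w for w in cur_fg if w[j] == r]
            cur_bg = [w for w in cur_bg if w[j] == r]
        if not fixed:
            break
        if len(cur_fg) >= min_occ:
            center_char = pool[0][center_idx] if pool else fg_windows[0][center_idx]
            pattern = "".join(
                fixed.get(j, center_char if j == center_idx else ".")
                for j in range(width)
            )
            results.append((pattern, trace))
        matched = set()
        for w in pool:
            if all(w[j] == r for j, r in fixed.items()):
                matched.add(id(w))
        pool = [w for w in pool if id(w) not in matched]
    return results


def count_matches_oracle(pattern: str, sequence: str) -> int:
    """Per-position scan; wildcard matches the 20 standard residues only."""
    m = len(pattern)
    count = 0
    for start in range(len(sequence) - m + 1):
        ok = True
        for pc, sc in zip(pattern, sequence[start : start + m]):
            if pc == ".":
                if sc not in AA_ORDER:
                    ok = False
                    break
            elif pc != sc:
                ok = False
                break
        if ok:
            count += 1
    return count


def dcor_oracle(x: list[float], y: list[float]) -> float:
    """Double-centring distance correlation with explicit loops."""
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(m):
        row = [sum(r) / n for r in m]
        col = [sum(m[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [[m[i][j] - row[i] - col[j] + grand for j in range(n)] for i in range(n)]

    A = center(a)
    B = center(b)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    dvarx = sum(v * v for r in A for v in r) / n**2
    dvary = sum(v * v for r in B for v in r) / n**2
    if dvarx <= 1e-15 or dvary <= 1e-15:
        return 0.0
    return math.sqrt(max(dcov2 / math.sqrt(dvarx * dvary), 0.0))


def entropy_oracle(window: str) -> float:
    counts: dict[str, int] = {}
    for c in window:
        if c in AA_ORDER:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return -sum((v / total) * math.log2(v / total) for v in counts.values())


def seg_oracle(
    sequence: str, window: int, trigger: float, extension: float
) -> list[tuple[int, int]]:
    """Direct window scan + coverage union; returns 1-based (start, end)."""
    L = len(sequence)
    if L < window:
        return []
    H = [entropy_oracle(sequence[i : i + window]) for i in range(L - window + 1)]
    covered = [False] * L
    for t in range(len(H)):
        if H[t] > trigger:
            continue
        lo = t
        while lo - 1 >= 0 and H[lo - 1] <= extension:
            lo -= 1
        hi = t
        while hi + 1 < len(H) and H[hi + 1] <= extension:
            hi += 1
        for pos in range(lo, hi + window):
            covered[pos] = True
    segments = []
    i = 0
    while i < L:
        if covered[i]:
            j = i
            while j + 1 < L and covered[j + 1]:
                j += 1
            segments.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return segments


def ranksum_exact_p(fg: list[float], bg: list[float]) -> float:
    """Exhaustive-permutation two-sided p for the rank-sum statistic.

    Enumerates every split of the pooled sample into groups of the
    observed sizes; p is the fraction of splits whose U deviates from its
    mean at least as much as the observed U.
    """
    pooled = list(fg) + list(bg)
    n1 = len(fg)
    n = len(pooled)
    sorted_vals = sorted(pooled)
    ranks = []
    for v in pooled:
        tied = [i for i, s in enumerate(sorted_vals) if s == v]
        ranks.append(sum(t + 1 for t in tied) / len(tied))
    obs_u = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    mu = n1 * (n - n1) / 2
    obs_dev = abs(obs_u - mu)
    hits = 0
    total = 0
    for idx in combinations(range(n), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
        if abs(u - mu) >= obs_dev - 1e-12:
            hits += 1
        total += 1
    return hits / total


def rand_index(a, b) -> float:
    n = len(a)
    agree = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            agree += (a[i] == a[j]) == (b[i] == b[j])
            total += 1
    return agree / total
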