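"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most direct method available
(full dynamic programming, per-base marking, exhaustive enumeration), on a
code path entirely separate from the implementation it checks.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numba import njit

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int8)


@njit(cache=False)
def _gotoh_local(a, b, match, mismatch, gap_open, gap_extend):
    """Optimal local alignment score, affine gaps costing open + k * extend."""
    n, m = len(a), len(b)
    neg = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), neg, dtype=np.int64)
    F = np.full((n + 1, m + 1), neg, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open - gap_extend, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_extend, F[i - 1, j] - gap_extend)
            if a[i - 1] == 4 or b[j - 1] == 4:
                s = mismatch
            else:
                s = match if a[i - 1] == b[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    return best


def smith_waterman_score(
    query: str,
    subject: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> int:
    return int(
        _gotoh_local(_encode(query), _encode(subject), match, mismatch, gap_open, gap_extend)
    )


def per_base_overlap(st, nat) -> list[tuple[int, int]]:
    """Opposite-strand exon overlap regions by marking every covered base."""
    lo = min(st.start, nat.start)
    hi = max(st.end, nat.end)
    covered_st = np.zeros(hi - lo, dtype=bool)
    covered_nat = np.zeros(hi - lo, dtype=bool)
    for a, b in st.exons:
        covered_st[a - lo : b - lo] = True
    for a, b in nat.exons:
        covered_nat[a - lo : b - lo] = True
    both = covered_st & covered_nat
    regions = []
    start = None
    for k, v in enumerate(both):
        if v and start is None:
            start = k
        elif not v and start is not None:
            regions.append((start + lo, k + lo))
            start = None
    if start is not None:
        regions.append((start + lo, len(both) + lo))
    return regions


def exhaustive_max_orf(seq: str) -> int:
    """Longest ATG..stop coding stretch (stop excluded) over every
    start/stop combination in every forward frame."""
    seq = seq.upper().replace("U", "T")
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    starts = [i for i in range(len(seq) - 2) if seq[i : i + 3] == "ATG"]
    for i in starts:
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in stops:
                best = max(best, j - i)
                break
            j += 3
    return best


def enumerate_max_pairs(seq: str, minloop: int = 3) -> int:
    """Maximum pair count over all nested structures, by recursion over
    every admissible pairing of the first base."""
    seq = seq.upper().replace("U", "T")
    pairable = {
        ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G"),
    }

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if j - i <= minloop:
            return 0
        best = rec(i + 1, j)  # i unpaired
        for k in range(i + minloop + 1, j + 1):
            if (seq[i], seq[k]) in pairable:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    result = rec(0, len(seq) - 1) if seq else 0
    rec.cache_clear()
    return result


def bh_step_up(pvals) -> np.ndarray:
    """Benjamini-Hochberg q-values straight from the step-up definition:
    q_i = min over j with p_(j) >= p_(i) of p_(j) * m / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def relationship_by_degrees(edges) -> dict:
    """Brute-force relationship labels from explicit degree counting."""
    labels = {}
    for st, nat in edges:
        d_n = len({s for s, n in edges if n == nat})
        d_s = len({n for s, n in edges if s == st})
        if d_n == 1 and d_s == 1:
            labels[(st, nat)] = "1v1"
        elif d_n > 1 and d_s == 1:
            labels[(st, nat)] = "1vn"
        elif d_n == 1 and d_s > 1:
            labels[(st, nat)] = "nv1"
        else:
            labels[(st, nat)] = "nvn"
    return labels
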