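"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the implementation paths it checks:
the translated-search oracle is a hand-written Smith-Waterman (Gotoh)
with its own traceback; the chaining oracle is pairwise transitive
closure; the Fisher oracle enumerates the hypergeometric distribution in
exact integer arithmetic; the rank-sum oracle enumerates permutations;
the k-mer oracle uses plain string sets.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from numba import njit

# ---------------------------------------------------------------------------
# translated-homology search oracle

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = _BLOSUM.alphabet  # includes X and *
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHA)}
_MASK_IDX = len(_ALPHA)  # sentinel index for masked-out subject positions

_SCORE = np.full((len(_ALPHA) + 1, len(_ALPHA) + 1), -10000.0)
for i, a in enumerate(_ALPHA):
    for j, b in enumerate(_ALPHA):
        _SCORE[i, j] = _BLOSUM[a][b]


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)


@njit(cache=False)
def _gotoh_local(q, s, score, open_cost, extend_cost):
    """Best local alignment of q (query) vs s (subject).

    Returns (score, qa, qb, sa, sb, n_ident, n_cols) for the optimal
    alignment found by its own traceback; gap of length L costs
    open_cost + L * extend_cost.
    """
    n, m = len(q), len(s)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -1e9)  # gap in query (horizontal)
    F = np.full((n + 1, m + 1), -1e9)  # gap in subject (vertical)
    tbH = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop,1 diag,2 E,3 F
    tbE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 open, 1 extend
    tbF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0.0
    bi = bj = 0
    go = open_cost + extend_cost
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - extend_cost
            if e_ext > e_open:
                E[i, j] = e_ext
                tbE[i, j] = 1
            else:
                E[i, j] = e_open
                tbE[i, j] = 0
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - extend_cost
            if f_ext > f_open:
                F[i, j] = f_ext
                tbF[i, j] = 1
            else:
                F[i, j] = f_open
                tbF[i, j] = 0
            diag = H[i - 1, j - 1] + score[q[i - 1], s[j - 1]]
            h = 0.0
            tb = 0
            if diag > h:
                h = diag
                tb = 1
            if E[i, j] > h:
                h = E[i, j]
                tb = 2
            if F[i, j] > h:
                h = F[i, j]
                tb = 3
            H[i, j] = h
            tbH[i, j] = tb
            if h > best:
                best = h
                bi, bj = i, j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, 0, 0
    # traceback
    i, j = bi, bj
    n_ident = 0
    n_cols = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            tb = tbH[i, j]
            if tb == 0:
                break
            if tb == 1:
                n_cols += 1
                if q[i - 1] == s[j - 1]:
                    n_ident += 1
                i -= 1
                j -= 1
            elif tb == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            n_cols += 1
            if tbE[i, j] == 0:
                state = 0
            j -= 1
        else:
            n_cols += 1
            if tbF[i, j] == 0:
                state = 0
            i -= 1
    return best, i, bi, j, bj, n_ident, n_cols


def translated_hits(
    protein: str,
    genome: Sequence[Tuple[str, str]],
    min_identity: float = 0.75,
    min_fragment_aa: int = 20,
    gap_open: int = 11,
    gap_extend: int = 1,
    include_gaps: bool = True,
    score_floor: float = 35.0,
) -> List[dict]:
    """All >= min_identity local translated matches, via iterative masking.

    For each scaffold/strand/frame the best local alignment is extracted,
    its subject region masked, and the search repeated until the best
    score drops below ``score_floor`` (well under the minimum score any
    fragment passing the identity and length filters can achieve).
    """
    q = _encode(protein)
    hits: List[dict] = []
    for scaffold, seq in genome:
        L = len(seq)
        rev = str(Seq(seq).reverse_complement())
        for strand, nt in (("+", seq), ("-", rev)):
            for frame in range(3):
                usable = (L - frame) // 3
                if usable <= 0:
                    continue
                aa = str(Seq(nt[frame : frame + 3 * usable]).translate())
                s = _encode(aa)
                for _ in range(200):
                    res = _gotoh_local(
                        q, s, _SCORE, float(gap_open), float(gap_extend)
                    )
                    score, qa, qb, sa, sb, n_ident, n_cols = res
                    if score < score_floor:
                        break
                    s = s.copy()
                    s[sa:sb] = _MASK_IDX
                    # diagonal (non-gap) columns: D = qlen + slen - n_cols
                    diag_cols = (qb - qa) + (sb - sa) - n_cols
                    denom = n_cols if include_gaps else diag_cols
                    identity = n_ident / denom if denom else 0.0
                    if identity < min_identity or (qb - qa) < min_fragment_aa:
                        continue
                    if strand == "+":
                        g_start = frame + 3 * sa
                        g_end = frame + 3 * sb
                    else:
                        g_start = L - frame - 3 * sb
                        g_end = L - frame - 3 * sa
                    hits.append(
                        dict(
                            scaffold=scaffold,
                            strand=strand,
                            frame=frame,
                            start=g_start,
                            end=g_end,
                            score=float(score),
                            identity=identity,
                            query_span=(qa, qb),
                        )
                    )
    hits.sort(key=lambda h: (h["scaffold"], h["start"], h["end"]))
    return hits


# ---------------------------------------------------------------------------
# chaining oracle: pairwise transitive closure


def transitive_closure_chains(
    fragments: Sequence[Tuple[str, str, int, int]], max_gap: int
) -> List[frozenset]:
    """Merge fragments (scaffold, strand, start, end) by pairwise linkage.

    Two fragments link when they share scaffold and strand and the gap
    between them (0 when overlapping) is strictly below ``max_gap``.
    Returns the partition of fragment indices into chains.
    """
    n = len(fragments)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for i in range(n):
        si, ti, ai, bi_ = fragments[i]
        for j in range(i + 1, n):
            sj, tj, aj, bj = fragments[j]
            if si != sj or ti != tj:
                continue
            gap = max(ai, aj) - min(bi_, bj)
            if gap < 0:
                gap = 0
            if gap < max_gap:
                union(i, j)
    comps: Dict[int, set] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return [frozenset(c) for c in comps.values()]


# ---------------------------------------------------------------------------
# exact-statistics oracles


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by integer enumeration.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    obs = math.comb(r1, a) * math.comb(r2, c)
    num = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, x) * math.comb(r2, c1 - x)
        if w <= obs:
            num += w
    return num / math.comb(n, c1)


def rank_sum_exact_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (no ties).

    p = 2 * P(U <= min(u, nm - u)), capped at 1, under the permutation
    null of all C(n+m, n) group splits.
    """
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n, m = len(x), len(y)

    def u_stat(xs):
        xs_set = set(xs)
        ranks = [i + 1 for i, v in enumerate(pooled) if v in xs_set]
        return sum(ranks) - n * (n + 1) / 2

    u_obs = u_stat(x)
    u_min = min(u_obs, n * m - u_obs)
    count = 0
    total = 0
    for subset in combinations(pooled, n):
        total += 1
        u = u_stat(subset)
        if min(u, n * m - u) <= u_min:
            count += 1
    # each split counted once; two-sidedness comes from min() folding
    return count / total


# ---------------------------------------------------------------------------
# k-mer oracle

_RC = str.maketrans("ACGT", "TGCA")


def naive_kmer_set(seqs: Sequence[str], k: int, canonical: bool = True) -> set:
    out = set()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(ch not in "ACGT" for ch in w):
                continue
            if canonical:
                rc = w.translate(_RC)[::-1]
                w = min(w, rc)
            out.add(w)
    return out
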