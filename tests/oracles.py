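"""Independent brute-force oracles used to validate the package's DP and
combinatorial code.  Everything here is deliberately written from first
principles (plain enumeration, naive loops) and must stay independent of the
implementations it checks."""

from __future__ import annotations

import itertools

import numpy as np

# ---------------------------------------------------------------------------
# secondary structure


def tier_stack_pairs(db: str) -> set[tuple[int, int]]:
    """Per-tier stack matcher for extended dot-bracket text."""
    openers = "([{<" + "".join(chr(c) for c in range(ord("A"), ord("Z") + 1))
    closers = ")]}>" + "".join(chr(c) for c in range(ord("a"), ord("z") + 1))
    pairs: set[tuple[int, int]] = set()
    for tier, (o, c) in enumerate(zip(openers, closers)):
        stack = []
        for pos, ch in enumerate(db, start=1):
            if ch == o:
                stack.append(pos)
            elif ch == c:
                pairs.add((stack.pop(), pos))
    return pairs


def all_pairs_crossings(pairs) -> set:
    """O(n^2) all-pairs crossing check."""
    out = set()
    for p, q in itertools.combinations(sorted(pairs), 2):
        (i, j), (k, l) = p, q
        if i < k < j < l:
            out.add((p, q))
    return out


def substructure_runs(pairs, tol: int) -> list[list[tuple[int, int]]]:
    """Run-merging by the stated definition: successive pairs (sorted by 5'
    end) chain iff nested with both internal gaps <= tol."""
    runs: list[list[tuple[int, int]]] = []
    for pair in sorted(pairs):
        if runs:
            (pi, pj), (i, j) = runs[-1][-1], pair
            if pi < i and j < pj and i - pi - 1 <= tol and pj - j - 1 <= tol:
                runs[-1].append(pair)
                continue
        runs.append([pair])
    return runs


# ---------------------------------------------------------------------------
# alignment enumeration


def enumerate_global_affine(
    m: int,
    n: int,
    score,
    open_q,
    ext_q,
    open_t=None,
    ext_t=None,
) -> float:
    """Exhaustive max over all monotone global alignments with affine gaps.

    A gap run's first position costs open, the rest extend; per-position costs
    are callables so MSA-scaled penalties can be checked too.
    """
    if open_t is None:
        open_t = open_q
    if ext_t is None:
        ext_t = ext_q
    best = [-np.inf]

    def rec(i: int, j: int, prev: str, total: float) -> None:
        if i == m and j == n:
            if total > best[0]:
                best[0] = total
            return
        if i < m and j < n:
            rec(i + 1, j + 1, "M", total + score(i + 1, j + 1))
        if i < m:
            cost = ext_q(i + 1) if prev == "X" else open_q(i + 1)
            rec(i + 1, j, "X", total - cost)
        if j < n:
            cost = ext_t(j + 1) if prev == "Y" else open_t(j + 1)
            rec(i, j + 1, "Y", total - cost)

    rec(0, 0, "start", 0.0)
    return best[0]


def reference_gotoh(
    m: int, n: int, score, gap_open: float, gap_extend: float,
    free_terminal: bool = False,
) -> float:
    """Textbook three-matrix affine-gap Needleman-Wunsch (score only)."""
    NEG = -1e18
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in second sequence
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in first sequence
    M[0][0] = 0.0
    for i in range(1, m + 1):
        Ix[i][0] = 0.0 if free_terminal else -(gap_open + (i - 1) * gap_extend)
    for j in range(1, n + 1):
        Iy[0][j] = 0.0 if free_terminal else -(gap_open + (j - 1) * gap_extend)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            M[i][j] = score(i, j) + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(
                M[i - 1][j] - gap_open,
                Ix[i - 1][j] - gap_extend,
                Iy[i - 1][j] - gap_open,
            )
            Iy[i][j] = max(
                M[i][j - 1] - gap_open,
                Iy[i][j - 1] - gap_extend,
                Ix[i][j - 1] - gap_open,
            )
    if not free_terminal:
        return max(M[m][n], Ix[m][n], Iy[m][n])
    best = NEG
    for i in range(m + 1):
        best = max(best, M[i][n], Ix[i][n], Iy[i][n])
    for j in range(n + 1):
        best = max(best, M[m][j], Ix[m][j], Iy[m][j])
    return best


# ---------------------------------------------------------------------------
# substructure matching enumeration


def _span(sub) -> tuple[int, int]:
    return min(sub.half1), max(sub.half2)


def _arcs_cross(sa, sb) -> bool:
    for p in zip(sa.half1, sa.half2):
        for q in zip(sb.half1, sb.half2):
            (i, j), (k, l) = sorted((p, q))
            if i < k < j < l:
                return True
    return False


def _pattern(sa, sb) -> str:
    """Arrangement of sa vs sb with sa starting 5' of sb (independent coding)."""
    if _arcs_cross(sa, sb):
        return "cross"
    a0, a1 = _span(sa)
    b0, b1 = _span(sb)
    if a1 < b0:
        return "before"
    if b1 < a1:
        return "nested"
    return "cross"


def _compatible(subs_q, subs_t, ma, mb) -> bool:
    (i, j), (ip, jp) = ma, mb
    if i == ip or j == jp:
        return False
    if i > ip:
        (i, j), (ip, jp) = (ip, jp), (i, j)
    if j >= jp:
        return False
    return _pattern(subs_q[i], subs_q[ip]) == _pattern(subs_t[j], subs_t[jp])


def enumerate_matchings(omega: np.ndarray, subs_q, subs_t) -> float:
    """Max objective over every feasible substructure matching, by full
    enumeration of injective match sets with pairwise compatibility."""
    cand = [
        (i, j)
        for i in range(omega.shape[0])
        for j in range(omega.shape[1])
        if omega[i, j] > 0
    ]
    best = 0.0
    for size in range(1, min(omega.shape) + 1):
        for combo in itertools.combinations(cand, size):
            ok = all(
                _compatible(subs_q, subs_t, combo[a], combo[b])
                for a in range(size)
                for b in range(a + 1, size)
            )
            if ok:
                total = sum(omega[i, j] for i, j in combo)
                if total > best:
                    best = total
    return best


# ---------------------------------------------------------------------------
# superposition


def kabsch_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Least-squares superposition RMSD via the SVD construction."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ Xc.T).T - Yc
    return float(np.sqrt((diff**2).sum() / len(X)))
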