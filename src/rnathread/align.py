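"""Two-stage RNA threading alignment.

Stage one aligns the *simplified diagrams*: every query/template substructure
pair gets a matching score omega from a partial Needleman-Wunsch dynamic
programming (NWDP) over the 5' halves (the 3' halves follow from base
pairing), and an exact combinatorial solver picks the best set of
substructure matches subject to no cross-alignment and one-to-one matching.
Stage two turns the matched substructures into a set of anchor nucleotide
pairs S_aln and runs a full-sequence affine-gap NWDP in which every anchor
pair earns a flat bonus; terminal gaps are free.

Scoring is sequence-sequence (RIBOSUM) when the query MSA is shallow
(Neff < 5) and profile-sequence otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, ScoringConfig
from .profile import SequenceProfile
from .scoring import NEG_INF, NUC_INDEX, ScoringTables
from .secstruct import (
    Env,
    SecondaryStructure,
    SimplifiedDiagram,
    Substructure,
    classify_environment,
    extract_substructures,
)

__all__ = [
    "GapModel",
    "Alignment",
    "StructureContext",
    "build_context",
    "score_pair",
    "partial_nwdp",
    "match_substructures",
    "final_alignment",
    "thread",
]


@dataclass(frozen=True)
class GapModel:
    """Affine gap penalties; a length-L gap costs open + (L-1)*extend."""

    open: float = 3.0
    extend: float = 1.0
    free_terminal: bool = True
    msa_gap_scaling: bool = True
    min_scale: float = 0.1

    def __post_init__(self) -> None:
        if not (self.open >= self.extend >= 0):
            raise ValueError("need open >= extend >= 0")

    def scale(self, gap_ratio: float) -> float:
        """Per-column penalty multiplier: gappier MSA columns gap cheaper."""
        return max(self.min_scale, 1.0 - gap_ratio)


@dataclass(frozen=True)
class Alignment:
    """Ordered aligned position pairs (1-based) with score and coverage."""

    pairs: tuple[tuple[int, int], ...]
    score: float
    query_length: int

    def __post_init__(self) -> None:
        qs = [p[0] for p in self.pairs]
        ts = [p[1] for p in self.pairs]
        if qs != sorted(set(qs)) or ts != sorted(set(ts)):
            raise ValueError("alignment positions must be strictly increasing")

    @property
    def coverage(self) -> float:
        return len(self.pairs) / self.query_length


@dataclass(frozen=True)
class StructureContext:
    """Per-molecule cache: sequence, structure, simplified diagram, pair environments."""

    sequence: str
    ss: SecondaryStructure
    diagram: SimplifiedDiagram
    env: dict[tuple[int, int], tuple[Env, Env]]


def build_context(
    ss: SecondaryStructure, max_internal_unpaired: int = 2
) -> StructureContext:
    """Precompute the simplified diagram and every pair's environment tuple."""
    diagram = extract_substructures(ss, max_internal_unpaired)
    env = {p: classify_environment(ss, *p) for p in ss.pairs}
    return StructureContext(sequence=ss.sequence, ss=ss, diagram=diagram, env=env)


# ---------------------------------------------------------------------------
# pairwise base-pair scoring (stage one cell score)


def environment_bonus(
    eq: tuple[Env, Env], et: tuple[Env, Env], config: ScoringConfig = DEFAULT_CONFIG
) -> float:
    if eq != et:
        return 0.0
    if eq == (Env.STEM, Env.STEM):
        return config.env_stem_bonus
    return config.env_other_bonus


def score_pair(
    q_pair: tuple[int, int],
    t_pair: tuple[int, int],
    qctx: StructureContext,
    tctx: StructureContext,
    tables: ScoringTables,
    profile: SequenceProfile | None = None,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """Score aligning one query base pair against one template base pair.

    RIBOSUM base-pair substitution (or the profile average over the two
    halves when a usable profile exists) plus the environment bonus.
    """
    m1, m2 = q_pair
    n1, n2 = t_pair
    s_env = environment_bonus(qctx.env[q_pair], tctx.env[t_pair], config)
    if profile is not None and profile.use_profile:
        base = config.profile_half_factor * (
            profile.score(m1, tctx.sequence[n1 - 1], tables)
            + profile.score(m2, tctx.sequence[n2 - 1], tables)
        )
    else:
        base = tables.pair(
            qctx.sequence[m1 - 1] + qctx.sequence[m2 - 1],
            tctx.sequence[n1 - 1] + tctx.sequence[n2 - 1],
        )
    return base + s_env


# ---------------------------------------------------------------------------
# affine-gap NWDP engine (shared by both stages)

_M, _X, _Y = 0, 1, 2  # matrix ids: match, gap-in-template (query consumed), gap-in-query


def _gotoh(
    m: int,
    n: int,
    score: Callable[[int, int], float],
    open_q: Callable[[int], float],
    ext_q: Callable[[int], float],
    open_t: Callable[[int], float],
    ext_t: Callable[[int], float],
    free_terminal: bool,
) -> tuple[float, list[tuple[int, int]]]:
    """Affine-gap global (or free-end) alignment; returns score and matched
    (i, j) 1-based index pairs.  Tie-breaking is fixed (diagonal > up > left,
    and M > X > Y within a cell) so alignments are byte-reproducible."""
    M = np.full((m + 1, n + 1), NEG_INF)
    X = np.full((m + 1, n + 1), NEG_INF)
    Y = np.full((m + 1, n + 1), NEG_INF)
    # predecessor matrix id for traceback
    ptr = np.zeros((3, m + 1, n + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        if free_terminal:
            X[i, 0] = 0.0
        elif i == 1:
            X[i, 0] = -open_q(1)
        else:
            X[i, 0] = X[i - 1, 0] - ext_q(i)
        ptr[_X, i, 0] = _X if i > 1 else _M
    for j in range(1, n + 1):
        if free_terminal:
            Y[0, j] = 0.0
        elif j == 1:
            Y[0, j] = -open_t(1)
        else:
            Y[0, j] = Y[0, j - 1] - ext_t(j)
        ptr[_Y, 0, j] = _Y if j > 1 else _M

    for i in range(1, m + 1):
        oq, eq_ = open_q(i), ext_q(i)
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, n + 1):
            # match
            s = score(i, j)
            cands = (Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            k = int(np.argmax(cands))
            Mi[j] = cands[k] + s
            ptr[_M, i, j] = k
            # gap in template (consume query i): from row i-1
            cands = (Mi1[j] - oq, Xi1[j] - eq_, Yi1[j] - oq)
            k = int(np.argmax(cands))
            Xi[j] = cands[k]
            ptr[_X, i, j] = k
            # gap in query (consume template j): from column j-1
            ot, et_ = open_t(j), ext_t(j)
            cands = (Mi[j - 1] - ot, Xi[j - 1] - ot, Yi[j - 1] - et_)
            k = int(np.argmax(cands))
            Yi[j] = cands[k]
            ptr[_Y, i, j] = k

    mats = (M, X, Y)
    if free_terminal:
        # best over last row and last column; deterministic preference order
        best = (NEG_INF, 0, 0, 0)
        for mat_id in (_M, _X, _Y):
            for i in range(m, -1, -1):
                v = mats[mat_id][i, n]
                if v > best[0]:
                    best = (v, mat_id, i, n)
            for j in range(n, -1, -1):
                v = mats[mat_id][m, j]
                if v > best[0]:
                    best = (v, mat_id, m, j)
        score_opt, mat_id, i, j = best
    else:
        vals = [mats[k][m, n] for k in (_M, _X, _Y)]
        mat_id = int(np.argmax(vals))
        score_opt, i, j = vals[mat_id], m, n

    pairs: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
            continue
        if j == 0:
            i -= 1
            continue
        prev = int(ptr[mat_id, i, j])
        if mat_id == _M:
            pairs.append((i, j))
            i -= 1
            j -= 1
        elif mat_id == _X:
            i -= 1
        else:
            j -= 1
        mat_id = prev
    pairs.reverse()
    return float(score_opt), pairs


# ---------------------------------------------------------------------------
# stage one: partial NWDP over substructure halves


def partial_nwdp(
    sq: Substructure,
    st: Substructure,
    qctx: StructureContext,
    tctx: StructureContext,
    tables: ScoringTables,
    profile: SequenceProfile | None = None,
    gaps: GapModel = GapModel(free_terminal=False),
    config: ScoringConfig = DEFAULT_CONFIG,
) -> tuple[float, list[tuple[int, int]]]:
    """Align two substructures by their 5' halves only.

    Cell (k, l) scores the full base pairs sq.pairs[k-1] vs st.pairs[l-1];
    the 3' half alignment is induced by pairing.  Returns the optimal global
    score (the omega of the matching objective) and the induced
    nucleotide-level alignment over both halves.
    """
    if len(sq) == 0 or len(st) == 0:
        raise ValueError("substructures must be non-empty")
    qp, tp = sq.pairs, st.pairs
    cell = {}

    def cell_score(k: int, l: int) -> float:
        key = (k, l)
        if key not in cell:
            cell[key] = score_pair(qp[k - 1], tp[l - 1], qctx, tctx, tables, profile, config)
        return cell[key]

    scaling = (
        profile is not None and profile.use_profile and gaps.msa_gap_scaling
    )

    def open_q(k: int) -> float:
        if scaling:
            return gaps.open * gaps.scale(profile.gap_ratio[qp[k - 1][0] - 1])
        return gaps.open

    def ext_q(k: int) -> float:
        if scaling:
            return gaps.extend * gaps.scale(profile.gap_ratio[qp[k - 1][0] - 1])
        return gaps.extend

    omega, half_pairs = _gotoh(
        len(qp), len(tp), cell_score, open_q, ext_q,
        lambda j: gaps.open, lambda j: gaps.extend, free_terminal=False,
    )
    induced: list[tuple[int, int]] = []
    for k, l in half_pairs:
        induced.append((qp[k - 1][0], tp[l - 1][0]))
        induced.append((qp[k - 1][1], tp[l - 1][1]))
    return omega, sorted(induced)


# ---------------------------------------------------------------------------
# stage one: exact substructure matching

# relative arrangement of two substructures a < b (ordered by 5' start):
# "before" (a entirely 5' of b), "nested" (b inside a's span), "cross"
# (arcs of the two substructures cross: a pseudoknot relationship)


def arrangement(sa: Substructure, sb: Substructure, crossing: bool) -> str:
    """Pattern of substructure sa vs sb, where sa starts 5' of sb."""
    if sa.span[0] > sb.span[0]:
        raise ValueError("arrangement expects sa to start before sb")
    if crossing:
        return "cross"
    if sa.span[1] < sb.span[0]:
        return "before"
    if sb.span[1] < sa.span[1]:
        return "nested"
    # overlapping spans without crossing arcs cannot occur for valid
    # substructures; treat defensively as a crossing-like pattern
    return "cross"


def _patterns(diagram: SimplifiedDiagram) -> dict[tuple[int, int], str]:
    subs = diagram.substructures
    return {
        (a, b): arrangement(subs[a], subs[b], (a, b) in diagram.crossing)
        for a in range(len(subs))
        for b in range(a + 1, len(subs))
    }


def compatible(
    match_a: tuple[int, int],
    match_b: tuple[int, int],
    pat_q: dict[tuple[int, int], str],
    pat_t: dict[tuple[int, int], str],
) -> bool:
    """No-cross-alignment test for two substructure matches (i->j, i'->j').

    Matches are compatible iff the template substructures appear in the same
    index order as the query ones and the relative arrangement (before /
    nested / crossing) is identical on both sides, so pseudoknots may only be
    matched to pseudoknots with a consistent crossing pattern.
    """
    (i, j), (ip, jp) = match_a, match_b
    if i == ip or j == jp:
        return False
    if i > ip:
        (i, j), (ip, jp) = (ip, jp), (i, j)
    if j >= jp:
        return False
    return pat_q[(i, ip)] == pat_t[(j, jp)]


class UnsupportedDiagramError(ValueError):
    """exact_dp was given a diagram with crossing substructures."""


def _nesting_forest(diagram: SimplifiedDiagram) -> tuple[list[int], dict[int, list[int]]]:
    """Roots and children lists of the span-containment forest (nested input)."""
    subs = diagram.substructures
    order = sorted(range(len(subs)), key=lambda k: subs[k].span[0])
    children: dict[int, list[int]] = {k: [] for k in range(len(subs))}
    roots: list[int] = []
    stack: list[int] = []
    for k in order:
        lo, hi = subs[k].span
        while stack and subs[stack[-1]].span[1] < lo:
            stack.pop()
        if stack:
            children[stack[-1]].append(k)
        else:
            roots.append(k)
        stack.append(k)
    return roots, children


def _exact_dp(
    omega: np.ndarray,
    dq: SimplifiedDiagram,
    dt: SimplifiedDiagram,
) -> tuple[float, set[tuple[int, int]]]:
    """Ordered-forest matching DP, exact for crossing-free diagrams."""
    if dq.crossing or dt.crossing:
        raise UnsupportedDiagramError(
            "exact_dp supports only nested diagrams; use branch_and_bound or milp"
        )
    rq, cq = _nesting_forest(dq)
    rt, ct = _nesting_forest(dt)
    memo: dict[tuple[tuple[int, ...], tuple[int, ...]], tuple[float, frozenset]] = {}

    def best(f1: tuple[int, ...], f2: tuple[int, ...]) -> tuple[float, frozenset]:
        if not f1 or not f2:
            return 0.0, frozenset()
        key = (f1, f2)
        if key in memo:
            return memo[key]
        a, r1 = f1[0], f1[1:]
        b, r2 = f2[0], f2[1:]
        # drop a (its children float up), or drop b, or match a with b
        res = best(tuple(cq[a]) + r1, f2)
        alt = best(f1, tuple(ct[b]) + r2)
        if alt[0] > res[0]:
            res = alt
        if omega[a, b] > 0:
            in_score, in_set = best(tuple(cq[a]), tuple(ct[b]))
            out_score, out_set = best(r1, r2)
            total = omega[a, b] + in_score + out_score
            if total > res[0]:
                res = (total, in_set | out_set | {(a, b)})
        memo[key] = res
        return res

    score, matches = best(tuple(rq), tuple(rt))
    return float(score), set(matches)


def _relaxed_dp(omega: np.ndarray) -> np.ndarray:
    """Order-preserving matching relaxation: upper-bound table B[i, j] =
    best score matching query substructures >= i to templates >= j."""
    m, n = omega.shape
    B = np.zeros((m + 1, n + 1))
    for i in range(m - 1, -1, -1):
        for j in range(n - 1, -1, -1):
            B[i, j] = max(
                B[i + 1, j],
                B[i, j + 1],
                (omega[i, j] if omega[i, j] > 0 else 0.0) + B[i + 1, j + 1],
            )
    return B


def _branch_and_bound(
    omega: np.ndarray,
    pat_q: dict[tuple[int, int], str],
    pat_t: dict[tuple[int, int], str],
) -> tuple[float, set[tuple[int, int]]]:
    """Depth-first search over query substructures in order, pruned by the
    crossing-relaxed DP bound; exact on any diagram."""
    m, n = omega.shape
    bound = _relaxed_dp(omega)
    best_score = 0.0
    best_set: set[tuple[int, int]] = set()
    chosen: list[tuple[int, int]] = []

    def dfs(i: int, min_j: int, score: float) -> None:
        nonlocal best_score, best_set
        if score > best_score:
            best_score = score
            best_set = set(chosen)
        if i == m or score + bound[i, min_j] <= best_score:
            return
        for j in range(min_j, n):
            if omega[i, j] <= 0:
                continue
            cand = (i, j)
            if all(compatible(prev, cand, pat_q, pat_t) for prev in chosen):
                chosen.append(cand)
                dfs(i + 1, j + 1, score + omega[i, j])
                chosen.pop()
        dfs(i + 1, min_j, score)

    dfs(0, 0, 0.0)
    return best_score, best_set


def _milp(
    omega: np.ndarray,
    pat_q: dict[tuple[int, int], str],
    pat_t: dict[tuple[int, int], str],
) -> tuple[float, set[tuple[int, int]]]:
    """Exact integer-programming backend (HiGHS through scipy).

    The matching objective is linear in the 0/1 match variables x_ij; the
    no-cross-alignment constraint becomes one x_a + x_b <= 1 row per
    incompatible variable pair."""
    from scipy.optimize import Bounds, LinearConstraint, milp
    from scipy.sparse import lil_matrix

    cand = [
        (i, j)
        for i in range(omega.shape[0])
        for j in range(omega.shape[1])
        if omega[i, j] > 0
    ]
    if not cand:
        return 0.0, set()
    nv = len(cand)
    rows: list[tuple[int, int]] = []
    for a in range(nv):
        for b in range(a + 1, nv):
            if not compatible(cand[a], cand[b], pat_q, pat_t):
                rows.append((a, b))
    A = lil_matrix((len(rows), nv))
    for r, (a, b) in enumerate(rows):
        A[r, a] = 1
        A[r, b] = 1
    c = -np.array([omega[i, j] for i, j in cand])
    constraints = (
        [LinearConstraint(A.tocsr(), -np.inf, 1)] if rows else []
    )
    res = milp(c, constraints=constraints, integrality=np.ones(nv), bounds=Bounds(0, 1))
    if not res.success:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    chosen = {cand[k] for k in range(nv) if res.x[k] > 0.5}
    return float(-res.fun), chosen


def match_substructures(
    omega: np.ndarray,
    dq: SimplifiedDiagram,
    dt: SimplifiedDiagram,
    solver: str = "auto",
) -> tuple[float, set[tuple[int, int]]]:
    """Maximize the sum of omega over matched substructure pairs subject to
    one-to-one matching and no cross-alignment.

    Solvers: ``exact_dp`` (interval/forest DP, nested diagrams only),
    ``branch_and_bound`` and ``milp`` (any diagram), ``auto`` (exact_dp when
    both diagrams are nested, else branch_and_bound).  All are provably
    optimal on their supported inputs.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (len(dq), len(dt)):
        raise ValueError("omega shape must be (len(query diagram), len(template diagram))")
    if solver == "auto":
        solver = (
            "exact_dp" if dq.is_nested() and dt.is_nested() else "branch_and_bound"
        )
    if solver == "exact_dp":
        return _exact_dp(omega, dq, dt)
    pat_q, pat_t = _patterns(dq), _patterns(dt)
    if solver == "branch_and_bound":
        return _branch_and_bound(omega, pat_q, pat_t)
    if solver == "milp":
        return _milp(omega, pat_q, pat_t)
    raise ValueError(f"unknown solver {solver!r}")


# ---------------------------------------------------------------------------
# stage two: final nucleotide-level alignment


def final_alignment(
    query: str,
    template: str,
    s_aln: set[tuple[int, int]],
    tables: ScoringTables,
    profile: SequenceProfile | None = None,
    gaps: GapModel = GapModel(),
    config: ScoringConfig = DEFAULT_CONFIG,
) -> Alignment:
    """Full-sequence affine-gap NWDP with anchor bonuses.

    Cell (i, j) scores Rs(q_i, t_j) — or the profile F(i, t_j) when a usable
    profile exists — plus a flat bonus for pairs anchored by the substructure
    stage.  Terminal gaps are free when the gap model says so; chain
    separators in the template can never be matched and are gapped for free.
    """
    if not query or not template:
        raise ValueError("sequences must be non-empty")
    query = query.upper()
    template = template.upper()
    m, n = len(query), len(template)
    use_prof = profile is not None and profile.use_profile

    # precompute the cell score matrix
    S = np.empty((m, n))
    tdists = np.stack([tables.nuc_dist(c) if c != "&" else np.zeros(4) for c in template])
    if use_prof:
        S[:] = profile.F @ tdists.T
    else:
        qdists = np.stack([tables.nuc_dist(c) for c in query])
        S[:] = qdists @ tables.Rs @ tdists.T
    for j, c in enumerate(template):
        if c == "&":
            S[:, j] = NEG_INF
    for i, j in s_aln:
        if 1 <= i <= m and 1 <= j <= n:
            S[i - 1, j - 1] += config.pair_bonus

    scaling = use_prof and gaps.msa_gap_scaling

    def open_q(i: int) -> float:
        if scaling:
            return gaps.open * gaps.scale(profile.gap_ratio[i - 1])
        return gaps.open

    def ext_q(i: int) -> float:
        if scaling:
            return gaps.extend * gaps.scale(profile.gap_ratio[i - 1])
        return gaps.extend

    def open_t(j: int) -> float:
        return 0.0 if template[j - 1] == "&" else gaps.open

    def ext_t(j: int) -> float:
        return 0.0 if template[j - 1] == "&" else gaps.extend

    score, pairs = _gotoh(
        m, n, lambda i, j: S[i - 1, j - 1], open_q, ext_q, open_t, ext_t,
        free_terminal=gaps.free_terminal,
    )
    return Alignment(pairs=tuple(pairs), score=score, query_length=m)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass(frozen=True)
class QueryBundle:
    """Everything known about the query: sequence, structure, optional profile."""

    ss: SecondaryStructure
    profile: SequenceProfile | None = None

    @property
    def sequence(self) -> str:
        return self.ss.sequence


def thread_one(
    query: QueryBundle,
    template_ss: SecondaryStructure,
    tables: ScoringTables,
    gaps: GapModel = GapModel(),
    config: ScoringConfig = DEFAULT_CONFIG,
    max_internal_unpaired: int = 2,
    solver: str = "auto",
    qctx: StructureContext | None = None,
) -> Alignment:
    """Run the two-stage pipeline for one query/template pair."""
    if qctx is None:
        qctx = build_context(query.ss, max_internal_unpaired)
    tctx = build_context(template_ss, max_internal_unpaired)
    dq, dt = qctx.diagram, tctx.diagram
    omega = np.zeros((len(dq), len(dt)))
    induced: dict[tuple[int, int], list[tuple[int, int]]] = {}
    stage_gaps = GapModel(
        open=gaps.open, extend=gaps.extend, free_terminal=False,
        msa_gap_scaling=gaps.msa_gap_scaling, min_scale=gaps.min_scale,
    )
    for a, sq in enumerate(dq.substructures):
        for b, st in enumerate(dt.substructures):
            w, pairs = partial_nwdp(
                sq, st, qctx, tctx, tables, query.profile, stage_gaps, config
            )
            omega[a, b] = max(w, 0.0)  # never match substructures at negative score
            induced[(a, b)] = pairs
    _, matches = match_substructures(omega, dq, dt, solver=solver)
    s_aln = {p for ab in matches for p in induced[ab]}
    return final_alignment(
        qctx.sequence, tctx.sequence, s_aln, tables, query.profile, gaps, config
    )


def thread(
    query: QueryBundle,
    library: Sequence[tuple[str, SecondaryStructure]],
    tables: ScoringTables,
    top_k: int = 10,
    gaps: GapModel = GapModel(),
    config: ScoringConfig = DEFAULT_CONFIG,
    max_internal_unpaired: int = 2,
    solver: str = "auto",
) -> list[tuple[str, Alignment]]:
    """Thread the query through a template library and rank the templates.

    *library* is a sequence of (template_id, SecondaryStructure).  Templates
    are ranked by final alignment score, ties broken by coverage then by
    template id, so results are fully deterministic.
    """
    if not library:
        raise ValueError("template library is empty")
    qctx = build_context(query.ss, max_internal_unpaired)
    results: list[tuple[str, Alignment]] = []
    for tid, tss in library:
        aln = thread_one(
            query, tss, tables, gaps, config, max_internal_unpaired, solver, qctx
        )
        results.append((tid, aln))
    results.sort(key=lambda r: (-r[1].score, -r[1].coverage, r[0]))
    return results[:top_k]
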