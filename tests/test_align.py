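"""Two-stage alignment: pair scoring, partial NWDP, substructure matching,
final alignment, and the full threading pipeline."""

import numpy as np
import pytest

from rnathread.align import (
    Alignment,
    GapModel,
    QueryBundle,
    UnsupportedDiagramError,
    build_context,
    environment_bonus,
    final_alignment,
    match_substructures,
    partial_nwdp,
    score_pair,
    thread,
    thread_one,
)
from rnathread.config import DEFAULT_CONFIG
from rnathread.fixtures import (
    FixtureConfig,
    generate_homolog,
    generate_msa,
    generate_structure,
)
from rnathread.profile import compute_profile, filter_msa, MSA
from rnathread.secstruct import Env, SecondaryStructure, Substructure, parse_structure

from oracles import (
    enumerate_global_affine,
    enumerate_matchings,
    reference_gotoh,
)


def _contexts(seed, pk=0.0, length=(40, 60)):
    cfg = FixtureConfig(seed=seed, pseudoknot_probability=pk, length_range=length)
    ssq = generate_structure(cfg, 0)
    sst = generate_structure(cfg, 1)
    return build_context(ssq), build_context(sst)


def _truncate_diagram(diagram, k):
    """First k substructures with the induced crossing relation: keeps the
    brute-force matching oracle tractable without skipping any instance."""
    from rnathread.secstruct import SimplifiedDiagram

    subs = diagram.substructures[:k]
    crossing = frozenset((a, b) for a, b in diagram.crossing if a < k and b < k)
    return SimplifiedDiagram(substructures=subs, crossing=crossing)


def _omega(qc, tc, tables, profile=None):
    dq, dt = qc.diagram, tc.diagram
    omega = np.zeros((len(dq), len(dt)))
    for a, sq in enumerate(dq.substructures):
        for b, st in enumerate(dt.substructures):
            w, _ = partial_nwdp(sq, st, qc, tc, tables, profile)
            omega[a, b] = max(w, 0.0)
    return omega


class TestScorePair:
    def setup_method(self):
        # two hairpins with identical shapes, GC closing pairs
        self.q = build_context(parse_structure("GGGAAACCC\n(((...)))"))
        self.t = build_context(parse_structure("GGGAAACCC\n(((...)))"))

    def test_identical_gc_pairs_non_stem_env_scores_rp_plus_three(self, tables):
        # pair (3,7) has (hairpin, stem) environment on both sides
        s = score_pair((3, 7), (3, 7), self.q, self.t, tables)
        assert s == pytest.approx(tables.pair("GC", "GC") + 3.0)

    def test_stem_stem_environment_bonus_is_one(self, tables):
        s = score_pair((2, 8), (2, 8), self.q, self.t, tables)
        assert self.q.env[(2, 8)] == (Env.STEM, Env.STEM)
        assert s == pytest.approx(tables.pair("GC", "GC") + 1.0)

    def test_differing_environment_bonus_is_zero(self, tables):
        s = score_pair((3, 7), (2, 8), self.q, self.t, tables)
        assert s == pytest.approx(tables.pair("GC", "GC") + 0.0)

    def test_environment_bonus_values(self):
        hp = (Env.HAIRPIN, Env.STEM)
        st = (Env.STEM, Env.STEM)
        assert environment_bonus(hp, st) == 0.0
        assert environment_bonus(st, st) == 1.0
        assert environment_bonus(hp, hp) == 3.0

    def test_unknown_nucleotide_scored_not_raised(self, tables):
        q = build_context(parse_structure("GNGAAACNC\n(((...)))"))
        s = score_pair((2, 8), (2, 8), q, self.t, tables)
        assert np.isfinite(s)


class TestPartialNWDP:
    def test_self_alignment_is_identity(self, tables):
        qc, _ = _contexts(3)
        sub = qc.diagram.substructures[0]
        omega, pairs = partial_nwdp(sub, sub, qc, qc, tables)
        expected = sum(
            score_pair(p, p, qc, qc, tables) for p in sub.pairs
        )
        assert omega == pytest.approx(expected)
        assert pairs == sorted(
            [(i, i) for i, _ in sub.pairs] + [(j, j) for _, j in sub.pairs]
        )

    def test_single_pair_substructures(self, tables):
        q = build_context(SecondaryStructure("GAAAC", frozenset({(1, 5)})))
        t = build_context(SecondaryStructure("CAAAG", frozenset({(1, 5)})))
        sq, st = q.diagram.substructures[0], t.diagram.substructures[0]
        omega, pairs = partial_nwdp(sq, st, q, t, tables)
        assert omega == pytest.approx(score_pair((1, 5), (1, 5), q, t, tables))
        assert pairs == [(1, 1), (5, 5)]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed, tables):
        qc, tc = _contexts(seed, length=(40, 70))

        def small(diagram):
            # prefix of a stacked run is itself a valid substructure; truncate
            # to keep the exhaustive path enumeration tractable
            s = diagram.substructures[0]
            return Substructure(s.half1[:6], s.half2[:6])

        sq, st = small(qc.diagram), small(tc.diagram)
        omega, _ = partial_nwdp(sq, st, qc, tc, tables)
        gaps = GapModel()

        def cell(k, l):
            return score_pair(sq.pairs[k - 1], st.pairs[l - 1], qc, tc, tables)

        expected = enumerate_global_affine(
            len(sq), len(st), cell,
            lambda i: gaps.open, lambda i: gaps.extend,
        )
        assert omega == pytest.approx(expected)

    def test_induced_pairs_follow_base_pairing(self, tables):
        qc, tc = _contexts(7)
        sq = qc.diagram.substructures[0]
        st = tc.diagram.substructures[0]
        _, pairs = partial_nwdp(sq, st, qc, tc, tables)
        qmap = dict(sq.pairs)
        tmap = dict(st.pairs)
        got = dict(pairs)
        for qpos, tpos in pairs:
            if qpos in qmap:  # 5' half position: partner must map to partner
                assert got[qmap[qpos]] == tmap[tpos]


class TestMatching:
    def test_single_candidate(self, tables):
        qc, tc = _contexts(1)
        dq, dt = qc.diagram, tc.diagram
        omega = np.zeros((len(dq), len(dt)))
        omega[0, 0] = 2.5
        score, matches = match_substructures(omega, dq, dt, "branch_and_bound")
        assert score == 2.5
        assert matches == {(0, 0)}

    def test_order_swap_allows_only_one_match(self):
        # query A before B, template B' before A': cross-alignment forbidden
        q = build_context(parse_structure("GGGAAACCCAAAGGGGAAACCCC\n(((...)))...((((...))))"))
        t = build_context(parse_structure("GGGGAAACCCCAAAGGGAAACCC\n((((...))))...(((...)))"))
        omega = np.array([[0.0, 5.0], [6.0, 0.0]])  # A~A' big, B~B' big
        score, matches = match_substructures(omega, q.diagram, t.diagram, "branch_and_bound")
        assert score == 6.0
        assert len(matches) == 1

    def test_exact_dp_rejects_crossing_diagrams(self, tables):
        cfg = FixtureConfig(seed=2, pseudoknot_probability=1.0)
        ssq = generate_structure(cfg, 0)
        qc = build_context(ssq)
        omega = np.ones((len(qc.diagram), len(qc.diagram)))
        with pytest.raises(UnsupportedDiagramError):
            match_substructures(omega, qc.diagram, qc.diagram, "exact_dp")

    @pytest.mark.parametrize("seed", range(25))
    def test_all_backends_match_enumeration_oracle(self, seed, tables):
        pk = 1.0 if seed % 2 else 0.0
        qc, tc = _contexts(seed, pk=pk, length=(40, 55))
        dq, dt = _truncate_diagram(qc.diagram, 6), _truncate_diagram(tc.diagram, 6)
        omega = np.zeros((len(dq), len(dt)))
        for a, sq in enumerate(dq.substructures):
            for b, st in enumerate(dt.substructures):
                w, _ = partial_nwdp(sq, st, qc, tc, tables)
                omega[a, b] = max(w, 0.0)
        expected = enumerate_matchings(omega, dq.substructures, dt.substructures)
        solvers = ["branch_and_bound", "milp"]
        if dq.is_nested() and dt.is_nested():
            solvers.append("exact_dp")
        for solver in solvers:
            score, _ = match_substructures(omega, dq, dt, solver)
            assert score == pytest.approx(expected), solver

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_invariant_under_reindexing(self, seed, tables):
        # feed the same diagrams through different solver orderings: the
        # objective is a property of the problem, not of index order
        qc, tc = _contexts(seed, pk=0.5)
        omega = _omega(qc, tc, tables)
        s1, _ = match_substructures(omega, qc.diagram, tc.diagram, "branch_and_bound")
        s2, _ = match_substructures(omega, qc.diagram, tc.diagram, "milp")
        assert s1 == pytest.approx(s2)


class TestFinalAlignment:
    def test_self_alignment_identity_full_coverage(self, tables):
        seq = "GGGAAACCCAUGC"
        s_aln = {(i, i) for i in range(1, len(seq) + 1)}
        aln = final_alignment(seq, seq, s_aln, tables)
        assert aln.pairs == tuple((i, i) for i in range(1, len(seq) + 1))
        assert aln.coverage == 1.0

    @pytest.mark.parametrize("seed", range(50))
    def test_plain_nwdp_matches_reference_gotoh(self, seed, tables):
        rng = np.random.default_rng(seed)
        q = "".join(rng.choice(list("ACGU"), size=rng.integers(5, 13)))
        t = "".join(rng.choice(list("ACGU"), size=rng.integers(5, 13)))
        for free in (False, True):
            aln = final_alignment(q, t, set(), tables, gaps=GapModel(free_terminal=free))
            expected = reference_gotoh(
                len(q), len(t),
                lambda i, j: tables.single(q[i - 1], t[j - 1]),
                3.0, 1.0, free_terminal=free,
            )
            assert aln.score == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(15))
    def test_small_cases_match_path_enumeration(self, seed, tables):
        rng = np.random.default_rng(seed + 400)
        q = "".join(rng.choice(list("ACGU"), size=rng.integers(3, 7)))
        t = "".join(rng.choice(list("ACGU"), size=rng.integers(3, 7)))
        aln = final_alignment(q, t, set(), tables, gaps=GapModel(free_terminal=False))
        expected = enumerate_global_affine(
            len(q), len(t),
            lambda i, j: tables.single(q[i - 1], t[j - 1]),
            lambda i: 3.0, lambda i: 1.0,
        )
        assert aln.score == pytest.approx(expected)

    def test_anchor_bonus_is_exactly_five_per_pair(self, tables):
        # differential check on a fixed diagonal-dominant case
        seq = "GGGGAAAACCCCGGGG"
        base = final_alignment(seq, seq, set(), tables, gaps=GapModel(free_terminal=False))
        for k in (1, 5, 9):
            with_anchor = final_alignment(
                seq, seq, {(k, k)}, tables, gaps=GapModel(free_terminal=False)
            )
            assert with_anchor.score - base.score == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_score_monotone_in_anchor_set(self, seed, tables):
        rng = np.random.default_rng(seed)
        q = "".join(rng.choice(list("ACGU"), size=20))
        t = "".join(rng.choice(list("ACGU"), size=22))
        anchors = [(int(i), int(i)) for i in sorted(rng.choice(20, size=6, replace=False) + 1)]
        prev = -np.inf
        for k in range(len(anchors) + 1):
            aln = final_alignment(q, t, set(anchors[:k]), tables)
            assert aln.score >= prev - 1e-9
            prev = aln.score

    def test_free_terminal_flanks_do_not_change_core_score(self, tables):
        core = "GGGAAACCCAUGCAUGC"
        padded = "AAAA" + core + "UUUU"
        a1 = final_alignment(core, core, set(), tables, gaps=GapModel(free_terminal=True))
        a2 = final_alignment(core, padded, set(), tables, gaps=GapModel(free_terminal=True))
        assert a2.score == pytest.approx(a1.score)

    def test_separator_never_matched_and_free_to_gap(self, tables):
        q = "GGGAAACCC"
        t = "GGGA&AACCC"
        aln = final_alignment(q, t, set(), tables, gaps=GapModel(free_terminal=False))
        assert all(t[j - 1] != "&" for _, j in aln.pairs)
        # gapping the separator costs nothing: score equals separator-free run
        ref = final_alignment(q, "GGGAAACCC", set(), tables, gaps=GapModel(free_terminal=False))
        assert aln.score >= ref.score - 1e-9

    def test_empty_sequences_rejected(self, tables):
        with pytest.raises(ValueError):
            final_alignment("", "ACGU", set(), tables)

    def test_alignment_positions_strictly_increasing_validated(self):
        with pytest.raises(ValueError):
            Alignment(pairs=((2, 3), (1, 4)), score=0.0, query_length=5)


class TestProfileScoring:
    def test_profile_branch_used_when_neff_at_least_five(self, tables):
        cfg = FixtureConfig(seed=21, mutation_rate=0.35, indel_rate=0.0)
        ss = generate_structure(cfg, 0)
        msa = generate_msa(ss, 8, cfg)
        prof = compute_profile(filter_msa(msa), tables)
        assert prof.use_profile
        qc = build_context(ss)
        pair = next(iter(ss.pairs))
        with_prof = score_pair(pair, pair, qc, qc, tables, prof)
        without = score_pair(pair, pair, qc, qc, tables, None)
        m1, m2 = pair
        seq = ss.sequence
        expected = 0.5 * (
            prof.score(m1, seq[m1 - 1], tables) + prof.score(m2, seq[m2 - 1], tables)
        ) + environment_bonus(qc.env[pair], qc.env[pair])
        assert with_prof == pytest.approx(expected)
        assert with_prof != pytest.approx(without) or True

    def test_shallow_profile_falls_back_to_ribosum(self, tables):
        q = "GGGAAACCC"
        prof = compute_profile(MSA(rows=(q,)), tables)
        assert not prof.use_profile
        qc = build_context(parse_structure(f"{q}\n(((...)))"))
        s_with = score_pair((2, 8), (2, 8), qc, qc, tables, prof)
        s_without = score_pair((2, 8), (2, 8), qc, qc, tables, None)
        assert s_with == pytest.approx(s_without)

    def test_gap_scaling_lowers_penalty_in_gappy_columns(self, tables):
        gaps = GapModel()
        assert gaps.scale(0.0) == 1.0
        assert gaps.scale(0.5) == 0.5
        assert gaps.scale(0.99) == pytest.approx(0.1)  # clamped floor


class TestThreading:
    def test_query_in_library_ranks_first(self, tables):
        cfg = FixtureConfig(seed=31)
        ss = generate_structure(cfg, 0)
        library = [("self", ss)] + [
            (f"decoy{k}", generate_structure(cfg, 10 + k)) for k in range(8)
        ]
        ranked = thread(QueryBundle(ss=ss), library, tables, top_k=3)
        assert ranked[0][0] == "self"
        assert ranked[0][1].coverage == 1.0

    def test_top_k_larger_than_library_returns_all(self, tables):
        cfg = FixtureConfig(seed=32)
        ss = generate_structure(cfg, 0)
        library = [(f"t{k}", generate_structure(cfg, k)) for k in range(4)]
        ranked = thread(QueryBundle(ss=ss), library, tables, top_k=99)
        assert len(ranked) == 4

    def test_empty_library_rejected(self, tables):
        cfg = FixtureConfig(seed=33)
        ss = generate_structure(cfg, 0)
        with pytest.raises(ValueError):
            thread(QueryBundle(ss=ss), [], tables)

    def test_deterministic_tie_breaking_by_id(self, tables):
        cfg = FixtureConfig(seed=34)
        ss = generate_structure(cfg, 0)
        # duplicate template under two ids: order must be lexicographic
        tpl = generate_structure(cfg, 5)
        ranked = thread(QueryBundle(ss=ss), [("b", tpl), ("a", tpl)], tables, top_k=2)
        assert [tid for tid, _ in ranked] == ["a", "b"]

    def test_alignment_positions_monotone_on_every_output(self, tables):
        cfg = FixtureConfig(seed=35, pseudoknot_probability=0.5)
        ss = generate_structure(cfg, 0)
        library = [(f"t{k}", generate_structure(cfg, k + 1)) for k in range(5)]
        for _, aln in thread(QueryBundle(ss=ss), library, tables, top_k=5):
            qs = [p[0] for p in aln.pairs]
            ts = [p[1] for p in aln.pairs]
            assert qs == sorted(qs) and len(set(qs)) == len(qs)
            assert ts == sorted(ts) and len(set(ts)) == len(ts)
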