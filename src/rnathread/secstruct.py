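"""RNA secondary structures as arc diagrams.

A secondary structure is a sequence plus a set of base pairs (i, j), drawn as
arcs over the nucleotide line.  Crossing arcs are pseudoknots.  This module
parses/writes the common plain-text formats (extended dot-bracket, CT, BPSEQ),
detects pseudoknots, groups stacked pairs into *substructures* (the units of
the simplified diagram used for coarse matching), and classifies the local
loop environment of each base pair.

All public coordinates are 1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "SecondaryStructure",
    "Substructure",
    "SimplifiedDiagram",
    "Env",
    "StructureError",
    "parse_structure",
    "write_structure",
    "detect_pseudoknots",
    "extract_substructures",
    "classify_environment",
]

RNA_ALPHABET = set("ACGUN&")  # '&' is the inter-chain separator, always unpaired

# bracket tiers of the extended dot-bracket dialect
_OPENERS = "([{<" + "".join(chr(c) for c in range(ord("A"), ord("Z") + 1))
_CLOSERS = ")]}>" + "".join(chr(c) for c in range(ord("a"), ord("z") + 1))
_CLOSE_OF = dict(zip(_OPENERS, _CLOSERS))
_TIER_OF_OPEN = {c: t for t, c in enumerate(_OPENERS)}
_TIER_OF_CLOSE = {c: t for t, c in enumerate(_CLOSERS)}


class StructureError(ValueError):
    """Raised for malformed or inconsistent secondary-structure input."""


class Env(str, Enum):
    """Loop-environment vocabulary for base pairs."""

    STEM = "stem"
    HAIRPIN = "hairpin"
    BULGE = "bulge"
    INTERIOR = "interior"
    MULTILOOP = "multiloop"
    PSEUDOKNOT = "pseudoknot"


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence with a set of base pairs (1-based, i < j)."""

    sequence: str
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise StructureError(f"invalid sequence characters: {sorted(bad)}")
        n = len(seq)
        seen: dict[int, tuple[int, int]] = {}
        for i, j in self.pairs:
            if not (1 <= i < j <= n):
                raise StructureError(f"pair ({i},{j}) out of range for length {n}")
            for p in (i, j):
                if p in seen:
                    raise StructureError(
                        f"position {p} paired twice: {seen[p]} and ({i},{j})"
                    )
                if seq[p - 1] == "&":
                    raise StructureError(f"separator position {p} cannot pair")
                seen[p] = (i, j)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def partner(self, i: int) -> int | None:
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None

    def partner_map(self) -> dict[int, int]:
        m: dict[int, int] = {}
        for i, j in self.pairs:
            m[i] = j
            m[j] = i
        return m


@dataclass(frozen=True)
class Substructure:
    """A maximal run of stacked base pairs (bulges/interior loops tolerated).

    half1 holds the 5' partners in increasing order, half2 the 3' partners in
    decreasing order, so half1[k] pairs with half2[k].
    """

    half1: tuple[int, ...]
    half2: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.half1) != len(self.half2):
            raise StructureError("substructure halves differ in length")
        if list(self.half1) != sorted(self.half1):
            raise StructureError("half1 not increasing")
        if list(self.half2) != sorted(self.half2, reverse=True):
            raise StructureError("half2 not decreasing")

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(zip(self.half1, self.half2))

    @property
    def span(self) -> tuple[int, int]:
        return self.half1[0], self.half2[0]

    def __len__(self) -> int:
        return len(self.half1)


@dataclass(frozen=True)
class SimplifiedDiagram:
    """Ordered substructures of a structure plus their crossing relations."""

    substructures: tuple[Substructure, ...]
    crossing: frozenset[tuple[int, int]]  # index pairs (a, b), a < b

    def is_nested(self) -> bool:
        return not self.crossing

    def __len__(self) -> int:
        return len(self.substructures)


# ---------------------------------------------------------------------------
# parsing / writing


def _parse_dotbracket(seq: str, db: str) -> frozenset[tuple[int, int]]:
    if len(seq) != len(db):
        raise StructureError(
            f"sequence length {len(seq)} != structure length {len(db)}"
        )
    stacks: dict[int, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for pos, c in enumerate(db, start=1):
        if c in ".-_,:&~":
            continue
        if c in _TIER_OF_OPEN:
            stacks.setdefault(_TIER_OF_OPEN[c], []).append(pos)
        elif c in _TIER_OF_CLOSE:
            tier = _TIER_OF_CLOSE[c]
            stack = stacks.get(tier)
            if not stack:
                raise StructureError(f"unbalanced bracket '{c}' at position {pos}")
            pairs.add((stack.pop(), pos))
        else:
            raise StructureError(f"unknown structure character '{c}' at {pos}")
    for tier, stack in stacks.items():
        if stack:
            raise StructureError(
                f"unbalanced bracket '{_OPENERS[tier]}' opened at position {stack[-1]}"
            )
    return frozenset(pairs)


def _parse_partner_rows(
    rows: Iterable[tuple[int, str, int]], drop_conflicts: bool
) -> tuple[str, frozenset[tuple[int, int]]]:
    seq: list[str] = []
    partner: dict[int, int] = {}
    for idx, base, mate in rows:
        if idx != len(seq) + 1:
            raise StructureError(f"non-contiguous index {idx}")
        seq.append(base.upper())
        if mate:
            if idx in partner and partner[idx] != mate:
                if drop_conflicts:
                    continue
                raise StructureError(f"position {idx} paired twice")
            partner[idx] = mate
    pairs: set[tuple[int, int]] = set()
    for i, j in partner.items():
        if partner.get(j, i if drop_conflicts else None) != i:
            if drop_conflicts:
                continue
            raise StructureError(f"asymmetric pair record ({i},{j})")
        if i < j:
            pairs.add((i, j))
    if drop_conflicts:
        # keep the first-listed pair per position
        used: set[int] = set()
        kept: set[tuple[int, int]] = set()
        for i, j in sorted(pairs):
            if i in used or j in used:
                continue
            used.update((i, j))
            kept.add((i, j))
        pairs = kept
    return "".join(seq), frozenset(pairs)


def _parse_ct(text: str, drop_conflicts: bool) -> tuple[str, frozenset]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureError("empty CT input")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise StructureError("CT header must start with the length") from exc
    rows = []
    for ln in lines[1 : n + 1]:
        f = ln.split()
        if len(f) < 6:
            raise StructureError(f"CT row needs 6 columns: {ln!r}")
        rows.append((int(f[0]), f[1], int(f[4])))
    if len(rows) != n:
        raise StructureError(f"CT header says {n} rows, found {len(rows)}")
    return _parse_partner_rows(rows, drop_conflicts)


def _parse_bpseq(text: str, drop_conflicts: bool) -> tuple[str, frozenset]:
    rows = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        f = ln.split()
        if len(f) != 3:
            raise StructureError(f"BPSEQ row needs 3 columns: {ln!r}")
        rows.append((int(f[0]), f[1], int(f[2])))
    if not rows:
        raise StructureError("empty BPSEQ input")
    return _parse_partner_rows(rows, drop_conflicts)


def parse_structure(
    text: str, format: str = "dotbracket", drop_conflicts: bool = False
) -> SecondaryStructure:
    """Parse a secondary structure from text.

    Formats: ``dotbracket`` (two lines: sequence then structure, with an
    optional leading FASTA header), ``ct`` (RNAstructure dialect) and
    ``bpseq``.  Base triples are rejected unless *drop_conflicts* is set, in
    which case the first-listed pair per position wins.
    """
    if format == "dotbracket":
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        if lines and lines[0].startswith(">"):
            lines = lines[1:]
        if len(lines) < 2:
            raise StructureError("dot-bracket input needs sequence and structure lines")
        seq, db = lines[0], lines[1]
        return SecondaryStructure(seq, _parse_dotbracket(seq.upper(), db))
    if format == "ct":
        seq, pairs = _parse_ct(text, drop_conflicts)
        return SecondaryStructure(seq, pairs)
    if format == "bpseq":
        seq, pairs = _parse_bpseq(text, drop_conflicts)
        return SecondaryStructure(seq, pairs)
    raise ValueError(f"unknown format {format!r} (use dotbracket, ct or bpseq)")


def _crosses(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = sorted((p, q))
    return i < k < j < l


def dotbracket_string(ss: SecondaryStructure) -> str:
    """Render pairs as extended dot-bracket, assigning pseudoknot tiers greedily."""
    tiers: list[list[tuple[int, int]]] = []
    for pair in sorted(ss.pairs):
        for tier in tiers:
            if not any(_crosses(pair, other) for other in tier):
                tier.append(pair)
                break
        else:
            if len(tiers) >= len(_OPENERS):
                raise StructureError("structure needs more pseudoknot tiers than available")
            tiers.append([pair])
    out = ["." if c != "&" else "&" for c in ss.sequence]
    for t, tier in enumerate(tiers):
        for i, j in tier:
            out[i - 1] = _OPENERS[t]
            out[j - 1] = _CLOSERS[t]
    return "".join(out)


def write_structure(ss: SecondaryStructure, format: str = "dotbracket") -> str:
    """Serialize a structure to dotbracket, ct, or bpseq text."""
    if format == "dotbracket":
        return f"{ss.sequence}\n{dotbracket_string(ss)}\n"
    partner = ss.partner_map()
    if format == "ct":
        lines = [f"{ss.length}  rnathread"]
        for i, base in enumerate(ss.sequence, start=1):
            nxt = i + 1 if i < ss.length else 0
            lines.append(f"{i} {base} {i - 1} {nxt} {partner.get(i, 0)} {i}")
        return "\n".join(lines) + "\n"
    if format == "bpseq":
        lines = [
            f"{i} {base} {partner.get(i, 0)}"
            for i, base in enumerate(ss.sequence, start=1)
        ]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# pseudoknots and substructures


def detect_pseudoknots(
    ss: SecondaryStructure,
) -> set[tuple[tuple[int, int], tuple[int, int]]]:
    """All crossing arc pairs ((i,j),(k,l)) with i<k<j<l; empty iff nested."""
    pairs = sorted(ss.pairs)
    out: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    # sweep: for each pair, compare with pairs opening inside it
    for a in range(len(pairs)):
        i, j = pairs[a]
        for b in range(a + 1, len(pairs)):
            k, l = pairs[b]
            if k >= j:
                break
            if j < l:
                out.add(((i, j), (k, l)))
    return out


def extract_substructures(
    ss: SecondaryStructure, max_internal_unpaired: int = 2
) -> SimplifiedDiagram:
    """Partition base pairs into substructures and build the simplified diagram.

    Two successive pairs (i,j) and (i',j') (sorted by 5' position) belong to
    the same substructure iff i<i', j'<j and the internal gaps i'-i-1 and
    j-j'-1 are each at most *max_internal_unpaired* — i.e. stacked pairs with
    small bulges or interior loops tolerated.
    """
    pairs = sorted(ss.pairs)
    runs: list[list[tuple[int, int]]] = []
    for pair in pairs:
        if runs:
            pi, pj = runs[-1][-1]
            i, j = pair
            if (
                pi < i
                and j < pj
                and (i - pi - 1) <= max_internal_unpaired
                and (pj - j - 1) <= max_internal_unpaired
            ):
                runs[-1].append(pair)
                continue
        runs.append([pair])
    subs = tuple(
        Substructure(
            half1=tuple(p[0] for p in run),
            half2=tuple(p[1] for p in run),
        )
        for run in runs
    )
    crossing: set[tuple[int, int]] = set()
    for a in range(len(subs)):
        for b in range(a + 1, len(subs)):
            if any(
                _crosses(p, q) for p in subs[a].pairs for q in subs[b].pairs
            ):
                crossing.add((a, b))
    return SimplifiedDiagram(substructures=subs, crossing=frozenset(crossing))


# ---------------------------------------------------------------------------
# environment classification


def _inner_loop(ss: SecondaryStructure, i: int, j: int, partner: dict[int, int]):
    """Walk the loop enclosed by (i, j): unpaired runs, closing pairs, crossings."""
    unpaired_runs: list[int] = []
    closing = 0
    crossing = False
    run = 0
    k = i + 1
    while k < j:
        mate = partner.get(k)
        if mate is None:
            run += 1
            k += 1
        elif i < mate < j and mate > k:
            unpaired_runs.append(run)
            run = 0
            closing += 1
            k = mate + 1
        else:
            # partner outside (i, j): an arc crossing the cut edge
            crossing = True
            run += 1
            k += 1
    unpaired_runs.append(run)
    return unpaired_runs, closing, crossing


def _outer_loop(ss: SecondaryStructure, i: int, j: int, partner: dict[int, int]):
    """Walk the loop on the far side of the cut at (i, j)."""
    # innermost pair strictly enclosing (i, j)
    enclosing = None
    for p, q in ss.pairs:
        if p < i and q > j:
            if enclosing is None or p > enclosing[0] or (
                p == enclosing[0] and q < enclosing[1]
            ):
                enclosing = (p, q)
    lo = enclosing[0] if enclosing else 0
    hi = enclosing[1] if enclosing else ss.length + 1
    unpaired_runs: list[int] = []
    closing = 1 if enclosing else 0
    crossing = False

    # left walk: i-1 down to lo+1
    run = 0
    k = i - 1
    while k > lo:
        mate = partner.get(k)
        if mate is None:
            run += 1
            k -= 1
        elif lo < mate < k:
            unpaired_runs.append(run)
            run = 0
            closing += 1
            k = mate - 1
        else:
            crossing = True
            run += 1
            k -= 1
    unpaired_runs.append(run)

    # right walk: j+1 up to hi-1
    run = 0
    k = j + 1
    while k < hi:
        mate = partner.get(k)
        if mate is None:
            run += 1
            k += 1
        elif k < mate < hi:
            unpaired_runs.append(run)
            run = 0
            closing += 1
            k = mate + 1
        else:
            crossing = True
            run += 1
            k += 1
    unpaired_runs.append(run)
    return unpaired_runs, closing, crossing, enclosing


def _classify(unpaired_runs: Sequence[int], closing: int, crossing: bool,
              exterior: bool) -> Env:
    if crossing:
        return Env.PSEUDOKNOT
    if exterior:
        # region outside the outermost pair has no closing pair; by convention
        # it is scored as a multiloop (any fixed label works: only equality of
        # environment tuples is ever tested downstream)
        return Env.MULTILOOP
    total_unpaired = sum(unpaired_runs)
    sides = sum(1 for r in unpaired_runs if r > 0)
    if closing == 0:
        return Env.HAIRPIN
    if closing == 1:
        if total_unpaired == 0:
            return Env.STEM
        if sides == 1:
            return Env.BULGE
        return Env.INTERIOR
    return Env.MULTILOOP


def classify_environment(
    ss: SecondaryStructure, i: int, j: int
) -> tuple[Env, Env]:
    """Environment tuple (inner, outer) of the base pair (i, j).

    The diagram is cut at the edge (i, j); the smallest closed loop bounded by
    i and j on each side is classified as stem, hairpin, bulge, interior,
    multiloop, or pseudoknot.
    """
    if (i, j) not in ss.pairs:
        raise ValueError(f"({i},{j}) is not a pair of this structure")
    partner = ss.partner_map()
    runs_in, closing_in, cross_in = _inner_loop(ss, i, j, partner)
    runs_out, closing_out, cross_out, enclosing = _outer_loop(ss, i, j, partner)
    inner = _classify(runs_in, closing_in, cross_in, exterior=False)
    outer = _classify(runs_out, closing_out, cross_out,
                      exterior=enclosing is None)
    if inner is not Env.PSEUDOKNOT and outer is not Env.PSEUDOKNOT:
        # a pair crossing (i,j) may be buried under closed pairs on both walks;
        # a directly crossed pair still reports a pseudoknot environment
        if any(_crosses((i, j), p) for p in ss.pairs):
            inner = Env.PSEUDOKNOT
    return inner, outer
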