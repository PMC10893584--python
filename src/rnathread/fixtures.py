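"""Deterministic synthetic RNA fixtures.

Everything the pipeline consumes can be generated here with a fixed seed:
random nested or H-type-pseudoknotted secondary structures with realistic
helix/loop geometry, structural homologs (compensatory pair mutations, loop
point mutations, loop-only indels), query MSAs built from such homologs, and
idealized helical backbone traces with Gaussian coordinate noise.  The
generators are not thermodynamic folders — they emulate the *shape* of real
structures (stacked helices, hairpins, bulges, multiloops, one pseudoknot at
most) so that combinatorial and scoring code can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .library import TemplateRecord, write_library
from .profile import MSA
from .secstruct import SecondaryStructure

__all__ = [
    "FixtureConfig",
    "generate_structure",
    "generate_homolog",
    "generate_msa",
    "generate_backbone",
    "make_library",
]

CANONICAL_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")
# stacked WC pairs dominate real helices; wobbles are present but rarer
PAIR_WEIGHTS = (0.22, 0.22, 0.24, 0.24, 0.04, 0.04)
NUCS = "ACGU"


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic generators; fixed seed implies identical output."""

    seed: int = 0
    length_range: tuple[int, int] = (50, 90)
    helix_length: tuple[int, int] = (3, 7)
    pseudoknot_probability: float = 0.3
    mutation_rate: float = 0.3
    indel_rate: float = 0.05
    msa_depth: int = 20
    coord_noise: float = 0.5  # Angstrom

    def __post_init__(self) -> None:
        for p in (self.pseudoknot_probability, self.mutation_rate, self.indel_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])


# ---------------------------------------------------------------------------
# structures


def _nested_pairs(rng: np.random.Generator, n: int, helix_lo: int, helix_hi: int,
                  offset: int = 0) -> list[tuple[int, int]]:
    """Random nested pair set over positions offset+1 .. offset+n."""
    if n < 2 * helix_lo + 3:
        return []
    r = rng.random()
    if r < 0.2:  # unpaired spacer, then the rest
        k = int(rng.integers(1, 4))
        return _nested_pairs(rng, n - k, helix_lo, helix_hi, offset + k)
    if r < 0.4 and n >= 2 * (2 * helix_lo + 3) + 2:  # branch into two regions
        k = int(rng.integers(2 * helix_lo + 3, n - (2 * helix_lo + 3) + 1))
        left = _nested_pairs(rng, k, helix_lo, helix_hi, offset)
        right = _nested_pairs(rng, n - k, helix_lo, helix_hi, offset + k)
        return left + right
    # wrap a helix around the interior
    h = int(min(rng.integers(helix_lo, helix_hi + 1), (n - 3) // 2))
    pairs = [(offset + k + 1, offset + n - k) for k in range(h)]
    return pairs + _nested_pairs(rng, n - 2 * h, helix_lo, helix_hi, offset + h)


def _pseudoknot_block(rng: np.random.Generator, offset: int) -> tuple[int, list[tuple[int, int]]]:
    """H-type pseudoknot: stem1-loop1-stem2-stem1'-loop2-stem2' (crossing arcs)."""
    h1 = int(rng.integers(3, 5))
    h2 = 3
    l1 = int(rng.integers(2, 4))
    l2 = int(rng.integers(2, 4))
    size = 2 * h1 + 2 * h2 + l1 + l2
    s1 = offset
    s2 = s1 + h1 + l1
    s1p = s2 + h2
    s2p = s1p + h1 + l2
    pairs = [(s1 + k + 1, s1p + h1 - k) for k in range(h1)]
    pairs += [(s2 + k + 1, s2p + h2 - k) for k in range(h2)]
    return size, pairs


def generate_structure(cfg: FixtureConfig, stream: int = 0) -> SecondaryStructure:
    """Random secondary structure with at most one pseudoknot.

    A nested scaffold is grown by recursive helix/loop insertion; with
    probability ``pseudoknot_probability`` a self-contained H-type pseudoknot
    block (apical-loop pairing with a downstream segment, i.e. crossing arcs)
    is spliced in at a random point, so crossings appear iff the coin came up.
    """
    rng = cfg.rng(stream, 0)
    n = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
    lo, hi = cfg.helix_length
    want_pk = rng.random() < cfg.pseudoknot_probability
    if want_pk:
        # reserve room for the pseudoknot block, then splice
        size, block = _pseudoknot_block(rng, 0)
        scaffold_len = max(n - size, 0)
        scaffold = _nested_pairs(rng, scaffold_len, lo, hi)
        cut = int(rng.integers(0, scaffold_len + 1))
        shifted = []
        for i, j in scaffold:
            si = i + size if i > cut else i
            sj = j + size if j > cut else j
            shifted.append((si, sj))
        block = [(i + cut, j + cut) for i, j in block]
        pairs = shifted + block
        n = scaffold_len + size
    else:
        pairs = _nested_pairs(rng, n, lo, hi)
    seq = _sequence_for(rng, n, pairs)
    return SecondaryStructure(sequence=seq, pairs=frozenset(pairs))


def _sequence_for(rng: np.random.Generator, n: int, pairs: list[tuple[int, int]]) -> str:
    seq = [""] * n
    for i, j in pairs:
        pt = CANONICAL_PAIRS[rng.choice(len(CANONICAL_PAIRS), p=PAIR_WEIGHTS)]
        seq[i - 1], seq[j - 1] = pt[0], pt[1]
    for k in range(n):
        if not seq[k]:
            seq[k] = NUCS[int(rng.integers(4))]
    return "".join(seq)


# ---------------------------------------------------------------------------
# homologs and MSAs


def _homolog_with_map(
    ss: SecondaryStructure, cfg: FixtureConfig, rng: np.random.Generator
) -> tuple[str, SecondaryStructure, dict[int, int]]:
    """Mutated copy plus the old-position -> new-position map (deleted: absent)."""
    seq = list(ss.sequence)
    paired = ss.partner_map()
    # compensatory pair mutations: base pairing preserved, letters change
    for i, j in ss.pairs:
        if rng.random() < cfg.mutation_rate:
            pt = CANONICAL_PAIRS[rng.choice(len(CANONICAL_PAIRS), p=PAIR_WEIGHTS)]
            seq[i - 1], seq[j - 1] = pt[0], pt[1]
    # loop point mutations
    for k in range(len(seq)):
        if (k + 1) not in paired and rng.random() < cfg.mutation_rate:
            others = [c for c in NUCS if c != seq[k]]
            seq[k] = others[int(rng.integers(3))]
    # loop-only indels
    out: list[str] = []
    mapping: dict[int, int] = {}
    for k, c in enumerate(seq, start=1):
        if k not in paired and cfg.indel_rate > 0:
            r = rng.random()
            if r < cfg.indel_rate / 2:  # delete
                continue
            if r < cfg.indel_rate:  # insert before
                out.append(NUCS[int(rng.integers(4))])
        out.append(c)
        mapping[k] = len(out)
    new_pairs = frozenset(
        (mapping[i], mapping[j]) for i, j in ss.pairs  # paired positions never deleted
    )
    return "".join(out), SecondaryStructure("".join(out), new_pairs), mapping


def generate_homolog(
    ss: SecondaryStructure, cfg: FixtureConfig, stream: int = 0
) -> tuple[str, SecondaryStructure]:
    """Structural homolog: same topology, mutated sequence, loop indels."""
    rng = cfg.rng(stream, 1)
    seq, hss, _ = _homolog_with_map(ss, cfg, rng)
    return seq, hss


def sequence_identity(a: str, b: str) -> float:
    """Identity of two equal-topology sequences via simple global comparison
    over min length (fixture diagnostics, not an aligner)."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(1 for x, y in zip(a, b) if x == y) / n


def generate_msa(ss: SecondaryStructure, n_rows: int, cfg: FixtureConfig,
                 stream: int = 0) -> MSA:
    """MSA in query coordinates: the query row plus n_rows-1 homolog rows.

    Homolog insertions (relative to the query) are dropped; deletions become
    gap characters, so every row has exactly the query's length.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rows = [ss.sequence]
    rng = cfg.rng(stream, 2)
    for r in range(n_rows - 1):
        seq, _, mapping = _homolog_with_map(ss, cfg, rng)
        row = [
            seq[mapping[k] - 1] if k in mapping else "-"
            for k in range(1, ss.length + 1)
        ]
        rows.append("".join(row))
    return MSA(rows=tuple(rows), query_row_index=0)


# ---------------------------------------------------------------------------
# backbone coordinates

# deterministic local offsets (Angstrom) giving each backbone atom a distinct
# position around the residue origin; loosely ribose-phosphate shaped
_ATOM_OFFSETS = {
    "P": (0.0, 0.0, 0.0),
    "OP1": (1.2, 0.6, 0.4),
    "OP2": (-1.2, 0.6, 0.4),
    "O5'": (0.4, -1.3, 0.3),
    "C5'": (0.9, -2.4, 0.9),
    "C4'": (1.7, -3.2, 0.1),
    "C3'": (2.9, -2.6, -0.4),
    "O3'": (3.9, -2.3, 0.5),
    "C2'": (3.2, -3.5, -1.5),
    "C1'": (2.0, -4.3, -1.6),
    "O4'": (1.1, -4.3, -0.6),
    "O2'": (4.3, -3.3, -2.3),
}

_TWIST = math.radians(32.7)  # A-form-like helical twist per residue
_RISE = 2.8
_RADIUS = 9.4


def generate_backbone(
    ss: SecondaryStructure, cfg: FixtureConfig, stream: int = 0
) -> dict[int, dict[str, tuple[float, float, float]]]:
    """Idealized helical backbone trace plus Gaussian noise of the configured
    amplitude (per atom, per coordinate)."""
    rng = cfg.rng(stream, 3)
    coords: dict[int, dict[str, tuple[float, float, float]]] = {}
    for i in range(1, ss.length + 1):
        if ss.sequence[i - 1] == "&":
            continue
        theta = i * _TWIST
        origin = np.array(
            [_RADIUS * math.cos(theta), _RADIUS * math.sin(theta), _RISE * i]
        )
        res = {}
        for atom, off in _ATOM_OFFSETS.items():
            noise = rng.normal(0.0, cfg.coord_noise, size=3) if cfg.coord_noise else 0.0
            res[atom] = tuple(origin + np.asarray(off) + noise)
        coords[i] = res
    return coords


# ---------------------------------------------------------------------------
# libraries


def make_library(out_dir: Path, n: int = 50, cfg: FixtureConfig | None = None,
                 with_coords: bool = True) -> list[TemplateRecord]:
    """Generate n synthetic templates and write the standard library layout."""
    cfg = cfg or FixtureConfig()
    records = []
    for k in range(n):
        ss = generate_structure(cfg, stream=1000 + k)
        coords = generate_backbone(ss, cfg, stream=1000 + k) if with_coords else None
        records.append(
            TemplateRecord(
                id=f"T{k:03d}", chains=(("A", ss.sequence),), ss=ss, coords=coords
            )
        )
    write_library(records, Path(out_dir))
    return records
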