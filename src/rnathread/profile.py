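"""Sequence profiles from multiple sequence alignments.

A query MSA is filtered on pairwise identity and coverage to the query; the
number of rows that survive is Neff, the effective sequence count.  When
Neff >= 5 a PSI-BLAST-style per-position log-odds profile F(i, k) is computed
and used downstream in place of plain RIBOSUM sequence scoring; shallower MSAs
fall back to sequence-sequence scoring.  Profiles are computed only for the
query — templates are always scored from their sequences.

The profile blends observed column frequencies with matrix-derived
pseudocounts:

    F(i,k) = log2[ (d(q_i) f(i,k) + 2 p(q_i) g(i,k)) / (p(q_i) (d(q_i)+2)) ]
    g(i,k) = sum_m 2^(tau * Rs(k,m)) f(i,m)

where q_i is the query nucleotide at position i, d(q_i) the number of
nucleotide types in column i different from q_i, f(i,k) the observed column
frequency, p the background probability, Rs the RIBOSUM single-nucleotide
matrix, and tau (default 0.4) the matrix temperature.  For a single-row MSA
the profile collapses to 0.4*Rs row-wise, so shallow MSAs reproduce RIBOSUM
scoring, while deep MSAs are dominated by the observed frequencies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

from .scoring import NUC_INDEX, NUCS, ScoringTables

__all__ = [
    "MSA",
    "SequenceProfile",
    "filter_msa",
    "compute_profile",
    "read_msa",
    "NEFF_THRESHOLD",
    "RIBOSUM_TEMPERATURE",
]

NEFF_THRESHOLD = 5  # below this, sequence profiles are not used
RIBOSUM_TEMPERATURE = 0.4  # tau in the pseudocount term 2^(tau*Rs)
GAP_CHARS = set("-.")


@dataclass(frozen=True)
class MSA:
    """Aligned rows over {A,C,G,U,N,-}; one row is the query."""

    rows: tuple[str, ...]
    query_row_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty MSA")
        rows = tuple(r.upper().replace(".", "-").replace("T", "U") for r in self.rows)
        object.__setattr__(self, "rows", rows)
        n = len(rows[0])
        if any(len(r) != n for r in rows):
            raise ValueError("MSA rows differ in length")
        if not (0 <= self.query_row_index < len(rows)):
            raise ValueError("query_row_index out of range")
        bad = set("".join(rows)) - set("ACGUN-")
        if bad:
            raise ValueError(f"invalid MSA characters: {sorted(bad)}")

    @property
    def query_row(self) -> str:
        return self.rows[self.query_row_index]

    @property
    def query(self) -> str:
        return self.query_row.replace("-", "")

    @property
    def depth(self) -> int:
        return len(self.rows)


def _identity_and_coverage(query_row: str, row: str) -> tuple[float, float]:
    """Pairwise identity and coverage of one row against the query row.

    Identity: identical residues over columns where both are non-gap.
    Coverage: columns where both are non-gap, over the query length.
    """
    both = matches = 0
    qlen = 0
    for q, r in zip(query_row, row):
        if q == "-":
            continue
        qlen += 1
        if r == "-":
            continue
        both += 1
        if q == r:
            matches += 1
    identity = matches / both if both else 0.0
    coverage = both / qlen if qlen else 0.0
    return identity, coverage


def filter_msa(msa: MSA, max_identity: float = 0.8, min_coverage: float = 0.75) -> MSA:
    """Drop rows sharing > max_identity identity or < min_coverage coverage
    with the query.  The query row always survives; row order is preserved."""
    qrow = msa.query_row
    kept: list[str] = []
    new_query_index = 0
    for idx, row in enumerate(msa.rows):
        if idx == msa.query_row_index:
            new_query_index = len(kept)
            kept.append(row)
            continue
        identity, coverage = _identity_and_coverage(qrow, row)
        if identity <= max_identity and coverage >= min_coverage:
            kept.append(row)
    return MSA(rows=tuple(kept), query_row_index=new_query_index)


@dataclass(frozen=True)
class SequenceProfile:
    """Per-query-position log-odds profile F(i, k), k over ACGU."""

    F: np.ndarray  # (query_length, 4)
    neff: int
    gap_ratio: np.ndarray  # (query_length,)

    def __post_init__(self) -> None:
        if self.F.ndim != 2 or self.F.shape[1] != 4:
            raise ValueError("F must be (L, 4)")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("profile contains non-finite entries")
        if self.gap_ratio.shape != (self.F.shape[0],):
            raise ValueError("gap_ratio length mismatch")
        if np.any(self.gap_ratio < 0) or np.any(self.gap_ratio > 1):
            raise ValueError("gap ratios must lie in [0, 1]")

    @property
    def use_profile(self) -> bool:
        return self.neff >= NEFF_THRESHOLD

    def score(self, i: int, t: str, tables: ScoringTables) -> float:
        """F(i, t) for a template symbol t at 1-based query position i."""
        return float(self.F[i - 1] @ tables.nuc_dist(t))


def compute_profile(
    msa: MSA,
    tables: ScoringTables,
    temperature: float = RIBOSUM_TEMPERATURE,
) -> SequenceProfile:
    """Build the sequence profile from an (already filtered) MSA.

    Columns are the query's non-gap columns.  'N' contributes no counts;
    all-gap (or all-N) columns fall back to the scaled RIBOSUM row of the
    query nucleotide.
    """
    if msa.depth < 1:
        raise ValueError("MSA must contain at least one row")
    qrow = msa.query_row
    qcols = [c for c, ch in enumerate(qrow) if ch != "-"]
    L = len(qcols)
    F = np.zeros((L, 4))
    gap_ratio = np.zeros(L)
    p = np.array([tables.background[k] for k in NUCS])
    pseudo = 2.0 ** (temperature * tables.Rs)  # pseudo[k, m]

    for i, col in enumerate(qcols):
        q = qrow[col]
        qi = NUC_INDEX.get(q)
        column = [row[col] for row in msa.rows]
        gap_ratio[i] = sum(1 for ch in column if ch == "-") / msa.depth
        counts = np.zeros(4)
        for ch in column:
            if ch in NUC_INDEX:
                counts[NUC_INDEX[ch]] += 1
        if qi is None:
            # query N: background-expected RIBOSUM row
            F[i] = temperature * (tables.Rs @ p)
            continue
        total = counts.sum()
        if total == 0:
            F[i] = temperature * tables.Rs[qi]
            continue
        f = counts / total
        d = int(sum(1 for k in range(4) if counts[k] > 0 and k != qi))
        g = pseudo @ f  # g[k] = sum_m 2^(tau Rs(k,m)) f(m)
        F[i] = np.log2((d * f + 2.0 * p[qi] * g) / (p[qi] * (d + 2.0)))
    return SequenceProfile(F=F, neff=msa.depth, gap_ratio=gap_ratio)


def read_msa(text: str, format: str = "fasta", query_id: str | None = None) -> MSA:
    """Read an aligned FASTA or Stockholm MSA from text.

    The query is the first row unless *query_id* names another record.
    """
    fmt = {"fasta": "fasta", "stockholm": "stockholm"}[format]
    aln = AlignIO.read(io.StringIO(text), fmt)
    rows = tuple(str(rec.seq) for rec in aln)
    qidx = 0
    if query_id is not None:
        ids = [rec.id for rec in aln]
        if query_id not in ids:
            raise ValueError(f"query id {query_id!r} not in alignment")
        qidx = ids.index(query_id)
    return MSA(rows=rows, query_row_index=qidx)
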