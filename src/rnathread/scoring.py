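"""RIBOSUM scoring tables and nucleotide scoring helpers.

Bundles the RIBOSUM85-60 single-nucleotide (4x4) and base-pair (16x16)
log-odds matrices together with background nucleotide probabilities.  An 'N'
(unknown nucleotide) is scored as the background-expected average over the
four nucleotides; the chain separator '&' can never be matched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["ScoringTables", "load_scoring_tables", "NEG_INF"]

NUCS = "ACGU"
NUC_INDEX = {c: i for i, c in enumerate(NUCS)}
NEG_INF = -1e9  # effective -infinity for forbidden matches

_BUNDLED = {"RIBOSUM85-60": "ribosum85_60.json"}


@dataclass(frozen=True)
class ScoringTables:
    """Single-nucleotide matrix Rs (4x4), pair matrix Rp (16x16), background."""

    name: str
    Rs: np.ndarray
    Rp: np.ndarray
    background: dict[str, float]

    def __post_init__(self) -> None:
        if self.Rs.shape != (4, 4) or not np.allclose(self.Rs, self.Rs.T):
            raise ValueError("Rs must be a symmetric 4x4 matrix")
        if self.Rp.shape != (16, 16) or not np.allclose(self.Rp, self.Rp.T):
            raise ValueError("Rp must be a symmetric 16x16 matrix")
        if abs(sum(self.background.values()) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")

    # -- scoring helpers ----------------------------------------------------

    def nuc_dist(self, c: str) -> np.ndarray:
        """Probability vector over ACGU for one symbol (N -> background)."""
        if c in NUC_INDEX:
            v = np.zeros(4)
            v[NUC_INDEX[c]] = 1.0
            return v
        if c == "N":
            return np.array([self.background[k] for k in NUCS])
        raise KeyError(f"cannot score symbol {c!r}")

    def single(self, a: str, b: str) -> float:
        """Rs score of two nucleotides; N averaged over the background."""
        if a == "&" or b == "&":
            return NEG_INF
        return float(self.nuc_dist(a) @ self.Rs @ self.nuc_dist(b))

    def pair(self, qpair: str, tpair: str) -> float:
        """Rp score of two base pairs given as 2-character strings."""
        if "&" in qpair or "&" in tpair:
            return NEG_INF
        wq = np.outer(self.nuc_dist(qpair[0]), self.nuc_dist(qpair[1])).ravel()
        wt = np.outer(self.nuc_dist(tpair[0]), self.nuc_dist(tpair[1])).ravel()
        return float(wq @ self.Rp @ wt)

    def pair_index(self, pair: str) -> int:
        return 4 * NUC_INDEX[pair[0]] + NUC_INDEX[pair[1]]


def load_scoring_tables(name: str = "RIBOSUM85-60") -> ScoringTables:
    """Load a bundled RIBOSUM matrix set by name."""
    if name not in _BUNDLED:
        raise KeyError(
            f"unknown scoring table {name!r}; bundled sets: {sorted(_BUNDLED)}"
        )
    raw = json.loads(
        resources.files("rnathread.data").joinpath(_BUNDLED[name]).read_text()
    )
    Rs = np.array(raw["Rs"], dtype=float)
    order = raw["pair_order"]
    idx = {p: i for i, p in enumerate(order)}
    Rp = np.zeros((16, 16))
    for a, row in raw["Rp_upper"].items():
        for b, v in row.items():
            Rp[idx[a], idx[b]] = v
            Rp[idx[b], idx[a]] = v
    return ScoringTables(
        name=raw["name"], Rs=Rs, Rp=Rp, background=dict(raw["background"])
    )
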