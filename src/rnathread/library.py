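"""Template library: per-template records and multi-chain merging.

Templates come in two flavours: single chains, and concatenations of chains
that pair with each other.  Two chains A and B are merged (both orders, A_B
and B_A) when the number of inter-chain base pairs strictly exceeds 20% of
the length of either chain; a chain pairing with several partners may pull in
one extra chain — the one sharing the most base pairs — for a maximum of
three chains per template.  Concatenated sequences carry a '&' separator
between chains; the separator never pairs and never aligns.

On disk a library is a directory of plain-text per-template records (FASTA +
BPSEQ + optional PDB + JSON sidecar) plus a TSV manifest — diffable and
VCS-friendly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .secstruct import (
    SecondaryStructure,
    StructureError,
    parse_structure,
    write_structure,
)

__all__ = [
    "TemplateRecord",
    "merge_chains",
    "build_library",
    "load_library",
    "save_record",
    "load_record",
    "MERGE_THRESHOLD",
    "MAX_CHAINS",
]

logger = logging.getLogger(__name__)

MERGE_THRESHOLD = 0.2  # inter-chain pairs must strictly exceed this fraction
MAX_CHAINS = 3
SEPARATOR = "&"


@dataclass(frozen=True)
class TemplateRecord:
    """One library template: chains, concatenated structure, optional coordinates."""

    id: str
    chains: tuple[tuple[str, str], ...]  # (chain_id, sequence)
    ss: SecondaryStructure  # over the '&'-joined concatenation
    coords: dict[int, dict[str, tuple[float, float, float]]] | None = None

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("template must have at least one chain")
        if len(self.chains) > MAX_CHAINS:
            raise ValueError(f"template {self.id} has more than {MAX_CHAINS} chains")
        expected = SEPARATOR.join(seq for _, seq in self.chains).upper()
        if self.ss.sequence != expected:
            raise ValueError(
                f"template {self.id}: structure sequence does not match chains"
            )
        if self.coords:
            n = self.ss.length
            for res in self.coords:
                if not (1 <= res <= n):
                    raise ValueError(f"coordinate residue {res} out of range")

    @property
    def sequence(self) -> str:
        return self.ss.sequence

    @property
    def n_pairs(self) -> int:
        return len(self.ss.pairs)


# ---------------------------------------------------------------------------
# chain merging


def merge_chains(
    chains: list[tuple[str, str]],
    inter_chain_pairs: dict[tuple[str, str], int],
) -> list[tuple[str, ...]]:
    """Decide the chain compositions of the library records.

    Returns a deterministic list of chain-id tuples: one single-chain entry
    per chain, then merged entries.  A pair of chains is merged in both orders
    when their inter-chain base-pair count strictly exceeds 20% of either
    chain's length; a merged pair whose first chain pairs above threshold with
    several chains gains the partner with the largest pair count as a third
    chain (ties broken by chain id).
    """
    ids = [cid for cid, _ in chains]
    length = {cid: len(seq) for cid, seq in chains}
    counts: dict[tuple[str, str], int] = {}
    for (a, b), n in inter_chain_pairs.items():
        key = (min(a, b), max(a, b))
        if counts.get(key, n) != n:
            raise ValueError(f"asymmetric pair counts for chains {a},{b}")
        counts[key] = n

    def npairs(a: str, b: str) -> int:
        return counts.get((min(a, b), max(a, b)), 0)

    def above(a: str, b: str) -> bool:
        n = npairs(a, b)
        return n > MERGE_THRESHOLD * length[a] or n > MERGE_THRESHOLD * length[b]

    out: list[tuple[str, ...]] = [(cid,) for cid in ids]
    for a in ids:
        for b in ids:
            if a == b or not above(a, b):
                continue
            combo = [a, b]
            # third chain: among the remaining partners of a or b above
            # threshold, the one sharing the largest number of base pairs
            partners = [
                (max(npairs(a, c), npairs(b, c)), c)
                for c in ids
                if c not in (a, b) and (above(a, c) or above(b, c))
            ]
            if partners:
                partners.sort(key=lambda t: (-t[0], t[1]))
                combo.append(partners[0][1])
            out.append(tuple(combo[:MAX_CHAINS]))
    return out


# ---------------------------------------------------------------------------
# on-disk records


def save_record(record: TemplateRecord, directory: Path) -> None:
    """Write one template as FASTA + BPSEQ (+ PDB) + JSON sidecar."""
    d = Path(directory) / record.id
    d.mkdir(parents=True, exist_ok=True)
    (d / "sequence.fasta").write_text(f">{record.id}\n{record.sequence}\n")
    (d / "structure.bpseq").write_text(write_structure(record.ss, "bpseq"))
    sidecar = {
        "id": record.id,
        "chains": [list(c) for c in record.chains],
        "has_coords": record.coords is not None,
    }
    (d / "record.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    if record.coords is not None:
        (d / "backbone.pdb").write_text(_coords_to_pdb(record))


def _coords_to_pdb(record: TemplateRecord) -> str:
    lines = []
    serial = 1
    seq = record.sequence
    for res in sorted(record.coords):
        base = seq[res - 1]
        for atom, (x, y, z) in sorted(record.coords[res].items()):
            name = atom if len(atom) == 4 else f" {atom:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name} {base:>3s} A{res:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def load_record(directory: Path) -> TemplateRecord:
    """Read one template record directory written by :func:`save_record`."""
    d = Path(directory)
    sidecar = json.loads((d / "record.json").read_text())
    fasta = (d / "sequence.fasta").read_text().splitlines()
    seq = "".join(ln.strip() for ln in fasta if not ln.startswith(">"))
    ss = parse_structure((d / "structure.bpseq").read_text(), "bpseq")
    if ss.sequence != seq.upper():
        raise StructureError(f"record {sidecar['id']}: FASTA/BPSEQ sequence mismatch")
    coords = None
    pdb = d / "backbone.pdb"
    if pdb.exists():
        from .evaluate import read_pdb_coords

        coords = read_pdb_coords(pdb.read_text())
    return TemplateRecord(
        id=sidecar["id"],
        chains=tuple((c[0], c[1]) for c in sidecar["chains"]),
        ss=ss,
        coords=coords,
    )


def build_library(input_dir: Path, output_dir: Path) -> list[dict]:
    """Build a library from a directory of per-structure inputs.

    Each subdirectory (or the directory itself, if it directly holds the
    files) must contain ``sequence.fasta`` and ``structure.bpseq`` or
    ``structure.ct`` (optionally ``backbone.pdb`` and ``record.json``).
    Malformed records are logged and skipped.  Returns the manifest and
    writes it as ``manifest.tsv``.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    entries = sorted(p for p in input_dir.iterdir() if p.is_dir())
    manifest: list[dict] = []
    skipped = 0
    if not entries:
        logger.warning("no template records found in %s", input_dir)
    for entry in entries:
        try:
            record = _read_input_record(entry)
            save_record(record, output_dir)
            manifest.append(
                {
                    "id": record.id,
                    "length": record.ss.length,
                    "n_pairs": record.n_pairs,
                    "n_chains": len(record.chains),
                    "has_coords": record.coords is not None,
                }
            )
        except (StructureError, ValueError, OSError, KeyError, json.JSONDecodeError) as exc:
            logger.warning("skipping record %s: %s", entry.name, exc)
            skipped += 1
    if entries and not manifest:
        raise RuntimeError(f"all {skipped} records in {input_dir} were malformed")
    _write_manifest(manifest, output_dir / "manifest.tsv")
    return manifest


def _read_input_record(entry: Path) -> TemplateRecord:
    fasta = (entry / "sequence.fasta").read_text().splitlines()
    seq = "".join(ln.strip() for ln in fasta if not ln.startswith(">")).upper()
    if (entry / "structure.bpseq").exists():
        ss = parse_structure((entry / "structure.bpseq").read_text(), "bpseq")
    elif (entry / "structure.ct").exists():
        ss = parse_structure((entry / "structure.ct").read_text(), "ct")
    else:
        raise StructureError("no structure.bpseq or structure.ct")
    if ss.sequence != seq:
        raise StructureError("FASTA/structure sequence mismatch")
    chains: tuple[tuple[str, str], ...]
    if (entry / "record.json").exists():
        sidecar = json.loads((entry / "record.json").read_text())
        chains = tuple((c[0], c[1]) for c in sidecar["chains"])
    else:
        chains = tuple(
            (chr(ord("A") + k), part) for k, part in enumerate(seq.split(SEPARATOR))
        )
    coords = None
    if (entry / "backbone.pdb").exists():
        from .evaluate import read_pdb_coords

        coords = read_pdb_coords((entry / "backbone.pdb").read_text())
    return TemplateRecord(id=entry.name, chains=chains, ss=ss, coords=coords)


def _write_manifest(manifest: list[dict], path: Path) -> None:
    cols = ["id", "length", "n_pairs", "n_chains", "has_coords"]
    lines = ["\t".join(cols)]
    for row in manifest:
        lines.append("\t".join(str(row[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n")


def write_library(records: list[TemplateRecord], directory: Path) -> list[dict]:
    """Write records plus manifest in the standard library layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for record in records:
        save_record(record, directory)
        manifest.append(
            {
                "id": record.id,
                "length": record.ss.length,
                "n_pairs": record.n_pairs,
                "n_chains": len(record.chains),
                "has_coords": record.coords is not None,
            }
        )
    _write_manifest(manifest, directory / "manifest.tsv")
    return manifest


def load_library(directory: Path) -> list[TemplateRecord]:
    """Load every record listed in a library directory's manifest."""
    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    if manifest.exists():
        ids = [ln.split("\t")[0] for ln in manifest.read_text().splitlines()[1:]]
    else:
        ids = sorted(p.name for p in directory.iterdir() if p.is_dir())
    return [load_record(directory / tid) for tid in ids]
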