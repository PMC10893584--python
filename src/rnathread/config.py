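"""Tunable scoring constants, overridable from a YAML file."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import yaml

__all__ = ["ScoringConfig", "DEFAULT_CONFIG", "load_config"]


@dataclass(frozen=True)
class ScoringConfig:
    """All scoring constants of the threading pipeline.

    pair_bonus: added in the final alignment for nucleotide pairs already
        matched by the substructure stage.
    env_stem_bonus / env_other_bonus: environment-similarity bonus when the
        two base pairs' environment tuples are equal and both (stem, stem),
        or equal otherwise; differing tuples score 0.
    temperature: exponent scale on the RIBOSUM matrix in profile pseudocounts.
    profile_half_factor: weight of each half's profile score when scoring a
        base pair against a pair of template nucleotides.
    gap_open / gap_extend: affine gap penalties (first gapped position costs
        gap_open, each further position gap_extend).
    min_gap_scale: floor of the MSA-derived per-column gap-penalty scaling.
    neff_threshold: minimum effective sequence count for using profiles.
    """

    pair_bonus: float = 5.0
    env_stem_bonus: float = 1.0
    env_other_bonus: float = 3.0
    temperature: float = 0.4
    profile_half_factor: float = 0.5
    gap_open: float = 3.0
    gap_extend: float = 1.0
    min_gap_scale: float = 0.1
    neff_threshold: int = 5


DEFAULT_CONFIG = ScoringConfig()


def load_config(path: str | Path) -> ScoringConfig:
    """Read a YAML mapping of config fields; unset fields keep defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - set(ScoringConfig.__dataclass_fields__)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    return replace(DEFAULT_CONFIG, **data)
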