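"""Pipeline run configuration.

All tunables of the analysis pipeline live in a single flat
:class:`PipelineConfig` that serializes losslessly to a ``key=value`` text
file, so that a run can be reproduced from its manifest alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import List

#: Conserved 5' nucleotide anchor immediately upstream of the VNAR insert
#: (primer-derived; amplicons are frame-anchored at its 3' end).
DEFAULT_FLANK5 = "GCCATGGCTGCTCGAGTGGACCAAACACCGCGTGACTGTGAATGGCCCGGGAGGCCA"

#: Conserved 3' anchor downstream of the insert. Synthetic default used by
#: the repertoire generator; real amplicon designs should override it.
DEFAULT_FLANK3 = "GGTGGAGGCGGTTCAGGCGGA"


class ConfigError(ValueError):
    """Raised for invalid or non-round-trippable configuration."""


@dataclass
class PipelineConfig:
    """Parameters for the repertoire-mining pipeline.

    Thresholds follow the mining protocol: clonotypes/clades are formed at
    >85% CDR3 identity, clonotype member searches run at >90%, differential
    mining pools the top 2000 most prevalent records per library and keeps
    target-unique clades with at least 30 unique sequences, at CDR3 lengths
    14 and 12 by default.
    """

    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    max_flank_mismatches: int = 0
    min_overlap_nt: int = 15
    max_overlap_mismatch_frac: float = 0.25
    min_phred: int = 20
    min_protein_len_aa: int = 80
    max_protein_len_aa: int = 220
    clonotype_identity_threshold: float = 85.0
    member_search_identity_threshold: float = 90.0
    top_n_prevalent: int = 2000
    min_clade_unique_sequences: int = 30
    cdr3_lengths_to_mine: List[int] = field(default_factory=lambda: [14, 12])
    rng_seed: int = 2025

    def __post_init__(self) -> None:
        if not self.flank5:
            raise ConfigError("flank5 must be non-empty")
        if self.max_flank_mismatches < 0:
            raise ConfigError("max_flank_mismatches must be >= 0")
        if self.min_overlap_nt < 1:
            raise ConfigError("min_overlap_nt must be >= 1")
        if not 0.0 <= self.max_overlap_mismatch_frac <= 1.0:
            raise ConfigError("max_overlap_mismatch_frac must be in [0, 1]")
        if self.min_protein_len_aa >= self.max_protein_len_aa:
            raise ConfigError("min_protein_len_aa must be < max_protein_len_aa")
        if not 0.0 < self.clonotype_identity_threshold <= 100.0:
            raise ConfigError("clonotype_identity_threshold must be in (0, 100]")
        if not 0.0 < self.member_search_identity_threshold <= 100.0:
            raise ConfigError("member_search_identity_threshold must be in (0, 100]")
        if self.top_n_prevalent < 1:
            raise ConfigError("top_n_prevalent must be >= 1")
        if self.min_clade_unique_sequences < 1:
            raise ConfigError("min_clade_unique_sequences must be >= 1")

    # -- flat key=value serialization ------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, list):
                value = ",".join(str(v) for v in value)
            lines.append(f"{f.name}={value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        kwargs: dict[str, object] = {}
        known = {f.name: f for f in fields(cls)}
        for key, value in raw.items():
            if key not in known:
                raise ConfigError(f"unknown configuration key {key!r}")
            kwargs[key] = _parse_field(key, value)
        return cls(**kwargs)


def _parse_field(name: str, value: str):
    if name in ("flank5", "flank3"):
        return value
    if name == "cdr3_lengths_to_mine":
        return [int(v) for v in value.split(",") if v != ""]
    if name in ("max_overlap_mismatch_frac", "clonotype_identity_threshold",
                "member_search_identity_threshold"):
        return float(value)
    return int(value)
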