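"""Correlation analyses linking NGS prevalence to hit frequency and affinity.

Clonal expansion in an immunized library should surface as agreement
between a clone's NGS read count, how often it recurs among Sanger-
sequenced biopanning hits, and its measured affinity. These helpers
compute the Pearson correlations behind those comparisons; because the
appropriate axis scaling is a judgment call, all raw/log variants are
emitted rather than a single number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps


@dataclass
class AffinityRecord:
    clone_id: str
    kd: float  # dissociation constant, molar
    ngs_repeats: int
    sanger_repeats: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if self.ngs_repeats < 0:
            raise ValueError("ngs_repeats must be >= 0")


def pearson_r2(x: Sequence[float], y: Sequence[float],
               log_x: bool = False, log_y: bool = False) -> Tuple[float, float]:
    """Pearson r and r^2 on optionally log10-transformed values."""
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if log_x:
        if np.any(xa <= 0):
            raise ValueError("log_x requires strictly positive x")
        xa = np.log10(xa)
    if log_y:
        if np.any(ya <= 0):
            raise ValueError("log_y requires strictly positive y")
        ya = np.log10(ya)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance")
    r = float(sps.pearsonr(xa, ya).statistic)
    return r, r * r


def prevalence_affinity_table(records: List[AffinityRecord]) -> Dict[str, object]:
    """Paired (ngs_repeats, kd) analysis with all axis-transform variants.

    The primary variant is raw repeats against log10(kd); raw-raw and
    log-log are reported alongside.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    repeats = [float(r.ngs_repeats) for r in records]
    kds = [r.kd for r in records]
    table = [(r.clone_id, r.ngs_repeats, r.kd) for r in records]
    out: Dict[str, object] = {"pairs": table}
    for name, lx, ly in (("raw_vs_logkd", False, True),
                         ("raw_vs_raw", False, False),
                         ("log_vs_logkd", True, True)):
        try:
            r, r2 = pearson_r2(repeats, kds, log_x=lx, log_y=ly)
            out[name] = {"r": r, "r_squared": r2}
        except ValueError as exc:
            out[name] = {"error": str(exc)}
    out["primary_r_squared"] = (
        out["raw_vs_logkd"]["r_squared"]  # type: ignore[index]
        if "r_squared" in out["raw_vs_logkd"] else math.nan  # type: ignore[operator]
    )
    return out


def sanger_vs_ngs_r2(records: List[AffinityRecord]) -> Tuple[float, float]:
    """Pearson r, r^2 of Sanger hit repeats against NGS repeats."""
    usable = [r for r in records if r.sanger_repeats is not None]
    if len(usable) < 3:
        raise ValueError("need at least 3 records with sanger_repeats")
    return pearson_r2([float(r.sanger_repeats) for r in usable],
                      [float(r.ngs_repeats) for r in usable])
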