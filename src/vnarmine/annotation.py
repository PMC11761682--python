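"""VNAR region delineation, cysteine profiling, and subtype classification.

A VNAR domain is tiled, N- to C-terminal, as
FR1 / CDR1 / FR2 / HV2 / FR3a / HV4 / FR3b / CDR3 / FR4.
VNARs lack a CDR2; the two hypervariable loops HV2 and HV4 supplement CDR1
and CDR3. Annotation is anchor-based rather than fixed-position, because
CDR length variation (CDR3s here run from a few to >80 residues) shifts
absolute coordinates:

* canonical Cys1  = first cysteine inside a fixed FR1 window,
* FR4             = rightmost occurrence of a conserved FR4 start motif,
* canonical Cys2  = the cysteine of the last ``YYC`` context motif before
  FR4 (the Tyr-Tyr context keeps CDR3 cysteines from being mistaken for
  the framework cysteine),
* CDR3            = the open interval between Cys2 and FR4,
* CDR1 and the inner framework blocks follow Cys1 at fixed offsets.

Subtypes I-IV are determined by non-canonical cysteine placement: Type I
cross-links CDR3 to FR2/FR4 via paired CDR3 cysteines; Types II/III have a
CDR1-CDR3 disulfide (III additionally shows CDR1 sequence conservation);
Type IV has only the canonical pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .repertoire import RepertoireTable

REGION_NAMES = ["FR1", "CDR1", "FR2", "HV2", "FR3a", "HV4", "FR3b", "CDR3", "FR4"]

#: First cysteine inside this protein-coordinate window anchors FR1.
CYS1_WINDOW: Tuple[int, int] = (15, 30)

#: Fixed region lengths between the Cys1 anchor and FR3b.
CDR1_LEN = 6
FR2_LEN = 8
HV2_LEN = 6
FR3A_LEN = 10
HV4_LEN = 5

#: Context motif whose final residue is canonical Cys2.
CYS2_CONTEXT = "YYC"

#: Conserved FR4 start motif (matched rightmost with <=1 mismatch).
FR4_MOTIF = "DGAGT"
FR4_MOTIF_MAX_MISMATCHES = 1

#: Default CDR1 conservation motif separating Type III from Type II.
CDR1_CONSERVED_MOTIF = "W"


@dataclass
class RegionAnnotation:
    """Per-region intervals (0-based half-open, protein coordinates)."""

    intervals: Dict[str, Tuple[int, int]]
    canonical_cys1: int
    canonical_cys2: int

    def region_of(self, pos: int) -> Optional[str]:
        for name, (start, end) in self.intervals.items():
            if start <= pos < end:
                return name
        return None

    @property
    def cdr3(self) -> Tuple[int, int]:
        return self.intervals["CDR3"]

    @property
    def cdr1(self) -> Tuple[int, int]:
        return self.intervals["CDR1"]


@dataclass
class Unannotatable:
    reason: str  # no_canonical_cys1 | no_fr4 | no_canonical_cys2 | bad_architecture


@dataclass
class CysteineProfile:
    positions: List[int]
    counts_by_region: Dict[str, int]
    noncanonical_by_region: Dict[str, int]
    n_total: int
    has_canonical_pair: bool
    cdr1_has_conserved_motif: bool


@dataclass
class SubtypeCall:
    subtype: str  # I | II | III | IV | unclassified
    rationale_flags: frozenset


@dataclass
class Cdr3LengthStats:
    lengths_by_subtype: Dict[str, List[int]]
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: List[Tuple[str, int]]  # (record id, length)


def _rfind_approx(seq: str, motif: str, max_mm: int) -> int:
    """Rightmost occurrence of motif with <= max_mm Hamming mismatches."""
    lm = len(motif)
    for pos in range(len(seq) - lm, -1, -1):
        mm = 0
        for i in range(lm):
            if seq[pos + i] != motif[i]:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            return pos
    return -1


def annotate_regions(protein: str) -> RegionAnnotation | Unannotatable:
    """Delineate all nine regions of a VNAR protein, or say why not."""
    lo, hi = CYS1_WINDOW
    cys1 = protein.find("C", lo, hi)
    if cys1 < 0:
        return Unannotatable("no_canonical_cys1")
    fr4_start = _rfind_approx(protein, FR4_MOTIF, FR4_MOTIF_MAX_MISMATCHES)
    if fr4_start < 0 or fr4_start <= cys1:
        return Unannotatable("no_fr4")
    ctx = protein.rfind(CYS2_CONTEXT, cys1 + 1, fr4_start)
    if ctx < 0:
        return Unannotatable("no_canonical_cys2")
    cys2 = ctx + len(CYS2_CONTEXT) - 1
    fr3b_start = cys1 + 1 + CDR1_LEN + FR2_LEN + HV2_LEN + FR3A_LEN + HV4_LEN
    if fr3b_start > cys2 or cys2 + 1 >= fr4_start:
        return Unannotatable("bad_architecture")
    bounds = [0, cys1 + 1]
    for length in (CDR1_LEN, FR2_LEN, HV2_LEN, FR3A_LEN, HV4_LEN):
        bounds.append(bounds[-1] + length)
    bounds += [cys2 + 1, fr4_start, len(protein)]
    intervals = {name: (bounds[i], bounds[i + 1]) for i, name in enumerate(REGION_NAMES)}
    return RegionAnnotation(intervals=intervals, canonical_cys1=cys1, canonical_cys2=cys2)


def cysteine_profile(protein: str, regions: RegionAnnotation) -> CysteineProfile:
    """Bucket every cysteine into its region; flag the canonical pair."""
    positions = [i for i, aa in enumerate(protein) if aa == "C"]
    counts = {name: 0 for name in REGION_NAMES}
    noncanon = {name: 0 for name in REGION_NAMES}
    canonical = {regions.canonical_cys1, regions.canonical_cys2}
    for pos in positions:
        region = regions.region_of(pos)
        if region is None:  # cannot happen for a valid annotation
            continue
        counts[region] += 1
        if pos not in canonical:
            noncanon[region] += 1
    has_pair = (protein[regions.canonical_cys1] == "C"
                and protein[regions.canonical_cys2] == "C")
    c1s, c1e = regions.cdr1
    return CysteineProfile(
        positions=positions,
        counts_by_region=counts,
        noncanonical_by_region=noncanon,
        n_total=len(positions),
        has_canonical_pair=has_pair,
        cdr1_has_conserved_motif=CDR1_CONSERVED_MOTIF in protein[c1s:c1e],
    )


def classify_subtype(profile: CysteineProfile) -> SubtypeCall:
    """Apply the subtype rule table to a cysteine profile.

    Type I:  FR2 >=1 and FR4 >=1 non-canonical Cys, CDR3 Cys >=2 and even
             (paired CDR3 cysteines cross-linking to the frameworks).
    Type II: CDR1 >=1 and CDR3 >=1, FR2 == FR4 == 0, CDR1 motif absent.
    Type III: as Type II with the CDR1 conservation motif present.
    Type IV: no non-canonical cysteines anywhere.
    Anything else (including odd CDR3 counts with FR2/FR4 cysteines, or a
    missing canonical pair) is ``unclassified``.
    """
    flags = set()
    nc = profile.noncanonical_by_region
    if nc["FR2"] >= 1:
        flags.add("fr2_cys")
    if nc["FR4"] >= 1:
        flags.add("fr4_cys")
    if nc["CDR1"] >= 1:
        flags.add("cdr1_cys")
    flags.add(f"cdr3_cys_count={nc['CDR3']}")
    if profile.cdr1_has_conserved_motif:
        flags.add("cdr1_conserved_motif")
    frozen = frozenset(flags)

    if not profile.has_canonical_pair:
        return SubtypeCall("unclassified", frozen)
    n_noncanon = sum(nc.values())
    if n_noncanon == 0:
        return SubtypeCall("IV", frozen)
    if nc["FR2"] >= 1 and nc["FR4"] >= 1 and nc["CDR3"] >= 2 and nc["CDR3"] % 2 == 0:
        return SubtypeCall("I", frozen)
    if (nc["CDR1"] >= 1 and nc["CDR3"] >= 1 and nc["FR2"] == 0 and nc["FR4"] == 0):
        subtype = "III" if profile.cdr1_has_conserved_motif else "II"
        return SubtypeCall(subtype, frozen)
    return SubtypeCall("unclassified", frozen)


def annotate_record(protein: str) -> Tuple[Optional[str], str]:
    """Convenience: (CDR3 sequence or None, subtype label) for one protein."""
    regions = annotate_regions(protein)
    if isinstance(regions, Unannotatable):
        return None, "unclassified"
    start, end = regions.cdr3
    profile = cysteine_profile(protein, regions)
    return protein[start:end], classify_subtype(profile).subtype


def annotate_table(table: RepertoireTable) -> RepertoireTable:
    """Fill cdr3/subtype columns of a repertoire table in place."""
    for record in table.records:
        record.cdr3, record.subtype = annotate_record(record.sequence)
    return table


def _quartiles_type6(values: np.ndarray) -> Tuple[float, float, float]:
    """Q1/median/Q3 by linear interpolation of order statistics, h=(n+1)p."""
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="weibull")
    return float(q1), float(med), float(q3)


def cdr3_length_stats(table: RepertoireTable) -> Cdr3LengthStats:
    """Tukey box statistics of CDR3 lengths over annotated unique sequences.

    Whiskers are Q1 - 1.5 IQR and Q3 + 1.5 IQR, clamped to the most extreme
    observed lengths inside those fences; lengths beyond the fences are the
    outliers (e.g. the rare hyper-elongated CDR3 loops of >80 residues).
    """
    annotated = [r for r in table.records if r.cdr3]
    if not annotated:
        raise ValueError("no annotated records")
    lengths = np.array([len(r.cdr3) for r in annotated], dtype=float)
    q1, med, q3 = _quartiles_type6(lengths)
    iqr = q3 - q1
    fence_low, fence_high = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = lengths[(lengths >= fence_low) & (lengths <= fence_high)]
    whisker_low = float(inside.min()) if inside.size else q1
    whisker_high = float(inside.max()) if inside.size else q3
    outliers = [(r.record_id, len(r.cdr3)) for r in annotated
                if not fence_low <= len(r.cdr3) <= fence_high]
    by_subtype: Dict[str, List[int]] = {}
    for r in annotated:
        by_subtype.setdefault(r.subtype or "unclassified", []).append(len(r.cdr3))
    return Cdr3LengthStats(
        lengths_by_subtype=by_subtype,
        median=med, q1=q1, q3=q3,
        whisker_low=whisker_low, whisker_high=whisker_high,
        outliers=outliers,
    )
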