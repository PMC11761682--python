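"""Differential clade mining between a target and a control library.

The discovery step works on CDR3s of one fixed length: the top-N most
prevalent records of that length are taken from each library, pooled with
library labels, and single-linkage clustered at the clonotype identity
threshold. Clades with no control-library member are "target-unique";
those with at least K unique sequences become candidates, each represented
by its most prevalent member's full-length sequence. This turns clonal
expansion in the immunized library into a ranked shortlist of putative
antigen-specific clones without any biopanning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .clonotyping import cluster_clonotypes
from .config import PipelineConfig
from .repertoire import RepertoireTable, VnarRecord

logger = logging.getLogger("vnarmine")


@dataclass
class CladeMember:
    record_id: str
    library_id: str
    count: int
    cdr3: str
    sequence: str


@dataclass
class Clade:
    clade_id: int
    cdr3_len: int
    members: List[CladeMember]
    n_unique_sequences: int
    n_target: int
    n_control: int
    is_target_unique: bool
    representative_id: str


@dataclass
class MiningReport:
    target_library: str
    control_library: str
    cdr3_len: int
    top_n: int
    identity_threshold: float
    min_clade_unique_sequences: int
    clades: List[Clade] = field(default_factory=list)
    candidates: List[Clade] = field(default_factory=list)
    candidate_representatives: Dict[str, str] = field(default_factory=dict)


def select_top_prevalent(table: RepertoireTable, cdr3_len: int,
                         n: int) -> List[VnarRecord]:
    """Top-n records whose CDR3 has the given length, by prevalence.

    Table order (count descending, sequence ascending) already encodes the
    deterministic tie-break; fewer than n matches returns them all with a
    warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    matching = [r for r in table.records if r.cdr3 and len(r.cdr3) == cdr3_len]
    if len(matching) < n:
        logger.warning(
            "library %s: only %d records with CDR3 length %d (requested top %d)",
            table.library_id, len(matching), cdr3_len, n)
    return matching[:n]


def mine_differential_clades(target: RepertoireTable, control: RepertoireTable,
                             config: PipelineConfig, cdr3_len: int) -> MiningReport:
    """Pool top-prevalence equal-length CDR3s and report target-unique clades."""
    top_target = select_top_prevalent(target, cdr3_len, config.top_n_prevalent)
    top_control = select_top_prevalent(control, cdr3_len, config.top_n_prevalent)
    if not top_target:
        raise ValueError(f"no CDR3s of length {cdr3_len} in library {target.library_id}")
    if not top_control:
        raise ValueError(f"no CDR3s of length {cdr3_len} in library {control.library_id}")

    pooled: List[CladeMember] = []
    for lib, records in ((target, top_target), (control, top_control)):
        for r in records:
            pooled.append(CladeMember(r.record_id, lib.library_id, r.count,
                                      r.cdr3 or "", r.sequence))
    cdr3s = [(m.record_id, m.cdr3) for m in pooled]
    counts = {m.record_id: m.count for m in pooled}
    clonotypes = cluster_clonotypes(cdr3s, config.clonotype_identity_threshold,
                                    counts=counts)
    by_id = {m.record_id: m for m in pooled}

    report = MiningReport(
        target_library=target.library_id,
        control_library=control.library_id,
        cdr3_len=cdr3_len,
        top_n=config.top_n_prevalent,
        identity_threshold=config.clonotype_identity_threshold,
        min_clade_unique_sequences=config.min_clade_unique_sequences,
    )
    for ct in clonotypes:
        members = [by_id[rid] for rid in ct.member_ids]
        n_target = sum(1 for m in members if m.library_id == target.library_id)
        n_control = len(members) - n_target
        n_unique = len({m.sequence for m in members})
        rep = min(members, key=lambda m: (-m.count, m.sequence, m.record_id))
        clade = Clade(
            clade_id=ct.cluster_id,
            cdr3_len=cdr3_len,
            members=members,
            n_unique_sequences=n_unique,
            n_target=n_target,
            n_control=n_control,
            is_target_unique=n_control == 0,
            representative_id=rep.record_id,
        )
        report.clades.append(clade)
        if clade.is_target_unique and n_unique >= config.min_clade_unique_sequences:
            report.candidates.append(clade)
            report.candidate_representatives[rep.record_id] = rep.sequence
    report.candidates = rank_candidates(report)
    return report


def rank_candidates(report: MiningReport) -> List[Clade]:
    """Candidates ordered by representative prevalence (ties lexicographic)."""
    by_id = {m.record_id: m for clade in report.clades for m in clade.members}

    def key(clade: Clade):
        rep = by_id[clade.representative_id]
        return (-rep.count, rep.sequence, rep.record_id)

    return sorted(report.candidates, key=key)
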