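"""Dereplicated, prevalence-ranked repertoire tables and library summaries.

Translated proteins are collapsed to unique sequences with read counts
("prevalence"), ranked by count descending with lexicographic tie-breaks so
that downstream "top N" selections are deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

from .reads import TranslatedVnar


@dataclass
class VnarRecord:
    """One unique full-length VNAR amino-acid sequence in a library."""

    sequence: str
    count: int
    rank: int
    library_id: str
    cdr3: Optional[str] = None
    subtype: Optional[str] = None

    @property
    def record_id(self) -> str:
        """Stable identifier derived from library and prevalence rank."""
        return f"{self.library_id}:{self.rank}"

    @property
    def cdr3_len(self) -> int:
        return len(self.cdr3) if self.cdr3 else 0


@dataclass
class RepertoireTable:
    library_id: str
    records: List[VnarRecord] = field(default_factory=list)
    total_reads: int = 0

    def validate(self) -> None:
        seqs = [r.sequence for r in self.records]
        if len(seqs) != len(set(seqs)):
            raise ValueError("duplicate sequences in repertoire table")
        if [r.rank for r in self.records] != list(range(1, len(self.records) + 1)):
            raise ValueError("ranks must be 1..n in table order")
        key = [(-r.count, r.sequence) for r in self.records]
        if key != sorted(key):
            raise ValueError("records not sorted by count desc, sequence asc")
        if sum(r.count for r in self.records) != self.total_reads:
            raise ValueError("counts do not sum to total_reads")

    @property
    def n_unique(self) -> int:
        return len(self.records)

    def sequences(self) -> set[str]:
        return {r.sequence for r in self.records}

    def by_id(self) -> Dict[str, VnarRecord]:
        return {r.record_id: r for r in self.records}


@dataclass
class AbundanceSummary:
    n_unique: int
    frac_lt_k_reads: float
    frac_singletons: float
    k: int


@dataclass
class LibraryOverlap:
    n_unique_a: int
    n_unique_b: int
    n_shared: int
    frac_shared_of_a: float
    frac_shared_of_b: float
    frac_shared_of_union: float  # Jaccard, reported alongside per-library


def table_from_counts(counts: Dict[str, int], library_id: str) -> RepertoireTable:
    """Build a ranked table from a {sequence: count} mapping."""
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    records = [
        VnarRecord(sequence=seq, count=cnt, rank=i + 1, library_id=library_id)
        for i, (seq, cnt) in enumerate(ordered)
    ]
    return RepertoireTable(library_id=library_id, records=records,
                           total_reads=sum(counts.values()))


def dereplicate(proteins: Iterable[TranslatedVnar], library_id: str) -> RepertoireTable:
    """Collapse identical proteins into unique records ranked by prevalence."""
    tally = Counter(p.protein for p in proteins)
    return table_from_counts(tally, library_id)


def abundance_summary(table: RepertoireTable, k: int = 10) -> AbundanceSummary:
    """Fractions of unique sequences seen fewer than ``k`` times / exactly once."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if table.n_unique == 0:
        raise ValueError("abundance summary undefined for an empty table")
    n_lt_k = sum(1 for r in table.records if r.count < k)
    n_single = sum(1 for r in table.records if r.count == 1)
    return AbundanceSummary(
        n_unique=table.n_unique,
        frac_lt_k_reads=n_lt_k / table.n_unique,
        frac_singletons=n_single / table.n_unique,
        k=k,
    )


def library_overlap(a: RepertoireTable, b: RepertoireTable) -> LibraryOverlap:
    """Sequence sharing between two dereplicated libraries.

    Per-library sharing fractions are the primary report; the Jaccard
    fraction over the union is emitted alongside.
    """
    sa, sb = a.sequences(), b.sequences()
    shared = len(sa & sb)
    union = len(sa | sb)
    return LibraryOverlap(
        n_unique_a=len(sa),
        n_unique_b=len(sb),
        n_shared=shared,
        frac_shared_of_a=shared / len(sa) if sa else 0.0,
        frac_shared_of_b=shared / len(sb) if sb else 0.0,
        frac_shared_of_union=shared / union if union else 0.0,
    )
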