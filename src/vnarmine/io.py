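"""Readers and writers for on-disk formats. No science here.

FASTQ is 4-line Phred+33 (gzip transparent by ``.gz`` suffix), tables are
UTF-8 TSV with a header row, trees are Newick with a canonical sibling
order. All intervals anywhere in the package are 0-based, half-open.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import IO, Iterator, List, Optional, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reads import ReadPair
from .repertoire import RepertoireTable, VnarRecord

logger = logging.getLogger("vnarmine")


class PairingError(ValueError):
    """Mate files disagree in record count or read identifiers."""


class FastqParseError(ValueError):
    """Malformed FASTQ record, with the offending file and line named."""


class TableIntegrityError(ValueError):
    """Repertoire table violates its invariants on read."""


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # fixed mtime so identical content gives identical bytes
            return gzip.open(path, mode, mtime=0)  # type: ignore[call-overload]
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _strip_mate_suffix(read_id: str) -> str:
    token = read_id.split()[0]
    if token.endswith("/1") or token.endswith("/2"):
        return token[:-2]
    return token


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    record_idx = 0
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                record_idx += 1
                yield title, seq, qual
        except ValueError as exc:
            raise FastqParseError(
                f"{path}: malformed FASTQ record near line {record_idx * 4 + 1}: {exc}"
            ) from exc


def read_fastq_pair(path_fwd: str | Path, path_rev: str | Path) -> Iterator[ReadPair]:
    """Stream positionally-paired reads from two FASTQ files.

    Record identifiers of a pair must match up to the ``/1``/``/2`` (or
    whitespace mate-field) suffix; unequal record counts raise
    :class:`PairingError`. Constant working state per record.
    """
    sentinel = object()
    n = 0
    for fwd, rev in zip_longest(_iter_fastq(path_fwd), _iter_fastq(path_rev),
                                fillvalue=sentinel):
        n += 1
        if fwd is sentinel or rev is sentinel:
            raise PairingError(
                f"unequal record counts: {path_fwd} vs {path_rev} (at record {n})"
            )
        ftitle, fseq, fqual = fwd  # type: ignore[misc]
        rtitle, rseq, rqual = rev  # type: ignore[misc]
        fid, rid = _strip_mate_suffix(ftitle), _strip_mate_suffix(rtitle)
        if fid != rid:
            raise PairingError(f"record {n}: mate ids differ: {fid!r} vs {rid!r}")
        yield ReadPair(fid, fseq, rseq, fqual, rqual)


def write_fastq(path: str | Path, records: Sequence[tuple[str, str, str]]) -> None:
    """Write (id, seq, qual) triples as 4-line FASTQ."""
    with _open_text(path, "wt") as handle:
        for rid, seq, qual in records:
            handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# repertoire tables
# ---------------------------------------------------------------------------

#: Fixed column order of the repertoire TSV.
TABLE_COLUMNS = ["sequence", "count", "rank", "cdr3", "cdr3_len", "subtype", "library"]


def write_repertoire_table(table: RepertoireTable, path: str | Path) -> None:
    rows = [
        {
            "sequence": r.sequence,
            "count": r.count,
            "rank": r.rank,
            "cdr3": r.cdr3 or "",
            "cdr3_len": len(r.cdr3) if r.cdr3 else 0,
            "subtype": r.subtype or "",
            "library": table.library_id,
        }
        for r in table.records
    ]
    frame = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_repertoire_table(path: str | Path) -> RepertoireTable:
    frame = pd.read_csv(path, sep="\t", dtype={"sequence": str, "cdr3": str,
                                               "subtype": str, "library": str},
                        keep_default_na=False)
    if list(frame.columns) != TABLE_COLUMNS:
        raise TableIntegrityError(f"{path}: unexpected columns {list(frame.columns)}")
    if frame["sequence"].duplicated().any():
        dup = frame.loc[frame["sequence"].duplicated(), "sequence"].iloc[0]
        raise TableIntegrityError(f"{path}: duplicate sequence row {dup[:30]!r}...")
    library_id = frame["library"].iloc[0] if len(frame) else ""
    records = [
        VnarRecord(
            sequence=row["sequence"],
            count=int(row["count"]),
            rank=int(row["rank"]),
            library_id=library_id,
            cdr3=row["cdr3"] or None,
            subtype=row["subtype"] or None,
        )
        for row in frame.to_dict("records")
    ]
    table = RepertoireTable(library_id=library_id, records=records,
                            total_reads=int(frame["count"].sum()) if len(frame) else 0)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# trees / Newick
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Rooted (possibly multifurcating) tree with labeled leaves.

    ``branch_length`` is the length of the edge above the node, in units of
    1 - identity. Internal nodes are unlabeled.
    """

    label: Optional[str] = None
    branch_length: Optional[float] = None
    children: List["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def _postorder(self) -> Iterator["TreeNode"]:
        # iterative: report trees can be caterpillar-deep
        stack: List[tuple["TreeNode", bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaf_labels(self) -> List[str]:
        return [n.label for n in self._postorder()
                if n.is_leaf() and n.label is not None]


def _fmt_bl(value: float) -> str:
    return f"{value:g}"


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick with canonical sibling ordering.

    Siblings are sorted by their lexicographically smallest descendant leaf
    label, so identical trees always serialize identically. Duplicate leaf
    labels are an error.
    """
    labels = tree.leaf_labels()
    if len(labels) != len(set(labels)):
        seen = set()
        dup = next(lab for lab in labels if lab in seen or seen.add(lab))
        raise ValueError(f"duplicate leaf label {dup!r}")
    rendered: dict[int, tuple[str, str]] = {}  # id(node) -> (newick, min label)
    for node in tree._postorder():
        if node.is_leaf():
            text, smallest = node.label or "", node.label or ""
        else:
            parts = sorted((rendered[id(c)] for c in node.children),
                           key=lambda rc: rc[1])
            text = "(" + ",".join(rc[0] for rc in parts) + ")"
            smallest = min(rc[1] for rc in parts)
        if node.branch_length is not None:
            text += f":{_fmt_bl(node.branch_length)}"
        rendered[id(node)] = (text, smallest)
    return rendered[id(tree)][0] + ";"
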