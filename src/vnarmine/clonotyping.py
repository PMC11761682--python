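"""CDR3 identity, clonotype clustering, member search, and report trees.

"Homology" throughout is percent identity. Equal-length CDR3s (the mining
path) use Hamming identity; unequal lengths fall back to a gap-tolerant
global alignment with unit match score and free gaps/mismatches — i.e. the
longest common subsequence — normalized by the longer sequence. Thresholds
are strict (identity must *exceed* the threshold), matching the >85% / >90%
clonotype definitions. Clonotypes are single-linkage connected components;
complete linkage is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import TreeNode
from .repertoire import RepertoireTable, VnarRecord


@dataclass
class Clonotype:
    cluster_id: int
    member_ids: List[str]
    representative_id: str
    cdr3_consensus_len: int


def _lcs_len(a: str, b: str) -> int:
    """Longest common subsequence length, O(len(a)*len(b))."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        curr = [0]
        for j, cb in enumerate(b, 1):
            if ca == cb:
                curr.append(prev[j - 1] + 1)
            else:
                curr.append(max(prev[j], curr[-1]))
        prev = curr
    return prev[-1]


def cdr3_identity(a: str, b: str) -> float:
    """Percent identity between two CDR3s; symmetric.

    Equal lengths: Hamming identity 100*matches/len. Unequal lengths:
    100*LCS(a, b)/max(len), the optimum of a global alignment scoring
    match=1, mismatch=0, gap=0.
    """
    if not a or not b:
        raise ValueError("cdr3_identity requires non-empty sequences")
    if len(a) == len(b):
        matches = sum(1 for x, y in zip(a, b) if x == y)
        return 100.0 * matches / len(a)
    return 100.0 * _lcs_len(a, b) / max(len(a), len(b))


class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _encode_equal_length(seqs: Sequence[str]) -> np.ndarray:
    length = len(seqs[0])
    return np.frombuffer("".join(seqs).encode("ascii"),
                         dtype=np.uint8).reshape(len(seqs), length)


def _union_hamming_edges(dsu: _DisjointSet, idx: List[int], seqs: List[str],
                         threshold: float, block: int = 512) -> None:
    """Union all equal-length pairs with identity > threshold (vectorized)."""
    n = len(idx)
    if n < 2:
        return
    length = len(seqs[0])
    arr = _encode_equal_length(seqs)
    for i0 in range(0, n, block):
        a = arr[i0:i0 + block]
        for j0 in range(i0, n, block):
            b = arr[j0:j0 + block]
            mism = (a[:, None, :] != b[None, :, :]).sum(axis=2)
            # identity > t  <=>  100*(L - mism) > t*L, kept in exact arithmetic
            ii, jj = np.nonzero(100.0 * (length - mism) > threshold * length)
            for i, j in zip(ii.tolist(), jj.tolist()):
                gi, gj = i0 + i, j0 + j
                if gi < gj:
                    dsu.union(idx[gi], idx[gj])


def _cluster_components(cdr3s: Sequence[Tuple[str, str]], threshold: float,
                        linkage_mode: str = "single") -> List[List[int]]:
    """Indices of connected components (single linkage) at the threshold."""
    n = len(cdr3s)
    dsu = _DisjointSet(n)
    if linkage_mode not in ("single", "complete"):
        raise ValueError("linkage_mode must be 'single' or 'complete'")
    by_len: Dict[int, List[int]] = {}
    for i, (_, seq) in enumerate(cdr3s):
        if not seq:
            raise ValueError("empty CDR3 in clustering input")
        by_len.setdefault(len(seq), []).append(i)
    if linkage_mode == "single":
        for length, idx in by_len.items():
            _union_hamming_edges(dsu, idx, [cdr3s[i][1] for i in idx], threshold)
        # cross-length pairs: the LCS bound 100*min/max prunes most of them
        lengths = sorted(by_len)
        for li, la in enumerate(lengths):
            for lb in lengths[li + 1:]:
                if 100.0 * la / lb <= threshold:
                    continue
                for i in by_len[la]:
                    for j in by_len[lb]:
                        if cdr3_identity(cdr3s[i][1], cdr3s[j][1]) > threshold:
                            dsu.union(i, j)
    else:  # complete linkage via agglomerative merge on distances
        return _complete_linkage_components(cdr3s, threshold)
    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(dsu.find(i), []).append(i)
    return list(groups.values())


def _complete_linkage_components(cdr3s, threshold):
    n = len(cdr3s)
    if n == 1:
        return [[0]]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - cdr3_identity(cdr3s[i][1], cdr3s[j][1]) / 100.0
            dist[i, j] = dist[j, i] = d
    link = linkage(squareform(dist, checks=False), method="complete")
    from scipy.cluster.hierarchy import fcluster

    cut = 1.0 - threshold / 100.0
    labels = fcluster(link, t=cut - 1e-12, criterion="distance")
    groups: Dict[int, List[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    return list(groups.values())


def _representative(indices: List[int], cdr3s, counts: Optional[Dict[str, int]]):
    """Member with the highest count; ties to the smallest (sequence, id)."""
    def key(i):
        rid, seq = cdr3s[i]
        cnt = counts.get(rid, 1) if counts else 1
        return (-cnt, seq, rid)

    return min(indices, key=key)


def cluster_clonotypes(cdr3s: Sequence[Tuple[str, str]], threshold: float,
                       counts: Optional[Dict[str, int]] = None,
                       linkage_mode: str = "single") -> List[Clonotype]:
    """Partition (id, CDR3) pairs into clonotypes at identity > threshold.

    Cluster ids are deterministic: clusters are ordered by representative
    (count descending, then sequence, then id).
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    if not cdr3s:
        return []
    components = _cluster_components(cdr3s, threshold, linkage_mode)
    reps = [_representative(comp, cdr3s, counts) for comp in components]

    def cluster_key(item):
        comp, rep = item
        rid, seq = cdr3s[rep]
        cnt = counts.get(rid, 1) if counts else 1
        return (-cnt, seq, rid)

    ordered = sorted(zip(components, reps), key=cluster_key)
    out = []
    for cid, (comp, rep) in enumerate(ordered):
        member_ids = sorted(cdr3s[i][0] for i in comp)
        out.append(Clonotype(
            cluster_id=cid,
            member_ids=member_ids,
            representative_id=cdr3s[rep][0],
            cdr3_consensus_len=len(cdr3s[rep][1]),
        ))
    return out


def find_clonotype_members(query_cdr3: str, table: RepertoireTable,
                           threshold: float) -> List[VnarRecord]:
    """All annotated records with CDR3 identity to the query > threshold.

    Sorted by count descending (ties by sequence) — the order in which
    clonotype members would be prioritized for expression.
    """
    if not query_cdr3:
        raise ValueError("query CDR3 must be non-empty")
    hits = [r for r in table.records
            if r.cdr3 and cdr3_identity(query_cdr3, r.cdr3) > threshold]
    return sorted(hits, key=lambda r: (-r.count, r.sequence))


def build_tree(cdr3s: Sequence[Tuple[str, str]]) -> TreeNode:
    """UPGMA tree over 1 - identity/100 distances, for reporting.

    Deterministic: scipy's average linkage with the canonical Newick
    sibling order applied at serialization.
    """
    n = len(cdr3s)
    if n < 2:
        raise ValueError("build_tree requires >= 2 sequences")
    ids = [rid for rid, _ in cdr3s]
    if len(set(ids)) != n:
        raise ValueError("duplicate sequence ids")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - cdr3_identity(cdr3s[i][1], cdr3s[j][1]) / 100.0
            dist[i, j] = dist[j, i] = d
    link = linkage(squareform(dist, checks=False), method="average")
    # convert to TreeNode; node heights are half the cophenetic distance
    nodes: List[TreeNode] = [TreeNode(label=rid) for rid in ids]
    heights = [0.0] * n
    for a, b, d, _ in link:
        left, right = nodes[int(a)], nodes[int(b)]
        h = d / 2.0
        left.branch_length = max(h - heights[int(a)], 0.0)
        right.branch_length = max(h - heights[int(b)], 0.0)
        nodes.append(TreeNode(children=[left, right]))
        heights.append(h)
    return nodes[-1]
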