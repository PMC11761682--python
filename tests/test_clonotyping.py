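"""Identity, clustering, member search, and UPGMA trees against oracles."""

from functools import lru_cache

import numpy as np
import pytest

from vnarmine.clonotyping import (build_tree, cdr3_identity, cluster_clonotypes,
                                  find_clonotype_members)
from vnarmine.io import write_newick
from vnarmine.repertoire import table_from_counts
from vnarmine.simulate import build_scaffold, expand_lineage

AA = "ACDEFGHIKLMNPQRSTVWY"


# -- independent oracles ----------------------------------------------------

def oracle_identity(a, b):
    """Naive identity: zip-Hamming for equal lengths, recursive LCS otherwise."""
    if len(a) == len(b):
        return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)

    @lru_cache(maxsize=None)
    def lcs(i, j):
        if i == 0 or j == 0:
            return 0
        if a[i - 1] == b[j - 1]:
            return lcs(i - 1, j - 1) + 1
        return max(lcs(i - 1, j), lcs(i, j - 1))

    return 100.0 * lcs(len(a), len(b)) / max(len(a), len(b))


def oracle_components(cdr3s, threshold):
    """Brute-force union-find over all pairs."""
    n = len(cdr3s)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if oracle_identity(cdr3s[i][1], cdr3s[j][1]) > threshold:
                parent[find(j)] = find(i)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(cdr3s[i][0])
    return {frozenset(g) for g in groups.values()}


def oracle_upgma(labels, dist):
    """Naive agglomerative UPGMA; returns the canonical Newick string."""
    from vnarmine.io import TreeNode

    clusters = {i: ([i], TreeNode(label=labels[i]), 0.0) for i in range(len(labels))}
    d = {(i, j): dist[i][j] for i in range(len(labels)) for j in range(len(labels))
         if i < j}
    next_id = len(labels)
    while len(clusters) > 1:
        (i, j), dij = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        mi, ni, hi = clusters[i]
        mj, nj, hj = clusters[j]
        h = dij / 2.0
        ni.branch_length = max(h - hi, 0.0)
        nj.branch_length = max(h - hj, 0.0)
        merged = (mi + mj, TreeNode(children=[ni, nj]), h)
        del clusters[i], clusters[j]
        d = {k: v for k, v in d.items() if i not in k and j not in k}
        for k, (mk, _, _) in clusters.items():
            avg = float(np.mean([dist[a][b] for a in mi + mj for b in mk]))
            d[(min(k, next_id), max(k, next_id))] = avg
        clusters[next_id] = merged
        next_id += 1
    (_, root, _), = clusters.values()
    return write_newick(root)


def random_cdr3s(rng, n, with_lineages=True):
    """Mixed-length CDR3 pool with planted near-identical groups."""
    out = []
    i = 0
    while len(out) < n:
        length = int(rng.integers(10, 17))
        seed = "".join(rng.choice(list(AA.replace("C", "").replace("Y", "")), length))
        out.append((f"s{i}", seed))
        i += 1
        if with_lineages and rng.random() < 0.4:
            for _ in range(int(rng.integers(1, 4))):
                if len(out) >= n:
                    break
                pos = int(rng.integers(0, length))
                alt = "".join(rng.choice(list("ADEFG")))
                variant = seed[:pos] + alt + seed[pos + 1:]
                out.append((f"s{i}", variant))
                i += 1
    return out


class TestCdr3Identity:
    def test_identical(self):
        assert cdr3_identity("A" * 14, "A" * 14) == 100.0

    def test_one_mismatch_fourteen_mer(self):
        a = "ARDESSGYAMDYWG"
        b = "ARDESSGYAMDYWA"
        assert cdr3_identity(a, b) == pytest.approx(100 * 13 / 14)

    def test_symmetry(self, rng):
        for _ in range(100):
            a = "".join(rng.choice(list(AA), int(rng.integers(3, 12))))
            b = "".join(rng.choice(list(AA), int(rng.integers(3, 12))))
            assert cdr3_identity(a, b) == cdr3_identity(b, a)

    def test_unequal_lengths_match_bruteforce_alignment(self, rng):
        for _ in range(150):
            a = "".join(rng.choice(list("ACDE"), int(rng.integers(1, 9))))
            b = "".join(rng.choice(list("ACDE"), int(rng.integers(1, 9))))
            assert cdr3_identity(a, b) == pytest.approx(oracle_identity(a, b))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cdr3_identity("", "AAA")


class TestClusterClonotypes:
    def test_simple_pair_and_singleton(self):
        cdr3s = [("a", "A" * 14), ("b", "A" * 13 + "B"), ("c", "C" * 14)]
        clusters = cluster_clonotypes(cdr3s, 85.0)
        members = {frozenset(ct.member_ids) for ct in clusters}
        assert members == {frozenset({"a", "b"}), frozenset({"c"})}

    def test_threshold_100_isolates_everything(self):
        cdr3s = [("a", "AAAA"), ("b", "AAAA"), ("c", "AAAB")]
        clusters = cluster_clonotypes(cdr3s, 100.0)
        assert all(len(ct.member_ids) == 1 for ct in clusters)

    def test_matches_bruteforce_oracle(self, rng):
        cdr3s = random_cdr3s(rng, 120)
        for threshold in (85.0, 90.0, 95.0):
            ours = {frozenset(ct.member_ids)
                    for ct in cluster_clonotypes(cdr3s, threshold)}
            assert ours == oracle_components(cdr3s, threshold)

    def test_partition_property(self, rng):
        cdr3s = random_cdr3s(rng, 80)
        clusters = cluster_clonotypes(cdr3s, 88.0)
        seen = [rid for ct in clusters for rid in ct.member_ids]
        assert sorted(seen) == sorted(rid for rid, _ in cdr3s)

    def test_refinement_monotonicity(self, rng):
        for _ in range(20):
            cdr3s = random_cdr3s(rng, 30)
            coarse = {frozenset(ct.member_ids)
                      for ct in cluster_clonotypes(cdr3s, 80.0)}
            fine = {frozenset(ct.member_ids)
                    for ct in cluster_clonotypes(cdr3s, 92.0)}
            for group in fine:
                assert any(group <= big for big in coarse)

    def test_representative_is_highest_count(self):
        cdr3s = [("a", "A" * 14), ("b", "A" * 13 + "D")]
        clusters = cluster_clonotypes(cdr3s, 85.0, counts={"a": 2, "b": 10})
        assert clusters[0].representative_id == "b"


class TestFindClonotypeMembers:
    @staticmethod
    def _annotated_table(seqs_with_cdr3_counts):
        counts = {seq: cnt for seq, _, cnt in seqs_with_cdr3_counts}
        table = table_from_counts(counts, "lib")
        cdr3 = {seq: c for seq, c, _ in seqs_with_cdr3_counts}
        for r in table.records:
            r.cdr3 = cdr3[r.sequence]
        return table

    def test_verbatim_query_included(self):
        table = self._annotated_table([("P1", "ARDYWGQGTLVTVS", 5),
                                       ("P2", "GGGGGGGGGGGGGG", 2)])
        hits = find_clonotype_members("ARDYWGQGTLVTVS", table, 90.0)
        assert [h.sequence for h in hits] == ["P1"]

    def test_no_neighbor_above_threshold(self):
        table = self._annotated_table([("P1", "AAAAAAAAAAAAAA", 5)])
        assert find_clonotype_members("DDDDDDDDDDDDDD", table, 85.0) == []

    def test_planted_lineage_fully_recovered(self, rng):
        """All 77 planted variants of a seed clonotype are found at >85%."""
        seed, regions = build_scaffold("II", 12, rng)
        cap_85 = 1  # 12-mer: 1 mismatch keeps identity 91.7 > 85; 2 gives 83.3
        variants = expand_lineage(seed, 77, 0.02, rng, max_cdr3_mutations=cap_85)
        s, e = regions.cdr3
        query = seed[s:e]
        rows = [(v, v[s:e], 77 - i) for i, v in enumerate(variants)]
        # distant decoys
        for j in range(40):
            decoy, dreg = build_scaffold("IV", 12, rng)
            ds, de = dreg.cdr3
            rows.append((decoy, decoy[ds:de], 1))
        table = self._annotated_table(rows)
        hits = find_clonotype_members(query, table, 85.0)
        assert {h.sequence for h in hits} == set(variants)
        counts = [h.count for h in hits]
        assert counts == sorted(counts, reverse=True)

    def test_consistent_with_cluster_edges(self, rng):
        cdr3s = random_cdr3s(rng, 40)
        rows = [("P" + str(i) + c * 20, c, 1) for i, (_, c) in enumerate(cdr3s)]
        table = self._annotated_table(rows)
        query = cdr3s[0][1]
        hits = {h.cdr3 for h in find_clonotype_members(query, table, 85.0)}
        direct = {c for _, c in cdr3s if cdr3_identity(query, c) > 85.0}
        assert hits == direct


class TestBuildTree:
    def test_identical_pair_zero_branches(self):
        tree = build_tree([("A", "KKKK"), ("B", "KKKK")])
        assert write_newick(tree) == "(A:0,B:0);"

    def test_closest_pair_joined_first(self):
        cdr3s = [("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAD"), ("c", "DDDDDAAAAA")]
        newick = write_newick(build_tree(cdr3s))
        assert newick.startswith("((a:")  # (a,b) cherry inside

    def test_leaf_set_preserved(self, rng):
        cdr3s = random_cdr3s(rng, 15)
        tree = build_tree(cdr3s)
        assert sorted(tree.leaf_labels()) == sorted(rid for rid, _ in cdr3s)

    def test_fewer_than_two_errors(self):
        with pytest.raises(ValueError):
            build_tree([("A", "KKKK")])

    def test_matches_naive_upgma_on_tie_free_instance(self):
        """Sidon-set block sequences give all-distinct pairwise distances."""
        sidon = [1, 2, 5, 11, 22, 40, 56, 69, 97, 101, 156, 163, 175, 218,
                 243, 265, 300, 327, 335, 410]
        L = 420
        seqs = [("t%02d" % i, "B" * c + "A" * (L - c)) for i, c in enumerate(sidon)]
        labels = [rid for rid, _ in seqs]
        dist = [[1.0 - cdr3_identity(a, b) / 100.0 if a != b else 0.0
                 for _, b in seqs] for _, a in seqs]
        assert write_newick(build_tree(seqs)) == oracle_upgma(labels, dist)
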