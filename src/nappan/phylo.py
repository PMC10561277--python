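"""Distance-based single-marker phylogenetics.

Distances are protein dissimilarities (100 - % identity, pairwise deletion
over gapped columns), trees are built with canonical neighbor-joining
(Saitou-Nei Q-criterion, deterministic lexicographic tie-breaking, branch
lengths clamped at zero) and compared with the unweighted Robinson-Foulds
bipartition distance. On additive distance matrices NJ recovers the
generating tree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


def read_alignment_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_alignment_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


def p_distance_matrix(aligned_seqs: Mapping[str, str]) -> DistanceMatrix:
    """Percent dissimilarity (100 - % identity) per sequence pair, counting
    only columns where neither sequence has a gap (pairwise deletion)."""
    taxa = sorted(aligned_seqs)
    if len(taxa) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(aligned_seqs[t]) for t in taxa}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    arrs = {t: np.frombuffer(aligned_seqs[t].encode(), dtype="S1") for t in taxa}
    gaps = {t: (arrs[t] == b"-") | (arrs[t] == b".") for t in taxa}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gaps[taxa[i]] & ~gaps[taxa[j]]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(f"no shared ungapped columns between {taxa[i]} and {taxa[j]}")
            diff = (arrs[taxa[i]][shared] != arrs[taxa[j]][shared]).mean()
            d[i, j] = d[j, i] = 100.0 * float(diff)
    return DistanceMatrix(taxa=taxa, d=d)


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Canonical NJ; returns an unrooted tree in Newick (trifurcating root).

    Ties on the Q-criterion resolve to the lexicographically smallest pair of
    cluster labels (a cluster is labeled by its smallest leaf), so output is
    deterministic across platforms.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    # active nodes: key -> (label-for-ties, newick fragment)
    nodes = {t: t for t in dm.taxa}  # key -> newick fragment
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.taxa[i], dm.taxa[j]))] = float(dm.d[i, j])

    def d_of(a, b):
        return dist[frozenset((a, b))]

    active = sorted(nodes)
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d_of(a, b) for b in active if b != a) for a in active}
        best_pair, best_q = None, None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d_of(a, b) - r[a] - r[b]
                key = tuple(sorted((a, b)))
                if best_q is None or q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and key < best_pair):
                    best_q, best_pair = q, key
        a, b = best_pair
        dab = d_of(a, b)
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new_key = min(a, b)
        children = sorted([(a, la), (b, lb)])
        fragment = "(" + ",".join(f"{nodes[c]}:{l:.10g}" for c, l in children) + ")"
        for k in active:
            if k in (a, b):
                continue
            dist[frozenset((new_key, k))] = max((d_of(a, k) + d_of(b, k) - dab) / 2.0, 0.0)
        active = sorted([k for k in active if k not in (a, b)] + [new_key])
        nodes[new_key] = fragment
        if a != new_key:
            del nodes[a]
        if b != new_key:
            del nodes[b]

    x, y, z = active
    lx = max((d_of(x, y) + d_of(x, z) - d_of(y, z)) / 2.0, 0.0)
    ly = max((d_of(x, y) + d_of(y, z) - d_of(x, z)) / 2.0, 0.0)
    lz = max((d_of(x, z) + d_of(y, z) - d_of(x, y)) / 2.0, 0.0)
    parts = sorted([(x, lx), (y, ly), (z, lz)])
    return "(" + ",".join(f"{nodes[c]}:{l:.10g}" for c, l in parts) + ");"


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """Unweighted Robinson-Foulds distance (bipartitions in exactly one tree)."""
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    leaves1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    leaves2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise ValueError(f"leaf sets differ: {sorted(leaves1 ^ leaves2)}")
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))


def tree_edge_count(newick: str) -> int:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return sum(1 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node)
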