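"""Protein-family clustering: global-alignment identity, greedy centroid
clustering at 50% identity, and reciprocal-best-hit triangle orthology.

Two complementary layers mirror common pangenome practice: a greedy identity
clustering (which may group within-genome paralogs) and a cross-genome
bidirectional-best-hit (BBH) triangle step in which three mutually-best
proteins from three distinct genomes seed an orthologous protein family (PF)
and triangles sharing an edge are merged.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .core_model import Thresholds

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PairwiseHit:
    query: str
    subject: str
    identity: float
    coverage: float
    score: float
    evalue: float

    def __post_init__(self):
        if not (0 <= self.identity <= 1) or not (0 <= self.coverage <= 1):
            raise ValueError(f"hit {self.query}->{self.subject}: identity/coverage outside [0, 1]")


@dataclass
class ProteinFamilyCluster:
    pf_id: str
    family: str
    members: set[str]
    centroid: str

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"{self.pf_id}: empty cluster")
        if self.centroid not in self.members:
            raise ValueError(f"{self.pf_id}: centroid {self.centroid!r} not a member")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def global_align_identity(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """Needleman-Wunsch identity, coverage and score for two protein sequences.

    Identity is matches over all alignment columns (gap columns included);
    coverage is the aligned (non-gap-paired) span of the shorter sequence over
    its length. Scoring: BLOSUM62, gap open 10, gap extend 1.
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        bad = set(seq) - _STANDARD_AA
        if bad:
            raise ValueError(f"{name} contains non-standard residues {sorted(bad)}")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = aln.length
    identity = counts.identities / columns
    aligned_pairs = counts.identities + counts.mismatches
    coverage = aligned_pairs / min(len(seq_a), len(seq_b))
    return identity, coverage, float(aln.score)


def greedy_identity_cluster(seqs: Mapping[str, str], threshold: float = 0.50,
                            family_of: Optional[Mapping[str, str]] = None,
                            ) -> list[ProteinFamilyCluster]:
    """Centroid-greedy clustering of protein sequences at an identity threshold.

    Sequences are processed sorted by length descending (ties by id) so the
    result does not depend on input order; each sequence joins the first
    centroid reaching the identity threshold, else opens a new cluster.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    order = sorted(seqs, key=lambda pid: (-len(seqs[pid]), pid))
    centroids: list[str] = []
    members: dict[str, list[str]] = {}
    for pid in order:
        for cid in centroids:
            ident, _, _ = global_align_identity(seqs[cid], seqs[pid])
            if ident >= threshold:
                members[cid].append(pid)
                break
        else:
            centroids.append(pid)
            members[pid] = [pid]
    clusters = []
    for i, cid in enumerate(centroids, start=1):
        fam = (family_of or {}).get(cid, "")
        clusters.append(ProteinFamilyCluster(
            pf_id=f"PF{i:04d}", family=fam, members=set(members[cid]), centroid=cid))
    return clusters


def _best_hits(hits: Sequence[PairwiseHit], genome_of: Mapping[str, str],
               th: Thresholds) -> dict[tuple[str, str], str]:
    """Best subject per (query protein, subject genome): max score, tie min
    e-value, then lexicographic subject."""
    best: dict[tuple[str, str], PairwiseHit] = {}
    for h in hits:
        if h.coverage < th.bbh_coverage or h.evalue > th.bbh_evalue:
            continue
        if h.query not in genome_of or h.subject not in genome_of:
            raise KeyError(f"hit {h.query}->{h.subject}: protein with unknown genome")
        if genome_of[h.query] == genome_of[h.subject]:
            continue  # BBH is cross-genome by construction
        key = (h.query, genome_of[h.subject])
        cur = best.get(key)
        if cur is None or (-h.score, h.evalue, h.subject) < (-cur.score, cur.evalue, cur.subject):
            best[key] = h
    return {key: h.subject for key, h in best.items()}


def bbh_edges(hits: Sequence[PairwiseHit], genome_of: Mapping[str, str],
              th: Thresholds) -> set[frozenset[str]]:
    """Bidirectional best hits between genome pairs, after coverage/e-value
    filtering."""
    best = _best_hits(hits, genome_of, th)
    edges = set()
    for (query, _sub_genome), subject in best.items():
        if best.get((subject, genome_of[query])) == query:
            edges.add(frozenset((query, subject)))
    return edges


def bbh_triangle_cluster(hits: Sequence[PairwiseHit], genome_of: Mapping[str, str],
                         th: Thresholds,
                         family_of: Optional[Mapping[str, str]] = None,
                         ) -> list[ProteinFamilyCluster]:
    """Cluster proteins into PFs by merging BBH triangles that share an edge.

    Proteins participating in no triangle remain singleton PFs, so the output
    partitions the full protein set given by ``genome_of``.
    """
    edges = bbh_edges(hits, genome_of, th)
    adjacency: dict[str, set[str]] = defaultdict(set)
    for e in edges:
        u, v = sorted(e)
        adjacency[u].add(v)
        adjacency[v].add(u)

    # union-find over edges: triangles (3 genomes) union their three edges
    parent: dict[frozenset[str], frozenset[str]] = {e: e for e in edges}

    def find(e):
        while parent[e] != e:
            parent[e] = parent[parent[e]]
            e = parent[e]
        return e

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for e in edges:
        u, v = sorted(e)
        for w in adjacency[u] & adjacency[v]:
            if len({genome_of[u], genome_of[v], genome_of[w]}) == 3:
                union(e, frozenset((u, w)))
                union(e, frozenset((v, w)))

    groups: dict[frozenset[str], set[str]] = defaultdict(set)
    in_triangle: set[str] = set()
    for e in edges:
        u, v = sorted(e)
        has_triangle = any(len({genome_of[u], genome_of[v], genome_of[w]}) == 3
                           for w in adjacency[u] & adjacency[v])
        if has_triangle:
            groups[find(e)].update(e)
            in_triangle.update(e)

    clusters = []
    pf_no = 0
    for root in sorted(groups, key=lambda r: sorted(groups[r])):
        pf_no += 1
        members = groups[root]
        centroid = min(members)
        clusters.append(ProteinFamilyCluster(
            pf_id=f"PF{pf_no:04d}", family=(family_of or {}).get(centroid, ""),
            members=set(members), centroid=centroid))
    for pid in sorted(set(genome_of) - in_triangle):
        pf_no += 1
        clusters.append(ProteinFamilyCluster(
            pf_id=f"PF{pf_no:04d}", family=(family_of or {}).get(pid, ""),
            members={pid}, centroid=pid))
    return clusters
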