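"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: alignments are enumerated
exhaustively, triangles are enumerated over all protein triples, and inverted
repeats over all (start, stem, loop) triples.
"""

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")

# ---------------------------------------------------------------------------
# global alignment
# ---------------------------------------------------------------------------


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as a list of column pairs."""
    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            yield list(cols)
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            yield from rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            yield from rec(i, j + 1, cols + [("-", b[j])])
    yield from rec(0, 0, [])


def score_alignment(cols, gap_open=10.0, gap_extend=1.0):
    """Affine-gap score: first gap position costs gap_open, the rest extend."""
    score, prev_gap = 0.0, None
    for x, y in cols:
        if x == "-" or y == "-":
            which = "a" if x == "-" else "b"
            score -= gap_open if which != prev_gap else gap_extend
            prev_gap = which
        else:
            score += BLOSUM62[x, y]
            prev_gap = None
    return score


def best_alignment_oracle(a: str, b: str):
    """(max score, set of identities over all optimal alignments)."""
    best_score, identities = None, set()
    for cols in enumerate_alignments(a, b):
        s = score_alignment(cols)
        ident = sum(x == y for x, y in cols) / len(cols)
        if best_score is None or s > best_score + 1e-9:
            best_score, identities = s, {ident}
        elif abs(s - best_score) <= 1e-9:
            identities.add(ident)
    return best_score, identities


# ---------------------------------------------------------------------------
# BBH triangles
# ---------------------------------------------------------------------------


def bbh_triangle_oracle(hits, genome_of, th):
    """Partition (set of frozensets) by exhaustive triangle enumeration."""
    def best(query, target_genome):
        cands = [h for h in hits
                 if h.query == query and genome_of[h.subject] == target_genome
                 and genome_of[h.query] != genome_of[h.subject]
                 and h.coverage >= th.bbh_coverage and h.evalue <= th.bbh_evalue]
        if not cands:
            return None
        return min(cands, key=lambda h: (-h.score, h.evalue, h.subject)).subject

    prots = sorted(genome_of)
    edges = set()
    for p, q in combinations(prots, 2):
        if genome_of[p] == genome_of[q]:
            continue
        if best(p, genome_of[q]) == q and best(q, genome_of[p]) == p:
            edges.add(frozenset((p, q)))
    triangles = [frozenset(t) for t in combinations(prots, 3)
                 if len({genome_of[x] for x in t}) == 3
                 and all(frozenset(pair) in edges for pair in combinations(t, 2))]
    groups = [set(t) for t in triangles]
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                # any shared pair of proteins is a shared edge for triangles
                if len(groups[i] & groups[j]) >= 2:
                    groups[i] |= groups[j]
                    del groups[j]
                    merged = True
                    break
            if merged:
                break
    covered = set().union(*groups) if groups else set()
    partition = {frozenset(g) for g in groups}
    partition |= {frozenset((p,)) for p in prots if p not in covered}
    return partition


# ---------------------------------------------------------------------------
# inverted repeats
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _match(seq, p, q):
    a, b = seq[p], seq[q]
    return a != "N" and b != "N" and _COMP.get(a) == b


def ir_oracle(seq, min_stem, max_loop, max_mismatch=0, k_max=None):
    """All maximal inverted repeats by enumeration of (start, stem, loop).

    Maximality mirrors the reporting rule: an IR is kept only if neither an
    outward nor an inward one-pair stem extension stays within the mismatch
    budget. ``k_max`` caps the enumerated stem length for long sequences.
    """
    n = len(seq)
    k_hi = n if k_max is None else min(n, k_max)
    out = set()
    for i in range(n):
        for k in range(min_stem, k_hi + 1):
            for loop in range(0, max_loop + 1):
                j = i + k + loop
                if j + k > n:
                    continue
                mism = sum(0 if _match(seq, i + t, j + k - 1 - t) else 1 for t in range(k))
                if mism > max_mismatch:
                    continue
                can_out = (i - 1 >= 0 and j + k <= n - 1
                           and mism + (0 if _match(seq, i - 1, j + k) else 1) <= max_mismatch)
                can_in = (loop >= 2
                          and mism + (0 if _match(seq, i + k, j - 1) else 1) <= max_mismatch)
                if can_out or can_in:
                    continue
                out.add((i + 1, i + k, j + 1, j + k, k, loop, mism))
    return sorted(out)


def ir_oracle_long(seq, min_stem, max_loop, max_mismatch=0, k_max=64):
    """Vectorized all-pairs enumeration for kilobase-scale sequences.

    For each (stem, loop) the mismatch count of every start position is
    computed with shifted NumPy comparisons; candidates within budget are then
    checked for maximality exactly as in ``ir_oracle``.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    comp = np.full(256, b"?", dtype="S1")
    for a, b in _COMP.items():
        comp[ord(a)] = b.encode()
    comp_arr = comp[arr.view(np.uint8)]
    is_n = arr == b"N"
    candidates = []
    for k in range(min_stem, min(n, k_max) + 1):
        for loop in range(0, max_loop + 1):
            span = 2 * k + loop
            if span > n:
                continue
            m = n - span + 1
            mism = np.zeros(m, dtype=np.int32)
            for t in range(k):
                left = slice(t, t + m)
                right = slice(span - 1 - t, span - 1 - t + m)
                ok = (comp_arr[left] == arr[right]) & ~is_n[left] & ~is_n[right]
                mism += ~ok
            for i in np.flatnonzero(mism <= max_mismatch):
                candidates.append((int(i), k, loop, int(mism[i])))
    out = set()
    for i, k, loop, mism in candidates:
        j = i + k + loop
        can_out = (i - 1 >= 0 and j + k <= n - 1
                   and mism + (0 if _match(seq, i - 1, j + k) else 1) <= max_mismatch)
        can_in = (loop >= 2
                  and mism + (0 if _match(seq, i + k, j - 1) else 1) <= max_mismatch)
        if not (can_out or can_in):
            out.add((i + 1, i + k, j + 1, j + k, k, loop, mism))
    return sorted(out)
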