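"""Mobile-genetic-element association: NAP-to-element mapping, ICE/IME/island
classification from hallmark genes, NAP-hallmark covariation, and detection
of inverted repeats such as those flanking transfer origins (oriT).

Element classification follows the conjugation-machinery logic: an integrated
element with a type IV secretion system and an integrase is an ICE; with a
relaxase and an integrase but no T4SS it is an IME (mobilizable but not
self-conjugative); anything else integrated is a plain island. Whole-replicon
regions are plasmids.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core_model import GeneFeature, NAPCandidate
from .pangenome_stats import CorrelationResult, pearson

HALLMARK_ROLES = ("relaxase", "t4ss", "integrase", "transposase", "toxin_antitoxin",
                  "parA", "rm_system")

#: Keyword mapper from product annotations to hallmark roles (convenience for
#: annotation tables lacking explicit role calls).
_ROLE_KEYWORDS = {
    "t4ss": ("virb", "trb", "tra", "t4ss", "type iv secretion"),
    "relaxase": ("mob", "relaxase", "vird2"),
    "integrase": ("xerd", "integrase", "int", "recombinase"),
    "transposase": ("transposase", "tnp", "insertion sequence"),
    "toxin_antitoxin": ("toxin", "antitoxin", "rele", "relb", "brnt", "brna", "addiction"),
    "parA": ("para", "partitioning", "parm"),
    "rm_system": ("restriction", "methyltransferase", "hsdr", "hsdm"),
}


def role_from_product(product: str) -> Optional[str]:
    text = product.lower()
    for role, keywords in _ROLE_KEYWORDS.items():
        if any(kw in text for kw in keywords):
            return role
    return None


@dataclass
class MGERegion:
    element_id: str
    replicon_id: str
    start: int = 1
    end: int = 1
    whole_replicon: bool = False
    mge_class: str = "unknown"
    hallmark_genes: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, role)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region {self.element_id}: start > end")
        for _gid, role in self.hallmark_genes:
            if role not in HALLMARK_ROLES:
                raise ValueError(f"region {self.element_id}: unknown hallmark role {role!r}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def roles(self) -> set[str]:
        return {role for _g, role in self.hallmark_genes}


def classify_element(region: MGERegion) -> str:
    """Deterministic, total classification of a region from its hallmarks."""
    if region.whole_replicon:
        return "plasmid"
    roles = region.roles()
    if "t4ss" in roles and "integrase" in roles:
        return "ICE"
    if "relaxase" in roles and "integrase" in roles and "t4ss" not in roles:
        return "IME"
    return "island"


def map_naps_to_mges(candidates: Sequence[NAPCandidate],
                     genes: Sequence[GeneFeature],
                     regions: Sequence[MGERegion],
                     ) -> dict[str, list[NAPCandidate]]:
    """Assign each NAP to at most one element: its replicon's plasmid region,
    or the innermost integrated region containing its gene midpoint."""
    gene_by_id = {g.gene_id: g for g in genes}
    plasmid_by_replicon = {r.replicon_id: r for r in regions if r.whole_replicon}
    integrated = [r for r in regions if not r.whole_replicon]
    out: dict[str, list[NAPCandidate]] = {r.element_id: [] for r in regions}
    for cand in candidates:
        gene = gene_by_id.get(cand.gene_id)
        if gene is None:
            continue
        plasmid = plasmid_by_replicon.get(gene.replicon_id)
        if plasmid is not None:
            out[plasmid.element_id].append(cand)
            continue
        mid = gene.midpoint
        containing = [r for r in integrated
                      if r.replicon_id == gene.replicon_id and r.start <= mid <= r.end]
        if containing:
            innermost = min(containing, key=lambda r: (r.span, r.element_id))
            out[innermost.element_id].append(cand)
    return out


_DNA_BENDING = ("HU", "IHF_A", "IHF_B")


def covariation(per_genome_nap_counts: Mapping[str, Mapping[str, int]],
                per_genome_hallmark_counts: Mapping[str, int],
                families: Sequence[str] = _DNA_BENDING,
                hallmark_label: str = "hallmark") -> CorrelationResult:
    """Pearson r between per-genome DNA-bending NAP counts (HU + IHF_A +
    IHF_B by default) and per-genome hallmark gene counts."""
    if set(per_genome_nap_counts) != set(per_genome_hallmark_counts):
        raise ValueError("genome sets differ between NAP and hallmark counts")
    genomes = sorted(per_genome_nap_counts)
    naps = [sum(per_genome_nap_counts[g].get(f, 0) for f in families) for g in genomes]
    marks = [per_genome_hallmark_counts[g] for g in genomes]
    return pearson(naps, marks, "+".join(families), hallmark_label)


# ---------------------------------------------------------------------------
# Inverted repeats
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class InvertedRepeat:
    left_start: int   # 1-based inclusive
    left_end: int
    right_start: int
    right_end: int
    stem_len: int
    loop_len: int
    mismatches: int

    def __post_init__(self):
        if self.loop_len != self.right_start - self.left_end - 1:
            raise ValueError("loop_len inconsistent with arm coordinates")
        if self.stem_len != self.left_end - self.left_start + 1:
            raise ValueError("stem_len inconsistent with left arm")


def _pair_matches(seq: str, p: int, q: int) -> bool:
    a, b = seq[p], seq[q]
    return a != "N" and b != "N" and _COMPLEMENT.get(a) == b


def find_inverted_repeats(seq: str, min_stem: int, max_loop: int,
                          max_mismatch: int = 0) -> list[InvertedRepeat]:
    """All maximal inverted repeats with the given stem/loop/mismatch bounds.

    Works per palindromic axis: for each axis and admissible loop length the
    stem is extended outward from the innermost base pair as far as the
    mismatch budget allows; a hit is reported only if it cannot be extended
    inward (loop shrunk by two) or outward without breaking the budget, so no
    reported repeat is a sub-stem of another on the same axis. 'N' never
    pairs. Coordinates are 1-based inclusive.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid DNA characters {sorted(bad)}")
    if min_stem < 4:
        raise ValueError("min_stem must be >= 4")
    if max_loop < 0 or max_mismatch < 0:
        raise ValueError("max_loop and max_mismatch must be non-negative")
    n = len(seq)
    results = []
    for c in range(1, 2 * n - 2):  # axis: pair (p, c - p)
        loop_start = 0 if (c % 2 == 1) else 1  # loop parity fixed by axis parity
        for loop in range(loop_start, max_loop + 1, 2):
            twice_p0 = c - loop - 1
            if twice_p0 % 2 != 0:
                continue
            p0 = twice_p0 // 2
            if p0 < 0 or c - p0 > n - 1:
                continue
            # extend outward from the innermost pair p0
            mismatches = 0
            p1 = p0 + 1
            p = p0
            while p >= 0 and c - p <= n - 1:
                if not _pair_matches(seq, p, c - p):
                    if mismatches + 1 > max_mismatch:
                        break
                    mismatches += 1
                p1 = p
                p -= 1
            stem = p0 - p1 + 1
            if stem < min_stem:
                continue
            # inward maximality: adding the pair just inside must break budget
            if loop >= 2:
                inward_mis = mismatches + (0 if _pair_matches(seq, p0 + 1, c - p0 - 1) else 1)
                if inward_mis <= max_mismatch:
                    continue
            i, k = p1, stem
            j = p0 + 1 + loop
            results.append(InvertedRepeat(
                left_start=i + 1, left_end=i + k, right_start=j + 1, right_end=j + k,
                stem_len=k, loop_len=loop, mismatches=mismatches))
    uniq = {(ir.left_start, ir.left_end, ir.right_start, ir.right_end): ir for ir in results}
    return sorted(uniq.values(), key=lambda ir: (ir.left_start, ir.right_start, -ir.stem_len))
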