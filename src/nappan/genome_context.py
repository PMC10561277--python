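"""Gene-vicinity analysis (5-kb window) and replication-origin-relative
positions of genes on circular replicons.

The vicinity window is measured from gene boundaries: a neighbor is included
when its span intersects [start - window, end + window] of the query gene,
with wraparound on circular replicons. Strand plays no role in inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core_model import GeneFeature, NAPCandidate, Replicon


@dataclass(frozen=True)
class VicinityProfile:
    family: str
    kegg_id: str
    annotation: str
    frequency_pct: float
    n_with: int
    n_total: int


@dataclass(frozen=True)
class RelativePosition:
    gene_id: str
    replicon_id: str
    fraction_from_ori: float
    quadrant: str

    def __post_init__(self):
        if not (0 <= self.fraction_from_ori < 1):
            raise ValueError("fraction_from_ori outside [0, 1)")


def _spans_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def neighborhood(gene: GeneFeature, genes: Sequence[GeneFeature],
                 window: int = 5000,
                 replicon: Optional[Replicon] = None) -> list[GeneFeature]:
    """Genes (excluding the query) intersecting the +/-window envelope of the
    query gene on the same replicon; wraps around circular replicons."""
    if gene not in genes:
        raise KeyError(f"gene {gene.gene_id} not in gene set")
    lo, hi = gene.start - window, gene.end + window
    length = replicon.length_bp if replicon is not None else None
    circular = replicon is not None and replicon.topology == "circular"
    out = []
    for other in genes:
        if other.replicon_id != gene.replicon_id or other == gene:
            continue
        hit = _spans_overlap(lo, hi, other.start, other.end)
        if not hit and circular:
            # try the neighbor shifted by one full replicon either way
            hit = (_spans_overlap(lo, hi, other.start - length, other.end - length)
                   or _spans_overlap(lo, hi, other.start + length, other.end + length))
        if hit:
            out.append(other)
    return sorted(out, key=lambda g: (g.start, g.gene_id))


def vicinity_frequency(candidates: Sequence[NAPCandidate],
                       genes: Sequence[GeneFeature],
                       annotations: Mapping[str, str],
                       window: int = 5000,
                       replicons: Optional[Mapping[str, Replicon]] = None,
                       annotation_text: Optional[Mapping[str, str]] = None,
                       denominator: str = "resolvable",
                       ) -> list[VicinityProfile]:
    """KEGG-based vicinity frequency index per NAP family x annotation.

    For every family, the percentage of its genes having at least one
    neighboring CDS bearing a given KEGG annotation, over the genes with a
    resolvable vicinity (>= 1 annotated neighbor; ``denominator="all"``
    divides by every located family gene instead). A KEGG id repeated within
    one neighborhood counts once per NAP gene.
    """
    if denominator not in ("resolvable", "all"):
        raise ValueError("denominator must be 'resolvable' or 'all'")
    gene_by_id = {g.gene_id: g for g in genes}
    per_family_totals: dict[str, int] = {}
    hits: dict[tuple[str, str], int] = {}
    for cand in candidates:
        gene = gene_by_id.get(cand.gene_id)
        if gene is None:
            continue
        rep = (replicons or {}).get(gene.replicon_id)
        neigh = neighborhood(gene, genes, window=window, replicon=rep)
        keggs = {annotations[g.gene_id] for g in neigh if g.gene_id in annotations}
        if denominator == "all" or keggs:
            per_family_totals[cand.family] = per_family_totals.get(cand.family, 0) + 1
        for kegg in keggs:
            hits[(cand.family, kegg)] = hits.get((cand.family, kegg), 0) + 1
    profiles = []
    for (family, kegg), n_with in hits.items():
        n_total = per_family_totals[family]
        profiles.append(VicinityProfile(
            family=family, kegg_id=kegg,
            annotation=(annotation_text or {}).get(kegg, ""),
            frequency_pct=round(100.0 * n_with / n_total, 2),
            n_with=n_with, n_total=n_total))
    return sorted(profiles, key=lambda p: (p.family, -p.frequency_pct, p.kegg_id))


def relative_position(gene: GeneFeature, replicon: Replicon) -> RelativePosition:
    """Position of a gene's midpoint relative to the replication origin, as a
    fraction of the replicon traversed ori -> ter -> ori, with quadrant."""
    if replicon.ori_pos is None:
        raise ValueError(f"replicon {replicon.replicon_id} has no ori_pos")
    frac = ((gene.midpoint - replicon.ori_pos) % replicon.length_bp) / replicon.length_bp
    quadrant = f"Q{int(frac * 4) + 1}"
    return RelativePosition(gene_id=gene.gene_id, replicon_id=replicon.replicon_id,
                            fraction_from_ori=frac, quadrant=quadrant)


def positions_table(genes: Iterable[GeneFeature], replicon: Replicon) -> pd.DataFrame:
    rows = [relative_position(g, replicon).__dict__ for g in genes]
    return pd.DataFrame(rows)
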