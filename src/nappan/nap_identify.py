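"""Validation of raw domain hits and construction of the family census.

A protein is accepted as a NAP candidate when at least one of its domain hits
clears the significance cut-offs (e-value below threshold; hit probability,
when reported, above threshold; alignment coverage, when reported, at or above
the pairwise coverage cut-off). Among a protein's passing hits the assigned
family is that of the minimum e-value hit; ties go to the higher probability,
then the lexicographically smaller profile label, so validation is
deterministic and independent of input order.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core_model import (NAP_FAMILIES, DomainHit, GenomeRecord, NAPCandidate,
                         Thresholds)


def _hit_passes(hit: DomainHit, th: Thresholds) -> bool:
    if hit.evalue >= th.validation_evalue:
        return False
    if hit.probability is not None and hit.probability <= th.validation_probability:
        return False
    if hit.coverage is not None and hit.coverage < th.bbh_coverage:
        return False
    return True


def _hit_rank(hit: DomainHit):
    # min e-value first; tie -> higher probability, then lexicographic profile
    prob = hit.probability if hit.probability is not None else -1.0
    return (hit.evalue, -prob, hit.profile_id)


def validate_hits(hits: Iterable[DomainHit], th: Thresholds,
                  genome_of: Optional[Mapping[str, str]] = None,
                  gene_of: Optional[Mapping[str, str]] = None) -> list[NAPCandidate]:
    """Filter domain hits and emit exactly one candidate per retained protein.

    ``genome_of``/``gene_of`` optionally resolve each protein to its genome
    and gene; proteins without a mapping get genome_id ``""``.
    """
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for hit in hits:
        if _hit_passes(hit, th):
            by_protein[hit.protein_id].append(hit)
    candidates = []
    for protein_id in sorted(by_protein):
        best = min(by_protein[protein_id], key=_hit_rank)
        candidates.append(NAPCandidate(
            protein_id=protein_id,
            genome_id=(genome_of or {}).get(protein_id, ""),
            family=best.profile_id, best_hit=best,
            gene_id=(gene_of or {}).get(protein_id)))
    return candidates


@dataclass
class CensusTable:
    """Per lineage x family occurrence table with per-genome dose ranges.

    ``cells`` is a tidy DataFrame (lineage_id, family, total, dose_min,
    dose_max); dose ranges cover carrier genomes only. ``n_genomes`` maps each
    lineage to its genome count; ``per_genome`` maps lineage to the sorted
    list of NAPs-per-genome totals (for medians and ranges).
    """
    cells: pd.DataFrame
    n_genomes: dict[str, int]
    per_genome: dict[str, list[int]]

    @property
    def grand_total(self) -> int:
        return int(self.cells["total"].sum())

    def family_totals(self) -> dict[str, int]:
        return self.cells.groupby("family")["total"].sum().astype(int).to_dict()

    def lineage_summary(self) -> pd.DataFrame:
        rows = []
        for lineage, counts in self.per_genome.items():
            s = pd.Series(counts) if counts else pd.Series([0])
            rows.append({"lineage_id": lineage, "n_genomes": self.n_genomes[lineage],
                         "total_naps": int(s.sum()), "naps_median": float(s.median()),
                         "naps_min": int(s.min()), "naps_max": int(s.max())})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        wide = self.cells.pivot(index="lineage_id", columns="family", values="total").fillna(0).astype(int)
        wide.insert(0, "n_genomes", pd.Series(self.n_genomes))
        wide.to_csv(path, sep="\t")


def census(candidates: Sequence[NAPCandidate], genomes: Sequence[GenomeRecord],
           families: Sequence[str] = NAP_FAMILIES) -> CensusTable:
    """Tally validated candidates into a lineage x family census."""
    genome_lineage = {g.genome_id: g.lineage_id for g in genomes}
    orphans = sorted({c.genome_id for c in candidates} - set(genome_lineage))
    if orphans:
        raise KeyError(f"candidates reference unknown genomes: {orphans}")

    lineages = sorted({g.lineage_id for g in genomes})
    fams = list(families) + sorted(
        {c.family for c in candidates} - set(families))
    # per (lineage, family, genome) copy counts
    dose: dict[tuple[str, str], dict[str, int]] = defaultdict(lambda: defaultdict(int))
    per_genome_total: dict[str, int] = defaultdict(int)
    for c in candidates:
        dose[(genome_lineage[c.genome_id], c.family)][c.genome_id] += 1
        per_genome_total[c.genome_id] += 1

    rows = []
    for lineage in lineages:
        for fam in fams:
            counts = dose.get((lineage, fam), {})
            total = sum(counts.values())
            rows.append({"lineage_id": lineage, "family": fam, "total": total,
                         "dose_min": min(counts.values()) if counts else 0,
                         "dose_max": max(counts.values()) if counts else 0})
    n_genomes = {lin: sum(1 for g in genomes if g.lineage_id == lin) for lin in lineages}
    per_genome = {lin: sorted(per_genome_total[g.genome_id]
                              for g in genomes if g.lineage_id == lin)
                  for lin in lineages}
    return CensusTable(cells=pd.DataFrame(rows), n_genomes=n_genomes, per_genome=per_genome)


def census_from_fixture(table1) -> CensusTable:
    """Rebuild a CensusTable from the tidy packaged census fixture."""
    cells = table1[["lineage_id", "family", "total", "dose_min", "dose_max"]].copy()
    meta = table1.drop_duplicates("lineage_id").set_index("lineage_id")
    n_genomes = meta["n_genomes"].astype(int).to_dict()
    # per-genome totals are not in the published table; keep the summary stats
    per_genome = {lin: [] for lin in n_genomes}
    return CensusTable(cells=cells, n_genomes=n_genomes, per_genome=per_genome)


def family_fractions(table: CensusTable) -> dict[str, float]:
    """Each family's share of the total NAP pool, in percent to one decimal."""
    grand = table.grand_total
    if grand <= 0:
        raise ValueError("census grand total is zero; fractions undefined")
    return {fam: round(100.0 * tot / grand, 1)
            for fam, tot in sorted(table.family_totals().items())}
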