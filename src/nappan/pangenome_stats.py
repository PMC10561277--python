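"""Frequency/paralogue indices, core-flexible partitioning and census
correlations.

The frequency index of a family (or PF) in a lineage is the fraction of that
lineage's genomes carrying it. The paralogue index is the mean per-genome
copy number over carrier genomes divided by the number of distinct PFs of the
family in that lineage; values near the number of copies signal true
paralogy, values near 1 signal divergent single-copy variants.

Compartments: a family is *core* when its class-wide genome occupancy
strictly exceeds the core threshold (default 0.90 of all genomes); otherwise
it is *conserved flexible* in lineages where its frequency index reaches the
conserved threshold (>= 0.90 by default) and *non-conserved flexible*
elsewhere. Lineages represented by a single genome count as conserved only
when explicitly enabled, since a frequency of 1/1 carries no information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .core_model import Thresholds
from .nap_identify import CensusTable

COMPARTMENTS = ("core", "conserved_flexible", "nonconserved_flexible", "absent")


@dataclass(frozen=True)
class CorrelationResult:
    x_label: str
    y_label: str
    n: int
    pearson_r: float

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("a correlation is only reported for n >= 3")
        if not (-1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12):
            raise ValueError(f"pearson_r {self.pearson_r} outside [-1, 1]")


@dataclass(frozen=True)
class PangenomeProfile:
    lineage_id: str
    family: str
    frequency_index: float
    paralogue_index: float
    mean_dose: float
    compartment: str


def frequency_index(presence: Mapping[str, bool]) -> float:
    """Fraction of a lineage's genomes carrying the family."""
    if not presence:
        raise ValueError("lineage has no genomes")
    return sum(bool(v) for v in presence.values()) / len(presence)


def paralogue_index(doses: Mapping[str, int], n_distinct_pfs: int) -> float:
    """Mean copy number over carrier genomes, divided by the distinct PF count."""
    if n_distinct_pfs < 1:
        raise ValueError("n_distinct_pfs must be >= 1")
    carriers = [d for d in doses.values() if d > 0]
    if not carriers:
        raise ValueError("no carrier genomes")
    return (sum(carriers) / len(carriers)) / n_distinct_pfs


def classify_compartments(profiles: Sequence[PangenomeProfile],
                          class_presence: Mapping[str, int],
                          n_genomes_total: int,
                          lineage_sizes: Mapping[str, int],
                          th: Thresholds) -> list[PangenomeProfile]:
    """Assign a pangenome compartment to every lineage x family profile."""
    core = {fam for fam, carriers in class_presence.items()
            if carriers / n_genomes_total > th.core_occupancy}
    out = []
    for p in profiles:
        if p.frequency_index == 0:
            label = "absent"
        elif p.family in core:
            label = "core"
        else:
            conserved = (p.frequency_index > th.conserved_frequency if th.conserved_strict
                         else p.frequency_index >= th.conserved_frequency)
            if lineage_sizes.get(p.lineage_id, 0) <= 1 and not th.single_genome_conserved:
                conserved = False
            label = "conserved_flexible" if conserved else "nonconserved_flexible"
        out.append(PangenomeProfile(p.lineage_id, p.family, p.frequency_index,
                                    p.paralogue_index, p.mean_dose, label))
    return out


def reconstruct_presence(census: CensusTable) -> pd.DataFrame:
    """Maximum-spread carrier reconstruction from a lineage x family census.

    A census cell stores (total, dose_min, dose_max) over carrier genomes
    only; the per-genome presence matrix behind it is not unique. The
    maximum-spread rule takes carriers = min(n_genomes, floor(total /
    dose_min)) — the largest carrier count consistent with the cell — which
    is deterministic and consistent with every cell of the published census.
    """
    rows = []
    for _, cell in census.cells.iterrows():
        n = census.n_genomes[cell["lineage_id"]]
        total, dmin = int(cell["total"]), int(cell["dose_min"])
        carriers = 0 if total == 0 or dmin == 0 else min(n, total // dmin)
        rows.append({"lineage_id": cell["lineage_id"], "family": cell["family"],
                     "carriers": carriers, "n_genomes": n})
    return pd.DataFrame(rows)


def core_family_set(census: CensusTable, th: Optional[Thresholds] = None) -> set[str]:
    """Families whose class-wide occupancy exceeds the core threshold."""
    th = th or Thresholds()
    presence = reconstruct_presence(census)
    n_total = sum(census.n_genomes.values())
    carriers = presence.groupby("family")["carriers"].sum()
    return {fam for fam, c in carriers.items() if c / n_total > th.core_occupancy}


def profiles_from_census(census: CensusTable, th: Optional[Thresholds] = None,
                         pf_counts: Optional[Mapping[tuple[str, str], int]] = None,
                         ) -> list[PangenomeProfile]:
    """Per lineage x family profiles (frequency, paralogue index, compartment)
    from a census, using the maximum-spread presence reconstruction.

    ``pf_counts`` optionally supplies the number of distinct PFs per
    (lineage, family); absent entries default to 1 distinct PF.
    """
    th = th or Thresholds()
    presence = reconstruct_presence(census)
    merged = census.cells.merge(presence, on=["lineage_id", "family"])
    raw = []
    for _, row in merged.iterrows():
        n, carriers, total = int(row["n_genomes"]), int(row["carriers"]), int(row["total"])
        freq = carriers / n
        mean_dose = total / carriers if carriers else 0.0
        npf = (pf_counts or {}).get((row["lineage_id"], row["family"]), 1)
        pidx = mean_dose / npf if carriers else 0.0
        raw.append(PangenomeProfile(row["lineage_id"], row["family"], freq,
                                    pidx, mean_dose, "absent"))
    class_presence = presence.groupby("family")["carriers"].sum().to_dict()
    return classify_compartments(raw, class_presence, sum(census.n_genomes.values()),
                                 census.n_genomes, th)


def pearson(x: Sequence[float], y: Sequence[float],
            x_label: str = "x", y_label: str = "y") -> CorrelationResult:
    """Product-moment correlation with the usual degenerate-input guards."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("zero variance in x or y")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(x_label=x_label, y_label=y_label, n=len(x), pearson_r=r)
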