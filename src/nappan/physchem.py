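"""Sequence-based molecular weight and isoelectric point, and the
lineage-level pI versus optimal-growth-pH correlation.

The theoretical pI is the pH at which the protein's net charge, modeled by
Henderson-Hasselbalch terms for the ionizable side chains and both termini,
crosses zero. Net charge is strictly decreasing in pH, so the root found by
bisection is unique.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from Bio.SeqUtils import molecular_weight as _bio_mw

from .pangenome_stats import CorrelationResult, pearson

# pKa constants of the classic EMBOSS-style pI calculator.
PKA_BASIC = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_ACIDIC = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinPhyschem:
    protein_id: str
    length_aa: int
    mw_da: float
    pi: float

    def __post_init__(self):
        if self.mw_da <= 0:
            raise ValueError("mw_da must be positive")
        if not (0 < self.pi < 14):
            raise ValueError("pI outside (0, 14)")


def _check_seq(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)}")


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Daltons (residue masses plus one water)."""
    _check_seq(seq)
    return float(_bio_mw(seq, seq_type="protein"))


def net_charge(seq: str, ph: float) -> float:
    """Net charge at a given pH from Henderson-Hasselbalch terms."""
    _check_seq(seq)
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_BASIC["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_ACIDIC["Cterm"] - ph))
    for aa in seq:
        if aa in PKA_BASIC:
            charge += 1.0 / (1.0 + 10 ** (ph - PKA_BASIC[aa]))
        elif aa in PKA_ACIDIC:
            charge -= 1.0 / (1.0 + 10 ** (PKA_ACIDIC[aa] - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    _check_seq(seq)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def protein_physchem(protein_id: str, seq: str) -> ProteinPhyschem:
    return ProteinPhyschem(protein_id=protein_id, length_aa=len(seq),
                           mw_da=molecular_weight(seq), pi=isoelectric_point(seq))


def pi_ph_correlation(lineage_median_pi: Mapping[str, float],
                      optimal_ph: Mapping[str, float],
                      acidophile_cutoff: Optional[float] = None,
                      ) -> dict:
    """Pearson r between per-lineage median pI and optimal growth pH.

    With ``acidophile_cutoff`` set, also reports the correlation computed
    separately for lineages at or below versus above the cut-off (where at
    least 3 lineages fall on a side), mirroring the acidophile /
    mild-acidophile split.
    """
    shared = sorted(set(lineage_median_pi) & set(optimal_ph))
    if len(shared) < 3:
        raise ValueError("need >= 3 lineages with both median pI and optimal pH")
    pis = [lineage_median_pi[l] for l in shared]
    phs = [optimal_ph[l] for l in shared]
    out = {"overall": pearson(phs, pis, "optimal_growth_ph", "median_pi")}
    if acidophile_cutoff is not None:
        lo = [l for l in shared if optimal_ph[l] <= acidophile_cutoff]
        hi = [l for l in shared if optimal_ph[l] > acidophile_cutoff]
        for label, group in (("acidophiles", lo), ("mild_acidophiles", hi)):
            if len(group) >= 3:
                try:
                    out[label] = pearson([optimal_ph[l] for l in group],
                                         [lineage_median_pi[l] for l in group],
                                         "optimal_growth_ph", "median_pi")
                except ValueError:
                    pass  # zero variance within the split
    return out


def lineage_median_pi(pis_by_lineage: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Median pI per lineage over validated family members."""
    import statistics
    return {lin: statistics.median(vals) for lin, vals in pis_by_lineage.items() if vals}
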