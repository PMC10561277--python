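"""Synthetic pangenomes, marker sequences and coverage tracks with known
ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-lineage family presence fractions with per-genome copy-number
(dose) ranges; mobile regions carrying hallmark genes with flexible-family
copies embedded in them; decoy domain hits above the validation thresholds;
site-independent sequence evolution of marker families along a known tree;
and Poisson read-depth tracks with designated high/low-expression genes.
Every emitted dataset comes with a TruthTable so recovery can be scored.

All randomness flows from one integer seed through a single NumPy generator,
so identical spec + seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import dendropy
import numpy as np

from .core_model import (DomainHit, GeneFeature, GenomeRecord, Replicon,
                         load_fixture)
from .mge_assoc import MGERegion

AA_ALPHABET = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")

_HALLMARK_CYCLE = ("relaxase", "t4ss", "integrase", "toxin_antitoxin", "parA")
_HALLMARK_KEGG = {"relaxase": "K03427x_mob", "t4ss": "K03194", "integrase": "K04763",
                  "toxin_antitoxin": "K06218", "parA": "K03496"}


@dataclass(frozen=True)
class LineageSpec:
    lineage_id: str
    n_genomes: int
    mean_genome_size_bp: float = 3_000_000.0
    size_sd: float = 200_000.0

    def __post_init__(self):
        if self.n_genomes < 1:
            raise ValueError(f"lineage {self.lineage_id}: n_genomes must be >= 1")


@dataclass(frozen=True)
class FamilySpec:
    family: str
    presence_fraction: Union[float, Mapping[str, float]]
    dose_range: Union[tuple[int, int], Mapping[str, tuple[int, int]]] = (1, 1)
    flexible: bool = False

    def presence(self, lineage_id: str) -> float:
        p = self.presence_fraction
        f = p.get(lineage_id, 0.0) if isinstance(p, Mapping) else float(p)
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"family {self.family}: presence fraction {f} outside [0, 1]")
        return f

    def dose(self, lineage_id: str) -> tuple[int, int]:
        d = self.dose_range
        lo, hi = d.get(lineage_id, (1, 1)) if isinstance(d, Mapping) else d
        if lo > hi:
            raise ValueError(f"family {self.family}: dose min {lo} > max {hi}")
        return int(lo), int(hi)


@dataclass
class PangenomeSpec:
    lineages: list[LineageSpec]
    families: list[FamilySpec]
    mge_rate: float = 0.0
    flexible_in_mge_fraction: float = 0.0
    mge_nap_rate: float = 0.0
    mge_nap_families: tuple[str, ...] = ("HU", "IHF_A", "IHF_B")
    hallmark_vicinity_rate: float = 1.0
    decoy_fraction: float = 0.10
    background_genes_per_genome: int = 5
    naps_scale_with_size: bool = False
    size_coupled_families: tuple[str, ...] = ("HU", "IHF_A", "IHF_B")
    transposase_rate: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.mge_rate < 0 or self.mge_nap_rate < 0:
            raise ValueError("mge_rate and mge_nap_rate must be >= 0")
        for name in ("flexible_in_mge_fraction", "hallmark_vicinity_rate", "decoy_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class TruthTable:
    copy_numbers: dict            # genome_id -> {family: copies}
    genome_of: dict               # protein_id -> genome_id
    gene_of: dict                 # protein_id -> gene_id
    mge_membership: dict          # protein_id -> element_id or None
    vicinity: dict                # protein_id -> [(gene_id, hallmark role)]
    genes: dict                   # genome_id -> [GeneFeature]
    regions: dict                 # genome_id -> [MGERegion]
    hallmark_counts: dict         # genome_id -> {role: count}
    tree_newick: Optional[str] = None
    expression: Optional[dict] = None  # gene_id -> multiplier
    seed: Optional[int] = None

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "copy_numbers": self.copy_numbers,
            "genome_of": self.genome_of,
            "gene_of": self.gene_of,
            "mge_membership": self.mge_membership,
            "vicinity": self.vicinity,
            "hallmark_counts": self.hallmark_counts,
            "tree_newick": self.tree_newick,
            "expression": self.expression,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _place_gene(rng: np.random.Generator, lo: int, hi: int, length: int) -> tuple[int, int]:
    """Random gene span of `length` bp with its start in [lo, hi]."""
    start = int(rng.integers(lo, max(lo + 1, hi - length)))
    return start, start + length - 1


def generate_pangenome(spec: PangenomeSpec,
                       ) -> tuple[list[GenomeRecord], list[DomainHit], TruthTable]:
    """Generate genomes, domain-hit tables and ground truth from a spec.

    For each lineage x family a genome carries the family with the stated
    presence probability at a dose drawn uniformly from the dose range.
    Flexible-family copies land inside mobile regions with probability
    ``flexible_in_mge_fraction``; each such copy gets a hallmark gene planted
    within the 5-kb vicinity window at ``hallmark_vicinity_rate``. True NAPs
    get domain hits far below the validation thresholds; a ``decoy_fraction``
    of genes get a decoy hit with e-value log-uniform in [1e-4, 1], above the
    1e-5 cut-off.
    """
    rng = np.random.default_rng(spec.seed)
    genomes: list[GenomeRecord] = []
    hits: list[DomainHit] = []
    truth = TruthTable(copy_numbers={}, genome_of={}, gene_of={}, mge_membership={},
                       vicinity={}, genes={}, regions={}, hallmark_counts={},
                       seed=spec.seed)

    for lin in spec.lineages:
        for g_idx in range(lin.n_genomes):
            genome_id = f"{lin.lineage_id}_{g_idx:03d}"
            z = float(rng.normal())
            size = max(500_000, int(round(lin.mean_genome_size_bp + lin.size_sd * z)))
            rep_id = f"{genome_id}_chr"
            replicon = Replicon(replicon_id=rep_id, length_bp=size, topology="circular",
                                kind="chromosome", ori_pos=1, ter_pos=size // 2)
            genes: list[GeneFeature] = []
            regions: list[MGERegion] = []
            hallmarks: dict[str, int] = {r: 0 for r in _HALLMARK_CYCLE}
            hallmarks["transposase"] = 0
            gene_no = 0

            def new_gene(lo, hi, product="", kegg=None, length=None):
                nonlocal gene_no
                gene_no += 1
                length = int(length if length is not None else rng.integers(300, 2400))
                start, end = _place_gene(rng, lo, min(hi, size - length - 1), length)
                gf = GeneFeature(gene_id=f"{genome_id}_g{gene_no:04d}", replicon_id=rep_id,
                                 start=start, end=end,
                                 strand="+" if rng.random() < 0.5 else "-",
                                 product=product, kegg_id=kegg)
                genes.append(gf)
                return gf

            def plant_vicinity_hallmark(gf):
                """Hallmark gene within the 5-kb window downstream of a NAP."""
                nonlocal gene_no
                if rng.random() >= spec.hallmark_vicinity_rate:
                    return
                role = _HALLMARK_CYCLE[int(rng.integers(len(_HALLMARK_CYCLE)))]
                gap = int(rng.integers(200, 3000))
                h_start = min(gf.end + gap, size - 1200)
                gene_no += 1
                hg = GeneFeature(gene_id=f"{genome_id}_g{gene_no:04d}", replicon_id=rep_id,
                                 start=h_start, end=h_start + 900, strand="+",
                                 product=role, kegg_id=_HALLMARK_KEGG[role])
                genes.append(hg)
                hallmarks[role] += 1
                truth.vicinity.setdefault(gf.gene_id, []).append((hg.gene_id, role))

            def emit_nap(gf, family, element_id=None):
                truth.mge_membership[gf.gene_id] = element_id
                truth.genome_of[gf.gene_id] = genome_id
                truth.gene_of[gf.gene_id] = gf.gene_id
                hits.append(DomainHit(
                    protein_id=gf.gene_id, profile_id=family,
                    evalue=float(10 ** rng.uniform(-30, -10)),
                    probability=float(rng.uniform(95, 100)),
                    coverage=float(rng.uniform(0.8, 1.0))))

            # mobile regions with hallmark complements and MGE-borne NAP cargo
            copy_numbers: dict[str, int] = {fam.family: 0 for fam in spec.families}
            n_mge = int(rng.poisson(spec.mge_rate))
            for m in range(n_mge):
                span = int(np.exp(rng.uniform(np.log(10_000), np.log(300_000))))
                span = min(span, size // 3)
                start = int(rng.integers(1, size - span))
                region = MGERegion(element_id=f"{genome_id}_mge{m + 1}", replicon_id=rep_id,
                                   start=start, end=start + span - 1)
                hallmark_ids = []
                region_roles = ["relaxase", "integrase"] + (["t4ss"] if rng.random() < 0.5 else [])
                for role in region_roles:
                    hg = new_gene(region.start, region.end, product=role,
                                  kegg=_HALLMARK_KEGG.get(role))
                    hallmarks[role] += 1
                    hallmark_ids.append((hg.gene_id, role))
                region.hallmark_genes = hallmark_ids
                regions.append(region)
                for _ in range(int(rng.poisson(spec.mge_nap_rate))):
                    fam_name = spec.mge_nap_families[int(rng.integers(len(spec.mge_nap_families)))]
                    gf = new_gene(region.start, region.end, product=fam_name,
                                  length=int(rng.integers(240, 900)))
                    copy_numbers[fam_name] = copy_numbers.get(fam_name, 0) + 1
                    emit_nap(gf, fam_name, region.element_id)
                    plant_vicinity_hallmark(gf)

            # unlinked transposases (translocative background)
            for _ in range(int(rng.poisson(spec.transposase_rate))):
                new_gene(1, size, product="transposase")
                hallmarks["transposase"] += 1

            # background housekeeping genes
            for _ in range(spec.background_genes_per_genome):
                new_gene(1, size, product="housekeeping")

            # lineage-level NAP family complements
            for fam in spec.families:
                f = fam.presence(lin.lineage_id)
                if rng.random() >= f:
                    continue
                lo, hi = fam.dose(lin.lineage_id)
                dose = int(rng.integers(lo, hi + 1))
                if spec.naps_scale_with_size and fam.family in spec.size_coupled_families:
                    dose += max(0, int(round(z)))
                copy_numbers[fam.family] = copy_numbers.get(fam.family, 0) + dose
                for _c in range(dose):
                    in_mge = (fam.flexible and regions
                              and rng.random() < spec.flexible_in_mge_fraction)
                    if in_mge:
                        region = regions[int(rng.integers(len(regions)))]
                        gf = new_gene(region.start, region.end, product=fam.family,
                                      length=int(rng.integers(240, 900)))
                        emit_nap(gf, fam.family, region.element_id)
                        plant_vicinity_hallmark(gf)
                    else:
                        gf = new_gene(1, size, product=fam.family,
                                      length=int(rng.integers(240, 900)))
                        emit_nap(gf, fam.family, None)

            # decoy hits on a fraction of the gene complement, above thresholds
            for gf in genes:
                if gf.gene_id not in truth.genome_of and rng.random() < spec.decoy_fraction:
                    hits.append(DomainHit(
                        protein_id=gf.gene_id, profile_id="DUF_decoy",
                        evalue=float(10 ** rng.uniform(-4, 0)),
                        probability=float(rng.uniform(95, 100)),
                        coverage=float(rng.uniform(0.8, 1.0))))

            genomes.append(GenomeRecord(genome_id=genome_id, lineage_id=lin.lineage_id,
                                        genome_size_bp=size, replicons=(replicon,)))
            truth.copy_numbers[genome_id] = copy_numbers
            truth.genes[genome_id] = sorted(genes, key=lambda g: (g.start, g.gene_id))
            truth.regions[genome_id] = regions
            truth.hallmark_counts[genome_id] = hallmarks
    return genomes, hits, truth


def generate_marker_sequences(tree_newick: str, root_seq_length: int,
                              subst_rate: float, seed: int) -> dict[str, str]:
    """Evolve an aligned protein marker along a tree (one sequence per leaf).

    Per branch, each site is replaced with probability 1 - exp(-rate x
    branch_length), the replacement drawn uniformly over the 19 other
    residues, so the expected p-distance between two leaves at patristic
    distance d is analytic and indels never occur (output is an alignment).
    """
    if root_seq_length < 50:
        raise ValueError("root_seq_length must be >= 50")
    if subst_rate < 0:
        raise ValueError("subst_rate must be >= 0")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    root_states = rng.integers(0, 20, size=root_seq_length)
    states = {id(tree.seed_node): root_states}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = root_states
        else:
            parent = states[id(node.parent_node)]
            bl = node.edge.length or 0.0
            p = 1.0 - math.exp(-subst_rate * bl)
            mask = rng.random(root_seq_length) < p
            seq = parent.copy()
            if mask.any():
                shift = rng.integers(0, 19, size=int(mask.sum()))
                seq[mask] = (parent[mask] + 1 + shift) % 20
        states[id(node)] = seq
        if node.is_leaf():
            out[node.taxon.label] = AA_ALPHABET[seq].tobytes().decode()
    return dict(sorted(out.items()))


def generate_coverage(genome: GenomeRecord, genes: Sequence[GeneFeature],
                      expression_map: Mapping[str, float], mean_depth: float,
                      seed: int, baseline: float = 1.0) -> dict[str, np.ndarray]:
    """Poisson per-base depth: mean_depth x multiplier inside mapped genes,
    mean_depth x baseline elsewhere. Returns per-replicon depth arrays."""
    if mean_depth < 0 or baseline < 0:
        raise ValueError("depth parameters must be >= 0")
    if any(m < 0 for m in expression_map.values()):
        raise ValueError("expression multipliers must be >= 0")
    rng = np.random.default_rng(seed)
    tracks = {}
    for rep in genome.replicons:
        mult = np.full(rep.length_bp, baseline, dtype=float)
        for g in genes:
            if g.replicon_id == rep.replicon_id and g.gene_id in expression_map:
                mult[g.start - 1: g.end] = expression_map[g.gene_id]
        tracks[rep.replicon_id] = rng.poisson(mean_depth * mult).astype(float)
    return tracks


def table1_spec(seed: int = 0, mean_genome_size_bp: float = 3_000_000.0,
                size_sd: float = 200_000.0) -> PangenomeSpec:
    """A PangenomeSpec whose expected census reproduces the packaged
    class-wide census fixture (maximum-spread carrier reconstruction)."""
    table1 = load_fixture("table1_census")
    lineages = []
    presence: dict[str, dict[str, float]] = {}
    doses: dict[str, dict[str, tuple[int, int]]] = {}
    for lin_id, sub in table1.groupby("lineage_id", sort=False):
        n = int(sub["n_genomes"].iloc[0])
        lineages.append(LineageSpec(lineage_id=lin_id, n_genomes=n,
                                    mean_genome_size_bp=mean_genome_size_bp,
                                    size_sd=size_sd))
        for _, row in sub.iterrows():
            fam, total, dmin, dmax = row["family"], int(row["total"]), int(row["dose_min"]), int(row["dose_max"])
            carriers = 0 if total == 0 or dmin == 0 else min(n, total // dmin)
            presence.setdefault(fam, {})[lin_id] = carriers / n
            doses.setdefault(fam, {})[lin_id] = (dmin, dmax) if dmin else (1, 1)
    families = [FamilySpec(family=fam, presence_fraction=presence[fam],
                           dose_range=doses[fam]) for fam in presence]
    return PangenomeSpec(lineages=lineages, families=families, seed=seed)
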