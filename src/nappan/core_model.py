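"""Shared domain types and readers/writers for the pipeline's file formats.

Coordinates are 1-based inclusive everywhere internally (GFF3 convention);
bedGraph intervals are 0-based half-open on disk and converted on read/write.
Strand is stored but ignored by all distance computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

try:  # package-data access; falls back to path-relative lookup for dev trees
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

#: The 12 NAP families tallied in the class-wide census, in census column order.
NAP_FAMILIES = (
    "EbfC", "Fis", "H-NS", "HU", "IHF_A", "IHF_B",
    "Lrp", "SMC", "Alba_2", "KfrA", "NdpA", "MukB",
)


class ParseError(ValueError):
    """A malformed record in an input file; message names the line number."""


class InvariantError(ValueError):
    """A record violating a domain-type invariant."""


@dataclass(frozen=True)
class Replicon:
    replicon_id: str
    length_bp: int
    topology: str = "circular"  # {circular, linear}
    kind: str = "chromosome"    # {chromosome, plasmid, contig}
    ori_pos: Optional[int] = None
    ter_pos: Optional[int] = None

    def __post_init__(self):
        if self.length_bp <= 0:
            raise InvariantError(f"replicon {self.replicon_id}: length_bp must be > 0")
        if self.topology not in ("circular", "linear"):
            raise InvariantError(f"replicon {self.replicon_id}: bad topology {self.topology!r}")
        if self.kind not in ("chromosome", "plasmid", "contig"):
            raise InvariantError(f"replicon {self.replicon_id}: bad kind {self.kind!r}")
        for name, pos in (("ori_pos", self.ori_pos), ("ter_pos", self.ter_pos)):
            if pos is not None and not (1 <= pos <= self.length_bp):
                raise InvariantError(f"replicon {self.replicon_id}: {name}={pos} outside [1, {self.length_bp}]")


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    kegg_id: Optional[str] = None
    protein_seq: Optional[str] = None

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise InvariantError(
                f"gene {self.gene_id}: require 1 <= start <= end, got start={self.start}, end={self.end}")
        if self.strand not in ("+", "-"):
            raise InvariantError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    lineage_id: str
    genome_size_bp: int = 0
    completeness_pct: Optional[float] = None
    optimal_growth_ph: Optional[float] = None
    replicons: tuple[Replicon, ...] = ()

    def __post_init__(self):
        if not self.lineage_id:
            raise InvariantError(f"genome {self.genome_id}: lineage_id must be non-empty")
        if self.genome_size_bp < 0:
            raise InvariantError(f"genome {self.genome_id}: genome_size_bp must be >= 0")

    def replicon(self, replicon_id: str) -> Replicon:
        for rep in self.replicons:
            if rep.replicon_id == replicon_id:
                return rep
        raise KeyError(replicon_id)


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    profile_id: str
    evalue: float
    probability: Optional[float] = None  # percent, 0-100
    coverage: Optional[float] = None     # fraction, 0-1

    def __post_init__(self):
        if self.evalue < 0:
            raise InvariantError(f"hit {self.protein_id}/{self.profile_id}: evalue must be >= 0")
        if self.probability is not None and not (0 <= self.probability <= 100):
            raise InvariantError(f"hit {self.protein_id}/{self.profile_id}: probability outside [0, 100]")


@dataclass(frozen=True)
class NAPCandidate:
    protein_id: str
    genome_id: str
    family: str
    best_hit: DomainHit
    gene_id: Optional[str] = None

    def __post_init__(self):
        if self.family != self.best_hit.profile_id:
            raise InvariantError(
                f"candidate {self.protein_id}: family {self.family!r} != best hit profile {self.best_hit.profile_id!r}")


@dataclass(frozen=True)
class Thresholds:
    """All pipeline cut-offs in one place; YAML-serializable.

    e-values are upper bounds, probability (percent) and coverage (fraction)
    lower bounds. ``core_occupancy`` uses a strict ``>`` comparison;
    ``conserved_frequency`` uses ``>=`` by default (``conserved_strict``
    switches it to ``>``).
    """
    psiblast_evalue: float = 0.01
    validation_evalue: float = 1e-5
    validation_probability: float = 90.0
    bbh_coverage: float = 0.75
    bbh_evalue: float = 1e-5
    identity_cluster_threshold: float = 0.50
    core_occupancy: float = 0.90
    conserved_frequency: float = 0.90
    conserved_strict: bool = False
    single_genome_conserved: bool = False
    vicinity_window_bp: int = 5000
    coverage_bin_bp: int = 10

    def __post_init__(self):
        for name in ("bbh_coverage", "identity_cluster_threshold", "core_occupancy", "conserved_frequency"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InvariantError(f"threshold {name}={v} outside [0, 1]")
        if not (0 <= self.validation_probability <= 100):
            raise InvariantError("validation_probability outside [0, 100]")
        if self.vicinity_window_bp <= 0 or self.coverage_bin_bp <= 0:
            raise InvariantError("vicinity_window_bp and coverage_bin_bp must be positive")

    @classmethod
    def from_yaml(cls, path) -> "Thresholds":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"{path}: unknown threshold keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

_TSV_GENE_COLUMNS = ("gene_id", "replicon_id", "start", "end", "strand", "product", "kegg_id", "protein_seq")


def _parse_gff3_attributes(text: str) -> dict:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gene_table(path, format: str = "gff3") -> list[GeneFeature]:
    """Read gene features from GFF3 or a plain TSV; sorted by (replicon, start)."""
    path = Path(path)
    if format == "gff3":
        feats = _read_gff3(path)
    elif format == "tsv":
        feats = _read_gene_tsv(path)
    else:
        raise ValueError(f"unknown gene-table format {format!r}")
    return sorted(feats, key=lambda g: (g.replicon_id, g.start, g.gene_id))


def _read_gff3(path: Path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            if ftype not in ("CDS", "gene"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            attrs = _parse_gff3_attributes(attrs_s)
            gene_id = attrs.get("ID") or attrs.get("locus_tag") or f"{seqid}:{start}-{end}"
            try:
                feats.append(GeneFeature(
                    gene_id=gene_id, replicon_id=seqid, start=start, end=end,
                    strand=strand if strand in ("+", "-") else "+",
                    product=attrs.get("product", ""), kegg_id=attrs.get("kegg") or attrs.get("Ontology_term")))
            except InvariantError as exc:
                raise InvariantError(f"{path}:{lineno}: {exc}") from None
    return feats


def _read_gene_tsv(path: Path) -> list[GeneFeature]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"gene_id", "replicon_id", "start", "end"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    feats = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # 1-based, after header
        try:
            feats.append(GeneFeature(
                gene_id=row["gene_id"], replicon_id=row["replicon_id"],
                start=int(row["start"]), end=int(row["end"]),
                strand=row.get("strand", "+") or "+",
                product=row.get("product", "") or "",
                kegg_id=(row.get("kegg_id") or None),
                protein_seq=(row.get("protein_seq") or None)))
        except (ValueError, InvariantError) as exc:
            raise type(exc)(f"{path}:{lineno}: {exc}") from None
    return feats


def write_gene_table(features: Iterable[GeneFeature], path) -> None:
    rows = [{c: getattr(g, c) if getattr(g, c) is not None else "" for c in _TSV_GENE_COLUMNS}
            for g in features]
    pd.DataFrame(rows, columns=list(_TSV_GENE_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Domain-hit tables
# ---------------------------------------------------------------------------

_HIT_COLUMNS = ("protein_id", "profile_id", "evalue", "probability", "coverage")


def read_domain_hits(path) -> list[DomainHit]:
    """Read a domain-hit TSV; empty probability/coverage fields parse as absent."""
    import warnings

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"protein_id", "profile_id", "evalue"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    extra = set(df.columns) - set(_HIT_COLUMNS)
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {sorted(extra)}", stacklevel=2)
    hits = []
    for idx, row in df.iterrows():
        lineno = idx + 2
        try:
            hits.append(DomainHit(
                protein_id=row["protein_id"], profile_id=row["profile_id"],
                evalue=float(row["evalue"]),
                probability=float(row["probability"]) if row.get("probability", "") != "" else None,
                coverage=float(row["coverage"]) if row.get("coverage", "") != "" else None))
        except (ValueError, InvariantError) as exc:
            raise type(exc)(f"{path}:{lineno}: {exc}") from None
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path) -> None:
    rows = [{"protein_id": h.protein_id, "profile_id": h.profile_id, "evalue": repr(h.evalue),
             "probability": "" if h.probability is None else h.probability,
             "coverage": "" if h.coverage is None else h.coverage}
            for h in hits]
    pd.DataFrame(rows, columns=list(_HIT_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph coverage tracks
# ---------------------------------------------------------------------------

def read_bedgraph(path, replicon_lengths: Optional[dict] = None) -> dict:
    """Read a bedGraph into per-replicon per-base depth arrays (1-based internally).

    On-disk intervals are 0-based half-open. ``replicon_lengths`` fixes the
    array sizes; otherwise the largest end coordinate seen per replicon is used.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
            rep, s, e, v = cols
            try:
                s, e, v = int(s), int(e), float(v)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed interval") from None
            if e < s:
                raise ParseError(f"{path}:{lineno}: end < start")
            intervals.setdefault(rep, []).append((s, e, v))
    out = {}
    for rep, ivals in intervals.items():
        n = replicon_lengths[rep] if replicon_lengths else max(e for _, e, _ in ivals)
        depth = np.zeros(n, dtype=float)
        for s, e, v in ivals:
            depth[s:e] = v
        out[rep] = depth
    return out


def write_bedgraph(tracks: dict, path) -> None:
    """Write per-replicon per-base depth arrays as run-length-merged bedGraph."""
    with open(path, "w") as fh:
        for rep in sorted(tracks):
            depth = np.asarray(tracks[rep], dtype=float)
            if depth.size == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [depth.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{rep}\t{s}\t{e}\t{depth[s]:g}\n")


# ---------------------------------------------------------------------------
# Packaged fixtures (transcribed from the published census/element tables)
# ---------------------------------------------------------------------------

_FIXTURES = {
    "table1_census": "table1_census.tsv",
    "table3_plasmids": "table3_plasmids.tsv",
    "table4_imges": "table4_imges.tsv",
    "orit_region": "orit_region_synthetic.fna",
}


def _fixture_path(filename: str) -> Path:
    if _pkg_files is not None:
        return Path(str(_pkg_files("nappan").joinpath("fixtures", filename)))
    return Path(__file__).parent / "fixtures" / filename  # pragma: no cover


def _parse_census_cell(cell: str) -> tuple[int, int, int]:
    """Parse a census cell 'total (min-max)' or 'total (d)' into integers."""
    cell = cell.strip()
    total_s, _, dose_s = cell.partition("(")
    total = int(total_s)
    dose_s = dose_s.rstrip(")")
    if "-" in dose_s:
        lo, hi = dose_s.split("-")
        return total, int(lo), int(hi)
    d = int(dose_s)
    return total, d, d


def load_fixture(name: str):
    """Load a packaged table fixture as a tidy pandas DataFrame.

    * ``table1_census`` — one row per lineage x family with columns
      ``lineage_id, n_genomes, total_naps, naps_median, naps_min, naps_max,
      family, total, dose_min, dose_max``.
    * ``table3_plasmids`` — one row per plasmid replicon with a NAP count and
      semicolon-separated family list.
    * ``table4_imges`` — one row per integrated element with its family list.
    * ``orit_region`` — a synthetic transfer-origin-like DNA sequence (string)
      carrying two planted inverted repeats.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    path = _fixture_path(_FIXTURES[name])
    if name == "orit_region":
        lines = path.read_text().splitlines()
        return "".join(l.strip() for l in lines if not l.startswith(">"))
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if name == "table1_census":
        long_rows = []
        for _, row in df.iterrows():
            rng = row["naps_range"]
            lo, _, hi = rng.partition("-")
            for fam in NAP_FAMILIES:
                total, dmin, dmax = _parse_census_cell(row[fam])
                long_rows.append({
                    "lineage_id": row["lineage_id"], "n_genomes": int(row["n_genomes"]),
                    "total_naps": int(row["total_naps"]), "naps_median": float(row["naps_median"]),
                    "naps_min": int(lo), "naps_max": int(hi or lo),
                    "family": fam, "total": total, "dose_min": dmin, "dose_max": dmax})
        return pd.DataFrame(long_rows)
    if name == "table3_plasmids":
        df = df.assign(size_kb=df["size_kb"].astype(float), n_cds=df["n_cds"].astype(int),
                       n_naps=df["n_naps"].astype(int))
        return df
    df = df.assign(size_kb=df["size_kb"].astype(float), n_cds=df["n_cds"].astype(int))
    return df
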