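"""Coverage binning and 1x (reads-per-genomic-content) normalization.

Depth tracks are binned (10 bp by default), then scaled by the genome-wide
mean depth over an effective genome size so the normalized genome average is
exactly 1.0; a gene's mean normalized coverage is then directly its
expression relative to the whole-genome average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_model import GeneFeature


@dataclass
class CoverageTrack:
    replicon_id: str
    bin_size_bp: int
    bins: np.ndarray                 # normalized coverage per bin
    effective_genome_size_bp: int
    genome_mean_raw: float
    track_length_bp: int

    def per_base(self) -> np.ndarray:
        out = np.repeat(self.bins, self.bin_size_bp)
        return out[: self.track_length_bp]


def bin_coverage(depth: Sequence[float], bin_size: int = 10) -> np.ndarray:
    """Mean per-base depth per bin; a final partial bin is averaged over its
    actual width."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    depth = np.asarray(depth, dtype=float)
    if depth.ndim != 1 or depth.size == 0:
        raise ValueError("depth must be a non-empty 1-D array")
    if (depth < 0).any():
        raise ValueError("depth values must be >= 0")
    n_full = depth.size // bin_size
    bins = []
    if n_full:
        bins.append(depth[: n_full * bin_size].reshape(n_full, bin_size).mean(axis=1))
    if depth.size % bin_size:
        bins.append([depth[n_full * bin_size:].mean()])
    return np.concatenate(bins)


def rpgc_normalize(raw_bins: Sequence[float], effective_genome_size: Optional[int] = None,
                   bin_size: int = 10, track_length_bp: Optional[int] = None,
                   replicon_id: str = "") -> CoverageTrack:
    """Scale binned depth so the genome-wide average coverage is 1x.

    The scaling factor is the total per-base signal divided by the effective
    genome size (default: the track length), i.e. the genome-wide mean depth.
    """
    raw_bins = np.asarray(raw_bins, dtype=float)
    if track_length_bp is None:
        track_length_bp = raw_bins.size * bin_size
    widths = np.full(raw_bins.size, bin_size, dtype=float)
    if track_length_bp < raw_bins.size * bin_size:
        widths[-1] = track_length_bp - (raw_bins.size - 1) * bin_size
    total_signal = float((raw_bins * widths).sum())
    if total_signal <= 0:
        raise ValueError("zero total signal; cannot normalize")
    egs = effective_genome_size if effective_genome_size is not None else track_length_bp
    scale = total_signal / egs  # genome-wide mean depth
    return CoverageTrack(replicon_id=replicon_id, bin_size_bp=bin_size,
                         bins=raw_bins / scale, effective_genome_size_bp=egs,
                         genome_mean_raw=scale, track_length_bp=track_length_bp)


@dataclass(frozen=True)
class LocusExpression:
    gene_id: str
    mean_rpgc: float
    below_average: bool


def locus_expression(track: CoverageTrack, genes: Sequence[GeneFeature],
                     focus_gene: Optional[str] = None,
                     flank_bp: int = 5000) -> list[LocusExpression]:
    """Mean normalized coverage per gene for a focus gene and its flanking
    neighbors (all genes when ``focus_gene`` is None); genes below the
    genome average (1.0) are flagged."""
    per_base = track.per_base()
    if focus_gene is not None:
        focus = next((g for g in genes if g.gene_id == focus_gene), None)
        if focus is None:
            raise KeyError(f"focus gene {focus_gene!r} not found")
        lo, hi = focus.start - flank_bp, focus.end + flank_bp
        genes = [g for g in genes if g.start <= hi and g.end >= lo]
    out = []
    for g in sorted(genes, key=lambda g: (g.start, g.gene_id)):
        if g.start < 1 or g.end > per_base.size:
            raise ValueError(f"gene {g.gene_id} outside track of length {per_base.size}")
        span = per_base[g.start - 1: g.end]
        if span.size == 0:
            raise ValueError(f"gene {g.gene_id} has an empty span")
        mean = float(span.mean())
        out.append(LocusExpression(gene_id=g.gene_id, mean_rpgc=mean,
                                   below_average=mean < 1.0))
    return out
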