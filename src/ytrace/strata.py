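"""Heterozygous-SNP filtering, windowed density and PAR/stratum boundary
detection.

In a male, a pseudoautosomal region (PAR, Strata 0) still recombining
between the sex chromosomes shows low heterozygous-SNP density, while a
differentiated stratum (Strata 1) shows a sharp excess of apparent
heterozygosity from diverged haplotypes.  Variants are filtered to credible
heterozygous SNVs (allele fraction 0.25-0.75, depth between half and 1.5x
the depth-histogram mode), binned into fixed windows with masked regions
excluded, and the boundary is placed by a single least-squares mean-shift
change point, accepted only when the post-boundary mean density exceeds the
pre-boundary mean by a configurable factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import SnpRecord

__all__ = [
    "SnpFilterConfig",
    "DensityTrack",
    "StratumCall",
    "estimate_depth_mode",
    "filter_het_snps",
    "windowed_density",
    "detect_boundary",
    "subdivide_stratum",
]


@dataclass
class SnpFilterConfig:
    """Heterozygous-SNV filter bounds (all inclusive)."""

    af_min: float = 0.25
    af_max: float = 0.75
    depth_lo: float = 21.0
    depth_hi: float = 63.0
    snv_only: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.af_min < self.af_max <= 1:
            raise ValueError("need 0 <= af_min < af_max <= 1")
        if self.depth_lo >= self.depth_hi:
            raise ValueError("need depth_lo < depth_hi")

    @classmethod
    def from_depth_mode(cls, mode: float, af_min: float = 0.25,
                        af_max: float = 0.75) -> "SnpFilterConfig":
        """Depth bounds from the rule: half of the mode to 1.5x the mode."""
        return cls(af_min, af_max, mode / 2.0, 1.5 * mode)


@dataclass
class DensityTrack:
    """Windowed SNP counts/density for one chromosome.

    ``masked`` flags windows overlapping excluded regions; their density is
    NaN and they are invisible to boundary detection.
    """

    chrom: str
    window_bp: int
    counts: np.ndarray
    masked: np.ndarray

    @property
    def density_per_kb(self) -> np.ndarray:
        d = self.counts / (self.window_bp / 1000.0)
        return np.where(self.masked, np.nan, d)

    @property
    def n_windows(self) -> int:
        return len(self.counts)


@dataclass
class StratumCall:
    """PAR/stratum boundary call; ``found`` is False for a flat track."""

    chrom: str
    found: bool
    boundary_bp: int | None
    mean_par: float | None
    mean_stratum: float | None
    segments: dict[str, tuple[int, int, float]] = field(default_factory=dict)


def estimate_depth_mode(snps: Sequence[SnpRecord], min_records: int = 100) -> int:
    """Mode of the integer depth histogram; ties resolve to the smallest
    depth."""
    if len(snps) < min_records:
        raise ValueError(f"need >= {min_records} records to estimate the depth mode")
    depths = np.array([s.depth for s in snps])
    return int(np.bincount(depths).argmax())


def filter_het_snps(snps: Sequence[SnpRecord], config: SnpFilterConfig) -> list[SnpRecord]:
    """Keep single-nucleotide substitutions within the AF and depth bounds
    (bounds inclusive)."""
    return [
        s for s in snps
        if (not config.snv_only or s.is_snv)
        and config.af_min <= s.allele_fraction <= config.af_max
        and config.depth_lo <= s.depth <= config.depth_hi
    ]


def windowed_density(
    snps: Sequence[SnpRecord],
    chrom_len: int,
    window_bp: int = 100_000,
    mask: Sequence[tuple[str, int, int]] | None = None,
    chrom: str | None = None,
) -> DensityTrack:
    """Bin SNPs into fixed windows; windows overlapping the mask are flagged
    and excluded from downstream statistics."""
    if window_bp < 1:
        raise ValueError("window must be >= 1 bp")
    if chrom is None:
        chrom = snps[0].chrom if snps else "chr"
    n = (chrom_len + window_bp - 1) // window_bp
    counts = np.zeros(n, dtype=int)
    for s in snps:
        if s.chrom != chrom:
            continue
        w = (s.pos - 1) // window_bp
        if 0 <= w < n:
            counts[w] += 1
    masked = np.zeros(n, dtype=bool)
    for m in mask or []:
        mchrom, ms, me = m[0], m[1], m[2]
        if mchrom != chrom:
            continue
        lo, hi = ms // window_bp, min(n - 1, (me - 1) // window_bp)
        masked[lo : hi + 1] = True
    return DensityTrack(chrom, window_bp, counts, masked)


def detect_boundary(track: DensityTrack, min_factor: float = 3.0,
                    min_windows: int = 10) -> StratumCall:
    """Single change point on window densities by least-squares mean shift.

    The split minimizing the two-segment residual sum of squares over the
    unmasked windows is accepted only if the post-boundary mean density
    exceeds the pre-boundary mean by ``min_factor``; otherwise the call is
    'no boundary' (found=False), as for a uniformly low female track.
    """
    keep = ~track.masked
    if keep.sum() < min_windows:
        raise ValueError(f"need >= {min_windows} unmasked windows")
    dens = track.density_per_kb[keep]
    idx = np.flatnonzero(keep)
    m = len(dens)
    csum = np.concatenate([[0.0], np.cumsum(dens)])
    csq = np.concatenate([[0.0], np.cumsum(dens**2)])

    def rss(lo: int, hi: int) -> float:  # [lo, hi)
        k = hi - lo
        s = csum[hi] - csum[lo]
        return (csq[hi] - csq[lo]) - s * s / k

    best_k, best_rss = None, np.inf
    for k in range(1, m):
        r = rss(0, k) + rss(k, m)
        if r < best_rss - 1e-12:
            best_k, best_rss = k, r
    mean_pre = float(csum[best_k] / best_k)
    mean_post = float((csum[m] - csum[best_k]) / (m - best_k))
    if mean_post <= min_factor * mean_pre and not (mean_pre == 0 and mean_post > 0):
        return StratumCall(track.chrom, False, None, None, None)
    boundary_bp = int(idx[best_k]) * track.window_bp
    segments = {
        "Strata0": (0, boundary_bp, mean_pre),
        "Strata1": (boundary_bp, track.n_windows * track.window_bp, mean_post),
    }
    return StratumCall(track.chrom, True, boundary_bp, mean_pre, mean_post, segments)


def subdivide_stratum(
    call: StratumCall,
    track: DensityTrack,
    inversion_interval: tuple[int, int],
) -> StratumCall:
    """Split Strata 1 into S1a / S1b at an inversion interval lying strictly
    inside it; per-segment mean densities are computed over unmasked windows
    only.  No statistical claim is attached to the split."""
    if not call.found or call.boundary_bp is None:
        raise ValueError("cannot subdivide: no boundary in call")
    s1_start, s1_end, _ = call.segments["Strata1"]
    lo, hi = inversion_interval
    if not (s1_start < lo and hi < s1_end):
        raise ValueError(
            f"inversion interval {inversion_interval} not strictly inside "
            f"Strata 1 [{s1_start}, {s1_end})"
        )
    dens = track.density_per_kb

    def seg_mean(a: int, b: int) -> float:
        wlo, whi = a // track.window_bp, (b + track.window_bp - 1) // track.window_bp
        vals = dens[wlo:whi]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if len(vals) else float("nan")

    out = StratumCall(call.chrom, True, call.boundary_bp, call.mean_par,
                      call.mean_stratum, dict(call.segments))
    out.segments["S1a"] = (s1_start, lo, seg_mean(s1_start, lo))
    out.segments["S1b"] = (lo, s1_end, seg_mean(lo, s1_end))
    return out
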