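"""Sliding-window detection of runs of homozygosity (ROH).

The procedure mirrors the classical SNP-array scanning heuristic: a window of
``window_snps`` consecutive SNPs slides along each chromosome one SNP at a
time; a window is called homozygous if it contains at most ``window_het_max``
heterozygous and ``window_missing_max`` missing calls.  Each SNP's hit rate is
the fraction of the windows covering it that are homozygous; SNPs with a hit
rate of at least ``window_hit_threshold`` are flagged.  Maximal stretches of
flagged SNPs become candidate segments, split where adjacent flagged SNPs lie
more than ``max_gap_kb`` apart, trimmed so they start and end on homozygous
non-missing SNPs, and finally screened by minimum SNP count, minimum length
and SNP density.

Defaults reproduce the widely used array parameterization: 30-SNP windows,
one heterozygote and five missing calls allowed per window, 5% hit threshold,
segments of at least 30 SNPs and 300 kb with at least 1 SNP per 30 kb and a
1 Mb maximum internal gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHParams:
    """Parameters of the sliding-window ROH scan (lengths in kb)."""

    min_snps: int = 30
    min_length_kb: float = 300.0
    density_kb_per_snp: float = 30.0
    window_snps: int = 30
    max_gap_kb: float = 1000.0
    window_het_max: int = 1
    window_missing_max: int = 5
    window_hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_snps", "min_length_kb", "density_kb_per_snp",
                     "window_snps", "max_gap_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_het_max < 0 or self.window_missing_max < 0:
            raise ValueError("window tolerances must be >= 0")
        if not 0 < self.window_hit_threshold <= 1:
            raise ValueError("window_hit_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run; coordinates are 1-based inclusive base pairs."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError("end_bp must be >= start_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


def _flag_snps(geno: np.ndarray, params: ROHParams) -> np.ndarray:
    """Step (i)-(ii): flag SNPs whose hit rate meets the window threshold.

    ``geno`` is one sample's calls on one chromosome.  Only full windows are
    formed; SNPs near chromosome ends are judged by the windows that do
    contain them.
    """
    s = geno.size
    w = params.window_snps
    if s < w:
        return np.zeros(s, dtype=bool)
    het = (geno == 1).astype(np.int32)
    mis = (geno == MISSING).astype(np.int32)
    # sliding sums over windows starting at 0..s-w
    c_het = np.concatenate([[0], np.cumsum(het)])
    c_mis = np.concatenate([[0], np.cumsum(mis)])
    het_w = c_het[w:] - c_het[:-w]
    mis_w = c_mis[w:] - c_mis[:-w]
    hom_window = (het_w <= params.window_het_max) & (mis_w <= params.window_missing_max)
    k = s - w + 1  # number of windows
    # windows containing SNP j start at i in [max(0, j-w+1), min(j, k-1)]
    j = np.arange(s)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, k - 1)
    c_hom = np.concatenate([[0], np.cumsum(hom_window.astype(np.int64))])
    hits = c_hom[hi + 1] - c_hom[lo]
    denom = hi - lo + 1
    return hits / denom >= params.window_hit_threshold


def _segments_for_chrom(
    sample_id: str,
    chrom: str,
    pos: np.ndarray,
    geno: np.ndarray,
    params: ROHParams,
) -> list[ROHSegment]:
    if geno.size < params.window_snps:
        logger.debug(
            "sample %s chromosome %s has %d SNPs (< window of %d): skipped",
            sample_id, chrom, geno.size, params.window_snps,
        )
        return []
    flagged = _flag_snps(geno, params)
    if not flagged.any():
        return []
    idx = np.nonzero(flagged)[0]
    # candidate runs: consecutive flagged SNP indices, split at large bp gaps
    breaks = np.nonzero(
        (np.diff(idx) > 1) | (np.diff(pos[idx]) > params.max_gap_kb * 1000)
    )[0]
    out: list[ROHSegment] = []
    hom = (geno == 0) | (geno == 2)
    for run in np.split(idx, breaks + 1):
        a, b = run[0], run[-1]
        # trim to the outermost homozygous non-missing SNPs
        inner = np.nonzero(hom[a : b + 1])[0]
        if inner.size == 0:
            continue
        a2, b2 = a + inner[0], a + inner[-1]
        n_snps = b2 - a2 + 1
        length_bp = pos[b2] - pos[a2] + 1
        if n_snps < params.min_snps:
            continue
        if length_bp < params.min_length_kb * 1000:
            continue
        if length_bp / 1000.0 > n_snps * params.density_kb_per_snp:
            continue
        out.append(
            ROHSegment(
                sample_id=sample_id,
                chromosome=str(chrom),
                start_bp=int(pos[a2]),
                end_bp=int(pos[b2]),
                n_snps=int(n_snps),
            )
        )
    return out


def call_roh(g: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Call ROH segments for every sample of ``g``.

    Returns segments sorted by (sample order in ``g``, chromosome order in
    the variant table, start position).  Chromosomes with fewer SNPs than one
    window yield no calls.
    """
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    chrom_arr = g.variants["chrom"].to_numpy()
    pos_arr = g.variants["pos"].to_numpy()
    # preserve chromosome order of first appearance
    chroms = list(dict.fromkeys(chrom_arr.tolist()))
    chrom_slices = {c: np.nonzero(chrom_arr == c)[0] for c in chroms}
    for si, sid in enumerate(g.sample_ids):
        row = g.calls[si]
        for c in chroms:
            sl = chrom_slices[c]
            segments.extend(
                _segments_for_chrom(sid, c, pos_arr[sl], row[sl], params)
            )
    return segments


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

_COLUMNS = ["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"]


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s.sample_id,
            "chrom": s.chromosome,
            "start_bp": s.start_bp,
            "end_bp": s.end_bp,
            "n_snps": s.n_snps,
            "length_kb": s.length_bp / 1000.0,
        }
        for s in segments
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_roh(segments: list[ROHSegment], path: str | Path) -> None:
    """Write segments as a TSV (header always present, deterministic order)."""
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def read_roh(path: str | Path) -> list[ROHSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    return [
        ROHSegment(
            sample_id=r.sample_id,
            chromosome=r.chrom,
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            n_snps=int(r.n_snps),
        )
        for r in df.itertuples()
    ]
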