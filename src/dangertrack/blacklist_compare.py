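"""Concordance between the danger score and curated region lists.

Curated lists (ENCODE-blacklist-style BED files, GRC issue regions) are
binned onto the same window grid as the score — as the fraction of each
window they cover, or binarized — and compared with the score by Pearson
correlation (Spearman optionally), with reproducible seeded subsampling
of windows, plus a threshold-based overlap summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .windows import WindowGrid

__all__ = [
    "RegionSet",
    "RegionCoverageTrack",
    "read_bed_regions",
    "regions_to_track",
    "correlate_tracks",
    "CorrelationResult",
    "overlap_summary",
]


@dataclass
class RegionSet:
    """Merged, sorted genomic intervals (0-based half-open) with a label."""

    intervals: list[tuple[str, int, int]]
    label: str = "regions"

    def __post_init__(self) -> None:
        for chrom, s, e in self.intervals:
            if s >= e:
                raise ValueError(f"invalid interval {chrom}:{s}-{e} (start >= end)")
        self.intervals = _merge(self.intervals)

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


@dataclass
class RegionCoverageTrack:
    grid: WindowGrid
    values: np.ndarray  # fraction covered, or {0,1} in binary mode
    mode: str
    label: str


def _merge(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for chrom, s, e in intervals:
        if chrom not in by_chrom:
            order.append(chrom)
        by_chrom.setdefault(chrom, []).append((s, e))
    merged = []
    for chrom in order:
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def read_bed_regions(path, label: str | None = None) -> RegionSet:
    """Read a BED3+ file (extra columns ignored; overlaps merged)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from None
    return RegionSet(intervals, label=label or str(path))


def regions_to_track(rs: RegionSet, grid: WindowGrid, mode: str = "fraction") -> RegionCoverageTrack:
    """Bin a region set onto the grid.

    fraction mode: covered bases / window length; binary mode: 1 iff any
    overlap. Regions on chromosomes outside the grid are skipped.
    """
    if mode not in ("fraction", "binary"):
        raise ValueError(f"unknown mode {mode!r}")
    W = grid.window_size
    covered = np.zeros(grid.n_windows, dtype=np.int64)
    for chrom, s, e in rs.intervals:
        if chrom not in grid.layout:
            continue
        length = grid.layout.length_of(chrom)
        s, e = max(0, s), min(e, length)
        if s >= e:
            continue
        off = grid.chrom_offsets[grid.layout._index[chrom]]
        for w in range(s // W, (e - 1) // W + 1):
            covered[off + w] += min(e, (w + 1) * W) - max(s, w * W)
    if mode == "binary":
        values = (covered > 0).astype(float)
    else:
        values = covered / grid.window_lengths()
    return RegionCoverageTrack(grid, values, mode=mode, label=rs.label)


@dataclass
class CorrelationResult:
    r: float | None  # None when either vector is constant
    n: int
    method: str
    indices: np.ndarray | None  # subsample used, None = all windows
    seed: int | None

    @property
    def undefined(self) -> bool:
        return self.r is None


def correlate_tracks(
    a: np.ndarray,
    b: np.ndarray,
    subsample_n: int | None = None,
    seed: int | None = None,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation between two per-window tracks.

    When ``subsample_n`` is set, that many windows are drawn without
    replacement with the given seed (recorded in the result); the paired
    values at those windows are correlated. A constant vector yields an
    undefined correlation (r = None), never a propagated NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("tracks must be 1-D and equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 windows")
    indices = None
    if subsample_n is not None:
        if not 2 <= subsample_n <= len(a):
            raise ValueError(f"subsample_n={subsample_n} outside [2, {len(a)}]")
        rng = np.random.default_rng(seed)
        indices = np.sort(rng.choice(len(a), size=subsample_n, replace=False))
        a, b = a[indices], b[indices]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(None, len(a), method, indices, seed)
    if method == "pearson":
        r = float(stats.pearsonr(a, b).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(a, b).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(r, len(a), method, indices, seed)


def overlap_summary(
    scores: np.ndarray,
    grid: WindowGrid,
    region_track: RegionCoverageTrack,
    threshold: float,
) -> dict:
    """Windows with score >= threshold and their overlap with a region set.

    Returns a dict with genome-wide counts/fractions and a per-chromosome
    pandas table. Overlap uses the region track in binary terms (any
    coverage counts).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0,1]")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (grid.n_windows,):
        raise ValueError("scores length does not match grid")
    flagged = scores >= threshold
    in_regions = np.asarray(region_track.values) > 0
    n_flagged = int(flagged.sum())
    rows = []
    for ci, chrom in enumerate(grid.layout.chroms):
        lo = grid.chrom_offsets[ci]
        hi = lo + grid.n_windows_of(chrom)
        fl = flagged[lo:hi]
        rows.append(
            {
                "chrom": chrom,
                "n_windows": hi - lo,
                "n_flagged": int(fl.sum()),
                "n_flagged_in_regions": int((fl & in_regions[lo:hi]).sum()),
            }
        )
    return {
        "threshold": threshold,
        "n_windows": grid.n_windows,
        "n_flagged": n_flagged,
        "fraction_flagged": n_flagged / grid.n_windows,
        "fraction_flagged_in_regions": (
            float((flagged & in_regions).sum() / n_flagged) if n_flagged else None
        ),
        "per_chromosome": pd.DataFrame(rows),
    }
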