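"""Structural-variant breakpoints: extraction, window counting, normalization.

Every SV contributes two breakpoints, the two boundaries where it joins or
interrupts the reference. For a deletion/duplication/inversion these are the
start and end of the affected span; an insertion has zero reference span, so
both breakpoints coincide at the insertion point; a breakend (BND) record
contributes its own position and the mate position parsed from the ALT
string. Breakpoints are binned into the window grid and the per-window
counts are divided by the genome-wide 99% quantile count (nearest-rank,
zeros included), clipping ratios above 1, which yields a density feature in
[0, 1]: the higher, the more breakpoint-dense (less trustworthy) the window.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

from .windows import GenomeLayout, WindowGrid

__all__ = [
    "Breakpoint",
    "ParseReport",
    "BreakpointCounts",
    "SVDensityFeature",
    "vcf_to_breakpoints",
    "count_breakpoints",
    "normalize_counts",
    "write_breakpoint_bed",
]

logger = logging.getLogger(__name__)

# one side of a breakend ALT, e.g. "A[chr2:321682[" or "]13:123456]T"
_BND_RE = re.compile(r"[\[\]](?P<chrom>[^\[\]:]+):(?P<pos>\d+)[\[\]]")
_SYMBOLIC_RE = re.compile(r"^<(?P<type>[^<>]+)>$")


@dataclass(frozen=True)
class Breakpoint:
    """A single SV boundary, 0-based."""

    chrom: str
    pos: int
    source_record_id: str


@dataclass
class ParseReport:
    """Bookkeeping from one VCF pass."""

    n_records: int = 0
    n_records_skipped: int = 0
    n_records_multiallelic: int = 0
    n_breakpoints: int = 0
    n_breakpoints_dropped: int = 0
    warnings: list[str] = field(default_factory=list)

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)
        logger.warning(msg)


@dataclass
class BreakpointCounts:
    """Per-window breakpoint tallies on a grid."""

    grid: WindowGrid
    counts: np.ndarray  # int64, one per window
    n_records: int
    n_breakpoints_placed: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.grid.n_windows,):
            raise ValueError("counts length does not match grid")
        if int(self.counts.sum()) != self.n_breakpoints_placed:
            raise ValueError("count total does not match n_breakpoints_placed")


@dataclass
class SVDensityFeature:
    """Quantile-normalized breakpoint density, one value in [0,1] per window."""

    grid: WindowGrid
    values: np.ndarray
    q99: float
    clipped: bool
    label: str = "sv_density"
    kind: str = "sv_density"


def _record_id(variant, idx: int) -> str:
    vid = variant.ID
    return vid if vid not in (None, ".", "") else f"record_{idx}"


def _first(value):
    """INFO fields may come back as scalars or per-ALT tuples."""
    if isinstance(value, (tuple, list, np.ndarray)):
        return value[0] if len(value) else None
    return value


def _sv_type(alt: str, variant) -> str | None:
    m = _SYMBOLIC_RE.match(alt)
    if m:
        return m.group("type").split(":")[0].upper()
    t = variant.INFO.get("SVTYPE")
    return str(t).upper() if t is not None else None


def vcf_to_breakpoints(
    vcf_path,
    layout: GenomeLayout,
    pass_only: bool = False,
) -> tuple[list[Breakpoint], ParseReport]:
    """Extract two breakpoints per SV record from a VCF.

    The end coordinate of a non-BND record is resolved in priority order:
    INFO/END (1-based inclusive), then start + |SVLEN|, then
    start + len(REF) - 1. Insertions have no reference span, so the SVLEN
    rule (which would measure the inserted sequence) is skipped for them
    and both breakpoints coincide at the insertion point. BND records
    contribute their own POS and the mate coordinate from the ALT string.

    Records on chromosomes absent from the layout are skipped and counted
    in the report; individual breakpoints falling outside the layout (e.g.
    a BND mate on an absent chromosome) are dropped and counted.

    Parameters
    ----------
    vcf_path : path to a VCF (plain or bgzipped).
    layout : genome layout used to validate breakpoint coordinates.
    pass_only : if True, keep only records whose FILTER is PASS/missing.

    Returns
    -------
    (breakpoints, report)
    """
    report = ParseReport()
    breakpoints: list[Breakpoint] = []

    for idx, variant in enumerate(VCF(str(vcf_path))):
        rid = _record_id(variant, idx)
        if pass_only and variant.FILTER is not None:  # cyvcf2: None == PASS/'.'
            report.n_records_skipped += 1
            continue
        chrom = variant.CHROM
        if chrom not in layout:
            report.n_records_skipped += 1
            report.warn(f"{rid}: chromosome {chrom!r} not in layout; record skipped")
            continue
        if not variant.ALT:
            report.n_records_skipped += 1
            report.warn(f"{rid}: no ALT allele; record skipped")
            continue
        if len(variant.ALT) > 1:
            report.n_records_multiallelic += 1
            report.warn(f"{rid}: multi-allelic record; using first ALT only")
        alt = variant.ALT[0]
        start0 = variant.POS - 1

        if "[" in alt or "]" in alt:
            m = _BND_RE.search(alt)
            if m is None:
                report.n_records_skipped += 1
                report.warn(f"{rid}: unparseable BND ALT {alt!r}; record skipped")
                continue
            pair = [
                Breakpoint(chrom, start0, rid),
                Breakpoint(m.group("chrom"), int(m.group("pos")) - 1, rid),
            ]
        else:
            svtype = _sv_type(alt, variant)
            end_info = _first(variant.INFO.get("END"))
            svlen = _first(variant.INFO.get("SVLEN"))
            if end_info is not None:
                end0 = int(end_info) - 1
            elif svtype == "INS":
                # inserted-sequence length is not a reference span
                end0 = start0 + len(variant.REF) - 1
            elif svlen is not None:
                try:
                    end0 = start0 + abs(int(svlen))
                except (TypeError, ValueError):
                    report.n_records_skipped += 1
                    report.warn(f"{rid}: unparseable SVLEN {svlen!r}; record skipped")
                    continue
            else:
                end0 = start0 + len(variant.REF) - 1
            pair = [Breakpoint(chrom, start0, rid), Breakpoint(chrom, end0, rid)]

        report.n_records += 1
        for bp in pair:
            if bp.chrom in layout and 0 <= bp.pos < layout.length_of(bp.chrom):
                breakpoints.append(bp)
                report.n_breakpoints += 1
            else:
                report.n_breakpoints_dropped += 1
                report.warn(f"{bp.source_record_id}: breakpoint {bp.chrom}:{bp.pos} outside layout; dropped")

    return breakpoints, report


def count_breakpoints(breakpoints: list[Breakpoint], grid: WindowGrid, n_records: int = 0) -> BreakpointCounts:
    """Tally breakpoints per window; order-invariant over the input list."""
    W = grid.window_size
    idx = np.fromiter(
        (grid.chrom_offsets[grid.layout._index[bp.chrom]] + bp.pos // W for bp in breakpoints),
        dtype=np.int64,
        count=len(breakpoints),
    )
    counts = np.bincount(idx, minlength=grid.n_windows).astype(np.int64)
    return BreakpointCounts(grid, counts, n_records=n_records, n_breakpoints_placed=len(breakpoints))


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: smallest value with cumulative proportion >= q."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile level must be in (0,1), got {q}")
    return float(np.quantile(np.asarray(values), q, method="inverted_cdf"))


def normalize_counts(counts: BreakpointCounts, q: float = 0.99, label: str = "sv_density") -> SVDensityFeature:
    """Divide per-window counts by the genome-wide q-quantile count.

    The quantile runs over all windows, zero-count windows included
    (nearest-rank estimator). Ratios above 1 are clipped to 1 so the
    feature stays in [0,1]. When the quantile is 0 (very sparse call
    sets) any window with at least one breakpoint gets 1, the rest 0.
    """
    c = counts.counts
    qv = nearest_rank_quantile(c, q)
    if qv > 0:
        ratios = c / qv
        clipped = bool((ratios > 1.0).any())
        values = np.minimum(ratios, 1.0)
    else:
        values = (c > 0).astype(float)
        clipped = bool(values.any())
    return SVDensityFeature(counts.grid, values, q99=qv, clipped=clipped, label=label)


def write_breakpoint_bed(breakpoints: list[Breakpoint], path) -> None:
    """Write one BED line per breakpoint: chrom, pos, pos+1, source id."""
    with open(path, "w") as fh:
        for bp in breakpoints:
            fh.write(f"{bp.chrom}\t{bp.pos}\t{bp.pos + 1}\t{bp.source_record_id}\n")
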