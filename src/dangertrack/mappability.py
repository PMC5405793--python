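"""Mappability tracks, per-window uniqueness, and an exact k-mer calculator.

Mappability of a base is 1 / (number of exact genome matches of the k-mer
starting there): 1 means unique, 0.5 means two matches, and so on. The
uniqueness of a window is 1 minus the average mappability over its bases,
so 0 marks a fully unique window and values near 1 mark repetitive or
unmappable sequence. Tracks are held interval-wise (never expanded to a
per-base array for aggregation), so full-genome tracks stay cheap.

Bases missing from a track (assembly gaps, N runs) are governed by a
missing policy: ``missing_as_zero`` (default) treats them as mappability 0
— maximally non-unique, which is what gaps are in practice — while
``missing_excluded`` averages over covered bases only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .windows import GenomeLayout, WindowGrid

__all__ = [
    "MappabilityTrack",
    "UniquenessFeature",
    "read_mappability",
    "write_mappability_bedgraph",
    "window_uniqueness",
    "kmer_mappability",
    "MISSING_AS_ZERO",
    "MISSING_EXCLUDED",
]

MISSING_AS_ZERO = "missing_as_zero"
MISSING_EXCLUDED = "missing_excluded"

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


@dataclass
class MappabilityTrack:
    """Per-base values in [0,1], stored as non-overlapping intervals.

    ``intervals[chrom] = (starts, ends, values)`` with 0-based half-open
    coordinates sorted by start. Bases not covered by any interval have no
    defined value.
    """

    layout: GenomeLayout
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    k: int | None = None
    label: str = "mappability"

    def values_at(self, chrom: str, length: int | None = None) -> np.ndarray:
        """Materialize per-base values for one chromosome (NaN = undefined).

        Test/oracle convenience; window aggregation never calls this.
        """
        if length is None:
            length = self.layout.length_of(chrom)
        out = np.full(length, np.nan)
        starts, ends, vals = self.intervals.get(chrom, (np.empty(0, int),) * 3)
        for s, e, v in zip(starts, ends, vals):
            out[s:e] = v
        return out


@dataclass
class UniquenessFeature:
    """Per-window uniqueness u = 1 − mean mappability, in [0,1]."""

    grid: WindowGrid
    values: np.ndarray
    k: int | None
    missing_policy: str
    label: str = "uniqueness"
    kind: str = "uniqueness"


def _finalize_intervals(raw: dict[str, list[tuple[int, int, float]]], path) -> dict:
    out = {}
    for chrom, ivs in raw.items():
        ivs.sort()
        starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
        vals = np.array([v for _, _, v in ivs], dtype=float)
        if (starts[1:] < ends[:-1]).any():
            i = int(np.argmax(starts[1:] < ends[:-1]))
            raise ValueError(
                f"{path}: overlapping intervals on {chrom} near {starts[i + 1]}"
            )
        out[chrom] = (starts, ends, vals)
    return out


def _check_value(v: float, path, lineno: int) -> float:
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{path}: line {lineno}: value {v} outside [0,1]")
    return v


def read_mappability(path, layout: GenomeLayout, k: int | None = None) -> MappabilityTrack:
    """Read a base-resolution mappability track.

    Accepts bedGraph (0-based half-open), wiggle (fixedStep/variableStep,
    1-based, step=1 span=1), or bigWig (by .bw/.bigwig extension, when
    pyBigWig is available). Intervals on chromosomes absent from the
    layout, or running past a chromosome end, are skipped with a warning;
    values outside [0,1] and overlapping intervals are errors.
    """
    spath = str(path)
    if spath.lower().endswith((".bw", ".bigwig")):
        return _read_bigwig(spath, layout, k)

    raw: dict[str, list[tuple[int, int, float]]] = {}
    skipped = 0
    mode = "bedgraph"
    cur_chrom = None
    cur_pos = 0  # 0-based next position for fixedStep

    def add(chrom: str, s: int, e: int, v: float) -> None:
        nonlocal skipped
        if chrom not in layout or e > layout.length_of(chrom) or s < 0:
            skipped += 1
            return
        raw.setdefault(chrom, []).append((s, e, v))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                fields = dict(kv.split("=", 1) for kv in line.split()[1:])
                cur_chrom = fields["chrom"]
                if int(fields.get("span", 1)) != 1:
                    raise ValueError(f"{path}: line {lineno}: only span=1 wiggle supported")
                if line.startswith("fixedStep"):
                    mode = "fixedstep"
                    if int(fields.get("step", 1)) != 1:
                        raise ValueError(f"{path}: line {lineno}: only step=1 fixedStep supported")
                    cur_pos = int(fields["start"]) - 1  # 1-based -> 0-based
                else:
                    mode = "variablestep"
                continue
            parts = line.split()
            try:
                if mode == "fixedstep":
                    v = _check_value(float(parts[0]), path, lineno)
                    add(cur_chrom, cur_pos, cur_pos + 1, v)
                    cur_pos += 1
                elif mode == "variablestep":
                    pos1, v = int(parts[0]), _check_value(float(parts[1]), path, lineno)
                    add(cur_chrom, pos1 - 1, pos1, v)
                else:
                    chrom, s, e = parts[0], int(parts[1]), int(parts[2])
                    v = _check_value(float(parts[3]), path, lineno)
                    if s >= e:
                        raise ValueError(f"{path}: line {lineno}: empty interval {s}..{e}")
                    add(chrom, s, e, v)
            except (IndexError, ValueError) as exc:
                if isinstance(exc, ValueError) and spath in str(exc):
                    raise
                raise ValueError(f"{path}: line {lineno}: cannot parse {line!r}") from None

    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "%s: skipped %d intervals outside the genome layout", path, skipped
        )
    return MappabilityTrack(layout, _finalize_intervals(raw, path), k=k)


def _read_bigwig(path: str, layout: GenomeLayout, k: int | None) -> MappabilityTrack:
    import pyBigWig  # optional dependency

    raw: dict[str, list[tuple[int, int, float]]] = {}
    with pyBigWig.open(path) as bw:
        for chrom, length in layout.items():
            if chrom not in bw.chroms():
                continue
            for s, e, v in bw.intervals(chrom, 0, min(length, bw.chroms()[chrom])) or []:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{path}: value {v} on {chrom}:{s} outside [0,1]")
                raw.setdefault(chrom, []).append((int(s), int(e), float(v)))
    return MappabilityTrack(layout, _finalize_intervals(raw, path), k=k)


def write_mappability_bedgraph(track: MappabilityTrack, path) -> None:
    """Write the track as bedGraph; float repr round-trips bit-exactly."""
    with open(path, "w") as fh:
        for chrom in track.layout.chroms:
            if chrom not in track.intervals:
                continue
            starts, ends, vals = track.intervals[chrom]
            for s, e, v in zip(starts, ends, vals):
                fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


def window_uniqueness(
    track: MappabilityTrack,
    grid: WindowGrid,
    missing_policy: str = MISSING_AS_ZERO,
    label: str | None = None,
) -> UniquenessFeature:
    """Per-window uniqueness: u_i = 1 − mean mappability over window bases.

    Under ``missing_as_zero`` uncovered bases contribute mappability 0;
    under ``missing_excluded`` the mean runs over covered bases only and a
    window with no covered base gets u = 1. Aggregation is interval-wise.
    """
    if missing_policy not in (MISSING_AS_ZERO, MISSING_EXCLUDED):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    W = grid.window_size
    sums = np.zeros(grid.n_windows)
    covered = np.zeros(grid.n_windows, dtype=np.int64)
    for ci, chrom in enumerate(grid.layout.chroms):
        if chrom not in track.intervals:
            continue
        off = grid.chrom_offsets[ci]
        starts, ends, vals = track.intervals[chrom]
        for s, e, v in zip(starts, ends, vals):
            w0, w1 = s // W, (e - 1) // W
            for w in range(w0, w1 + 1):
                ov = min(e, (w + 1) * W) - max(s, w * W)
                sums[off + w] += v * ov
                covered[off + w] += ov
    wl = grid.window_lengths()
    if missing_policy == MISSING_AS_ZERO:
        u = 1.0 - sums / wl
    else:
        with np.errstate(invalid="ignore"):
            u = np.where(covered > 0, 1.0 - sums / np.maximum(covered, 1), 1.0)
    u = np.clip(u, 0.0, 1.0)  # guard float round-off at the boundaries
    return UniquenessFeature(
        grid, u, k=track.k, missing_policy=missing_policy,
        label=label or f"uniqueness_{track.label}",
    )


def _runs_to_intervals(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode a per-base array; NaN runs are omitted."""
    n = len(values)
    if n == 0:
        return (np.empty(0, np.int64),) * 2 + (np.empty(0),)
    defined = ~np.isnan(values)
    # break at value changes or defined-mask changes
    change = np.empty(n, dtype=bool)
    change[0] = True
    same = (values[1:] == values[:-1]) | (~defined[1:] & ~defined[:-1])
    change[1:] = ~same
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], n)
    keep = defined[starts]
    return starts[keep], ends[keep], values[starts[keep]]


def kmer_mappability(
    sequences: dict[str, str],
    k: int,
    count_reverse_complement: bool = False,
) -> MappabilityTrack:
    """Exact k-mer mappability of a (small) genome.

    For every position with a full k-mer, the value is 1 / (number of
    exact occurrences of that k-mer across all chromosomes, plus
    occurrences of its reverse complement when requested). K-mers with
    non-ACGT characters, and the last k−1 positions of each chromosome,
    are undefined. Intended for toy genomes (≲10 Mb); exact matches only,
    no mismatch tolerance.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seqs = {c: s.upper().encode() for c, s in sequences.items()}
    max_len = max((len(s) for s in seqs.values()), default=0)
    if k > max_len:
        raise ValueError(f"k={k} exceeds longest chromosome ({max_len} bp)")

    valid_acgt = {c: np.frombuffer(s, dtype=np.uint8) for c, s in seqs.items()}
    acgt_mask = {
        c: np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8)) for c, a in valid_acgt.items()
    }

    counter: Counter[bytes] = Counter()
    for c, s in seqs.items():
        mask = acgt_mask[c]
        ok = _full_kmer_mask(mask, k)
        for i in np.flatnonzero(ok):
            counter[s[i : i + k]] += 1

    layout = GenomeLayout(tuple(seqs), tuple(len(s) for s in seqs.values()))
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c, s in seqs.items():
        vals = np.full(len(s), np.nan)
        ok = _full_kmer_mask(acgt_mask[c], k)
        for i in np.flatnonzero(ok):
            kmer = s[i : i + k]
            n = counter[kmer]
            if count_reverse_complement:
                rc = kmer.translate(_COMPLEMENT)[::-1]
                if rc != kmer:
                    n += counter[rc]
            vals[i] = 1.0 / n
        intervals[c] = _runs_to_intervals(vals)
    return MappabilityTrack(layout, intervals, k=k, label=f"kmer_k{k}")


def _full_kmer_mask(acgt: np.ndarray, k: int) -> np.ndarray:
    """Positions whose k-mer fits the chromosome and is all-ACGT."""
    n = len(acgt)
    ok = np.zeros(n, dtype=bool)
    if n >= k:
        window_ok = np.convolve(acgt.astype(np.int32), np.ones(k, dtype=np.int32), "valid") == k
        ok[: n - k + 1] = window_ok
    return ok
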