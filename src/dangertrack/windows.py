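"""Genome layout and fixed-size window grids.

All coordinates in this package are 0-based half-open (BED convention).
VCF input (1-based) is converted at the parser boundary; wiggle input
(1-based) is converted when read. The window grid tiles every chromosome
from 0 to its length without gaps or overlaps; the last window of a
chromosome is truncated when the length is not a multiple of the window
size, so every base belongs to exactly one window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeLayout",
    "WindowGrid",
    "read_genome_layout",
    "make_windows",
    "locate_window",
]

DEFAULT_WINDOW_SIZE = 5000


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes and their lengths in bases.

    The input order is canonical: every track produced by this package
    lists windows in this chromosome order.
    """

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths differ in length")
        if len(set(self.chroms)) != len(self.chroms):
            seen: set[str] = set()
            for c in self.chroms:
                if c in seen:
                    raise ValueError(f"duplicate chromosome {c!r}")
                seen.add(c)
        for c, n in zip(self.chroms, self.lengths):
            if n < 1:
                raise ValueError(f"chromosome {c!r} has non-positive length {n}")

    def __len__(self) -> int:
        return len(self.chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    @property
    def _index(self) -> dict[str, int]:
        # cached lazily on the instance despite frozen dataclass
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {c: i for i, c in enumerate(self.chroms)}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self._index[chrom]]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in layout") from None

    def items(self):
        return zip(self.chroms, self.lengths)


@dataclass(frozen=True)
class WindowGrid:
    """Fixed-size tiling of a :class:`GenomeLayout`.

    Windows are ordered chromosome-major in layout order, then by start.
    ``chrom_offsets[i]`` is the index of the first window of chromosome i.
    """

    layout: GenomeLayout
    window_size: int
    chrom_offsets: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError(f"window size must be >= 1, got {self.window_size}")
        offsets = []
        total = 0
        for n in self.layout.lengths:
            offsets.append(total)
            total += -(-n // self.window_size)  # ceil div
        object.__setattr__(self, "chrom_offsets", tuple(offsets))
        object.__setattr__(self, "_n_windows", total)

    @property
    def n_windows(self) -> int:
        return self._n_windows  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return self.n_windows

    def n_windows_of(self, chrom: str) -> int:
        n = self.layout.length_of(chrom)
        return -(-n // self.window_size)

    def windows(self):
        """Yield (chrom, start, end) for every window in canonical order."""
        W = self.window_size
        for chrom, length in self.layout.items():
            for start in range(0, length, W):
                yield chrom, start, min(start + W, length)

    def window_bounds(self, index: int) -> tuple[str, int, int]:
        """Return (chrom, start, end) of the window at a global index."""
        if not 0 <= index < self.n_windows:
            raise IndexError(f"window index {index} out of range")
        ci = int(np.searchsorted(self.chrom_offsets, index, side="right")) - 1
        local = index - self.chrom_offsets[ci]
        chrom = self.layout.chroms[ci]
        length = self.layout.lengths[ci]
        start = local * self.window_size
        return chrom, start, min(start + self.window_size, length)

    def window_lengths(self) -> np.ndarray:
        """Per-window lengths in bases (last window per chromosome may be short)."""
        out = np.empty(self.n_windows, dtype=np.int64)
        for i, (_, s, e) in enumerate(self.windows()):
            out[i] = e - s
        return out


def read_genome_layout(path) -> GenomeLayout:
    """Read a UCSC chrom.sizes or samtools faidx ``.fai`` file.

    Both formats put the chromosome name in column 1 and its length in
    column 2; extra ``.fai`` columns are ignored. Order is preserved.
    """
    chroms: list[str] = []
    lengths: list[int] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 columns, got {len(fields)}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: length {fields[1]!r} is not an integer") from None
            if length < 1:
                raise ValueError(f"{path}: line {lineno}: non-positive length {length}")
            if name in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            chroms.append(name)
            lengths.append(length)
    if not chroms:
        raise ValueError(f"{path}: no chromosomes found")
    return GenomeLayout(tuple(chroms), tuple(lengths))


def make_windows(layout: GenomeLayout, window_size: int = DEFAULT_WINDOW_SIZE) -> WindowGrid:
    """Tile the genome into fixed-size windows (default 5 kb)."""
    return WindowGrid(layout, window_size)


def locate_window(grid: WindowGrid, chrom: str, pos: int) -> int:
    """Global index of the window containing 0-based position ``pos``."""
    if chrom not in grid.layout:
        raise KeyError(f"chromosome {chrom!r} not in layout")
    length = grid.layout.length_of(chrom)
    if not 0 <= pos < length:
        raise ValueError(f"position {chrom}:{pos} outside [0, {length})")
    ci = grid.layout._index[chrom]
    return grid.chrom_offsets[ci] + pos // grid.window_size
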