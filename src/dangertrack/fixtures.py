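"""Synthetic genomes, SV call sets and blacklists with known ground truth.

Every generator is a pure function of its spec (which embeds the seed):
repeated calls are byte-identical. Repeats are planted as exact copies so
k-mer occurrence counts — hence mappability — are analytically known; SV
breakpoints are placed window-by-window so per-window truth counts come
from the generator's own bookkeeping; blacklists mark chosen windows with
optional endpoint jitter. These stand in for the real inputs (population
SV call sets, benchmark call sets, reference mappability tracks, curated
blacklists) at toy scale; they make no attempt at realistic SV size or
type distributions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .windows import GenomeLayout, WindowGrid, make_windows

__all__ = [
    "RepeatPlan",
    "SVTrackPlan",
    "FixtureSpec",
    "gen_genome",
    "gen_sv_vcf",
    "gen_blacklist",
    "write_fasta",
    "write_vcf",
    "write_bed",
    "simulate",
    "default_fixture_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatPlan:
    """Copy the source interval to each destination (exact, no mutations)."""

    chrom: str
    start: int
    end: int
    destinations: tuple[tuple[str, int], ...]  # (chrom, start) per extra copy


@dataclass(frozen=True)
class SVTrackPlan:
    """Breakpoint placement plan for one SV call set.

    ``hotspots`` maps a global window index to a breakpoint count for that
    window (must be even: each planted record puts both its breakpoints
    inside the window). ``n_background`` records are scattered uniformly
    over the genome with short spans.
    """

    hotspots: tuple[tuple[int, int], ...] = ()
    n_background: int = 0
    background_max_span: int = 500


@dataclass(frozen=True)
class FixtureSpec:
    """Everything the generators need; the seed determines all outputs."""

    chrom_lengths: tuple[tuple[str, int], ...]
    window_size: int = 5000
    repeats: tuple[RepeatPlan, ...] = ()
    sv_tracks: tuple[tuple[str, SVTrackPlan], ...] = ()
    blacklist_windows: tuple[int, ...] = ()
    blacklist_jitter: int = 0
    kmer_sizes: tuple[int, ...] = (50, 100)
    unique_kmer_k: int | None = None  # retry base sequence until no repeated k-mer
    seed: int = 0

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            tuple(c for c, _ in self.chrom_lengths),
            tuple(n for _, n in self.chrom_lengths),
        )

    def grid(self) -> WindowGrid:
        return make_windows(self.layout, self.window_size)


def _rng(spec: FixtureSpec, *stream) -> np.random.Generator:
    ids = [spec.seed] + [
        zlib.crc32(s.encode()) if isinstance(s, str) else int(s) for s in stream
    ]
    return np.random.default_rng(ids)


def gen_genome(spec: FixtureSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with the repeat plan applied by copy-paste.

    Returns (sequences, truth) where truth lists every copy of every
    planted repeat, the source included, one row per placed copy. With
    ``unique_kmer_k`` set, the base sequence (before planting) is redrawn
    until no k-mer of that size repeats, so planted copies are the only
    repeats of that order.
    """
    rng = _rng(spec, "genome")
    layout = spec.layout
    for attempt in range(100):
        seqs = {
            c: rng.choice(_BASES, size=n).tobytes().decode()
            for c, n in layout.items()
        }
        if spec.unique_kmer_k is None or _all_kmers_unique(seqs, spec.unique_kmer_k):
            break
    else:
        raise RuntimeError("could not draw a genome with all-unique k-mers")

    # plant exact copies; reject overlap between any two placed intervals
    placed: list[tuple[str, int, int]] = []
    rows = []
    for ri, rp in enumerate(spec.repeats):
        src = seqs[rp.chrom][rp.start : rp.end]
        if len(src) != rp.end - rp.start:
            raise ValueError(f"repeat {ri}: source outside chromosome")
        copies = [(rp.chrom, rp.start)] + list(rp.destinations)
        for chrom, start in copies:
            end = start + len(src)
            if end > layout.length_of(chrom):
                raise ValueError(f"repeat {ri}: copy at {chrom}:{start} outside chromosome")
            for pc, ps, pe in placed:
                if pc == chrom and start < pe and ps < end:
                    raise ValueError(f"repeat {ri}: copy at {chrom}:{start} overlaps another copy")
            placed.append((chrom, start, end))
            rows.append(
                {"repeat_id": ri, "chrom": chrom, "start": start, "end": end,
                 "source_chrom": rp.chrom, "source_start": rp.start}
            )
    for rp in spec.repeats:
        src = seqs[rp.chrom][rp.start : rp.end]
        for chrom, start in rp.destinations:
            s = seqs[chrom]
            seqs[chrom] = s[:start] + src + s[start + len(src):]
    truth = pd.DataFrame(rows, columns=["repeat_id", "chrom", "start", "end", "source_chrom", "source_start"])
    return seqs, truth


def _all_kmers_unique(seqs: dict[str, str], k: int) -> bool:
    seen: set[str] = set()
    for s in seqs.values():
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if km in seen:
                return False
            seen.add(km)
    return True


@dataclass
class SyntheticVCF:
    """Records plus the generator's own per-window breakpoint truth."""

    records: list[tuple[str, int, str, str, str]]  # chrom, pos0, id, alt, info
    truth_counts: np.ndarray
    n_records: int


_SV_TYPES = ("DEL", "DUP", "INV")


def gen_sv_vcf(spec: FixtureSpec, track_label: str) -> SyntheticVCF:
    """SV records per the track's hotspot/background plan, with truth counts.

    Hotspot records sit entirely inside their window (both breakpoints in
    it); background records get a uniform start and a short span. Truth
    counts are tallied as breakpoints are placed and are exactly what
    window-binning of the emitted VCF must reproduce.
    """
    plan = dict(spec.sv_tracks).get(track_label)
    if plan is None:
        raise KeyError(f"no SV track {track_label!r} in spec")
    rng = _rng(spec, "sv", track_label)
    grid = spec.grid()
    layout = spec.layout
    counts = np.zeros(grid.n_windows, dtype=np.int64)
    records = []
    rec_i = 0

    def add(chrom: str, start0: int, end0: int, svtype: str) -> None:
        nonlocal rec_i
        if svtype == "INS":
            info = f"SVTYPE=INS;SVLEN={int(rng.integers(50, 500))}"
        else:
            info = f"SVTYPE={svtype};END={end0 + 1}"
        records.append((chrom, start0, f"{track_label}_{rec_i}", f"<{svtype}>", info))
        rec_i += 1
        W = grid.window_size
        off = grid.chrom_offsets[layout._index[chrom]]
        counts[off + start0 // W] += 1
        counts[off + end0 // W] += 1

    for win_idx, n_bp in plan.hotspots:
        if n_bp % 2:
            raise ValueError(f"hotspot breakpoint count must be even, got {n_bp}")
        chrom, wstart, wend = grid.window_bounds(win_idx)
        for _ in range(n_bp // 2):
            a, b = np.sort(rng.integers(wstart, wend, size=2))
            svtype = _SV_TYPES[int(rng.integers(len(_SV_TYPES)))]
            add(chrom, int(a), int(b), svtype)

    lengths = np.array(layout.lengths, dtype=float)
    for _ in range(plan.n_background):
        ci = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
        chrom = layout.chroms[ci]
        n = layout.lengths[ci]
        start0 = int(rng.integers(0, n))
        svtype = ("DEL", "DUP", "INV", "INS")[int(rng.integers(4))]
        if svtype == "INS":
            end0 = start0
        else:
            end0 = min(start0 + int(rng.integers(50, plan.background_max_span + 1)), n - 1)
        add(chrom, start0, end0, svtype)

    records.sort(key=lambda r: (layout._index[r[0]], r[1]))
    return SyntheticVCF(records, counts, n_records=rec_i)


def gen_blacklist(spec: FixtureSpec) -> list[tuple[str, int, int]]:
    """Intervals covering the designated windows, endpoints jittered ±jitter."""
    rng = _rng(spec, "blacklist")
    grid = spec.grid()
    out = []
    for win_idx in spec.blacklist_windows:
        chrom, wstart, wend = grid.window_bounds(win_idx)
        length = spec.layout.length_of(chrom)
        j = spec.blacklist_jitter
        if j:
            wstart = max(0, wstart + int(rng.integers(-j, j + 1)))
            wend = min(length, wend + int(rng.integers(-j, j + 1)))
        if wstart < wend:
            out.append((chrom, wstart, wend))
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf(sv: SyntheticVCF, layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="SV length">\n')
        for t in ("DEL", "DUP", "INV", "INS"):
            fh.write(f'##ALT=<ID={t},Description="{t}">\n')
        for chrom, n in layout.items():
            fh.write(f"##contig=<ID={chrom},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, rid, alt, info in sv.records:
            fh.write(f"{chrom}\t{pos0 + 1}\t{rid}\tN\t{alt}\t.\t.\t{info}\n")


def write_bed(intervals: list[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def simulate(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Write the full fixture bundle: genome, SV VCFs, mappability
    bedGraphs (via the exact k-mer calculator), blacklist, truth tables."""
    from .mappability import kmer_mappability, write_mappability_bedgraph

    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    seqs, repeat_truth = gen_genome(spec)
    paths["genome"] = out / "genome.fa"
    write_fasta(seqs, paths["genome"])
    repeat_truth.to_csv(out / "truth" / "repeats.tsv", sep="\t", index=False)

    with open(out / "genome.chrom.sizes", "w") as fh:
        for c, n in spec.layout.items():
            fh.write(f"{c}\t{n}\n")
    paths["chrom_sizes"] = out / "genome.chrom.sizes"

    grid = spec.grid()
    for label, _ in spec.sv_tracks:
        sv = gen_sv_vcf(spec, label)
        p = out / f"sv_{label}.vcf"
        write_vcf(sv, spec.layout, p)
        paths[f"sv_{label}"] = p
        pd.DataFrame(
            {"window": np.arange(grid.n_windows), "breakpoints": sv.truth_counts}
        ).to_csv(out / "truth" / f"sv_{label}_counts.tsv", sep="\t", index=False)

    for k in spec.kmer_sizes:
        track = kmer_mappability(seqs, k)
        p = out / f"mappability_k{k}.bedgraph"
        write_mappability_bedgraph(track, p)
        paths[f"mappability_k{k}"] = p

    bl = gen_blacklist(spec)
    paths["blacklist"] = out / "blacklist.bed"
    write_bed(bl, paths["blacklist"])
    return paths


def default_fixture_spec(seed: int = 0) -> FixtureSpec:
    """The package's reference study condition, at toy scale.

    Ten 50 kb chromosomes tiled into 100 windows of 5 kb (the standard
    window size). One window per chromosome is planted as a trouble
    window: a 1 kb exact repeat copied into it from chromosome 1 plus an
    SV hotspot of 40 breakpoints (20 records) in each of two independent
    call sets — mimicking a breakpoint-dense, repetitive region; in real
    genome-scale call sets, windows with more than ~20 breakpoints are
    rare outliers, so 40 is an unambiguous hotspot. Background: 30 scattered
    records per call set. The blacklist marks exactly the 10 planted
    windows with 200 bp endpoint jitter. Mappability uses the standard
    k = 50 and k = 100 tracks.
    """
    chroms = tuple((f"chr{i + 1}", 50_000) for i in range(10))
    # trouble window w of chromosome c at global index c*10 + w
    trouble = [(c, (c * 3 + 4) % 10) for c in range(10)]
    repeat_src = (0, 1000)  # chr1:1000-2000, inside chr1's trouble window? keep src separate
    repeats = []
    dests = []
    for c, w in trouble:
        dest_start = w * 5000 + 2000
        if c == 0 and repeat_src[0] // 5000 == w:
            continue
        dests.append((f"chr{c + 1}", dest_start))
    repeats.append(RepeatPlan("chr1", 1000, 2000, tuple(dests)))
    hotspot_windows = tuple(c * 10 + w for c, w in trouble)
    plan = SVTrackPlan(hotspots=tuple((i, 40) for i in hotspot_windows), n_background=30)
    return FixtureSpec(
        chrom_lengths=chroms,
        window_size=5000,
        repeats=tuple(repeats),
        sv_tracks=(("callset_a", plan), ("callset_b", plan)),
        blacklist_windows=hotspot_windows,
        blacklist_jitter=200,
        kmer_sizes=(50, 100),
        seed=seed,
    )
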