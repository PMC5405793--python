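"""Combine feature tracks into the danger score and serialize it.

The score of a window is the weighted mean of its features (SV breakpoint
density and k-mer uniqueness tracks, all in [0,1]). With uniform weights —
the default — it is the plain arithmetic mean, so it stays in [0,1]:
0 marks a unique, easy-to-assess window; 1 a repetitive, SV-enriched one.
The classic recipe combines four features (two SV call sets + 50 bp and
100 bp uniqueness), but any J >= 1 features are accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .windows import WindowGrid

__all__ = [
    "FeatureSet",
    "DangerScoreTrack",
    "combine",
    "write_bedgraph",
    "write_bed",
    "write_provenance",
    "read_bedgraph_values",
]


@dataclass
class FeatureSet:
    """Aligned per-window feature vectors plus combination weights.

    ``features`` is an ordered list of (label, values, kind) with kind in
    {"sv_density", "uniqueness"}. Weights must be non-negative; they are
    normalized to sum to 1. ``uniform()`` builds the default equal-weight
    set from feature objects (anything with .label/.values/.kind).
    """

    grid: WindowGrid
    features: list[tuple[str, np.ndarray, str]]
    weights: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.n_windows
        if not self.features:
            raise ValueError("at least one feature is required")
        feats = []
        for label, values, kind in self.features:
            values = np.asarray(values, dtype=float)
            if values.shape != (n,):
                raise ValueError(f"feature {label!r}: length {values.shape} != grid ({n},)")
            if np.nanmin(values) < 0 or np.nanmax(values) > 1:
                raise ValueError(f"feature {label!r}: values outside [0,1]")
            feats.append((label, values, kind))
        self.features = feats
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.features),):
            raise ValueError("one weight per feature required")
        if (w < 0).any():
            raise ValueError("negative weight")
        if w.sum() <= 0:
            raise ValueError("weights sum to zero")
        self.weights = w / w.sum()

    @classmethod
    def uniform(cls, grid: WindowGrid, feature_objs) -> "FeatureSet":
        feats = [(f.label, f.values, f.kind) for f in feature_objs]
        return cls(grid, feats, np.ones(len(feats)))


@dataclass
class DangerScoreTrack:
    grid: WindowGrid
    scores: np.ndarray
    provenance: dict = field(default_factory=dict)


def combine(fs: FeatureSet, provenance_extra: dict | None = None) -> DangerScoreTrack:
    """Weighted combination D_i = Σ_j w_j · f_{j,i}; uniform weights = mean."""
    mat = np.stack([v for _, v, _ in fs.features])
    scores = fs.weights @ mat
    scores = np.clip(scores, 0.0, 1.0)  # float round-off guard only
    prov = {
        "tool": "dangertrack",
        "version": __version__,
        "window_size": fs.grid.window_size,
        "n_windows": fs.grid.n_windows,
        "features": [
            {"label": label, "kind": kind, "weight": float(w)}
            for (label, _, kind), w in zip(fs.features, fs.weights)
        ],
    }
    if provenance_extra:
        prov.update(provenance_extra)
    return DangerScoreTrack(fs.grid, scores, prov)


def write_bedgraph(track: DangerScoreTrack, path, trackline: bool = False) -> None:
    """One line per window: chrom, start, end, score to 4 decimal places."""
    with open(path, "w") as fh:
        if trackline:
            fh.write('track type=bedGraph name="DangerTrack" description="danger score"\n')
        for (chrom, s, e), d in zip(track.grid.windows(), track.scores):
            fh.write(f"{chrom}\t{s}\t{e}\t{d:.4f}\n")


def write_bed(track: DangerScoreTrack, path) -> None:
    """BED5 with the UCSC 0–1000 score convention.

    score = round(1000·D) with round-half-even (Python/IEEE rounding);
    the bedGraph carries the authoritative 0–1 value.
    """
    with open(path, "w") as fh:
        for i, ((chrom, s, e), d) in enumerate(zip(track.grid.windows(), track.scores)):
            fh.write(f"{chrom}\t{s}\t{e}\tdanger_{i}\t{round(1000 * d)}\n")


def write_provenance(track: DangerScoreTrack, path) -> None:
    with open(path, "w") as fh:
        json.dump(track.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_bedgraph_values(path) -> np.ndarray:
    """Read back the value column of a window-per-line bedGraph."""
    vals = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            vals.append(float(line.split()[3]))
    return np.array(vals)
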