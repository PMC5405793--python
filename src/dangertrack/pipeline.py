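"""File-to-track convenience pipeline: inputs on disk -> danger score."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .mappability import MISSING_AS_ZERO, read_mappability, window_uniqueness
from .scoring import DangerScoreTrack, FeatureSet, combine
from .sv_breakpoints import count_breakpoints, normalize_counts, vcf_to_breakpoints
from .windows import GenomeLayout, make_windows

__all__ = ["compute_danger_track"]


def compute_danger_track(
    layout: GenomeLayout,
    sv_vcfs: Sequence = (),
    mappability_tracks: Sequence = (),
    window_size: int = 5000,
    quantile: float = 0.99,
    missing_policy: str = MISSING_AS_ZERO,
    weights=None,
    pass_only: bool = False,
) -> tuple[DangerScoreTrack, dict]:
    """Build the danger score from SV VCFs and mappability track files.

    Each VCF becomes one quantile-normalized breakpoint-density feature;
    each mappability track one per-window uniqueness feature. Features are
    combined with uniform weights unless ``weights`` is given. Returns the
    score track and a per-input report dict (record counts, q99 values).
    """
    grid = make_windows(layout, window_size)
    features = []
    info: dict[str, dict] = {}
    for p in sv_vcfs:
        bps, report = vcf_to_breakpoints(p, layout, pass_only=pass_only)
        counts = count_breakpoints(bps, grid, n_records=report.n_records)
        feat = normalize_counts(counts, q=quantile, label=f"sv_density:{Path(p).name}")
        features.append(feat)
        info[feat.label] = {
            "n_records": report.n_records,
            "n_breakpoints_placed": counts.n_breakpoints_placed,
            "q99": feat.q99,
            "clipped": feat.clipped,
        }
    for p in mappability_tracks:
        track = read_mappability(p, layout)
        feat = window_uniqueness(track, grid, missing_policy=missing_policy,
                                 label=f"uniqueness:{Path(p).name}")
        features.append(feat)
        info[feat.label] = {"missing_policy": missing_policy}
    if not features:
        raise ValueError("no input features")
    if weights is None:
        fs = FeatureSet.uniform(grid, features)
    else:
        fs = FeatureSet(grid, [(f.label, f.values, f.kind) for f in features], weights)
    return combine(fs, provenance_extra={"quantile": quantile, "inputs_info": info}), info
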