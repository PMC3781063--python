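"""Case-vs-control relative read-depth scanning.

Per-base depth tracks (pileup-style) are normalized to each sample's mean,
the interval is tiled into non-overlapping windows, and the case/control
log2 ratio of mean normalized depth flags putative deletions, insertions and
copy-number differences.  Bases with zero depth in every sample (unalignable
reference-gap emulation) are masked; windows that are mostly masked are
skipped.  Per-sample normalization makes the scan invariant to absolute
sequencing yield, so desk-scale depth behaves like the original ~11,000x data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

# Flagged ratios where one side has zero coverage are reported at +/- this
# magnitude rather than infinity.
LOG2_FLOOR = 10.0


class CoverageError(ValueError):
    pass


@dataclass(frozen=True)
class DepthTrack:
    sample_id: str
    interval: GenomicInterval
    depth: np.ndarray  # per-base, length == interval.length()

    def __post_init__(self) -> None:
        arr = np.asarray(self.depth)
        if arr.ndim != 1 or len(arr) != self.interval.length():
            raise CoverageError(
                f"depth array length {len(arr)} != interval length "
                f"{self.interval.length()} for {self.sample_id}"
            )
        if (arr < 0).any():
            raise CoverageError("depth values must be >= 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.depth))


def normalize_depth(track: DepthTrack) -> np.ndarray:
    """Per-base depth divided by the track mean (normalized mean = 1)."""
    mean = track.mean
    if mean <= 0:
        raise CoverageError(f"track {track.sample_id} has zero mean depth")
    return np.asarray(track.depth, dtype=float) / mean


@dataclass(frozen=True)
class CNVCall:
    window: GenomicInterval
    log2_ratio: float
    direction: str  # "loss" | "gain"


def relative_coverage_scan(
    case_tracks: Sequence[DepthTrack],
    control_tracks: Sequence[DepthTrack],
    window_bp: int = 500,
    min_abs_log2: float = 0.58,
    max_masked_fraction: float = 0.5,
) -> list[CNVCall]:
    """Windowed case-vs-control scan of normalized depth.

    Windows with |log2(case mean / control mean)| >= ``min_abs_log2``
    (default ~1.5-fold, sized to catch a single-copy change) are returned,
    with adjacent same-direction windows merged (length-weighted mean ratio).
    """
    if window_bp < 1:
        raise CoverageError("window_bp must be >= 1")
    if not case_tracks or not control_tracks:
        raise CoverageError("need at least one case and one control track")
    interval = case_tracks[0].interval
    for t in list(case_tracks) + list(control_tracks):
        if t.interval != interval:
            raise CoverageError(
                f"track {t.sample_id} interval {t.interval} != {interval}"
            )

    raw = np.vstack([np.asarray(t.depth, dtype=float)
                     for t in list(case_tracks) + list(control_tracks)])
    mask = raw.sum(axis=0) == 0  # reference-gap bases: no sample has coverage

    case_mean = np.vstack([normalize_depth(t) for t in case_tracks]).mean(axis=0)
    control_mean = np.vstack([normalize_depth(t) for t in control_tracks]).mean(axis=0)

    flagged: list[tuple[GenomicInterval, float]] = []
    n = interval.length()
    for w_start in range(0, n, window_bp):
        w_end = min(w_start + window_bp, n)
        w_mask = mask[w_start:w_end]
        if w_mask.mean() > max_masked_fraction:
            continue
        keep = ~w_mask
        c = case_mean[w_start:w_end][keep].mean()
        k = control_mean[w_start:w_end][keep].mean()
        if c == 0 and k == 0:
            continue
        if c == 0:
            stat = -LOG2_FLOOR
        elif k == 0:
            stat = LOG2_FLOOR
        else:
            stat = math.log2(c / k)
        if abs(stat) >= min_abs_log2:
            window = GenomicInterval(
                interval.chrom, interval.start + w_start, interval.start + w_end - 1
            )
            flagged.append((window, stat))

    # merge adjacent flagged windows with the same direction
    calls: list[CNVCall] = []
    for window, stat in flagged:
        direction = "loss" if stat < 0 else "gain"
        if (
            calls
            and calls[-1].direction == direction
            and calls[-1].window.end + 1 == window.start
        ):
            prev = calls[-1]
            total = prev.window.length() + window.length()
            merged_ratio = (
                prev.log2_ratio * prev.window.length() + stat * window.length()
            ) / total
            calls[-1] = CNVCall(
                GenomicInterval(window.chrom, prev.window.start, window.end),
                merged_ratio,
                direction,
            )
        else:
            calls.append(CNVCall(window, stat, direction))
    return calls


# ---------------------------------------------------------------------------
# depth TSV I/O
# ---------------------------------------------------------------------------

def write_depth_tsv(path: str | Path, tracks: Sequence[DepthTrack]) -> None:
    """chrom, pos, one integer depth column per sample."""
    if not tracks:
        raise CoverageError("no tracks to write")
    interval = tracks[0].interval
    positions = np.arange(interval.start, interval.end + 1)
    data = {"chrom": interval.chrom, "pos": positions}
    for t in tracks:
        if t.interval != interval:
            raise CoverageError("all tracks must share the interval")
        data[t.sample_id] = np.asarray(t.depth, dtype=int)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_depth_tsv(path: str | Path) -> list[DepthTrack]:
    df = pd.read_csv(path, sep="\t")
    if df.empty or "chrom" not in df.columns or "pos" not in df.columns:
        raise CoverageError(f"malformed depth table {path}")
    chrom = str(df["chrom"].iloc[0])
    interval = GenomicInterval(chrom, int(df["pos"].min()), int(df["pos"].max()))
    if len(df) != interval.length():
        raise CoverageError(f"depth table {path} has gaps in its position column")
    samples = [c for c in df.columns if c not in ("chrom", "pos")]
    df = df.sort_values("pos")
    return [
        DepthTrack(s, interval, df[s].to_numpy(dtype=int)) for s in samples
    ]


def write_cnv_report(path_bed: str | Path, path_json: str | Path,
                     calls: Sequence[CNVCall]) -> None:
    with open(path_bed, "w") as fh:
        for call in calls:
            chrom, start, end = call.window.to_bed_fields()
            fh.write(f"{chrom}\t{start}\t{end}\t{call.direction}\t"
                     f"{call.log2_ratio:.4f}\n")
    payload = [
        {"chrom": c.window.chrom, "start": c.window.start, "end": c.window.end,
         "log2_ratio": c.log2_ratio, "direction": c.direction}
        for c in calls
    ]
    with open(path_json, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# sequencing-run summary statistics
# ---------------------------------------------------------------------------

PANEL_STATS_COLUMNS = ["yield_gb", "mapped_pct", "ibd_mapped_pct", "mean_coverage"]


@dataclass(frozen=True)
class PanelStatsSummary:
    total_yield_gb: float
    mean_mapped_pct: float
    mean_ibd_mapped_pct: float
    mean_coverage: float
    n_samples: int


def summarize_panel_stats(table: pd.DataFrame) -> PanelStatsSummary:
    """Aggregate a per-sample sequencing-yield table.

    Expects columns yield_gb, mapped_pct, ibd_mapped_pct, mean_coverage; the
    total is the yield sum and the rest are arithmetic column means.
    """
    if table.empty:
        raise CoverageError("panel statistics table is empty")
    missing = [c for c in PANEL_STATS_COLUMNS if c not in table.columns]
    if missing:
        raise CoverageError(f"panel statistics table lacks columns {missing}")
    return PanelStatsSummary(
        total_yield_gb=float(table["yield_gb"].sum()),
        mean_mapped_pct=float(table["mapped_pct"].mean()),
        mean_ibd_mapped_pct=float(table["ibd_mapped_pct"].mean()),
        mean_coverage=float(table["mean_coverage"].mean()),
        n_samples=len(table),
    )


__all__ = [
    "DepthTrack", "CNVCall", "CoverageError", "PanelStatsSummary",
    "normalize_depth", "relative_coverage_scan", "summarize_panel_stats",
    "write_depth_tsv", "read_depth_tsv", "write_cnv_report",
    "PANEL_STATS_COLUMNS", "LOG2_FLOOR",
]
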