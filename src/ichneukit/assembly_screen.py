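"""GC-content x sequencing-depth contamination screening.

Bacterial contaminant scaffolds in an insect assembly typically sit away
from the host cloud in the (GC, depth) plane: divergent base composition
and different copy number in the sequenced DNA pool. The screen tiles each
scaffold with non-overlapping windows, computes per-window GC over non-N
bases and mean depth, and flags windows that are outliers on BOTH axes;
scaffolds are labelled by majority vote over their windows.

The window statistics mirror the published screen (10 kb windows for one
wasp, 20 kb for the other); the outlier rule is an explicit, deterministic
surrogate for what is usually a visual inspection of the scatter plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import SequenceRecord


@dataclass(frozen=True)
class GenomeWindow:
    """One tiling window; coordinates are 0-based half-open."""

    scaffold: str
    start: int
    end: int
    gc: float
    mean_depth: float
    n_frac: float

    def __post_init__(self) -> None:
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must be in [0, 1]")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def excluded(self) -> bool:
        """Windows that are mostly N carry no compositional signal."""
        return self.n_frac > 0.5


def _depth_array(track: pd.DataFrame, scaffold: str, length: int) -> np.ndarray:
    """Per-base depth for one scaffold; uncovered positions are depth 0."""
    diff = np.zeros(length + 1, dtype=np.float64)
    sub = track[track["scaffold"] == scaffold]
    for start, end, depth in zip(sub["start"], sub["end"], sub["depth"]):
        s = max(0, int(start))
        e = min(length, int(end))
        if e > s:
            diff[s] += depth
            diff[e] -= depth
    return np.cumsum(diff[:-1])


def window_gc_depth(
    assembly: Sequence[SequenceRecord],
    depth_track: pd.DataFrame,
    window_size: int,
) -> list[GenomeWindow]:
    """Tile scaffolds with non-overlapping windows of GC and mean depth.

    Windows step from position 0 in units of window_size; a terminal
    partial window is kept when it spans at least half a window, else
    dropped. GC is computed over non-N bases; mean depth over all window
    positions.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    windows: list[GenomeWindow] = []
    for rec in assembly:
        length = len(rec.seq)
        depth = _depth_array(depth_track, rec.id, length)
        arr = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_n = ~((arr == ord("A")) | (arr == ord("C"))
                 | (arr == ord("G")) | (arr == ord("T")))
        for start in range(0, length, window_size):
            end = min(start + window_size, length)
            span = end - start
            if span < window_size and span < window_size / 2:
                continue
            n_count = int(is_n[start:end].sum())
            non_n = span - n_count
            gc = float(is_gc[start:end].sum()) / non_n if non_n else 0.0
            windows.append(GenomeWindow(
                scaffold=rec.id, start=start, end=end, gc=gc,
                mean_depth=float(depth[start:end].mean()),
                n_frac=n_count / span,
            ))
    return windows


def _mad_bounds(values: np.ndarray, mult: float) -> tuple[float, float]:
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med - mult * mad, med + mult * mad


def flag_outlier_windows(
    windows: Sequence[GenomeWindow],
    gc_bounds: Optional[tuple[float, float]] = None,
    depth_bounds: Optional[tuple[float, float]] = None,
    mad_mult: float = 5.0,
) -> dict:
    """Label windows and scaffolds as host or contaminant candidates.

    Bounds may be given explicitly; otherwise they are derived per axis as
    median +/- mad_mult * MAD over non-excluded windows (requires >= 10
    such windows). A window is a contaminant candidate only when it falls
    outside the bounds on both axes; scaffolds take the majority label of
    their non-excluded windows.

    Returns {"window_labels": [...], "scaffold_labels": {...},
    "gc_bounds": ..., "depth_bounds": ...}; window labels are
    "host" | "contaminant" | "excluded".
    """
    usable = [w for w in windows if not w.excluded]
    if gc_bounds is None or depth_bounds is None:
        if len(usable) < 10:
            raise ValueError(
                f"only {len(usable)} usable windows: too few for auto-bounds, "
                "supply gc_bounds and depth_bounds explicitly"
            )
        gcs = np.array([w.gc for w in usable])
        depths = np.array([w.mean_depth for w in usable])
        if gc_bounds is None:
            gc_bounds = _mad_bounds(gcs, mad_mult)
        if depth_bounds is None:
            depth_bounds = _mad_bounds(depths, mad_mult)

    labels: list[str] = []
    for w in windows:
        if w.excluded:
            labels.append("excluded")
            continue
        gc_out = not (gc_bounds[0] <= w.gc <= gc_bounds[1])
        depth_out = not (depth_bounds[0] <= w.mean_depth <= depth_bounds[1])
        labels.append("contaminant" if (gc_out and depth_out) else "host")

    scaffold_votes: dict[str, list[int]] = {}
    for w, lab in zip(windows, labels):
        if lab == "excluded":
            continue
        scaffold_votes.setdefault(w.scaffold, []).append(1 if lab == "contaminant" else 0)
    scaffold_labels = {
        s: ("contaminant" if sum(v) * 2 > len(v) else "host")
        for s, v in scaffold_votes.items()
    }
    return {
        "window_labels": labels,
        "scaffold_labels": scaffold_labels,
        "gc_bounds": tuple(gc_bounds),
        "depth_bounds": tuple(depth_bounds),
    }


def screen_assembly(
    assembly: Sequence[SequenceRecord],
    depth_track: pd.DataFrame,
    window_size: int,
    **flag_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Windowing plus outlier flagging in one call.

    Returns a per-window DataFrame (with label column) and the scaffold
    label dict.
    """
    windows = window_gc_depth(assembly, depth_track, window_size)
    result = flag_outlier_windows(windows, **flag_kwargs)
    df = pd.DataFrame(
        [
            {
                "scaffold": w.scaffold, "start": w.start, "end": w.end,
                "gc": w.gc, "mean_depth": w.mean_depth, "n_frac": w.n_frac,
                "label": lab,
            }
            for w, lab in zip(windows, result["window_labels"])
        ]
    )
    return df, result["scaffold_labels"]
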