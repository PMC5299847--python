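"""Per-cell fluorescence extraction from image + mask stacks.

Readout rules: proteins distributed through the cell, at the membrane
or in mitochondria are quantified as the mean intensity over all member
pixels; nuclear proteins as the mean of the brightest 10% of member
pixels (ceil(0.1 * n) pixels). Background is the per-frame median of
non-cell pixels and is subtracted from every measurement.

Cell identity over time comes from a greedy nearest-centroid tracker
with a maximum-displacement gate; cells that vanish are truncated, new
labels (buds) start fresh ids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import CellTrajectory, StrainPanel

__all__ = [
    "FrameStack",
    "MaskStack",
    "IngestionError",
    "track_labels",
    "measure_cell",
    "estimate_background",
    "extract_trajectories",
    "MIN_REGION_PX",
    "MIN_BACKGROUND_PX",
]

#: regions below this pixel count give a low-quality (but still reported) value
MIN_REGION_PX = 10
#: minimum non-cell pixels for a trusted background estimate
MIN_BACKGROUND_PX = 100
#: default tracker gate: max centroid displacement between frames, px
DEFAULT_MAX_DISPLACEMENT_PX = 10.0


class IngestionError(ValueError):
    """Frame/mask stacks do not satisfy the ingestion contract."""


@dataclass
class FrameStack:
    """Fluorescence frames (T, H, W) on a uniform time grid (minutes)."""

    data: np.ndarray
    times: np.ndarray
    position: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise IngestionError("frame stack must be (T, H, W)")
        if len(self.times) != self.data.shape[0]:
            raise IngestionError("time grid length does not match frame count")
        dt = np.diff(self.times)
        if len(dt) and (not np.allclose(dt, dt[0]) or dt[0] <= 0):
            raise IngestionError("time grid must be strictly increasing and uniform")


@dataclass
class MaskStack:
    """Integer-labeled segmentation per frame; label 0 = background."""

    data: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise IngestionError("mask stack must be (T, H, W)")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise IngestionError("mask stack must be integer-labeled")


def _centroids(mask: np.ndarray) -> dict[int, np.ndarray]:
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return {}
    coms = ndimage.center_of_mass(np.ones_like(mask), mask, labels)
    return {int(l): np.asarray(c) for l, c in zip(labels, coms)}


def track_labels(
    masks: MaskStack, max_displacement_px: float = DEFAULT_MAX_DISPLACEMENT_PX
) -> MaskStack:
    """Relabel a mask stack so each cell keeps one id across frames.

    Greedy nearest-centroid matching between consecutive frames: pairs
    are accepted in order of increasing centroid distance up to the
    gate; unmatched previous ids terminate (trajectory truncated),
    unmatched new regions receive fresh ids.
    """
    data = masks.data
    T = data.shape[0]
    if T < 1:
        raise IngestionError("need at least one frame")
    out = np.zeros_like(data, dtype=np.int32)

    prev_centroids: dict[int, np.ndarray] = {}  # persistent id -> centroid
    next_id = 1

    for t in range(T):
        cents = _centroids(data[t])
        mapping: dict[int, int] = {}  # raw label -> persistent id
        if prev_centroids and cents:
            pairs = sorted(
                (
                    (float(np.linalg.norm(c - pc)), raw, pid)
                    for raw, c in cents.items()
                    for pid, pc in prev_centroids.items()
                ),
                key=lambda x: (x[0], x[2], x[1]),
            )
            used_raw: set[int] = set()
            used_pid: set[int] = set()
            for d, raw, pid in pairs:
                if d > max_displacement_px:
                    break
                if raw in used_raw or pid in used_pid:
                    continue
                mapping[raw] = pid
                used_raw.add(raw)
                used_pid.add(pid)
        for raw in sorted(cents):
            if raw not in mapping:
                mapping[raw] = next_id
                next_id += 1

        frame_out = out[t]
        for raw, pid in mapping.items():
            frame_out[data[t] == raw] = pid
        prev_centroids = {pid: cents[raw] for raw, pid in mapping.items()}

    return MaskStack(out, masks.times)


def measure_cell(
    frame: np.ndarray, mask: np.ndarray, cell_id: int, localization: str = "uniform"
) -> float:
    """Intensity readout for one labeled cell region (a.u.).

    Whole-cell mean for uniform/membrane/mitochondrial proteins; mean of
    the ceil(0.1 * n) brightest pixels for nuclear proteins (stable
    descending sort, so ties at the cutoff resolve deterministically).
    """
    member = np.asarray(frame)[np.asarray(mask) == cell_id]
    if member.size == 0:
        raise KeyError(f"cell id {cell_id} not present in mask")
    if localization == "nuclear":
        n_top = math.ceil(0.1 * member.size)
        top = np.sort(member, kind="stable")[::-1][:n_top]
        return float(top.mean())
    return float(member.mean())


def estimate_background(
    frame: np.ndarray, mask: np.ndarray, previous: float | None = None
) -> float:
    """Median of non-cell (label 0) pixels.

    With fewer than MIN_BACKGROUND_PX background pixels the previous
    frame's estimate is reused; a first-frame shortfall is an error.
    """
    bg = np.asarray(frame)[np.asarray(mask) == 0]
    if bg.size < MIN_BACKGROUND_PX:
        if previous is None:
            raise IngestionError(
                f"only {bg.size} background pixels (< {MIN_BACKGROUND_PX}) "
                "and no previous estimate"
            )
        return previous
    return float(np.median(bg))


def extract_trajectories(
    frames: FrameStack,
    masks: MaskStack,
    strain: str,
    condition: str = "0.4M",
    localization: str = "uniform",
    tracked: bool = False,
    max_displacement_px: float = DEFAULT_MAX_DISPLACEMENT_PX,
) -> list[CellTrajectory]:
    """Background-subtracted per-cell trajectories from one chamber.

    Composes tracking, per-cell readout and background estimation.
    ``tracked=True`` means mask labels are already temporally
    consistent and the tracker is skipped. Cells absent at a frame get
    valid=False there; cells whose region ever falls below
    MIN_REGION_PX are flagged low-quality.
    """
    if frames.data.shape[0] != masks.data.shape[0]:
        raise IngestionError("frame and mask stacks differ in length")
    if masks.times is not None and not np.array_equal(frames.times, masks.times):
        raise IngestionError("frame and mask time grids differ")

    tracked_masks = masks if tracked else track_labels(masks, max_displacement_px)
    data = tracked_masks.data
    T = frames.data.shape[0]

    all_ids = np.unique(data)
    all_ids = all_ids[all_ids > 0]

    values = {int(i): np.full(T, np.nan) for i in all_ids}
    valid = {int(i): np.zeros(T, dtype=bool) for i in all_ids}
    low_quality = {int(i): False for i in all_ids}

    previous_bg: float | None = None
    for t in range(T):
        frame = frames.data[t]
        mask = data[t]
        previous_bg = estimate_background(frame, mask, previous_bg)
        ids_here = np.unique(mask)
        for i in ids_here[ids_here > 0]:
            i = int(i)
            npx = int((mask == i).sum())
            if npx < MIN_REGION_PX:
                low_quality[i] = True
            values[i][t] = measure_cell(frame, mask, i, localization) - previous_bg
            valid[i][t] = True

    return [
        CellTrajectory(
            cell_id=i,
            strain=strain,
            condition=condition,
            times=frames.times,
            values=values[i],
            valid=valid[i],
            low_quality=low_quality[i],
        )
        for i in sorted(values)
    ]
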