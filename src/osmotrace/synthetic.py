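"""Ground-truthed synthetic single-cell trajectories and image stacks.

Emulates the statistical structure of a microfluidic chip experiment on
GFP-tagged yeast under osmotic stress: chambers start with 20-50 cells,
imaged every 5 minutes, stimulated after a pre-stimulus culture window;
cells divide, some are extruded from the chamber (truncated
trajectories); each strain follows one of four dynamic archetypes with
per-cell variability in response delay, production rate and steady
level; a subset of strains shows asynchronous post-peak bursts; signal
decays multiplicatively by photobleaching and sits on an additive
background with Gaussian measurement noise.

Everything is reproducible: identical (seed, config) gives bit-identical
trajectories, truth records and rendered images.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import CellTrajectory, StrainPanel

__all__ = [
    "ArchetypeClass",
    "ChamberCohort",
    "SimulationConfig",
    "SimulationTruth",
    "RenderGeometry",
    "ConfigurationError",
    "PlacementError",
    "DEFAULT_ARCHETYPES",
    "ARCHETYPE_LABELS",
    "default_time_grid",
    "archetype_profile",
    "simulate_trajectories",
    "render_images",
    "make_default_panel",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class PlacementError(RuntimeError):
    """Cells cannot be placed without overlap in the frame."""


ARCHETYPE_LABELS = (
    "rapid_up_adapt",
    "down_regulated",
    "slow_up_adapt",
    "late_up_no_adapt",
)


@dataclass(frozen=True)
class ArchetypeClass:
    """Shape parameters of one dynamic response archetype (fold scale).

    The fold curve is 1.0 before the stimulus, stays at 1.0 for
    ``response_delay_min`` after it, ramps linearly at
    ``rise_rate_per_min`` (fold units per minute) to ``peak_fold``, then
    relaxes exponentially toward ``steady_fold`` at
    ``adapt_rate_per_min``. ``adapt_rate_per_min = 0`` means no
    adaptation (the curve holds its peak level).
    """

    label: str
    response_delay_min: float
    rise_rate_per_min: float
    peak_fold: float
    adapt_rate_per_min: float
    steady_fold: float

    def __post_init__(self) -> None:
        if self.label not in ARCHETYPE_LABELS:
            raise ConfigurationError(f"unknown archetype label {self.label!r}")
        if self.rise_rate_per_min <= 0:
            raise ConfigurationError("rise_rate_per_min must be positive")
        if self.label in ("rapid_up_adapt", "slow_up_adapt"):
            if self.adapt_rate_per_min <= 0:
                raise ConfigurationError(f"{self.label} requires adapt_rate_per_min > 0")
        if self.label == "late_up_no_adapt" and self.adapt_rate_per_min != 0:
            raise ConfigurationError("late_up_no_adapt requires adapt_rate_per_min = 0")
        if self.label == "down_regulated" and self.peak_fold >= 1:
            raise ConfigurationError("down_regulated requires peak_fold < 1")

    @property
    def time_to_peak_min(self) -> float:
        """Minutes from stimulus until the curve attains peak_fold."""
        return self.response_delay_min + abs(self.peak_fold - 1.0) / self.rise_rate_per_min


#: Default archetype parameters (free config values; chosen to give the
#: four qualitatively distinct response shapes on the default 7.5 h grid).
DEFAULT_ARCHETYPES: dict[str, ArchetypeClass] = {
    "rapid_up_adapt": ArchetypeClass("rapid_up_adapt", 5.0, 0.08, 3.0, 0.02, 1.5),
    "down_regulated": ArchetypeClass("down_regulated", 10.0, 0.01, 0.5, 0.0, 0.5),
    "slow_up_adapt": ArchetypeClass("slow_up_adapt", 30.0, 0.015, 2.5, 0.008, 1.4),
    "late_up_no_adapt": ArchetypeClass("late_up_no_adapt", 150.0, 0.015, 2.5, 0.0, 2.5),
}


def default_time_grid(
    pre_min: float = 30.0, post_min: float = 420.0, dt_min: float = 5.0
) -> np.ndarray:
    """Canonical sampling grid: minutes relative to stimulus at t = 0.

    Default is 30 min pre-stimulus plus 7 h post-stimulus at 5-min
    spacing (91 points). The full 10 h acquisition (3 h pre-stimulus)
    is available via ``pre_min=180, post_min=420``.
    """
    n = int(round((pre_min + post_min) / dt_min)) + 1
    return -pre_min + dt_min * np.arange(n)


def archetype_profile(arch: ArchetypeClass, t) -> np.ndarray | float:
    """Deterministic archetype fold curve at time(s) ``t`` (min since stimulus).

    Returns 1.0 for all t < 0; continuous in t; attains ``peak_fold``
    exactly at ``arch.time_to_peak_min``.
    """
    t_arr = np.asarray(t, dtype=float)
    u = t_arr - arch.response_delay_min
    sign = 1.0 if arch.peak_fold >= 1.0 else -1.0
    ramp_dur = abs(arch.peak_fold - 1.0) / arch.rise_rate_per_min
    # linear ramp 1 -> peak_fold, then exponential relaxation to steady_fold
    rising = 1.0 + sign * arch.rise_rate_per_min * np.clip(u, 0.0, ramp_dur)
    v = np.where(
        u <= ramp_dur,
        rising,
        arch.steady_fold
        + (arch.peak_fold - arch.steady_fold)
        * np.exp(-arch.adapt_rate_per_min * np.maximum(u - ramp_dur, 0.0)),
    )
    v = np.where(t_arr < 0.0, 1.0, v)
    return v if v.ndim else float(v)


@dataclass(frozen=True)
class ChamberCohort:
    """Cell-count dynamics of one observation chamber.

    ``initial_cells`` None means a uniform draw from
    ``initial_cell_range`` (20-50 cells, the chip's loading regime).
    ``truncation_hazard`` is the per-frame probability that a cell is
    extruded from the chamber (trajectory truncated); ``division_rate``
    is the per-cell per-minute birth rate of new (non-full-length)
    cells.
    """

    times: np.ndarray = field(default_factory=default_time_grid)
    initial_cells: int | None = None
    initial_cell_range: tuple[int, int] = (20, 50)
    division_rate: float = 0.004
    truncation_hazard: float = 0.004

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if len(times) < 2:
            raise ConfigurationError("time grid needs at least 2 points")
        dt = np.diff(times)
        if not np.allclose(dt, dt[0]) or dt[0] <= 0:
            raise ConfigurationError("time grid must be uniform and increasing")
        if not (times < 0).any() or not (times >= 0).any():
            raise ConfigurationError("grid must span the stimulus (t=0)")

    @property
    def stimulus_index(self) -> int:
        return int(np.searchsorted(self.times, 0.0))

    @property
    def n_timepoints(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SimulationConfig:
    """Global signal/noise parameters and per-cell variability.

    Units: fluorescence in arbitrary units (a.u.), rates per minute.
    ``bleach_rate`` multiplies the signal by exp(-rate * elapsed) where
    elapsed is minutes since the first acquired frame.
    """

    baseline_level: float = 200.0  # mean pre-stimulus cell signal, a.u.
    background_level: float = 50.0  # additive camera/medium background, a.u.
    bleach_rate: float = 0.001  # per-min multiplicative decay
    noise_sd: float = 3.0  # additive Gaussian measurement noise, a.u.
    # per-cell parameter variability
    baseline_cv: float = 0.10
    delay_jitter_sd_min: float = 4.0
    rate_cv: float = 0.20
    steady_cv: float = 0.10
    # asynchronous post-peak bursts (strains flagged bursty in the panel)
    burst_rate_per_min: float = 0.006  # Poisson rate after the peak
    burst_amp_fold_mean: float = 0.8
    burst_amp_fold_sd: float = 0.2
    burst_width_min: float = 12.0

    def __post_init__(self) -> None:
        if self.baseline_level <= 0:
            raise ConfigurationError("baseline_level must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.bleach_rate < 0:
            raise ConfigurationError("bleach_rate must be >= 0")

    def noiseless(self) -> "SimulationConfig":
        """Copy with noise, bleaching, background and jitter all zero."""
        return replace(
            self,
            background_level=0.0,
            bleach_rate=0.0,
            noise_sd=0.0,
            baseline_cv=0.0,
            delay_jitter_sd_min=0.0,
            rate_cv=0.0,
            steady_cv=0.0,
        )


@dataclass
class SimulationTruth:
    """Per-cell ground truth plus the global generative parameters."""

    cells: pd.DataFrame  # one row per (strain, cell)
    archetypes: dict[str, ArchetypeClass]  # per-strain assignment
    config: SimulationConfig
    seed: int

    def cell_record(self, strain: str, cell_id: int) -> pd.Series:
        m = (self.cells["strain"] == strain) & (self.cells["cell_id"] == cell_id)
        rows = self.cells[m]
        if rows.empty:
            raise KeyError(f"no truth record for ({strain!r}, {cell_id})")
        return rows.iloc[0]


def make_default_panel(
    n_per_archetype: int = 10,
    condition: str = "0.4M",
    bursty_strains: tuple[str, ...] | None = None,
) -> StrainPanel:
    """Synthetic strain panel: n strains per archetype, round-robin localization.

    Strains are named ``<ARCHETYPE>_<i>``; ``bursty_strains`` marks
    which get asynchronous post-peak bursts (HSP12/PGM2-like).
    """
    locs = ["uniform", "membrane", "mitochondrial", "nuclear"]
    rows = []
    i = 0
    for label in ARCHETYPE_LABELS:
        for j in range(n_per_archetype):
            name = f"{label.upper()}_{j}"
            rows.append(
                {
                    "strain": name,
                    "localization": locs[i % 4],
                    "condition": condition,
                    "chamber": i,
                    "archetype": label,
                    "bursty": bursty_strains is not None and name in bursty_strains,
                }
            )
            i += 1
    return StrainPanel(pd.DataFrame(rows))


def _simulate_one_strain(
    strain: str,
    arch: ArchetypeClass,
    bursty: bool,
    condition: str,
    cohort: ChamberCohort,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[CellTrajectory], list[dict]]:
    times = cohort.times
    T = len(times)
    dt = float(times[1] - times[0])
    elapsed = times - times[0]

    if cohort.initial_cells is not None:
        n0 = int(cohort.initial_cells)
    else:
        lo, hi = cohort.initial_cell_range
        n0 = int(rng.integers(lo, hi + 1))

    # birth frame for every cell ever present: initial cells at frame 0,
    # then divisions at rate division_rate * n_alive per minute
    birth_frames = [0] * n0
    n_alive = n0
    for k in range(1, T):
        births = rng.poisson(cohort.division_rate * n_alive * dt)
        birth_frames.extend([k] * births)
        n_alive += births

    trajs: list[CellTrajectory] = []
    records: list[dict] = []
    for cell_id, birth in enumerate(birth_frames):
        # geometric washout: first frame >= birth at which the cell exits
        if cohort.truncation_hazard > 0:
            surv = rng.random(T - birth) >= cohort.truncation_hazard
            alive = np.flatnonzero(~surv)
            end = birth + int(alive[0]) if alive.size else T
            if end == birth:  # present for at least one frame
                end = birth + 1
        else:
            end = T

        delay = arch.response_delay_min + rng.normal(0.0, config.delay_jitter_sd_min)
        rate = arch.rise_rate_per_min * math.exp(rng.normal(0.0, config.rate_cv))
        steady_scale = math.exp(rng.normal(0.0, config.steady_cv))
        steady = 1.0 + (arch.steady_fold - 1.0) * steady_scale
        peak = 1.0 + (arch.peak_fold - 1.0) * steady_scale
        if arch.peak_fold < 1.0:  # keep down-regulated folds in (0, 1)
            peak = max(peak, 0.05)
            steady = max(steady, 0.05)
        cell_arch = replace(
            arch,
            response_delay_min=max(delay, 0.0),
            rise_rate_per_min=rate,
            peak_fold=peak,
            steady_fold=steady,
        )
        fold = np.asarray(archetype_profile(cell_arch, times), dtype=float)

        burst_times: list[float] = []
        burst_amps: list[float] = []
        if bursty:
            t_peak = cell_arch.time_to_peak_min
            t_end = float(times[-1])
            if t_end > t_peak:
                n_bursts = rng.poisson(config.burst_rate_per_min * (t_end - t_peak))
                for _ in range(n_bursts):
                    tb = float(rng.uniform(t_peak, t_end))
                    amp = max(
                        float(rng.normal(config.burst_amp_fold_mean, config.burst_amp_fold_sd)),
                        0.0,
                    )
                    burst_times.append(tb)
                    burst_amps.append(amp)
                    fold = fold + amp * np.exp(
                        -0.5 * ((times - tb) / config.burst_width_min) ** 2
                    )

        baseline = config.baseline_level * math.exp(rng.normal(0.0, config.baseline_cv))
        signal = baseline * fold * np.exp(-config.bleach_rate * elapsed)
        noise = rng.normal(0.0, config.noise_sd, T) if config.noise_sd > 0 else 0.0
        values = signal + config.background_level + noise

        valid = np.zeros(T, dtype=bool)
        valid[birth:end] = True
        values = np.where(valid, values, np.nan)

        trajs.append(
            CellTrajectory(cell_id, strain, condition, times, values, valid)
        )
        records.append(
            {
                "strain": strain,
                "cell_id": cell_id,
                "archetype": arch.label,
                "birth_frame": birth,
                "end_frame": end,
                "full_length": birth == 0 and end == T,
                "baseline_au": baseline,
                "response_delay_min": cell_arch.response_delay_min,
                "rise_rate_per_min": cell_arch.rise_rate_per_min,
                "peak_fold": cell_arch.peak_fold,
                "steady_fold": cell_arch.steady_fold,
                "n_bursts": len(burst_times),
                "burst_times_min": ";".join(f"{t:.2f}" for t in burst_times),
                "burst_amps_fold": ";".join(f"{a:.4f}" for a in burst_amps),
            }
        )
    return trajs, records


def simulate_trajectories(
    panel: StrainPanel,
    cohort: ChamberCohort,
    config: SimulationConfig | None = None,
    seed: int = 0,
    archetypes: dict[str, ArchetypeClass] | None = None,
) -> tuple[list[CellTrajectory], SimulationTruth]:
    """Simulate per-cell trajectories for every strain in the panel.

    Each cell's series is baseline x archetype fold curve (per-cell
    jittered parameters, optional asynchronous bursts) x exp(-bleach
    rate x elapsed) + background + Gaussian noise. Cells extruded from
    the chamber carry valid=False after exit. Returns the trajectories
    and a :class:`SimulationTruth` that traces every cell to its
    generative parameters.
    """
    config = config or SimulationConfig()
    archetypes = archetypes or DEFAULT_ARCHETYPES
    rng = np.random.default_rng(seed)

    assigned: dict[str, ArchetypeClass] = {}
    all_trajs: list[CellTrajectory] = []
    all_records: list[dict] = []
    for row in panel.table.itertuples(index=False):
        label = getattr(row, "archetype", None)
        if label is None or (isinstance(label, float) and math.isnan(label)):
            # stable across processes (unlike built-in str hash)
            label = ARCHETYPE_LABELS[zlib.crc32(row.strain.encode()) % 4]
        if label not in archetypes:
            raise ConfigurationError(f"unknown archetype label {label!r}")
        arch = archetypes[label]
        assigned[row.strain] = arch
        bursty = bool(getattr(row, "bursty", False))
        trajs, records = _simulate_one_strain(
            row.strain, arch, bursty, row.condition, cohort, config, rng
        )
        all_trajs.extend(trajs)
        all_records.extend(records)

    truth = SimulationTruth(
        cells=pd.DataFrame(all_records), archetypes=assigned, config=config, seed=seed
    )
    return all_trajs, truth


# ---------------------------------------------------------------------------
# image rendering


@dataclass(frozen=True)
class RenderGeometry:
    """Frame geometry for rendering one chamber's cells.

    Cells are rendered as non-overlapping disks. In ``nuclear`` mode a
    bright sub-region covering 10% of the cell's pixels carries the
    trajectory value and the remaining pixels a ``cyto_fraction`` of it,
    so the top-10% readout reproduces the input trajectory.
    """

    shape: tuple[int, int] = (192, 192)
    cell_radius_px: int = 6
    background_level: float = 0.0
    noise_sd: float = 0.0
    localization: str = "uniform"
    cyto_fraction: float = 0.25
    margin_px: int = 2


def _place_cells(
    n: int, geom: RenderGeometry, rng: np.random.Generator
) -> list[tuple[int, int]]:
    h, w = geom.shape
    r = geom.cell_radius_px
    min_sep2 = (2 * r + geom.margin_px) ** 2
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < n:
        if attempts > 2000 * n:
            raise PlacementError(
                f"could not place {n} cells of radius {r} in a {h}x{w} frame"
            )
        cy = int(rng.integers(r, h - r))
        cx = int(rng.integers(r, w - r))
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep2 for y, x in centers):
            centers.append((cy, cx))
        attempts += 1
    return centers


def render_images(
    trajs: list[CellTrajectory],
    geometry: RenderGeometry | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render trajectories as (fluorescence stack, labeled mask stack).

    Returns float64 fluorescence frames of shape (T, H, W) and an int32
    mask stack where pixel label ``cell_id + 1`` marks cell membership
    (0 = background). Pixel statistics reproduce each input trajectory
    under the matching readout rule; use
    :func:`osmotrace.pipeline.write_image_stacks` for 16-bit TIFF export.
    """
    geom = geometry or RenderGeometry()
    rng = np.random.default_rng(seed)
    if not trajs:
        raise ValueError("no trajectories to render")
    T = trajs[0].n_timepoints
    h, w = geom.shape
    centers = _place_cells(len(trajs), geom, rng)

    yy, xx = np.mgrid[0:h, 0:w]
    disks = []
    for (cy, cx), traj in zip(centers, trajs):
        member = (yy - cy) ** 2 + (xx - cx) ** 2 <= geom.cell_radius_px**2
        idx = np.flatnonzero(member.ravel())
        n_nuc = math.ceil(0.1 * idx.size)
        nuc_idx = rng.choice(idx, size=n_nuc, replace=False)
        disks.append((traj, idx, nuc_idx))

    frames = np.empty((T, h, w), dtype=np.float64)
    masks = np.zeros((T, h, w), dtype=np.int32)
    for t in range(T):
        if geom.noise_sd > 0:
            frame = geom.background_level + rng.normal(0.0, geom.noise_sd, (h, w))
        else:
            frame = np.full((h, w), geom.background_level, dtype=np.float64)
        frame = frame.ravel()
        mask = masks[t].ravel()
        for traj, idx, nuc_idx in disks:
            if not traj.valid[t]:
                continue
            v = traj.values[t]
            if geom.localization == "nuclear":
                frame[idx] = geom.cyto_fraction * v
                frame[nuc_idx] = v
            else:
                frame[idx] = v
            mask[idx] = traj.cell_id + 1
        frames[t] = frame.reshape(h, w)
        masks[t] = mask.reshape(h, w)
    return frames, masks
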