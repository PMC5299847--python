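"""Shared data containers for the single-cell trajectory pipeline.

Time convention: the canonical time axis is minutes relative to the
osmotic stimulus (stimulus at t = 0, pre-stimulus times negative).
All trajectories in a panel share one time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: KCl conditions used in the osmotic stress experiments (molarity labels).
CONDITIONS = ("0M", "0.2M", "0.4M", "0.8M")

#: Localization classes and their readout mode. Whole-cell mean for
#: uniform/membrane/mitochondrial proteins, mean of the brightest 10% of
#: pixels for nuclear proteins.
LOCALIZATION_CLASSES = ("uniform", "membrane", "mitochondrial", "nuclear")


@dataclass
class CellTrajectory:
    """One cell's fluorescence time series S_t with validity flags.

    ``values`` are arbitrary fluorescence units on the shared grid;
    ``valid`` is False where the cell was absent (not yet born, or
    extruded from the observation chamber).
    """

    cell_id: int
    strain: str
    condition: str
    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    low_quality: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.times) == len(self.values) == len(self.valid)):
            raise ValueError("times, values and valid must have equal length")

    @property
    def n_timepoints(self) -> int:
        return len(self.times)

    @property
    def is_full_length(self) -> bool:
        """True if the cell persists from the first to the last frame."""
        return bool(self.valid.all())


@dataclass
class PopulationProfile:
    """Per-time mean over valid cells in one chamber (S̄_t), with counts.

    ``flagged`` marks time points whose cell count fell below the
    configured minimum (default 10).
    """

    strain: str
    condition: str
    times: np.ndarray
    mean: np.ndarray
    counts: np.ndarray
    flagged: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.flagged = np.asarray(self.flagged, dtype=bool)


@dataclass
class NormalizedProfile:
    """log2 fold values per time, zero-mean over the baseline window.

    value_t = log2(profile_t / baseline_mean); the baseline window is
    given in minutes relative to stimulus, default the 30 min before it.
    """

    strain: str
    condition: str
    times: np.ndarray
    log2_values: np.ndarray
    baseline_window: tuple[float, float]
    source: str = "population"  # "population" | "representative"
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.log2_values = np.asarray(self.log2_values, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(self.log2_values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)


@dataclass
class StrainPanel:
    """Strain/protein metadata table.

    Columns: strain, localization (one of LOCALIZATION_CLASSES),
    condition, chamber; optional simulation columns archetype and bursty.
    """

    table: pd.DataFrame

    REQUIRED = ("strain", "localization", "condition")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        bad = set(self.table["localization"]) - set(LOCALIZATION_CLASSES)
        if bad:
            raise ValueError(f"unknown localization classes: {sorted(bad)}")

    @property
    def strains(self) -> list[str]:
        return list(self.table["strain"])

    def localization(self, strain: str) -> str:
        rows = self.table.loc[self.table["strain"] == strain, "localization"]
        if rows.empty:
            raise KeyError(f"strain {strain!r} not in panel")
        return str(rows.iloc[0])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RepresentativeResult:
    """M1 scores, representative cell and M2 for one strain cohort."""

    strain: str
    cell_ids: np.ndarray
    m1_scores: np.ndarray
    rep_cell_id: int
    rep_series: np.ndarray
    m2: float
    n_cells: int
    n_timepoints: int


@dataclass
class ProfileMatrix:
    """Proteins × time matrix of log2 normalized expression."""

    values: np.ndarray
    row_labels: list[str]
    time_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_labels = np.asarray(self.time_labels, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.time_labels)):
            raise ValueError("matrix shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_labels, columns=self.time_labels
        )


@dataclass
class ClusterResult:
    """Hierarchical clustering of protein dynamic profiles."""

    linkage: np.ndarray
    leaf_order: np.ndarray
    modules: np.ndarray  # 1-based module label per row
    k: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    row_labels: list[str] = field(default_factory=list)
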