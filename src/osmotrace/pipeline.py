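"""Run configuration, tidy-CSV I/O and stage orchestration.

One CSV dialect everywhere: comma-separated, UTF-8, header line
mandatory, one observation per row, times in minutes relative to the
stimulus. Every output file starts with ``#`` comment lines carrying
the config hash and seed, so any artifact can be traced to the run
that produced it.

Stages: simulate -> (quantify) -> analyze -> represent -> cluster.
``quantify`` consumes rendered image/mask TIFF stacks; when the run is
purely trajectory-based the simulate stage's CSV feeds ``analyze``
directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .clustering import (
    build_profile_matrix,
    cut_modules,
    hcluster,
    linkage_to_newick,
    module_summary,
)
from .imaging import FrameStack, MaskStack, extract_trajectories
from .representative import rank_m2, representative_analysis
from .synthetic import (
    ChamberCohort,
    RenderGeometry,
    SimulationConfig,
    default_time_grid,
    make_default_panel,
    render_images,
    simulate_trajectories,
)
from .trajectories import (
    DEFAULT_BASELINE_WINDOW,
    DEFAULT_MIN_CELLS,
    FOLD_CHANGE_THRESHOLD,
    SNR_THRESHOLD,
    compute_fold_change,
    compute_snr,
    correct_bleach,
    fit_bleach,
    normalize_log2,
    population_mean,
    select_proteins,
)
from .types import CellTrajectory, NormalizedProfile, StrainPanel

logger = logging.getLogger("osmotrace")

__all__ = [
    "RunConfig",
    "run_pipeline",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_image_stacks",
    "read_image_stacks",
    "PipelineError",
]

STAGES = ("simulate", "quantify", "analyze", "represent", "cluster")


class PipelineError(RuntimeError):
    """A stage's inputs are missing or the configuration is invalid."""


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run."""

    outdir: str = "osmotrace_out"
    seed: int = 0
    condition: str = "0.4M"
    # time grid (minutes)
    pre_min: float = 30.0
    post_min: float = 420.0
    dt_min: float = 5.0
    # synthetic panel / cohort
    n_per_archetype: int = 10
    bursty_strains: tuple[str, ...] = ()
    initial_cells: int | None = None
    division_rate: float = 0.004
    truncation_hazard: float = 0.004
    # signal model
    baseline_level: float = 200.0
    background_level: float = 50.0
    bleach_rate: float = 0.001
    noise_sd: float = 3.0
    # analysis thresholds
    min_cells: int = DEFAULT_MIN_CELLS
    snr_threshold: float = SNR_THRESHOLD
    fc_threshold: float = FOLD_CHANGE_THRESHOLD
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW
    bleach_mode: str = "fit"  # "fit" | "known" | "off"
    # representative / clustering
    cluster_k: int | None = None  # None = silhouette-selected
    cluster_source: str = "representative"  # or "population"
    # rendering (quantify stage)
    render: bool = False
    render_strains: int = 4  # how many strains get image stacks
    frame_px: int = 192
    cell_radius_px: int = 6

    def __post_init__(self) -> None:
        for name in ("snr_threshold", "fc_threshold", "dt_min"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"config field {name} must be positive")
        if self.bleach_mode not in ("fit", "known", "off"):
            raise PipelineError(f"invalid bleach_mode {self.bleach_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(raw) - known)
        if bad:
            raise PipelineError(f"unknown config keys: {bad}")
        if "baseline_window" in raw:
            raw["baseline_window"] = tuple(raw["baseline_window"])
        if "bursty_strains" in raw:
            raw["bursty_strains"] = tuple(raw["bursty_strains"])
        return cls(**raw)

    def config_hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("outdir")  # paths don't change the science
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def time_grid(self) -> np.ndarray:
        return default_time_grid(self.pre_min, self.post_min, self.dt_min)

    def cohort(self) -> ChamberCohort:
        return ChamberCohort(
            times=self.time_grid(),
            initial_cells=self.initial_cells,
            division_rate=self.division_rate,
            truncation_hazard=self.truncation_hazard,
        )

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            baseline_level=self.baseline_level,
            background_level=self.background_level,
            bleach_rate=self.bleach_rate,
            noise_sd=self.noise_sd,
        )


# ---------------------------------------------------------------------------
# tidy CSV I/O


def _header_lines(config: RunConfig) -> str:
    return (
        f"# osmotrace {__version__}\n"
        f"# config_hash={config.config_hash()}\n"
        f"# seed={config.seed}\n"
    )


def write_trajectories_csv(
    trajs: list[CellTrajectory], path: str | Path, config: RunConfig | None = None
) -> None:
    """Tidy long-format table: strain, condition, cell_id, time_min, intensity_au, valid."""
    frames = []
    for t in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "strain": t.strain,
                    "condition": t.condition,
                    "cell_id": t.cell_id,
                    "time_min": t.times,
                    "intensity_au": t.values,
                    "valid": t.valid.astype(int),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(_header_lines(config))
        df.to_csv(fh, index=False)


def read_trajectories_csv(path: str | Path) -> list[CellTrajectory]:
    df = pd.read_csv(path, comment="#")
    trajs = []
    for (strain, condition, cell_id), g in df.groupby(
        ["strain", "condition", "cell_id"], sort=True
    ):
        g = g.sort_values("time_min")
        trajs.append(
            CellTrajectory(
                cell_id=int(cell_id),
                strain=str(strain),
                condition=str(condition),
                times=g["time_min"].to_numpy(),
                values=g["intensity_au"].to_numpy(),
                valid=g["valid"].to_numpy().astype(bool),
            )
        )
    return trajs


def _write_df(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, index=index)


def write_image_stacks(
    frames: np.ndarray, masks: np.ndarray, frame_path: str | Path, mask_path: str | Path
) -> None:
    """Export rendered stacks as multi-page TIFF (fluorescence 16-bit, masks int32)."""
    fl = np.clip(np.rint(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(frame_path, fl)
    tifffile.imwrite(mask_path, masks.astype(np.int32))


def read_image_stacks(
    frame_path: str | Path, mask_path: str | Path, times: np.ndarray
) -> tuple[FrameStack, MaskStack]:
    fl = tifffile.imread(frame_path)
    mk = tifffile.imread(mask_path)
    return FrameStack(fl.astype(float), times), MaskStack(mk.astype(np.int64), times)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, outdir: Path) -> None:
    panel = make_default_panel(
        n_per_archetype=config.n_per_archetype,
        condition=config.condition,
        bursty_strains=config.bursty_strains or None,
    )
    trajs, truth = simulate_trajectories(
        panel, config.cohort(), config.sim_config(), seed=config.seed
    )
    write_trajectories_csv(trajs, outdir / "trajectories.csv", config)
    _write_df(truth.cells, outdir / "truth.csv", config)
    _write_df(panel.table, outdir / "panel.csv", config)
    logger.info(
        "simulate: %d strains, %d cells, grid of %d points",
        len(panel),
        len(truth.cells),
        config.cohort().n_timepoints,
    )
    if config.render:
        geom = RenderGeometry(
            shape=(config.frame_px, config.frame_px),
            cell_radius_px=config.cell_radius_px,
            background_level=config.background_level,
            noise_sd=config.noise_sd,
        )
        imgdir = outdir / "images"
        imgdir.mkdir(parents=True, exist_ok=True)
        by_strain: dict[str, list[CellTrajectory]] = {}
        for t in trajs:
            by_strain.setdefault(t.strain, []).append(t)
        for strain in list(by_strain)[: config.render_strains]:
            full = [t for t in by_strain[strain] if t.is_full_length]
            fr, mk = render_images(full, geom, seed=config.seed)
            write_image_stacks(
                fr, mk, imgdir / f"{strain}_fluor.tif", imgdir / f"{strain}_mask.tif"
            )


def _stage_quantify(config: RunConfig, outdir: Path) -> None:
    imgdir = outdir / "images"
    panel_path = outdir / "panel.csv"
    if not imgdir.is_dir():
        raise PipelineError(
            f"stage 'quantify' needs rendered image stacks in {imgdir} "
            "(run 'simulate' with render: true, or point outdir at real stacks)"
        )
    if not panel_path.exists():
        raise PipelineError(f"stage 'quantify' needs the panel table {panel_path}")
    panel = StrainPanel(pd.read_csv(panel_path, comment="#"))
    times = config.time_grid()
    all_trajs: list[CellTrajectory] = []
    for fpath in sorted(imgdir.glob("*_fluor.tif")):
        strain = fpath.name[: -len("_fluor.tif")]
        mpath = imgdir / f"{strain}_mask.tif"
        if not mpath.exists():
            raise PipelineError(f"stage 'quantify': missing mask stack {mpath}")
        frames, masks = read_image_stacks(fpath, mpath, times)
        all_trajs.extend(
            extract_trajectories(
                frames,
                masks,
                strain=strain,
                condition=config.condition,
                localization=panel.localization(strain),
                tracked=True,
            )
        )
    write_trajectories_csv(all_trajs, outdir / "quantified.csv", config)
    logger.info("quantify: %d trajectories from %s", len(all_trajs), imgdir)


def _load_corrected(config: RunConfig, outdir: Path) -> dict[str, list[CellTrajectory]]:
    traj_path = outdir / "trajectories.csv"
    if not traj_path.exists():
        raise PipelineError(
            f"stage needs trajectory table {traj_path} (run 'simulate' first)"
        )
    trajs = read_trajectories_csv(traj_path)
    # background subtraction: simulated tables carry signal + background
    for t in trajs:
        t.values = t.values - config.background_level

    by_strain: dict[str, list[CellTrajectory]] = {}
    for t in trajs:
        by_strain.setdefault(t.strain, []).append(t)

    if config.bleach_mode == "off":
        return by_strain
    if config.bleach_mode == "known":
        rate = config.bleach_rate
    else:
        # fit on pooled pre-stimulus data (no 0 M chamber in the default panel)
        n_pre = int((config.time_grid() < 0).sum())
        pre = []
        for ts in by_strain.values():
            for t in ts:
                m = (t.times < 0) & t.valid & np.isfinite(t.values)
                if m.sum() == n_pre:  # only cells spanning the whole window
                    pre.append(t.values[m])
        mean_by_t = np.stack(pre).mean(axis=0) if pre else None
        if mean_by_t is None or len(mean_by_t) < 5:
            logger.warning("too few pre-stimulus points for a bleach fit; rate=0")
            rate = 0.0
        else:
            grid = config.time_grid()[:n_pre]
            control = CellTrajectory(
                0, "pooled", config.condition, grid, mean_by_t, np.ones(n_pre, bool)
            )
            try:
                rate = fit_bleach(control)
            except ValueError:
                rate = 0.0
    logger.info("bleach correction: mode=%s rate=%.5f/min", config.bleach_mode, rate)
    return {
        s: [correct_bleach(t, rate) for t in ts] for s, ts in by_strain.items()
    }


def _stage_analyze(config: RunConfig, outdir: Path) -> None:
    by_strain = _load_corrected(config, outdir)
    heat_rows, metric_rows = {}, []
    for strain in sorted(by_strain):
        ts = by_strain[strain]
        prof = population_mean(ts, min_cells=config.min_cells)
        norm = normalize_log2(prof, config.baseline_window, source="population")
        heat_rows[strain] = norm.log2_values
        snr = compute_snr(ts, background_sd=max(config.noise_sd, 1e-9))
        fc = compute_fold_change(norm)
        metric_rows.append({"strain": strain, "snr": snr, "fold_change": fc})
    times = config.time_grid()
    heat = pd.DataFrame(heat_rows, index=times).T
    heat.index.name = "strain"
    _write_df(heat, outdir / "heatmap_population.csv", config, index=True)
    metrics = pd.DataFrame(metric_rows)
    kept = select_proteins(metrics, config.snr_threshold, config.fc_threshold)
    metrics["kept"] = metrics["strain"].isin(kept).astype(int)
    _write_df(metrics, outdir / "selection_metrics.csv", config)
    logger.info(
        "analyze: %d/%d strains pass SNR>%g and FC>%g",
        len(kept),
        len(metrics),
        config.snr_threshold,
        config.fc_threshold,
    )


def _stage_represent(config: RunConfig, outdir: Path) -> None:
    by_strain = _load_corrected(config, outdir)
    results, m1_rows, heat_rows = [], [], {}
    for strain in sorted(by_strain):
        res = representative_analysis(by_strain[strain])
        results.append(res)
        for cid, score in zip(res.cell_ids, res.m1_scores):
            m1_rows.append({"strain": strain, "cell_id": int(cid), "m1": float(score)})
        rep = CellTrajectory(
            res.rep_cell_id,
            strain,
            config.condition,
            config.time_grid(),
            res.rep_series,
            np.ones_like(res.rep_series, dtype=bool),
        )
        prof = population_mean([rep], min_cells=1)
        norm = normalize_log2(prof, config.baseline_window, source="representative")
        heat_rows[strain] = norm.log2_values
    _write_df(pd.DataFrame(m1_rows), outdir / "m1_scores.csv", config)
    _write_df(rank_m2(results), outdir / "representative_summary.csv", config)
    heat = pd.DataFrame(heat_rows, index=config.time_grid()).T
    heat.index.name = "strain"
    _write_df(heat, outdir / "heatmap_representative.csv", config, index=True)
    logger.info("represent: %d strains, top M2 = %s", len(results), rank_m2(results).iloc[0]["strain"])


def _stage_cluster(config: RunConfig, outdir: Path) -> None:
    src = "representative" if config.cluster_source == "representative" else "population"
    heat_path = outdir / f"heatmap_{src}.csv"
    if not heat_path.exists():
        raise PipelineError(
            f"stage 'cluster' needs the profile matrix {heat_path} "
            f"(run '{'represent' if src == 'representative' else 'analyze'}' first)"
        )
    heat = pd.read_csv(heat_path, comment="#", index_col=0)
    profiles = [
        NormalizedProfile(
            strain=str(s),
            condition=config.condition,
            times=heat.columns.to_numpy(dtype=float),
            log2_values=heat.loc[s].to_numpy(dtype=float),
            baseline_window=config.baseline_window,
            source=src,
        )
        for s in heat.index
    ]
    matrix = build_profile_matrix(profiles, source=src)
    tree = hcluster(matrix)
    result = cut_modules(tree, matrix, k=config.cluster_k)
    _write_df(
        pd.DataFrame({"strain": matrix.row_labels, "module": result.modules}),
        outdir / "modules.csv",
        config,
    )
    (outdir / "dendrogram.nwk").write_text(linkage_to_newick(result) + "\n")
    _write_df(module_summary(result, matrix), outdir / "module_summary.csv", config)
    _plot_heatmap(matrix, result, outdir / "heatmap_clustered.png")
    logger.info("cluster: k=%d modules over %d strains", result.k, len(matrix.row_labels))


def _plot_heatmap(matrix, result, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = result.leaf_order
    fig, ax = plt.subplots(figsize=(8, max(3, 0.18 * len(order))))
    vmax = np.nanmax(np.abs(matrix.values)) or 1.0
    im = ax.imshow(
        matrix.values[order],
        aspect="auto",
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        extent=(matrix.time_labels[0], matrix.time_labels[-1], len(order), 0),
    )
    ax.set_yticks(np.arange(len(order)) + 0.5)
    ax.set_yticklabels([matrix.row_labels[i] for i in order], fontsize=5)
    ax.set_xlabel("time since stimulus (min)")
    fig.colorbar(im, ax=ax, label="log2 normalized expression")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig, stage: str = "all") -> Path:
    """Execute one stage (or all, in order) and write a run manifest.

    Re-running with an identical config and seed reproduces identical
    CSV outputs.
    """
    if stage != "all" and stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info(
        "run: seed=%d baseline_window=%s snr>%g fc>%g min_cells=%d bleach=%s "
        "cluster_k=%s linkage=average metric=euclidean",
        config.seed,
        config.baseline_window,
        config.snr_threshold,
        config.fc_threshold,
        config.min_cells,
        config.bleach_mode,
        config.cluster_k,
    )
    stages = list(STAGES) if stage == "all" else [stage]
    if stage == "all" and not config.render:
        stages.remove("quantify")
    for s in stages:
        {
            "simulate": _stage_simulate,
            "quantify": _stage_quantify,
            "analyze": _stage_analyze,
            "represent": _stage_represent,
            "cluster": _stage_cluster,
        }[s](config, outdir)

    manifest = {
        "package": f"osmotrace {__version__}",
        "stages": stages,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "versions": _versions(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return outdir


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
    }
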