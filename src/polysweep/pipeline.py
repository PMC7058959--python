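"""End-to-end experiment orchestration: grids, replicates, seeds, tables.

For each grid cell (ploidy k, selection s, dominance H, population size N,
post-fixation delay tau_post) and replicate, the pipeline chains
trajectory -> trajectory-conditioned coalescent -> windowed statistics ->
peak summaries, and writes three tidy TSVs (trajectory summaries, window
statistics, peak summaries).  The trajectory ploidy `k_traj` and the
genomic ploidy `k_genomic` can be crossed independently to decompose the
sweep-trajectory effect from the diversity/recombination-rate effect.

Seeding: replicate seed = (master_seed + crc32(f"{cell}:{rep}")) mod 2^31,
so any cell x replicate is independently re-runnable and a fixed master
seed reproduces byte-identical tables.
"""

from __future__ import annotations

import logging
import time as _time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import peaks as pk
from . import popstats as ps
from .coalescent import Demography, LocusConfig, simulate_sweep_sample
from .trajectory import ConditioningError, SelectionModel, simulate_trajectory

__all__ = ["ExperimentConfig", "Cell", "run_experiment", "default_paper_grid",
           "replicate_seed", "run_replicate"]

logger = logging.getLogger("polysweep")


@dataclass(frozen=True)
class Cell:
    """One parameter combination of the experiment grid."""

    k_traj: int
    k_genomic: int
    s: float
    H: float
    N: int
    tau_post: float = 0.0


@dataclass
class ExperimentConfig:
    """Grid specification plus shared sampling/locus settings.

    By default `k` values drive both the trajectory and the genome copy
    number; `decompose=True` additionally crosses k_traj x k_genomic over
    the same k list (the trajectory-versus-diversity decomposition).
    """

    k: list[int] = field(default_factory=lambda: [2, 4])
    s: list[float] = field(default_factory=lambda: [0.01])
    H: list[float] = field(default_factory=lambda: [0.0])
    N: list[int] = field(default_factory=lambda: [1000])
    tau_post: list[float] = field(default_factory=lambda: [0.0])
    n: int = 10
    sample_mode: str = "individuals"
    reps: int = 20
    master_seed: int = 1
    decompose: bool = False
    locus: LocusConfig = field(default_factory=LocusConfig)
    span: float = 0.1
    max_attempts: int = 10**6
    metrics: tuple[str, ...] = ("pi", "tajd", "fst")

    def cells(self) -> list[Cell]:
        out = []
        for N in self.N:
            for s in self.s:
                for H in self.H:
                    for tau in self.tau_post:
                        if self.decompose:
                            pairs = [(kt, kg) for kt in self.k for kg in self.k]
                        else:
                            pairs = [(k, k) for k in self.k]
                        for kt, kg in pairs:
                            out.append(Cell(kt, kg, s, H, N, tau))
        return out

    def validate(self) -> None:
        for cell in self.cells():
            SelectionModel(k=cell.k_traj, N=cell.N, s=cell.s, H=cell.H)
            Demography(N=cell.N, k_genomic=cell.k_genomic, n=self.n,
                       tau_post=cell.tau_post, sample_mode=self.sample_mode)
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def replicate_seed(master_seed: int, cell_index: int, rep: int) -> int:
    """Stable per-replicate seed below 2^31."""
    h = zlib.crc32(f"{cell_index}:{rep}".encode()) & 0x3FFFFFFF
    return (master_seed + h) % (2**31)


def default_paper_grid(reps: int = 5) -> ExperimentConfig:
    """The headline grid (desk-scale replicate count).

    k in {2,4,8}, s in {0.001,0.01,0.1}, H in {-0.4,0,0.4},
    N in {1000, 10000}, n = 10 individuals per population.
    """
    return ExperimentConfig(
        k=[2, 4, 8],
        s=[0.001, 0.01, 0.1],
        H=[-0.4, 0.0, 0.4],
        N=[1000, 10000],
        reps=reps,
    )


def run_replicate(
    cell: Cell, config: ExperimentConfig, seed: int
) -> tuple[dict, pd.DataFrame, dict]:
    """One full replicate of one grid cell; returns (trajectory row,
    window-stat table, peak row)."""
    rng = np.random.default_rng(seed)
    t_start = _time.perf_counter()
    model = SelectionModel(k=cell.k_traj, N=cell.N, s=cell.s, H=cell.H)
    traj = simulate_trajectory(model, rng, max_attempts=config.max_attempts)
    demog = Demography(
        N=cell.N, k_genomic=cell.k_genomic, n=config.n,
        tau_post=cell.tau_post, sample_mode=config.sample_mode,
    )
    matrix = simulate_sweep_sample(traj, demog, config.locus, rng)
    windows = ps.window_spec(config.locus.L, cell.N)
    table = ps.window_table(matrix, windows)

    mids = table["window_mid"].to_numpy()
    sel_pos = config.locus.sel_pos
    smooth_sel = pk.loess_smooth(mids, table["pi_sel"].to_numpy(), span=config.span)
    smooth_neu = pk.loess_smooth(mids, table["pi_neu"].to_numpy(), span=config.span)
    baseline = float(np.nanmean(smooth_neu))
    summary = pk.peak_metrics(mids, smooth_sel, baseline, sel_pos)
    peak_row = {
        "magnitude": summary.magnitude,
        "breadth": summary.breadth,
        "area": summary.area,
        "recovered": summary.recovered,
        "censored": summary.censored,
        "baseline_pi": baseline,
        "min_pi": float(np.nanmin(smooth_sel)),
        "pi_auc": pk.area_under_peak(mids, smooth_sel, sel_pos),
    }
    central = np.argmin(np.abs(mids - sel_pos))
    peak_row["central_pi"] = float(table["pi_sel"].iloc[central])
    for metric, col in (("tajd", "tajd_neg_sel"), ("fst", "fst_std")):
        if metric in config.metrics and col in table:
            vals = table[col].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            if ok.sum() >= max(5, int(np.ceil(config.span * ok.sum()))):
                sm = pk.loess_smooth(mids[ok], vals[ok], span=config.span)
                peak_row[f"{metric}_max"] = float(np.nanmax(sm))
                try:
                    peak_row[f"{metric}_auc"] = pk.area_under_peak(mids[ok], sm, sel_pos)
                except ValueError:
                    peak_row[f"{metric}_auc"] = np.nan
    traj_row = {
        "fixation_time": traj.length,
        "attempts": traj.attempts + 1,
        "n_sites": matrix.n_sites,
    }
    # wall-clock stays out of the tables so reruns are byte-identical
    traj_row["_runtime_s"] = round(_time.perf_counter() - t_start, 3)
    return traj_row, table, peak_row


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> dict[str, pd.DataFrame]:
    """Run the full grid; returns (and optionally writes) the three tables.

    Failed replicates (e.g. conditioning failures in strongly recessive,
    high-ploidy cells) are logged and skipped; a cell whose replicates all
    fail aborts the run.
    """
    config.validate()
    traj_rows, stat_rows, peak_rows = [], [], []
    for ci, cell in enumerate(config.cells()):
        n_ok = 0
        errors: list[str] = []
        for rep in range(config.reps):
            seed = replicate_seed(config.master_seed, ci, rep)
            params = {
                "cell": ci, "replicate": rep, "seed": seed,
                "k_traj": cell.k_traj, "k_genomic": cell.k_genomic,
                "s": cell.s, "H": cell.H, "N": cell.N,
                "tau_post": cell.tau_post, "n": config.n,
                "sample_mode": config.sample_mode,
            }
            try:
                traj_row, table, peak_row = run_replicate(cell, config, seed)
            except (ConditioningError, RuntimeError, ValueError) as exc:
                errors.append(f"rep {rep}: {exc}")
                logger.warning("cell %d rep %d failed: %s", ci, rep, exc)
                continue
            n_ok += 1
            runtime = traj_row.pop("_runtime_s")
            traj_rows.append({**params, **traj_row})
            peak_rows.append({**params, **peak_row})
            table = table.assign(**params)
            stat_rows.append(table)
            logger.info(
                "cell %d rep %d seed %d: T=%d attempts=%d S=%d %.2fs",
                ci, rep, seed, traj_row["fixation_time"],
                traj_row["attempts"], traj_row["n_sites"], runtime,
            )
        if n_ok == 0:
            raise RuntimeError(
                f"all {config.reps} replicates failed for cell {cell}: {errors}"
            )
    tables = {
        "trajectories": pd.DataFrame(traj_rows),
        "stats": pd.concat(stat_rows, ignore_index=True),
        "peaks": pd.DataFrame(peak_rows),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
    return tables
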