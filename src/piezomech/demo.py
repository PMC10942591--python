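"""End-to-end synthetic study: every pipeline stage on generated data.

``run_demo`` generates IRM, fluorescence, track and puncta fixtures with
known ground truth, runs each analysis stage, and writes a JSON report
plus CSV tables.  It doubles as an executable validation of the whole
package: parameter recovery, MSD diffusion recovery, polarity skew
recovery and the colocalization test are all computed from scratch.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from piezomech import coloc, fluctsim, irm, motility, polarity, tension_corr
from piezomech.config import PipelineConfig, RunManifest
from piezomech.model import (
    DEFAULT_PARAMS,
    MechanicalParams,
    N_PER_M_TO_PN_PER_UM,
)
from piezomech.optics import IRMOptics


def _fit_tension_map(params: MechanicalParams, cfg: PipelineConfig,
                     n_rois: int, seed: int) -> irm.FluctuationMap:
    """Simulate ``n_rois`` 16-pixel ROIs and fit each tile-averaged PSD."""
    grid = cfg.spectral.grid()
    hm = fluctsim.simulate_height_series(params, grid,
                                         n_pixels=(n_rois, 16), seed=seed)
    tensions = np.full((1, n_rois), np.nan)
    for i in range(n_rois):
        spec = irm.tile_spectrum(hm.heights[:, i, :].T, grid.fs)
        fit = irm.fit_helfrich(spec, grid=grid, fix={"A": params.A},
                               exposure=cfg.spectral.exposure,
                               fit_band=cfg.spectral.fit_band())
        if fit.converged:
            tensions[0, i] = fit.params.sigma * N_PER_M_TO_PN_PER_UM
    sd = hm.heights.std(axis=0, ddof=1).mean(axis=1, keepdims=True).T
    return irm.FluctuationMap(sd_time=sd, tension=tensions,
                              mask=np.isfinite(tensions))


def tension_trajectory_demo(cfg: PipelineConfig, seed: int,
                            n_rois: int = 10,
                            sigma_step: float = 2.0) -> pd.DataFrame:
    """Baseline + post-chemokine tension time course.

    Chemokine addition is emulated by stepping sigma up by
    ``sigma_step``-fold after the baseline time point.
    """
    base = DEFAULT_PARAMS
    stepped = base.with_(sigma=base.sigma * sigma_step)
    measurements = []
    for i, (t_min, p) in enumerate([(0.0, base), (3.0, stepped),
                                    (6.0, stepped), (9.0, stepped)]):
        measurements.append(
            (t_min, _fit_tension_map(p, cfg, n_rois, seed + 17 * i)))
    return irm.tension_trajectory(measurements, baseline_index=0)


def tension_corr_demo(seed: int, n_points: int = 20,
                      lag: int = 1) -> dict:
    """Lagged tension-fluorescence correlation on an AR(1) tension series
    with counts following the lagged tension at SNR ~ 3."""
    rng = np.random.default_rng(seed)
    tension = np.empty(n_points)
    tension[0] = 1.0
    for i in range(1, n_points):
        tension[i] = 0.8 * tension[i - 1] + rng.normal(0, 0.3)
    tension = tension - tension.min() + 0.5
    counts = np.empty(n_points)
    counts[lag:] = tension[:-lag]
    counts[:lag] = tension[0]
    counts = counts + rng.normal(0, counts.std() / 3.0, n_points)
    counts = counts - counts.min() + 0.1
    r, p, traj = tension_corr.lagged_correlation(counts, tension,
                                                 lag_frames=lag)
    return {"pearson_r": r, "p_value": p, "n_pairs": len(traj.times)}


def msd_demo(seed: int, n_tracks: int = 200, D: float = 0.5,
             dt: float = 30.0) -> dict:
    tracks = fluctsim.simulate_tracks("brownian", D=D, n_tracks=n_tracks,
                                      n_steps=30, dt=dt, seed=seed)
    curve = motility.compute_msd(tracks)["all"]
    d_hat = motility.estimate_diffusion(curve)
    return {"D_true_um2_s": D, "D_fit_um2_s": d_hat,
            "rel_err_pct": 100 * abs(d_hat - D) / D}


def polarity_demo(seed: int, skew: float = 0.75) -> dict:
    stack, truth = fluctsim.simulate_polarized_cell_movie(
        n_cells=4, skew_fraction=skew, seed=seed)
    # masks come from a uniform-intensity channel of the same geometry,
    # as they would from an evenly distributed cytoskeletal stain
    uniform, _ = fluctsim.simulate_polarized_cell_movie(
        n_cells=4, skew_fraction=0.5, seed=seed)
    df = polarity.fb_timeseries(
        {"actin": uniform.intensity, "piezo1": stack.intensity}, "actin",
        min_area=30)
    per_cell = df[df.channel == "piezo1"].groupby(
        "cell_id")["fb_ratio"].mean()
    return {"skew_fraction": skew,
            "expected_fb": skew / (1 - skew),
            "mean_fb": float(per_cell.mean()),
            "n_cells": int(per_cell.size)}


def pooled_coloc_experiment(n_cells: int = 13, n_timepoints: int = 4,
                            coloc_fraction: float = 0.0,
                            n_objects: int = 25,
                            mask_px: int = 128,
                            area_range: tuple[int, int] = (50, 120),
                            seed: int = 0) -> coloc.ColocResult:
    """Observed vs null overlap pooled over cells x time points.

    Each (cell, time point) contributes one observed overlap percentage
    from a fresh synthetic puncta field and one matched random-placement
    simulation, so both groups have n_cells * n_timepoints observations
    (52 for the 13-cell, 4-time-point design).
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros((mask_px, mask_px), dtype=bool)
    yy, xx = np.mgrid[0:mask_px, 0:mask_px]
    mask[(yy - mask_px / 2) ** 2 + (xx - mask_px / 2) ** 2
         <= (0.45 * mask_px) ** 2] = True
    real, null = [], []
    for _ in range(n_cells * n_timepoints):
        sub = int(rng.integers(2 ** 31))
        ref, query = fluctsim.simulate_puncta_field(
            mask, n_ref=n_objects, n_query=n_objects,
            coloc_fraction=coloc_fraction, area_range_px=area_range,
            seed=sub)
        real.append(coloc.overlap_percentage(query, ref))
        null.append(coloc.random_placement_null(query, ref, mask,
                                                n_sims=1, seed=sub + 1)[0])
    return coloc.coloc_test(real, null)


def run_demo(seed: int = 0, outdir: str | Path = "demo_out",
             config: PipelineConfig | None = None) -> dict:
    """Run every stage on synthetic data and write a JSON report."""
    cfg = config or PipelineConfig(seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg)
    report: dict = {"seed": seed}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")

        traj = tension_trajectory_demo(cfg, seed)
        traj_path = outdir / "tension_trajectory.csv"
        traj.to_csv(traj_path, index=False)
        manifest.record("tension_trajectory", table=traj_path)
        report["tension_trajectory"] = {
            "baseline_median_pn_um":
                float(traj["median_tension_pn_um"].iloc[0]),
            "post_step_significant":
                [bool(s) for s in traj["significant"].iloc[1:]],
        }

        report["tension_correlation"] = tension_corr_demo(seed + 1)
        report["msd"] = msd_demo(seed + 2)
        report["polarity"] = polarity_demo(seed + 3)

        res = pooled_coloc_experiment(coloc_fraction=0.6, seed=seed + 4)
        pd.DataFrame({"overlap_pct": res.overlap_pct,
                      "null_pct": res.null_overlaps}).to_csv(
            outdir / "coloc_overlaps.csv", index=False)
        manifest.record("coloc", table=outdir / "coloc_overlaps.csv")
        report["coloc"] = {"n_observations": res.n_observations,
                           "p_value": res.p_value,
                           "mean_overlap_pct": float(res.overlap_pct.mean()),
                           "mean_null_pct": float(res.null_overlaps.mean())}

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    manifest.write(outdir / "manifest.json")
    return report
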