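"""End-to-end orchestration: simulate → analyze → report.

``analyze_colony_stack`` is the reusable core of the imaging pipeline
(illumination correction → segmentation → circle tracking → fluorescent
patches → clone assignment → clone statistics); ``run_colony_pipeline`` and
``run_trap_pipeline`` wrap it with configuration validation, deterministic
seeding, and on-disk reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field

from . import clonedyn, colonyimg, io, synthgen, trapforce
from .config import ColonySimConfig, TrapSimConfig

logger = logging.getLogger("pilisort")

__all__ = [
    "RunConfig",
    "ColonyAnalysis",
    "analyze_colony_stack",
    "run_colony_pipeline",
    "run_trap_pipeline",
]


class DetectionParams(BaseModel):
    threshold: float = 10.0  # pN
    min_duration: float = 0.050  # s
    drop_fraction: float = 0.5
    cutoff: float = 65.0  # pN upper fit limit (trap linear range)


class RunConfig(BaseModel):
    """Single validated document driving a full run."""

    seed: int = 0
    output_dir: str = "pilisort_out"
    pixel_size: float = Field(0.32, gt=0)
    colony_sim: Optional[ColonySimConfig] = None
    trap_sim: Optional[TrapSimConfig] = None
    tau_growth: Optional[float] = Field(None, gt=0, description="min; from equilibrium colonies")
    detection: DetectionParams = DetectionParams()
    make_plots: bool = True


@dataclass
class ColonyAnalysis:
    """Bundle of everything the imaging pipeline extracts from one stack."""

    track: colonyimg.ColonyTrack
    growth_rate: float  # 1/min on log R
    analysis_window: np.ndarray
    times: np.ndarray  # min, analyzed frames
    frames: np.ndarray
    circles: List[Tuple[float, float, float]]
    patches_per_frame: List[List[colonyimg.FluorescentPatch]]
    clone_pixels: Dict[int, List[Optional[np.ndarray]]]  # clone -> per-frame coords
    clone_series: List[clonedyn.CloneTimeSeries]
    growth_fits: Dict[int, clonedyn.GrowthFit] = field(default_factory=dict)
    front_traces: Dict[int, clonedyn.FrontTrace] = field(default_factory=dict)


def analyze_colony_stack(
    brightfield: np.ndarray,
    fluorescence: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    illumination: Optional[colonyimg.IlluminationField] = None,
    tau_growth: Optional[float] = None,
    min_radius_px: float = 5.0,
    front_eps: float = 0.5,
    min_clone_frames: int = 3,
    smoothing_sigma: float = 1.5,
) -> ColonyAnalysis:
    """Run the full imaging chain on one single-position time-lapse stack.

    Segments every brightfield frame by local variance, fits a circle to each
    colony contour, tracks the main (largest) colony, restricts analysis to
    its exponential-growth window, segments fluorescent patches inside the
    circle ROI, groups them into clones on the pooled unit disk, and computes
    per-clone spatial variances, total fluorescence, front distances and —
    when ``tau_growth`` is given — fluorescence-model fits with inferred
    offspring numbers.
    """
    n_frames = brightfield.shape[0]
    circles_per_frame: List[List[Tuple[float, float, float]]] = []
    for f in range(n_frames):
        bf = brightfield[f]
        if illumination is not None:
            bf = illumination.correct(bf)
        labels = colonyimg.segment_colonies(bf)
        contours = colonyimg.extract_contour(labels)
        circles = []
        for lab, pts in contours.items():
            if len(pts) < 8:
                continue
            try:
                cx, cy, r, _rms = colonyimg.fit_circle(pts)
            except ValueError:
                continue
            if r >= min_radius_px:
                circles.append((cx, cy, r))
        circles_per_frame.append(circles)
        logger.debug("frame %d: %d colony circle(s)", f, len(circles))

    tracks = colonyimg.track_colonies(circles_per_frame)
    if not tracks:
        raise RuntimeError("segmentation produced no colony tracks")
    track = max(tracks, key=lambda tr: len(tr.frames))

    t_all = np.asarray(track.frames, float) * frame_interval
    radii = np.asarray(track.radii, float)
    rate, window = clonedyn.fit_radius_exponential(t_all, radii)
    valid = np.asarray(track.valid) & window
    frames = np.asarray(track.frames)[valid]
    times = t_all[valid]
    circles = [track.circle_at(int(f)) for f in frames]

    patches_per_frame: List[List[colonyimg.FluorescentPatch]] = []
    norm_coords: List[colonyimg.NormalizedCoordinates] = []
    for f, circle in zip(frames, circles):
        fl = fluorescence[int(f)]
        if illumination is not None:
            fl = illumination.correct(fl)
        patches = colonyimg.segment_fluorescence(fl, circle, frame=int(f))
        patches_per_frame.append(patches)
        if patches:
            coords = np.vstack([p.coords for p in patches])
        else:
            coords = np.empty((0, 2))
        norm_coords.append(colonyimg.normalize_coordinates(coords, circle, frame=int(f)))

    labels_per_frame = colonyimg.assign_clones(norm_coords)
    clone_ids = sorted(
        {int(l) for labels in labels_per_frame for l in np.unique(labels) if l >= 0}
    )

    clone_pixels: Dict[int, List[Optional[np.ndarray]]] = {ci: [] for ci in clone_ids}
    clone_series: List[clonedyn.CloneTimeSeries] = []
    for ci in clone_ids:
        sx2l, sy2l, s2l, s2nl, itotl, fr_l, t_l = [], [], [], [], [], [], []
        touch = []
        for fi, (f, circle, patches, labels, nc) in enumerate(
            zip(frames, circles, patches_per_frame, labels_per_frame, norm_coords)
        ):
            if patches:
                coords = np.vstack([p.coords for p in patches])
                inten = np.concatenate([p.intensities for p in patches])
            else:
                coords = np.empty((0, 2))
                inten = np.empty(0)
            sel = labels == ci
            if not sel.any():
                clone_pixels[ci].append(None)
                continue
            cpix = coords[sel]
            cint = inten[sel]
            clone_pixels[ci].append(cpix)
            sx2, sy2, s2 = clonedyn.spatial_variance(cpix[:, 1], cpix[:, 0], cint)
            # remove the known broadening of the Gaussian pre-smoothing
            kvar = smoothing_sigma**2
            sx2 = max(sx2 - kvar, 0.0)
            sy2 = max(sy2 - kvar, 0.0)
            s2 = sx2 + sy2
            xs = nc.r_norm[sel] * np.cos(nc.theta[sel])
            ys = nc.r_norm[sel] * np.sin(nc.theta[sel])
            _, _, s2n = clonedyn.spatial_variance(xs, ys, cint)
            cx, cy, R = circle
            rmax = np.hypot(cpix[:, 1] - cx, cpix[:, 0] - cy).max()
            touch.append((R - rmax) * pixel_size < front_eps)
            sx2l.append(sx2)
            sy2l.append(sy2)
            s2l.append(s2)
            s2nl.append(s2n)
            itotl.append(float(cint.sum()))
            fr_l.append(int(f))
            t_l.append(float(f) * frame_interval)
        if len(fr_l) < min_clone_frames:
            # transient specks that survive segmentation are not clones
            del clone_pixels[ci]
            continue
        clone_series.append(
            clonedyn.CloneTimeSeries(
                clone_id=ci,
                frames=np.asarray(fr_l),
                times=np.asarray(t_l),
                itot=np.asarray(itotl),
                sx2=np.asarray(sx2l),
                sy2=np.asarray(sy2l),
                s2=np.asarray(s2l),
                s2_norm=np.asarray(s2nl),
                front_touching=np.asarray(touch),
                pixel_size=pixel_size,
            )
        )

    analysis = ColonyAnalysis(
        track=track,
        growth_rate=rate,
        analysis_window=window,
        times=times,
        frames=frames,
        circles=circles,
        patches_per_frame=patches_per_frame,
        clone_pixels=clone_pixels,
        clone_series=clone_series,
    )

    for series in analysis.clone_series:
        ci = series.clone_id
        # frames of this clone within the analyzed window
        idx = [int(np.nonzero(frames == f)[0][0]) for f in series.frames]
        pix = clone_pixels[ci]
        analysis.front_traces[ci] = clonedyn.front_distance_trace(
            pix,
            circles,
            pixel_size,
            frames=frames,
            clone_id=ci,
            front_eps=front_eps,
        )
        if tau_growth is not None:
            # full analyzed time axis: zeros before the clone appears
            itot_full = np.zeros(len(frames))
            itot_full[idx] = series.itot
            try:
                fit = clonedyn.fit_fluorescence_model(
                    times, itot_full, tau_growth, lineage="integer"
                )
            except (RuntimeError, ValueError) as exc:
                logger.warning("clone %d: fluorescence fit failed (%s)", ci, exc)
                continue
            analysis.growth_fits[ci] = fit
            series.n_est = fit.n_cells(series.times)
    return analysis


# ---------------------------------------------------------------------------
# Report-producing runners
# ---------------------------------------------------------------------------

def _manifest(config: RunConfig) -> dict:
    from importlib.metadata import PackageNotFoundError, version

    try:
        ver = version("pilisort")
    except PackageNotFoundError:  # pragma: no cover
        ver = "unknown"
    return {"pilisort_version": ver, "config": config.model_dump()}


def run_colony_pipeline(config: RunConfig) -> dict:
    """Simulate (or load) a colony stack, analyze it, and write the report."""
    if config.colony_sim is None:
        raise ValueError("config.colony_sim block is required")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.colony_sim.model_copy(update={"seed": config.seed})

    logger.info("simulating colony stack (%d frames)", sim.n_frames)
    bf, fl, gt = synthgen.simulate_colony_stack(sim)
    tiles, meta, _ = synthgen.simulate_position_grid(sim)
    field_est = colonyimg.estimate_illumination(tiles)

    analysis = analyze_colony_stack(
        bf,
        fl,
        pixel_size=sim.pixel_size,
        frame_interval=sim.frame_interval,
        illumination=field_est,
        tau_growth=config.tau_growth or sim.generation_time,
    )

    io.write_stack_tiff(out / "brightfield.tiff", bf)
    io.write_stack_tiff(out / "fluorescence.tiff", fl)
    io.write_tracks_csv(out / "tracks.csv", [analysis.track])
    io.write_front_traces_csv(out / "front_traces.csv", list(analysis.front_traces.values()))
    clone_rows = []
    for s in analysis.clone_series:
        for i in range(len(s.frames)):
            clone_rows.append(
                {
                    "clone_id": s.clone_id,
                    "frame": int(s.frames[i]),
                    "I_tot": s.itot[i],
                    "sx2_px2": s.sx2[i],
                    "sy2_px2": s.sy2[i],
                    "s2_px2": s.s2[i],
                    "s2_norm": s.s2_norm[i],
                    "N_est": float(s.n_est[i]) if s.n_est is not None else float("nan"),
                    "front_touching": bool(s.front_touching[i]),
                }
            )
    import pandas as pd

    pd.DataFrame(clone_rows).to_csv(out / "clones.csv", index=False)
    io.write_json(
        out / "fits.json",
        {
            str(ci): {"I0": f.I0, "t0_min": f.t0, "k_deg_per_min": f.k_deg,
                      "k_prod": f.k_prod, "tau_growth_min": f.tau_growth,
                      "residual_rms": f.residual_rms}
            for ci, f in analysis.growth_fits.items()
        },
    )
    io.write_json(out / "manifest.json", _manifest(config))
    if config.make_plots:
        _colony_plots(out, analysis)
    return {"analysis": analysis, "ground_truth": gt, "output_dir": str(out)}


def run_trap_pipeline(config: RunConfig) -> dict:
    """Simulate (or load) trap traces, extract events and fits, write report."""
    if config.trap_sim is None:
        raise ValueError("config.trap_sim block is required")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.trap_sim.model_copy(update={"seed": config.seed})

    # calibration from an event-free companion trace at the same settings
    calib_sim = sim.model_copy(update={"event_rate": 0.0, "n_events": None, "duration": 20.0})
    t_free, x_free, _ = synthgen.simulate_trap_trace(calib_sim)
    calibration = trapforce.calibrate_trap_psd(
        x_free,
        sampling_rate=sim.sampling_rate,
        bead_diameter=sim.bead_diameter,
        temperature=sim.temperature,
        viscosity=sim.viscosity,
    )
    logger.info("calibrated stiffness %.4f pN/nm", calibration.stiffness)

    t, x, gt = synthgen.simulate_trap_trace(sim)
    trace = trapforce.ForceTrace(time=t, deflection=x, calibration=calibration)
    det = config.detection
    events = trapforce.detect_retraction_events(
        trace,
        threshold=det.threshold,
        min_duration=det.min_duration,
        drop_fraction=det.drop_fraction,
    )
    forces = [e.rupture_force for e in events]
    loading_rate = calibration.stiffness * sim.retraction_speed  # pN/s
    lower = det.threshold + loading_rate * det.min_duration
    fit = trapforce.fit_rupture_distribution(forces, cutoff=det.cutoff, lower=lower)
    freq = trapforce.retraction_frequency(events, observation_time=float(t[-1]))

    io.write_trace_csv(out / "trace.csv", t, x)
    io.write_events_csv(out / "events.csv", events)
    io.write_json(
        out / "fit.json",
        {
            "location_pN": fit.location,
            "scale_pN": fit.scale,
            "location_se_pN": fit.location_se,
            "n_events_used": fit.n_events_used,
            "cutoff_pN": fit.cutoff,
            "lower_pN": fit.lower,
            "stiffness_pN_per_nm": calibration.stiffness,
            "corner_frequency_hz": calibration.corner_frequency,
            "mean_frequency_hz": freq["mean_hz"],
        },
    )
    io.write_json(out / "manifest.json", _manifest(config))
    return {
        "calibration": calibration,
        "events": events,
        "fit": fit,
        "frequency": freq,
        "ground_truth": gt,
        "output_dir": str(out),
    }


def _colony_plots(out: Path, analysis: ColonyAnalysis) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    axes[0].semilogy(analysis.times / 60.0, [c[2] for c in analysis.circles], "o-")
    axes[0].set(xlabel="time (h)", ylabel="radius (px)", title="colony radius")
    for s in analysis.clone_series:
        axes[1].plot(s.times / 60.0, s.s2_um2, "o-", label=f"clone {s.clone_id}")
    axes[1].set(xlabel="time (h)", ylabel="σ² (µm²)", title="sector variance")
    for ci, tr in analysis.front_traces.items():
        axes[2].plot(tr.frames, tr.distances, "o-", label=f"clone {ci}")
    axes[2].set(xlabel="frame", ylabel="distance to front (µm)", title="front approach")
    fig.tight_layout()
    fig.savefig(out / "summary.png", dpi=110)
    plt.close(fig)
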