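"""Synthetic microscopy stacks, trap traces and intensity series with ground truth.

Every downstream stage of the package is tested against data produced here:
exponentially expanding speckle colonies carrying fluorescent clones, optical
trap deflection recordings with pilus-retraction events, fluorescence
maturation series, and distance-to-front random walks.  All randomness flows
from explicit seeds; there is no hidden global state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .config import KB_PN_NM, ColonySimConfig, TrapSimConfig

__all__ = [
    "SimGroundTruth",
    "simulate_colony_stack",
    "simulate_position_grid",
    "simulate_trap_trace",
    "simulate_intensity_series",
    "simulate_front_traces",
    "piecewise_probability",
]


@dataclass
class SimGroundTruth:
    """Generator-side truth used as a test oracle.

    Image-side fields are per frame; ``circles`` rows are ``(cx, cy, R)`` in
    pixel units with ``cx = column``, ``cy = row`` of the colony centre.
    ``clone_pixels[c][f]`` holds the raster coordinates (``(n, 2)`` array of
    ``(row, col)``) and rendered intensities of clone ``c`` at frame ``f``,
    restricted to pixels inside the colony circle.
    """

    circles: Optional[np.ndarray] = None
    clone_pixels: Optional[List[List[Dict[str, np.ndarray]]]] = None
    clone_n: Optional[np.ndarray] = None
    clone_itot: Optional[np.ndarray] = None
    front_distance: Optional[np.ndarray] = None
    times: Optional[np.ndarray] = None
    event_times: Optional[np.ndarray] = None
    event_rupture_times: Optional[np.ndarray] = None
    event_forces: Optional[np.ndarray] = None
    illumination: Optional[np.ndarray] = None
    extras: Dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Illumination and rendering helpers
# ---------------------------------------------------------------------------

def illumination_field(shape: Tuple[int, int], amplitude: float) -> np.ndarray:
    """Smooth multiplicative illumination: radial parabola, normalized to mean 1."""
    rows, cols = shape
    r = (np.arange(rows) - (rows - 1) / 2.0) / max(rows / 2.0, 1.0)
    c = (np.arange(cols) - (cols - 1) / 2.0) / max(cols / 2.0, 1.0)
    d2 = r[:, None] ** 2 + c[None, :] ** 2
    f = 1.0 + amplitude * (0.5 - d2 / max(d2.max(), 1e-12))
    return f / f.mean()


def _render_cells(
    canvas: np.ndarray,
    rows_c: np.ndarray,
    cols_c: np.ndarray,
    intensities: np.ndarray,
    sigma_px: float,
) -> None:
    """Deposit per-cell Gaussian blobs; each blob's pixel sum equals its intensity."""
    half = int(math.ceil(3.0 * sigma_px))
    nrows, ncols = canvas.shape
    for rc, cc, inten in zip(rows_c, cols_c, intensities):
        if inten <= 0:
            continue
        r0, r1 = int(math.floor(rc)) - half, int(math.floor(rc)) + half + 1
        c0, c1 = int(math.floor(cc)) - half, int(math.floor(cc)) + half + 1
        r0, r1 = max(r0, 0), min(r1, nrows)
        c0, c1 = max(c0, 0), min(c1, ncols)
        if r0 >= r1 or c0 >= c1:
            continue
        dr = np.arange(r0, r1) - rc
        dc = np.arange(c0, c1) - cc
        kern = np.exp(-(dr[:, None] ** 2 + dc[None, :] ** 2) / (2.0 * sigma_px**2))
        s = kern.sum()
        if s > 0:
            canvas[r0:r1, c0:c1] += inten * kern / s


# ---------------------------------------------------------------------------
# Colony time-lapse
# ---------------------------------------------------------------------------

class _CloneState:
    """Cell positions of one clone in analysis coordinates (x right, y up, µm
    relative to the colony centre)."""

    def __init__(self, t0: float, r_norm: float, theta: float, phenotype: str):
        self.t0 = t0
        self.r_norm = r_norm
        self.theta = theta
        self.phenotype = phenotype
        self.xy: Optional[np.ndarray] = None  # (n_cells, 2)

    def born(self) -> bool:
        return self.xy is not None


def simulate_colony_stack(
    config: ColonySimConfig,
) -> Tuple[np.ndarray, np.ndarray, SimGroundTruth]:
    """Render a brightfield + fluorescence time-lapse of one expanding colony.

    The colony is a disk of high-variance speckle on a smooth background whose
    radius grows as ``R(t) = R0 · 2^(t / radius_doubling_time)``.  Clones are
    explicit cell populations: lineage counts follow ``N(t) = 2^((t−t0)/τ)``
    (rounded), cells co-move homothetically with the expansion plus diffusive
    displacement, and P− clones additionally drift outward when within the
    activation distance of the front.  Per-cell fluorescence matures as
    ``I0·(1 − e^(−2·k_deg·(t−t0)))`` with the lineage clock t0.

    Returns ``(brightfield, fluorescence, ground_truth)`` with stacks of shape
    ``(n_frames, rows, cols)``.
    """
    rng = np.random.default_rng(config.seed)
    nrows, ncols = config.image_shape
    times = np.arange(config.n_frames) * config.frame_interval
    radii_um = config.initial_radius * 2.0 ** (times / config.radius_doubling)
    radii_px = radii_um / config.pixel_size
    half_extent = min(nrows, ncols) / 2.0
    too_big = np.nonzero(radii_px + 2.0 > half_extent)[0]
    if too_big.size:
        raise ValueError(
            f"colony radius exceeds the frame bounds at frame {int(too_big[0])} "
            f"(R = {radii_um[too_big[0]]:.1f} µm)"
        )
    center_row, center_col = (nrows - 1) / 2.0, (ncols - 1) / 2.0
    field_arr = illumination_field((nrows, ncols), config.illumination.amplitude)

    clones = [
        _CloneState(ev.t0, ev.r_norm, ev.theta, ev.phenotype) for ev in config.clone_events
    ]
    n_clones = len(clones)
    tau = config.generation_time
    I0 = config.fluorescence.I0
    k_deg = config.fluorescence.k_deg
    sigma_blob = 0.5 / config.pixel_size  # ~1 µm cell rendered as a 0.5 µm sd blob
    bf_base, bf_contrast, fl_base = 100.0, 0.3, 2.0

    bf = np.empty((config.n_frames, nrows, ncols), dtype=np.float32)
    fl = np.empty_like(bf)
    gt = SimGroundTruth(
        circles=np.column_stack(
            [np.full_like(radii_px, center_col), np.full_like(radii_px, center_row), radii_px]
        ),
        clone_pixels=[[] for _ in range(n_clones)],
        clone_n=np.zeros((n_clones, config.n_frames), dtype=int),
        clone_itot=np.zeros((n_clones, config.n_frames)),
        front_distance=np.full((n_clones, config.n_frames), np.nan),
        times=times,
        illumination=field_arr,
        extras={"pixel_size": config.pixel_size, "generation_time": tau},
    )

    rr = np.arange(nrows)[:, None] - center_row
    cc = np.arange(ncols)[None, :] - center_col
    dist_px = np.sqrt(rr**2 + cc**2)

    for f, t in enumerate(times):
        R = radii_um[f]
        mask = dist_px <= radii_px[f]

        # --- clone state update -------------------------------------------
        if f > 0:
            scale = radii_um[f] / radii_um[f - 1]
        else:
            scale = 1.0
        for clone in clones:
            if clone.born() and f > 0:
                clone.xy = clone.xy * scale
                step_sd = math.sqrt(config.diffusion * config.frame_interval / tau)
                clone.xy = clone.xy + rng.normal(0.0, step_sd, clone.xy.shape)
                if clone.phenotype == "P-" and config.front_bias.drift_um_per_frame > 0:
                    r = np.linalg.norm(clone.xy, axis=1)
                    near = (R - r) < config.front_bias.activation_distance_um
                    nz = near & (r > 1e-9)
                    if nz.any():
                        unit = clone.xy[nz] / r[nz, None]
                        clone.xy[nz] += config.front_bias.drift_um_per_frame * unit
            if not clone.born() and t >= clone.t0:
                r_abs = clone.r_norm * R
                clone.xy = np.array(
                    [[r_abs * math.cos(clone.theta), r_abs * math.sin(clone.theta)]]
                )
            if clone.born():
                # keep cells inside the colony
                r = np.linalg.norm(clone.xy, axis=1)
                out = r > (R - 0.3)
                if out.any():
                    clone.xy[out] *= ((R - 0.3) / r[out])[:, None]
                # lineage growth
                n_target = max(1, int(round(2.0 ** ((t - clone.t0) / tau))))
                while len(clone.xy) < n_target:
                    parent = rng.integers(len(clone.xy))
                    child = clone.xy[parent] + rng.normal(0.0, 0.3, 2)
                    clone.xy = np.vstack([clone.xy, child])

        # --- brightfield ---------------------------------------------------
        frame = np.full((nrows, ncols), bf_base)
        n_in = int(mask.sum())
        frame[mask] = bf_base * (1.0 + bf_contrast * rng.standard_normal(n_in))
        frame *= field_arr
        if config.noise.sigma_brightfield > 0:
            frame += rng.normal(0.0, config.noise.sigma_brightfield, frame.shape)
        bf[f] = frame

        # --- fluorescence --------------------------------------------------
        total = np.full((nrows, ncols), fl_base)
        for ci, clone in enumerate(clones):
            canvas = np.zeros((nrows, ncols))
            if clone.born():
                delta = t - clone.t0
                i_cell = I0 * (1.0 - math.exp(-2.0 * k_deg * delta)) if delta > 0 else 0.0
                n_cells = len(clone.xy)
                gt.clone_n[ci, f] = n_cells
                gt.clone_itot[ci, f] = i_cell * n_cells
                rows_c = center_row - clone.xy[:, 1] / config.pixel_size
                cols_c = center_col + clone.xy[:, 0] / config.pixel_size
                _render_cells(canvas, rows_c, cols_c, np.full(n_cells, i_cell), sigma_blob)
                r_cells = np.linalg.norm(clone.xy, axis=1)
                gt.front_distance[ci, f] = max(R - r_cells.max(), 0.0)
            member = (canvas > 0) & mask
            coords = np.argwhere(member)
            gt.clone_pixels[ci].append(
                {"coords": coords, "intensities": canvas[coords[:, 0], coords[:, 1]]}
            )
            total += canvas
        total *= field_arr
        if config.noise.sigma_fluorescence > 0:
            total += rng.normal(0.0, config.noise.sigma_fluorescence, total.shape)
        fl[f] = total

    return bf, fl, gt


def simulate_position_grid(
    config: ColonySimConfig, cells_per_tile: float = 4.0
) -> Tuple[np.ndarray, Dict[str, object], SimGroundTruth]:
    """First-timepoint image of every stage position: sparse single cells only.

    Each tile shares the same multiplicative illumination field, so the
    pixelwise average across positions reveals the field.  Returns
    ``(tiles, metadata, ground_truth)`` with ``tiles`` of shape
    ``(n_positions, rows, cols)`` and stitching metadata (grid shape, tile
    shape, overlap, row-major order).
    """
    rng = np.random.default_rng(config.seed + 1)
    nrows, ncols = config.image_shape
    gr, gc = config.grid_shape
    n_pos = gr * gc
    field_arr = illumination_field((nrows, ncols), config.illumination.amplitude)
    tiles = np.empty((n_pos, nrows, ncols), dtype=np.float32)
    base = 100.0
    for p in range(n_pos):
        tile = np.full((nrows, ncols), base)
        for _ in range(rng.poisson(cells_per_tile)):
            r = rng.integers(3, nrows - 3)
            c = rng.integers(3, ncols - 3)
            tile[r - 1 : r + 2, c - 1 : c + 2] *= 1.0 + 0.4 * rng.standard_normal((3, 3))
        tile *= field_arr
        if config.noise.sigma_brightfield > 0:
            tile += rng.normal(0.0, config.noise.sigma_brightfield, tile.shape)
        tiles[p] = tile
    metadata = {
        "grid_shape": (gr, gc),
        "tile_shape": (nrows, ncols),
        "overlap": 0,
        "order": "row-major",
    }
    return tiles, metadata, SimGroundTruth(illumination=field_arr)


# ---------------------------------------------------------------------------
# Optical trap
# ---------------------------------------------------------------------------

def _ou_baseline(n: int, config: TrapSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Exactly discretized Ornstein–Uhlenbeck position trace, nm."""
    if n <= 0:
        return np.zeros(0)
    var_eq = KB_PN_NM * config.temperature / config.stiffness  # nm²
    sd_eq = math.sqrt(var_eq) * config.noise_scale
    if sd_eq == 0:
        return np.zeros(n)
    dt = 1.0 / config.sampling_rate
    tau_c = config.drag / config.stiffness  # s
    phi = math.exp(-dt / tau_c)
    innov = rng.normal(0.0, sd_eq * math.sqrt(1.0 - phi * phi), n)
    innov[0] = rng.normal(0.0, sd_eq)
    x = lfilter([1.0], [1.0, -phi], innov)
    return x


def simulate_trap_trace(
    config: TrapSimConfig,
) -> Tuple[np.ndarray, np.ndarray, SimGroundTruth]:
    """Synthetic trap deflection recording with pilus-retraction events.

    The baseline is an Ornstein–Uhlenbeck process with equipartition variance
    k_B·T/k and corner frequency k/(2πγ).  Events ramp the deflection linearly
    at the retraction speed (force loading rate k·v) up to a rupture force
    drawn from the configured Gaussian preset, then relax exponentially with
    the trap's corner time.  With ``config.n_events`` set, exactly that many
    non-overlapping events are laid out with Exp(event_rate) gaps and the
    trace duration is derived; otherwise event starts form a Poisson process
    over ``config.duration`` (arrivals falling inside an ongoing event are
    dropped, with a warning when the expected occupancy exceeds 10%).

    Returns ``(time_s, deflection_nm, ground_truth)``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    k = config.stiffness
    v = config.retraction_speed
    tau_c = config.drag / k

    mu_f, sd_f = config.force_distribution

    if config.n_events is not None:
        n_ev = config.n_events
        forces = np.maximum(rng.normal(mu_f, sd_f, n_ev), 1.0)
        gaps = (
            rng.exponential(1.0 / config.event_rate, n_ev)
            if config.event_rate > 0
            else np.full(n_ev, 1.0)
        )
        starts = np.empty(n_ev)
        t_cursor = 0.5
        for i in range(n_ev):
            t_cursor += gaps[i]
            starts[i] = t_cursor
            t_cursor += forces[i] / (k * v) + 10.0 * tau_c
        duration = t_cursor + 0.5
    else:
        duration = config.duration
        n_arr = rng.poisson(config.event_rate * duration)
        arrivals = np.sort(rng.uniform(0.0, duration, n_arr))
        forces_all = np.maximum(rng.normal(mu_f, sd_f, n_arr), 1.0)
        mean_ev = (mu_f / (k * v)) + 10.0 * tau_c
        if config.event_rate * mean_ev > 0.10:
            warnings.warn(
                "expected event occupancy exceeds 10% of the trace; overlapping "
                "arrivals are dropped",
                stacklevel=2,
            )
        starts_l, forces_l = [], []
        t_busy = -np.inf
        for t0, F in zip(arrivals, forces_all):
            if t0 >= t_busy:
                starts_l.append(t0)
                forces_l.append(F)
                t_busy = t0 + F / (k * v) + 10.0 * tau_c
        starts = np.asarray(starts_l)
        forces = np.asarray(forces_l)

    n = int(round(duration * fs))
    x = _ou_baseline(n, config, rng)
    t = np.arange(n) / fs

    ruptures = starts + forces / (k * v)
    for t0, F in zip(starts, forces):
        d_peak = F / k  # nm
        ramp_n = max(int(round((d_peak / v) * fs)), 1)
        i0 = int(round(t0 * fs))
        i1 = min(i0 + ramp_n, n)
        if i0 >= n:
            continue
        x[i0:i1] += d_peak * (np.arange(i1 - i0) + 1) / ramp_n
        relax_n = min(int(round(8.0 * tau_c * fs)) + 1, n - i1)
        if relax_n > 0:
            x[i1 : i1 + relax_n] += d_peak * np.exp(
                -np.arange(relax_n) / (tau_c * fs)
            )

    keep = starts < t[-1] if n else np.zeros(0, bool)
    gt = SimGroundTruth(
        event_times=starts[keep],
        event_rupture_times=ruptures[keep],
        event_forces=forces[keep],
        extras={"duration": duration, "stiffness": k, "sampling_rate": fs},
    )
    return t, x, gt


# ---------------------------------------------------------------------------
# Fluorescence intensity series
# ---------------------------------------------------------------------------

def simulate_intensity_series(
    I0: float,
    t0: float,
    k_deg: float,
    tau: float,
    timepoints: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
    initially_fluorescent: bool = False,
) -> np.ndarray:
    """Total clone fluorescence over time.

    De-novo clones follow ``I_tot(t) = I0 · 2^((t−t0)/τ) · (1 − e^(−2·k_deg·(t−t0)))``
    for t ≥ t0 and 0 before.  With ``initially_fluorescent=True`` the reporter
    is at its equilibrium concentration from the start and
    ``I_tot(t) = I0 · 2^(t/τ)`` (used for generation-time estimation).
    Multiplicative Gaussian noise of relative sd ``noise_sigma`` is applied.
    """
    t = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("timepoints must be sorted")
    if min(I0, k_deg, tau) <= 0:
        raise ValueError("I0, k_deg and tau must be positive")
    if initially_fluorescent:
        series = I0 * 2.0 ** (t / tau)
    else:
        if t.size and t0 > t[-1]:
            raise ValueError(f"onset t0={t0} lies beyond the last timepoint {t[-1]}")
        delta = t - t0
        series = np.where(
            delta > 0,
            I0 * 2.0 ** (delta / tau) * (1.0 - np.exp(-2.0 * k_deg * delta)),
            0.0,
        )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        series = series * (1.0 + rng.normal(0.0, noise_sigma, series.shape))
    return series


# ---------------------------------------------------------------------------
# Distance-to-front random walks
# ---------------------------------------------------------------------------

def piecewise_probability(
    edges: Sequence[float], probs: Sequence[float], default: float = 0.5
) -> Callable[[float], float]:
    """Step function over distance bins ``[edges[i], edges[i+1])`` -> probs[i]."""
    edges = np.asarray(edges, float)
    probs = np.asarray(probs, float)
    if len(probs) != len(edges) - 1:
        raise ValueError("need one probability per bin")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")

    def p(d: float) -> float:
        i = np.searchsorted(edges, d, side="right") - 1
        if 0 <= i < len(probs):
            return float(probs[i])
        return default

    return p


def simulate_front_traces(
    n_traces: int,
    p_toward: Callable[[float], float],
    step: float,
    n_steps: int,
    seed: int = 0,
    d0: float = 5.0,
) -> np.ndarray:
    """Reflected random walks of the distance to the colony front (µm, >= 0).

    At each step the walker moves toward the front (distance decreases by
    ``step``, floored at 0) with probability ``p_toward(current distance)``,
    otherwise away.  Returns an array of shape ``(n_traces, n_steps + 1)``.
    """
    rng = np.random.default_rng(seed)
    traces = np.empty((n_traces, n_steps + 1))
    traces[:, 0] = d0
    for s in range(n_steps):
        d = traces[:, s]
        p = np.array([p_toward(float(di)) for di in d])
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p_toward must map distances into [0, 1]")
        toward = rng.random(n_traces) < p
        traces[:, s + 1] = np.where(toward, np.maximum(d - step, 0.0), d + step)
    return traces
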