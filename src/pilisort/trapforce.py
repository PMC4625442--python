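"""Optical-trap force spectroscopy: calibration, event detection, rupture forces.

A trapped monococcus deflects from the trap centre when one of its type IV
pili binds the pilus-coated surface and retracts; the deflection is
proportional to the force on the pilus–pilus bond.  This module turns raw
deflection traces (nm, uniformly sampled) into trap calibrations, retraction
events with rupture forces, truncated-Gaussian force-distribution fits, and
retraction frequencies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, signal, stats
from scipy.ndimage import uniform_filter1d

from .config import KB_PN_NM

__all__ = [
    "TrapCalibration",
    "ForceTrace",
    "RetractionEvent",
    "RuptureForceFit",
    "CalibrationError",
    "calibrate_trap_psd",
    "deflection_to_force",
    "detect_retraction_events",
    "fit_rupture_distribution",
    "retraction_frequency",
]


class CalibrationError(RuntimeError):
    """Power-spectrum calibration failed (non-Lorentzian spectrum, bad trace)."""


@dataclass
class TrapCalibration:
    """Trap stiffness and linear range.

    ``f_max`` is the maximum trustworthy force (default 65 pN); forces beyond
    it are flagged as overestimated because the trap leaves its linear regime.
    """

    stiffness: float  # pN/nm
    linear_range: float = 450.0  # nm
    f_max: float = 65.0  # pN
    sampling_rate: float = 20_000.0  # Hz
    corner_frequency: Optional[float] = None  # Hz
    fit_r2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.stiffness <= 0 or self.sampling_rate <= 0:
            raise ValueError("stiffness and sampling_rate must be positive")
        if self.f_max > 1.1 * self.stiffness * self.linear_range:
            warnings.warn(
                f"f_max={self.f_max} pN exceeds k·d="
                f"{self.stiffness * self.linear_range:.1f} pN by more than 10%",
                stacklevel=2,
            )


@dataclass
class ForceTrace:
    """Uniformly sampled deflection trace with its calibration.

    ``force`` is derived elementwise as ``k × deflection``.
    """

    time: np.ndarray  # s
    deflection: np.ndarray  # nm
    calibration: TrapCalibration

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.deflection = np.asarray(self.deflection, float)
        if self.time.size != self.deflection.size:
            raise ValueError("time and deflection must have equal length")
        if self.time.size >= 3:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("trace must be uniformly sampled")

    @property
    def force(self) -> np.ndarray:
        """Force in pN."""
        return deflection_to_force(self.deflection, self.calibration)[0]


@dataclass
class RetractionEvent:
    """One contiguous pilus-retraction episode ending in bond rupture."""

    t_start: float  # s
    t_rupture: float  # s
    rupture_force: float  # pN
    above_linear_range: bool = False

    def __post_init__(self) -> None:
        if self.t_start >= self.t_rupture:
            raise ValueError("t_start must precede t_rupture")


@dataclass
class RuptureForceFit:
    """Gaussian fit of a rupture-force sample restricted to the linear range."""

    location: float  # pN
    scale: float  # pN
    location_se: float
    scale_se: float
    n_events_used: int
    cutoff: float
    lower: float = 0.0
    histogram: Optional[Tuple[np.ndarray, np.ndarray]] = None  # (bin_edges, counts)
    mode: str = "mle"


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _sampled_lorentzian(f, diff_coeff, f_c, fs):
    """One-sided PSD of the exactly sampled OU process (aliased Lorentzian).

    Parametrized by the equipartition variance ``diff_coeff`` (nm²) and corner
    frequency ``f_c`` (Hz); ``fs`` is the sampling rate.
    """
    dt = 1.0 / fs
    phi = np.exp(-2.0 * np.pi * f_c * dt)
    num = diff_coeff * (1.0 - phi**2) * dt
    den = 1.0 - 2.0 * phi * np.cos(2.0 * np.pi * f * dt) + phi**2
    return 2.0 * num / den


def _plain_lorentzian(f, a, f_c):
    return a / (f_c**2 + f**2)


def calibrate_trap_psd(
    deflection: np.ndarray,
    sampling_rate: float,
    bead_diameter: float = 1.0,
    temperature: float = 310.0,
    viscosity: float = 7.0e-4,
    fit_band: Optional[Tuple[float, float]] = None,
    aliasing: bool = True,
    min_duration: float = 5.0,
    r2_threshold: float = 0.2,
    nperseg: int = 16384,
) -> TrapCalibration:
    """Trap stiffness from power-spectrum analysis of the Brownian motion.

    A Welch power spectrum of the event-free deflection trace (nm) is fitted
    to a Lorentzian ``S(f) = A/(f_c² + f²)``; by default the fit uses the
    sampled-process (aliasing-corrected) form of the same Lorentzian, which
    matters when the corner frequency is a sizeable fraction of the Nyquist
    frequency.  Stiffness follows from ``k = 2π·γ·f_c`` with the Stokes drag
    ``γ = 3π·viscosity·bead_diameter``.  The fit band excludes low-frequency
    drift and the Nyquist region (default 50 Hz to 0.8·f_Nyquist).

    Raises :class:`CalibrationError` on short traces, corner frequencies that
    run out of the fitted band, or spectra that a Lorentzian cannot describe.
    """
    x = np.asarray(deflection, float)
    duration = x.size / sampling_rate
    if duration < min_duration:
        raise CalibrationError(
            f"trace of {duration:.2f} s is shorter than the required {min_duration} s"
        )
    nyquist = sampling_rate / 2.0
    lo, hi = fit_band if fit_band is not None else (50.0, 0.8 * nyquist)
    freqs, psd = signal.welch(x - x.mean(), fs=sampling_rate, nperseg=min(nperseg, x.size))
    band = (freqs >= lo) & (freqs <= hi)
    f_fit, s_fit = freqs[band], psd[band]
    if f_fit.size < 10:
        raise CalibrationError("fit band contains too few spectral points")

    # least squares on log-PSD: roughly uniform relative weighting
    logy = np.log(s_fit)
    if aliasing:
        def model(f, var_eq, f_c):
            return np.log(_sampled_lorentzian(f, var_eq, f_c, sampling_rate))
        p0 = (float(np.var(x)), 0.1 * nyquist)
    else:
        def model(f, a, f_c):
            return np.log(_plain_lorentzian(f, a, f_c))
        p0 = (float(s_fit[0] * (lo**2 + (0.1 * nyquist) ** 2)), 0.1 * nyquist)
    try:
        popt, _ = optimize.curve_fit(
            model, f_fit, logy, p0=p0, bounds=([1e-12, 1.0], [np.inf, 10.0 * nyquist]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological spectra
        raise CalibrationError(f"Lorentzian fit did not converge: {exc}") from exc
    f_c = float(popt[1])
    resid = logy - model(f_fit, *popt)
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    if f_c >= 0.95 * hi or f_c <= lo:
        raise CalibrationError(
            f"fitted corner frequency {f_c:.0f} Hz lies outside the usable band "
            f"({lo:.0f}–{hi:.0f} Hz); spectrum is not Lorentzian in-band"
        )
    if r2 < r2_threshold:
        raise CalibrationError(f"Lorentzian fit R²={r2:.3f} below {r2_threshold}")
    gamma = 3.0 * math.pi * viscosity * (bead_diameter * 1e-6) * 1e3  # pN·s/nm
    stiffness = 2.0 * math.pi * gamma * f_c
    return TrapCalibration(
        stiffness=stiffness,
        sampling_rate=sampling_rate,
        corner_frequency=f_c,
        fit_r2=r2,
    )


# ---------------------------------------------------------------------------
# Force conversion and event detection
# ---------------------------------------------------------------------------

def deflection_to_force(
    deflection: np.ndarray, calibration: TrapCalibration
) -> Tuple[np.ndarray, np.ndarray]:
    """Convert deflection (nm) to force (pN): ``F = k·x``, elementwise.

    Returns ``(force, overestimated)`` where the flag marks samples whose
    deflection exceeds the trap's linear range (forces there are
    overestimated).  NaN deflections propagate with a warning.
    """
    x = np.asarray(deflection, float)
    if np.isnan(x).any():
        warnings.warn("NaN deflection samples propagate to NaN forces", stacklevel=2)
    force = calibration.stiffness * x
    flagged = np.abs(x) >= calibration.linear_range
    return force, flagged


def detect_retraction_events(
    trace: ForceTrace,
    threshold: float = 10.0,
    min_duration: float = 0.050,
    drop_fraction: float = 0.5,
    drop_window: float = 0.025,
    smooth_ms: float = 1.5,
    merge_gap: float = 0.005,
) -> List[RetractionEvent]:
    """Detect pilus-retraction episodes and register their rupture forces.

    An event is a contiguous episode in which the smoothed force stays above
    ``threshold`` (pN) for at least ``min_duration`` (s) and terminates with a
    drop of at least ``drop_fraction`` of its peak within ``drop_window`` (s).
    The rupture force is the maximum smoothed force before the drop (with
    ``smooth_ms = 0`` the raw maximum, exact on noiseless traces).  Episodes
    separated by less than ``merge_gap`` are merged; events are returned in
    temporal order.
    """
    if trace.time.size == 0:
        raise ValueError("empty trace")
    fs = trace.calibration.sampling_rate
    force = trace.force
    w = max(int(round(smooth_ms * 1e-3 * fs)), 1)
    smoothed = uniform_filter1d(force, size=w) if w > 1 else force

    above = smoothed > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)

    # merge close episodes
    merged: List[Tuple[int, int]] = []
    gap_n = int(round(merge_gap * fs))
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= gap_n:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    min_n = int(round(min_duration * fs))
    drop_n = max(int(round(drop_window * fs)), 1)
    events: List[RetractionEvent] = []
    for s, e in merged:
        if e - s < min_n:
            continue
        seg = smoothed[s:e]
        peak_rel = int(np.argmax(seg))
        peak_idx = s + peak_rel
        peak = float(seg[peak_rel])
        tail = smoothed[peak_idx : min(peak_idx + drop_n, smoothed.size)]
        if tail.size == 0 or tail.min() > (1.0 - drop_fraction) * peak:
            continue
        events.append(
            RetractionEvent(
                t_start=float(trace.time[s]),
                t_rupture=float(trace.time[peak_idx]),
                rupture_force=peak,
                above_linear_range=peak > trace.calibration.f_max,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Rupture-force distribution
# ---------------------------------------------------------------------------

def fit_rupture_distribution(
    forces: Sequence[float],
    cutoff: float = 65.0,
    lower: float = 0.0,
    min_events: int = 50,
    mode: str = "mle",
    bin_width: float = 5.0,
) -> RuptureForceFit:
    """Gaussian fit of rupture forces restricted to ``lower <= F < cutoff``.

    Forces beyond the trap's linear range (>= ``cutoff``, 65 pN by default)
    are overestimated and excluded; the default fit is a maximum-likelihood
    fit of a Gaussian truncated to the kept window, so the exclusion itself
    does not bias the location.  ``lower`` can encode a detection floor (a
    force below which events cannot pass the detector) and defaults to 0.
    ``mode="histogram"`` instead least-squares fits a Gaussian to a histogram
    with ``bin_width`` pN bins, mirroring a plot-level fit.
    """
    f = np.asarray(list(forces), float)
    kept = f[(f < cutoff) & (f >= lower)]
    n = kept.size
    if n < min_events:
        raise ValueError(f"only {n} events below cutoff; need at least {min_events}")
    if np.ptp(kept) == 0:
        raise ValueError("degenerate fit: all kept forces are identical")

    edges = np.arange(lower, cutoff + bin_width, bin_width)
    counts, edges = np.histogram(kept, bins=edges)

    if mode == "histogram":
        centers = 0.5 * (edges[:-1] + edges[1:])
        def gauss(x, a, mu, sd):
            return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
        p0 = (counts.max(), kept.mean(), max(kept.std(), 1.0))
        popt, pcov = optimize.curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
        mu, sd = float(popt[1]), abs(float(popt[2]))
        mu_se, sd_se = (float(np.sqrt(pcov[1, 1])), float(np.sqrt(pcov[2, 2])))
    elif mode == "mle":
        def nll(params):
            mu, log_sd = params
            sd = math.exp(log_sd)
            a = (lower - mu) / sd
            b = (cutoff - mu) / sd
            return -np.sum(stats.truncnorm.logpdf(kept, a, b, loc=mu, scale=sd))

        res = optimize.minimize(
            nll,
            x0=np.array([kept.mean(), math.log(max(kept.std(), 1e-3))]),
            method="BFGS",
        )
        mu, sd = float(res.x[0]), float(math.exp(res.x[1]))
        # delta method on (mu, log_sd) from the inverse Hessian
        try:
            cov = np.asarray(res.hess_inv)
            mu_se = float(np.sqrt(max(cov[0, 0], 0.0)))
            sd_se = float(sd * np.sqrt(max(cov[1, 1], 0.0)))
        except Exception:  # pragma: no cover
            mu_se = sd_se = float("nan")
    else:
        raise ValueError(f"unknown fit mode {mode!r}")

    return RuptureForceFit(
        location=mu,
        scale=sd,
        location_se=mu_se,
        scale_se=sd_se,
        n_events_used=int(n),
        cutoff=cutoff,
        lower=lower,
        histogram=(edges, counts),
        mode=mode,
    )


def retraction_frequency(
    events_per_trace: Sequence[Sequence[RetractionEvent]] | Sequence[RetractionEvent],
    observation_time: float,
) -> dict:
    """Per-trace retraction frequencies (events / observation time, s⁻¹).

    Accepts either one event list or a list of per-trace event lists; returns
    a dict with per-trace frequencies, their mean and standard error, and the
    mean expressed per minute.
    """
    if observation_time <= 0:
        raise ValueError("observation_time must be positive")
    if len(events_per_trace) and isinstance(events_per_trace[0], RetractionEvent):
        groups: List[Sequence[RetractionEvent]] = [events_per_trace]  # type: ignore[list-item]
    else:
        groups = list(events_per_trace)  # type: ignore[assignment]
    freqs = np.array([len(g) / observation_time for g in groups])
    mean = float(freqs.mean()) if freqs.size else 0.0
    se = float(freqs.std(ddof=1) / math.sqrt(freqs.size)) if freqs.size > 1 else 0.0
    return {
        "frequencies_hz": freqs,
        "mean_hz": mean,
        "se_hz": se,
        "mean_per_min": mean * 60.0,
    }
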