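"""Clone-level statistics: spatial variance, offspring counts, front dynamics.

Given tracked colony circles and background-corrected fluorescent patches,
this module computes the intensity-weighted spatial variance of clonal
sectors, fits the fluorescence-production model to infer offspring numbers,
estimates generation times from the fluorescence increase of
initially-fluorescent colonies, and quantifies how likely the offspring of a
clone is to move toward the expanding colony front as a function of its
distance from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CloneTimeSeries",
    "GrowthFit",
    "FrontTrace",
    "FrontProbabilityCurve",
    "spatial_variance",
    "fit_radius_exponential",
    "estimate_generation_time",
    "fit_fluorescence_model",
    "fluorescence_model",
    "variance_vs_offspring",
    "front_distance_trace",
    "front_probability",
]


# ---------------------------------------------------------------------------
# Spatial variance
# ---------------------------------------------------------------------------

def spatial_variance(
    x: np.ndarray, y: np.ndarray, intensities: np.ndarray
) -> Tuple[float, float, float]:
    """Intensity-weighted spatial variance of a clonal sector.

    σx² = Σ xᵢ²Iᵢ/I_tot − (Σ xᵢIᵢ/I_tot)², likewise for y, and
    σ² = σx² + σy².  Units follow the input coordinates (px², µm², or
    unitless on radius-normalized coordinates).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(intensities, float)
    if x.size == 0:
        raise ValueError("empty pixel set")
    if x.size != y.size or x.size != w.size:
        raise ValueError("x, y and intensities must have equal length")
    itot = w.sum()
    if itot <= 0:
        raise ValueError("total intensity must be positive")
    wx = w / itot
    sx2 = float(np.sum(x * x * wx) - np.sum(x * wx) ** 2)
    sy2 = float(np.sum(y * y * wx) - np.sum(y * wx) ** 2)
    return max(sx2, 0.0), max(sy2, 0.0), max(sx2, 0.0) + max(sy2, 0.0)


@dataclass
class CloneTimeSeries:
    """Per-frame record of one clonal sector."""

    clone_id: int
    frames: np.ndarray
    times: np.ndarray  # min
    itot: np.ndarray
    sx2: np.ndarray  # px²
    sy2: np.ndarray
    s2: np.ndarray
    s2_norm: np.ndarray  # on radius-normalized coordinates, unitless
    front_touching: np.ndarray  # bool per frame
    n_est: Optional[np.ndarray] = None  # inferred offspring count
    pixel_size: float = 1.0  # µm/px

    @property
    def s2_um2(self) -> np.ndarray:
        return self.s2 * self.pixel_size**2

    def mobility_frames(self) -> np.ndarray:
        """Frames usable for mobility statistics: before first front contact."""
        touched = np.nonzero(self.front_touching)[0]
        cut = touched[0] if touched.size else len(self.frames)
        return np.arange(len(self.frames)) < cut


# ---------------------------------------------------------------------------
# Radius growth and generation time
# ---------------------------------------------------------------------------

def fit_radius_exponential(
    times: np.ndarray,
    radii: np.ndarray,
    resid_band: float = 0.1,
    min_frames: int = 8,
) -> Tuple[float, np.ndarray]:
    """Exponential growth rate of the colony radius and its analysis window.

    Fits log R against t; the analysis window is the longest prefix of frames
    whose log-residuals stay within ``resid_band``.  Downstream clone analysis
    is restricted to that window.  Returns ``(rate per min, boolean window)``.
    """
    t = np.asarray(times, float)
    r = np.asarray(radii, float)
    if np.any(r <= 0):
        raise ValueError("radii must be positive")
    if t.size < min_frames:
        raise ValueError(f"need at least {min_frames} frames")
    logr = np.log(r)
    for m in range(t.size, max(min_frames - 1, 2) - 1, -1):
        slope, intercept = np.polyfit(t[:m], logr[:m], 1)
        resid = logr[:m] - (slope * t[:m] + intercept)
        if np.all(np.abs(resid) < resid_band):
            window = np.arange(t.size) < m
            return float(slope), window
    # no prefix satisfies the band; fall back to the minimal prefix fit
    slope, _ = np.polyfit(t[:2], logr[:2], 1)
    return float(slope), np.arange(t.size) < 2


def estimate_generation_time(
    times: np.ndarray, itot: np.ndarray
) -> Tuple[float, float]:
    """Generation time from the fluorescence increase of an equilibrium colony.

    For colonies fluorescent from the start, total fluorescence doubles once
    per generation, so a linear fit of log I_tot against t gives
    τ = ln 2 / slope.  Returns ``(tau_min, tau_se_min)``.
    """
    t = np.asarray(times, float)
    y = np.asarray(itot, float)
    if np.any(y <= 0):
        raise ValueError("intensity series must be strictly positive")
    if y[-1] <= y[0]:
        raise ValueError("intensity series does not increase; cannot estimate τ")
    res = stats.linregress(t, np.log(y))
    if res.slope <= 0:
        raise ValueError("non-positive growth rate")
    tau = math.log(2.0) / res.slope
    tau_se = math.log(2.0) * res.stderr / res.slope**2
    return float(tau), float(tau_se)


# ---------------------------------------------------------------------------
# Fluorescence-production model
# ---------------------------------------------------------------------------

def fluorescence_model(
    t: np.ndarray, I0: float, t0: float, k_deg: float, tau: float
) -> np.ndarray:
    """Total fluorescence of a de-novo clone.

    ``I_tot(t) = I0 · N(t−t0) · (1 − e^(−2·k_deg·(t−t0)))`` with
    ``N(Δ) = 2^(Δ/τ)``; zero before onset.  The production rate is tied to
    the equilibrium single-cell intensity by ``k_prod = I0·k_deg``.
    """
    delta = np.asarray(t, float) - t0
    return np.where(
        delta > 0,
        I0 * 2.0 ** (delta / tau) * (1.0 - np.exp(-2.0 * k_deg * np.maximum(delta, 0.0))),
        0.0,
    )


def exact_ode_model(
    t: np.ndarray, I0: float, t0: float, k_deg: float, tau: float
) -> np.ndarray:
    """Exact solution of dI/dt = k_prod·N − k_deg·I with N(Δ)=2^(Δ/τ), I(t0)=0.

    Provided for comparison with :func:`fluorescence_model`; not used by the
    standard analysis.
    """
    delta = np.asarray(t, float) - t0
    lam = math.log(2.0) / tau
    k_prod = I0 * k_deg
    with np.errstate(over="ignore"):
        val = k_prod / (lam + k_deg) * (np.exp(lam * delta) - np.exp(-k_deg * delta))
    return np.where(delta > 0, val, 0.0)


@dataclass
class GrowthFit:
    """Fitted fluorescence-production parameters of one clone."""

    I0: float
    t0: float  # min
    k_deg: float  # 1/min
    tau_growth: float  # min, supplied (not fitted)
    residual_rms: float
    times: np.ndarray
    model_itot: np.ndarray

    @property
    def k_prod(self) -> float:
        """Fluorescence production rate per cell, I0·k_deg."""
        return self.I0 * self.k_deg

    def n_cells(self, t: np.ndarray) -> np.ndarray:
        """Inferred number of fluorescent bacteria N(t − t0) = 2^((t−t0)/τ)."""
        delta = np.asarray(t, float) - self.t0
        return np.where(delta >= 0, 2.0 ** (delta / self.tau_growth), 0.0)

    def per_cell_normalization(self, t: np.ndarray, itot: np.ndarray) -> np.ndarray:
        """Measured I_tot normalized by I0·N: approaches 1 once matured."""
        n = self.n_cells(t)
        return np.divide(
            np.asarray(itot, float),
            self.I0 * n,
            out=np.full(np.asarray(t).shape, np.nan),
            where=n > 0,
        )


def fit_fluorescence_model(
    times: np.ndarray,
    itot: np.ndarray,
    tau_growth: float,
    k_deg_init: float = 1.0 / 60.0,
    lineage: str = "continuous",
) -> GrowthFit:
    """Fit (I0, t0, k_deg) of the fluorescence-production model to I_tot(t).

    τ_growth is supplied externally from initially-fluorescent colonies and is
    never co-fitted, which removes the growth/maturation degeneracy.
    Initialization: t0 at the first time I_tot exceeds 3× the pre-onset noise
    floor, k_deg = 1/60 min⁻¹, I0 from the late-time amplitude.  Residuals are
    weighted relatively (multiplicative noise model), with a small floor so
    pre-onset zeros still constrain t0.

    ``lineage="continuous"`` (default) uses ``N(Δ) = 2^(Δ/τ)`` as printed in
    the model; ``lineage="integer"`` profiles t0 over a grid and rounds the
    lineage count to integers inside the model — at small N the continuous
    interpolation misattributes the rounding staircase to (I0, t0, k_deg),
    which biases inferred offspring numbers, so the integer mode is preferred
    when the clone is followed from its first one or two cells.
    """
    t = np.asarray(times, float)
    y = np.asarray(itot, float)
    if not np.any(y > 0):
        raise ValueError("no fluorescence onset: series is non-positive throughout")
    sigma = np.maximum(np.abs(y), 1e-3 * y.max())
    noise_floor = max(float(np.abs(y[y <= np.percentile(y, 25)]).std()), 1e-12)
    above = np.nonzero(y > 3.0 * noise_floor)[0]
    t0_init = t[above[0]] if above.size else t[0]
    t0_init = max(t0_init, t[0] + 1e-6)
    n_late = 2.0 ** ((t[-1] - t0_init) / tau_growth)
    i0_init = max(y[-1] / n_late, 1e-9)

    if lineage == "integer":
        i0_f, t0_f, kd_f, fitted = _fit_integer_lineage(
            t, y, sigma, tau_growth, t0_init, i0_init, k_deg_init
        )
    elif lineage == "continuous":
        def model(tt, i0, t0, kd):
            return fluorescence_model(tt, i0, t0, kd, tau_growth)

        bounds = ([1e-12, t[0], 1e-6], [np.inf, t[-1], 10.0])
        # multi-start: the weighted objective can have local minima, so seed it
        # from two onset candidates, several maturation rates, and the
        # unweighted solution
        t0_small = float(t[np.nonzero(y > 0)[0][0]])
        t0_cands = {t0_init, max(t0_small, t[0] + 1e-6)}
        starts = [
            (max(y[-1] / 2.0 ** ((t[-1] - t0c) / tau_growth), 1e-9), t0c, kd)
            for t0c in t0_cands
            for kd in (k_deg_init, 0.05, 0.2)
        ]
        for p0 in list(starts):
            try:
                p_abs, _ = optimize.curve_fit(
                    model, t, y, p0=p0, bounds=bounds, maxfev=20000
                )
            except RuntimeError:
                continue
            starts.append(tuple(p_abs))
        best = None
        last_exc: Optional[Exception] = None
        for p0 in starts:
            try:
                popt, _ = optimize.curve_fit(
                    model, t, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
                )
            except RuntimeError as exc:
                last_exc = exc
                continue
            chi2 = float(np.sum(((model(t, *popt) - y) / sigma) ** 2))
            if best is None or chi2 < best[0]:
                best = (chi2, popt)
        if best is None:
            raise RuntimeError(
                f"fluorescence-model fit did not converge (t0 init {t0_init:.1f} min, "
                f"I0 init {i0_init:.3g}): {last_exc}"
            )
        popt = best[1]
        i0_f, t0_f, kd_f = (float(v) for v in popt)
        fitted = model(t, *popt)
    else:
        raise ValueError(f"unknown lineage mode {lineage!r}")
    rms = float(np.sqrt(np.mean((fitted - y) ** 2)))
    return GrowthFit(
        I0=i0_f, t0=t0_f, k_deg=kd_f, tau_growth=tau_growth,
        residual_rms=rms, times=t, model_itot=fitted,
    )


def _fit_integer_lineage(
    t: np.ndarray,
    y: np.ndarray,
    sigma: np.ndarray,
    tau: float,
    t0_init: float,
    i0_init: float,
    k_deg_init: float,
) -> Tuple[float, float, float, np.ndarray]:
    """Profile t0 on a grid with integer lineage counts in the model."""
    pos = np.nonzero(y > 0)[0]
    t_first = t[pos[0]]
    dt = float(np.median(np.diff(t))) if t.size > 1 else 15.0
    lo = max(float(t[0]), t_first - dt)
    best = None
    for t0c in np.arange(lo, t_first + 0.25, 0.5):
        delta = t - t0c
        n_vec = np.where(delta > 0, np.round(2.0 ** (delta / tau)), 0.0)

        def model(tt, i0, kd):
            d = np.maximum(tt - t0c, 0.0)
            return n_vec * i0 * (1.0 - np.exp(-2.0 * kd * d))

        try:
            popt, _ = optimize.curve_fit(
                model, t, y, p0=(i0_init, k_deg_init), sigma=sigma,
                bounds=([1e-12, 1e-6], [np.inf, 10.0]), maxfev=10000,
            )
        except RuntimeError:
            continue
        chi2 = float(np.sum(((model(t, *popt) - y) / sigma) ** 2))
        if best is None or chi2 < best[0]:
            best = (chi2, t0c, popt, model(t, *popt))
    if best is None:
        raise RuntimeError("integer-lineage fluorescence fit did not converge")
    _, t0_f, (i0_f, kd_f), fitted = best
    return float(i0_f), float(t0_f), float(kd_f), fitted


# ---------------------------------------------------------------------------
# Variance vs offspring number
# ---------------------------------------------------------------------------

def variance_vs_offspring(
    clones: Sequence[CloneTimeSeries],
    min_sectors: int = 1,
    use_um2: bool = True,
) -> Dict[str, np.ndarray]:
    """Average sector variance as a function of the number of offspring N.

    Frames after a sector first touches the expanding front are excluded
    (front contact distorts the spread).  σ² values are binned by integer
    generation (round of log₂ N) and averaged across sectors; bins observed in
    fewer than ``min_sectors`` sectors are dropped.  Returns arrays
    ``n`` (representative offspring count 2^g), ``mean``, ``se``,
    ``n_sectors`` per bin.
    """
    per_bin: Dict[int, List[float]] = {}
    for clone in clones:
        if clone.n_est is None:
            raise ValueError(f"clone {clone.clone_id} lacks inferred offspring counts")
        keep = clone.mobility_frames()
        s2 = clone.s2_um2 if use_um2 else clone.s2
        for ok, n, v in zip(keep, clone.n_est, s2):
            if not ok or not np.isfinite(n) or n < 1:
                continue
            per_bin.setdefault(int(round(math.log2(n))), []).append(float(v))
    gens = sorted(g for g, vals in per_bin.items() if len(vals) >= min_sectors)
    if not gens:
        import warnings

        warnings.warn("no surviving frames: variance-vs-offspring curve is empty", stacklevel=2)
        return {"n": np.empty(0), "mean": np.empty(0), "se": np.empty(0), "n_sectors": np.empty(0, int)}
    means = np.array([np.mean(per_bin[g]) for g in gens])
    ses = np.array(
        [
            np.std(per_bin[g], ddof=1) / math.sqrt(len(per_bin[g])) if len(per_bin[g]) > 1 else 0.0
            for g in gens
        ]
    )
    counts = np.array([len(per_bin[g]) for g in gens])
    return {"n": 2.0 ** np.asarray(gens, float), "mean": means, "se": ses, "n_sectors": counts}


# ---------------------------------------------------------------------------
# Front dynamics
# ---------------------------------------------------------------------------

@dataclass
class FrontTrace:
    """Distance (µm) of a clone's closest pixel to the colony front, per frame."""

    clone_id: int
    frames: np.ndarray
    distances: np.ndarray  # µm, >= 0; NaN marks frames without clone pixels
    clipped: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    front_eps: float = 0.5  # µm

    @property
    def front_touching(self) -> np.ndarray:
        return self.distances < self.front_eps


def front_distance_trace(
    pixels_per_frame: Sequence[Optional[np.ndarray]],
    circles_per_frame: Sequence[Tuple[float, float, float]],
    pixel_size: float,
    frames: Optional[Sequence[int]] = None,
    clone_id: int = 0,
    front_eps: float = 0.5,
) -> FrontTrace:
    """Distance of the clone pixel closest to the front, per frame.

    ``distance = (R − max_i r_i) · pixel_size``, clipped at 0 (with a flag)
    when the circle fit places pixels outside the front.  Frames with no clone
    pixels are recorded as NaN gaps, never interpolated.
    """
    n = len(circles_per_frame)
    dist = np.full(n, np.nan)
    clipped = np.zeros(n, dtype=bool)
    for i, (pix, (cx, cy, R)) in enumerate(zip(pixels_per_frame, circles_per_frame)):
        if pix is None or len(pix) == 0:
            continue
        pts = np.asarray(pix, float)
        r = np.hypot(pts[:, 1] - cx, pts[:, 0] - cy)
        d = (R - r.max()) * pixel_size
        if d < 0:
            clipped[i] = True
            d = 0.0
        dist[i] = d
    fr = np.asarray(frames if frames is not None else np.arange(n), int)
    return FrontTrace(clone_id=clone_id, frames=fr, distances=dist, clipped=clipped, front_eps=front_eps)


@dataclass
class FrontProbabilityCurve:
    """Probability of moving toward the front, binned by current distance."""

    bin_edges: np.ndarray  # µm
    probability: np.ndarray  # cross-experiment weighted mean; NaN = empty bin
    weighted_sd: np.ndarray
    n_transitions: np.ndarray  # pooled over experiments
    per_experiment: List[Dict[str, np.ndarray]] = field(default_factory=list)


def front_probability(
    traces_by_experiment: Sequence[Sequence[FrontTrace]],
    bin_width: float = 1.0,
    max_distance: float = 10.0,
    front_eps: float = 0.5,
) -> FrontProbabilityCurve:
    """Front-approach probability as a function of distance from the front.

    Every consecutive frame pair of every trace contributes one transition,
    binned by its current distance.  "Moves toward the front" means the
    distance strictly decreases; in the at-front bin (distance below
    ``front_eps``) remaining at the front also counts as success, since
    residing and staying at the front is the behaviour of interest there.
    Probabilities are pooled within each experiment; across experiments the
    curve reports the trace-count-weighted mean and the weighted standard
    deviation σ_w = sqrt(Σ wₑ(pₑ−p̄)² / Σ wₑ).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    n_bins = edges.size - 1
    per_exp: List[Dict[str, np.ndarray]] = []
    for traces in traces_by_experiment:
        succ = np.zeros(n_bins)
        tot = np.zeros(n_bins)
        for trace in traces:
            d = trace.distances
            for a, b in zip(d[:-1], d[1:]):
                if not (np.isfinite(a) and np.isfinite(b)):
                    continue
                bi = min(int(a // bin_width), n_bins - 1)
                if a < front_eps:
                    success = b < front_eps
                else:
                    success = b < a
                tot[bi] += 1
                succ[bi] += success
        with np.errstate(invalid="ignore"):
            p = np.divide(succ, tot, out=np.full(n_bins, np.nan), where=tot > 0)
        per_exp.append({"p": p, "n": tot, "n_traces": np.array(len(traces))})

    prob = np.full(n_bins, np.nan)
    wsd = np.full(n_bins, np.nan)
    pooled_n = np.zeros(n_bins)
    for bi in range(n_bins):
        ps, ws = [], []
        for exp in per_exp:
            pooled_n[bi] += exp["n"][bi]
            if np.isfinite(exp["p"][bi]):
                ps.append(exp["p"][bi])
                ws.append(float(exp["n_traces"]))
        if ps:
            ps_a, ws_a = np.asarray(ps), np.asarray(ws)
            pbar = float(np.sum(ws_a * ps_a) / np.sum(ws_a))
            prob[bi] = pbar
            wsd[bi] = float(np.sqrt(np.sum(ws_a * (ps_a - pbar) ** 2) / np.sum(ws_a)))
    return FrontProbabilityCurve(
        bin_edges=edges,
        probability=prob,
        weighted_sd=wsd,
        n_transitions=pooled_n,
        per_experiment=per_exp,
    )
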