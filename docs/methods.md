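# Methods

This note documents the models implemented in `pilisort`, the defaults and
their rationale, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter for reproducing results.

## Trap force spectroscopy

**Physical model.** A cell (monococcus, treated as a 1 µm sphere) held in an
optical trap of stiffness k experiences Brownian motion with equipartition
variance k_B·T/k and relaxes with the corner time γ/k, where γ = 3πηd is the
Stokes drag. The generator produces this baseline as an exactly discretized
Ornstein–Uhlenbeck process, so its sampled power spectrum is the aliased
Lorentzian of an AR(1) process — not the continuous Lorentzian.

**Calibration.** `calibrate_trap_psd` fits the Welch spectrum of an
event-free trace over a band excluding low-frequency drift and the Nyquist
region (default 50 Hz – 0.8·f_Nyquist). By default it fits the sampled-process
form of the Lorentzian: at the default settings the corner frequency
(≈3.4 kHz) is a third of the Nyquist frequency, and ignoring aliasing biases
a plain-Lorentzian fit by more than the 10% calibration tolerance. A
plain-Lorentzian mode (`aliasing=False`) is kept for comparison. Stiffness
follows from k = 2πγf_c. Calibration fails loudly when the fitted corner
leaves the usable band (e.g. white-noise input) or the log-spectrum R² is
poor.

**Events.** Pilus retraction is modelled as a linear deflection ramp at the
retraction speed v (default 1000 nm/s, loading rate k·v = 140 pN/s), ending
instantaneously at a rupture force drawn from a condition preset, followed by
relaxation to baseline within one corner time. Presets place the Gaussian
location at 39 pN (wt on wt pili), 46 pN (non-glycosylated on
non-glycosylated) and 25 pN (non-glycosylated on wt); the scale is 8 pN for
all three — a package default chosen for plausibility, since only the
locations are experimentally constrained. Two event layouts exist: Poisson
arrivals over a fixed duration (arrivals inside an ongoing event are dropped;
a warning fires when expected occupancy exceeds 10%), and a fixed-count mode
(`n_events`) that lays events out sequentially with Exp(rate) gaps, used when
an exact sample size is wanted.

**Detection.** An event is a contiguous episode with smoothed force above a
threshold (10 pN) for at least 50 ms, terminated by a drop of ≥50% of peak
within 25 ms. The rupture force is the maximum of the smoothed force in the
episode. The smoothing window (default 1.5 ms) balances two opposing biases:
averaging flattens the ramp peak (−k·v·w/2) while noise inflates the maximum
(+); at 1.5 ms the net per-event bias is below 0.1 pN at default noise. With
`smooth_ms=0` detection is exact on noiseless ramps, which is how the
detector is validated.

**Distribution fits.** The default fit is maximum likelihood of a Gaussian
truncated to a window [lower, cutoff). The upper cutoff (65 pN) is the trap's
linear-range limit — beyond ≈450 nm deflection forces are overestimated, so
those events are excluded and the truncation is modelled rather than ignored.
The lower bound (default 0 = no lower truncation) encodes the detector's
force floor: an event must sustain the threshold for the minimum duration, so
forces below threshold + loading rate × min-duration (≈17 pN at defaults)
cannot be detected. For low-force conditions (the 25 pN cross-condition)
ignoring this censoring would bias the location upward by >1 pN. A
histogram least-squares mode (5 pN bins) is provided for plot-level
comparisons; neither mode is claimed to replicate the original fit exactly,
whose weighting is unknown.

## Colony imaging

**Generator.** One colony per position grows from radius R₀ (4 µm) with
R(t) = R₀·2^(t/T_R); the radius doubling time T_R defaults to 2τ (area ∝
cell number in a monolayer — the growth law itself is only constrained to be
exponential). The colony interior is rendered as high-variance speckle
(contrast 0.3 on a base level of 100) on a smooth background; a low-order
radial polynomial illumination field (amplitude 0.15, mean 1) multiplies both
channels, and additive Gaussian noise is applied per channel. Frame interval
15 min and a 120-position grid (10×12 by default) mirror the imaging
protocol; pixel size 0.32 µm/px is a package default, not a reported value.

**Clones.** A clone starts as one cell at (r/R, θ) at onset t₀. Lineage
counts follow N(t) = round(2^((t−t₀)/τ)). Cells co-move homothetically with
the expansion, take Gaussian diffusion steps of variance D·Δt/τ per frame
(D = 0.5 µm²/generation by default — roughly one cell-diameter-scale
rearrangement per division, consistent with sector spreads of a few to tens
of µm²), and, for the P− (non-piliated) preset, drift outward by 0.6 µm/frame
whenever within 3 µm of the front. Cells are kept inside the colony. Each
cell's fluorescence matures as I₀(1−e^(−2·k_deg·Δ)) on the shared lineage
clock — reusing the bulk fit form at single-cell level is a modelling choice,
not an experimentally established kinetic. Cells are rendered as normalized
Gaussian blobs (σ = 0.5 µm) so each cell's pixel sum equals its intensity
exactly; ground truth records circles, per-frame clone pixel memberships
(clipped to the colony circle), N(t), I_tot(t) and front distances.

**Pipeline.** The imaging chain follows the stated order: flat-field from
the normalized, smoothed average of all first-timepoint positions (only
single cells are present then, so the average shows the illumination);
stitching by metadata placement (no registration — the generator is
drift-free); 5×5 local-variance segmentation with Otsu threshold (fixed-value
mode available); 3 binary dilations and 3 erosions with a 3×3 cross followed
by hole filling (iteration count and element are package defaults — the
protocol states the operations but not their parameters); contour = pixels
removed by one further erosion; Kåsa algebraic circle fit (exact on
noise-free circles); nearest-centre tracking gated at max(5 px, 0.5R), with
tracks invalidated permanently once circles overlap (centre distance <
R₁+R₂+3 px). Fluorescence is smoothed with an 11×11 Gaussian (σ = 1.5 px);
the ROI background is the median of pixels below the ROI's 75th percentile
(robust to the bright patch itself); the threshold is 5× the MAD of the
background residuals, with a fixed-value override, and components under
4 px are discarded as specks. Clone assignment pools all frames'
radius-normalized coordinates on the unit disk, bins them 64×64, and takes
connected occupied components as clones (the original selection was manual;
polygon input is supported for that workflow).

**σ² correction.** Sector variances are computed with the intensity-weighted
formula and then corrected for the known broadening of the Gaussian
pre-smoothing by subtracting σ_kernel² per axis (floored at zero). Without
this the measured variance of a compact sector is offset by 2σ_kernel²
≈ 4.5 px² regardless of its true spread.

## Clone statistics

**Generation time.** For colonies fluorescent from the start (reporter at
equilibrium), total fluorescence doubles once per generation, so τ = ln2 /
slope of a linear fit to log I_tot vs t. Exact on noiseless exponentials;
unbiased within Monte-Carlo error at 5% multiplicative noise.

**Offspring counting.** The production–degradation model
dI_tot/dt = k_prod·N − k_deg·I_tot is fitted through its closed form
I_tot(t) = I₀·N(t−t₀)·(1−e^(−2·k_deg·(t−t₀))), N(Δ) = 2^(Δ/τ), with
(I₀, t₀, k_deg) free and τ supplied externally from equilibrium colonies —
never co-fitted, which removes the growth/maturation degeneracy. Note this
printed form is not the exact ODE solution (the exact solution,
k_prod/(λ+k_deg)·(e^(λΔ)−e^(−k_deg·Δ)) with λ = ln2/τ, is provided as
`exact_ode_model` for comparison); the fitted form is used as stated.
Residuals are weighted relatively (multiplicative-noise model) with a small
floor so pre-onset zeros pin t₀; the weighted objective can be multimodal, so
the fit multi-starts from two onset candidates, three maturation rates, and
the unweighted solution. For data with integer lineage counts (the generator,
and arguably reality at small N), a `lineage="integer"` mode profiles t₀ on a
grid with N rounded inside the model: at N ≤ ~8 the continuous interpolation
misreads the rounding staircase as a shifted onset, biasing inferred N by
~15%, which the integer mode removes. The imaging pipeline uses the integer
mode; the continuous printed form remains the default of the public fitting
function.

**Front statistics.** The front distance of a clone is (R − max rᵢ)·pixel
size, clipped at zero (flagged when the circle fit places pixels outside);
frames without clone pixels are gaps, never interpolated. A transition
"moves toward the front" when the distance strictly decreases; in the
at-front bin (< 0.5 µm) remaining at the front counts as success, since
residing and staying there is the behaviour of interest. Probabilities are
pooled per experiment in 1 µm bins; across experiments the curve reports the
trace-count-weighted mean and weighted SD σ_w = sqrt(Σwₑ(pₑ−p̄)²/Σwₑ).
Sector-mobility statistics (variance vs offspring number) exclude all frames
from a sector's first front contact onward, and bin σ² by integer generation
(round of log₂N).

## What the generator does and does not emulate

Emulated: exponential colony expansion, homothetic co-movement of clones,
heritable fluorescence with maturation, illumination inhomogeneity shared
across positions, shot-like per-channel noise, trap Brownian statistics with
the correct spectrum, condition-specific rupture-force distributions, and
outward displacement of non-piliated cells near the front. Not emulated:
diplococcus geometry, cell shape and packing, stage drift and registration
error, photobleaching, depth effects, within-event pilus kinetics (ramps are
linear), multi-pilus force superposition, and colony–colony collisions other
than circle overlap. Passing tests therefore demonstrate correctness of the
analysis chain under the stated models, not robustness to every artefact of
real microscopy.

## Numerical choices and problem sizes

Default test and acceptance runs use 20-frame 384×384 colony movies (3
replicates for front statistics), 12-tile illumination grids, 20 s
calibration traces at 20 kHz, and 600-event force recordings — sizes chosen
so every stage is exercised end to end in seconds per run. Seeds are explicit
everywhere (`numpy.random.default_rng`); reruns with the same configuration
are bit-identical. Degenerate inputs fail loudly: empty pixel sets, zero
total intensity, collinear circle points, all-identical forces, onsets
outside the series, colonies outgrowing the frame (the error names the
frame). Known limitations: the t₀/I₀/k_deg split is weakly identified when
maturation (1/(2k_deg)) is short compared to the frame interval; sectors
smaller than the smoothing kernel are measured at reduced relative accuracy
even after the broadening correction; and the front-distance readout is
offset by roughly the rendered cell radius, so near-front sectors read as
touching the front slightly before their cell centres do.
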