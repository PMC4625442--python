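"""Validated configuration objects for the simulators and pipelines.

Units are stated on every field: lengths in µm (images) or nm (trap),
times in minutes (microscopy) or seconds (trap), forces in pN,
stiffness in pN/nm.
"""

from __future__ import annotations

from typing import Literal, Optional, Tuple

from pydantic import BaseModel, Field, model_validator

#: Boltzmann constant in pN·nm/K (1.380649e-23 J/K = 1.380649e-2 pN·nm/K).
KB_PN_NM = 1.380649e-2

#: Gaussian rupture-force presets (location µ in pN) for pilus–pilus bonds.
#: wt/wt: wild-type pili on wild-type pili; G-/G-: non-glycosylated pilins on
#: both sides; G-/wt: non-glycosylated bacterium pulling on wild-type pili.
#: The scale (8 pN) is a documented package default; only the locations are
#: experimentally constrained quantities.
FORCE_PRESETS = {
    "wt/wt": (39.0, 8.0),
    "G-/G-": (46.0, 8.0),
    "G-/wt": (25.0, 8.0),
}

#: Generation-time presets (min) per reporter strain phenotype.
STRAIN_GENERATION_TIMES = {
    "P+ green": 49.0,
    "P- green": 41.0,
    "P++ red": 56.0,
    "G- green": 50.0,
}


class CloneEvent(BaseModel):
    """A de-novo transformation event seeding one fluorescent clone."""

    t0: float = Field(..., gt=0, description="onset time of the clone, min")
    r_norm: float = Field(..., ge=0.0, le=1.0, description="radial position r/R at onset")
    theta: float = Field(0.0, description="angular position at onset, rad")
    phenotype: Literal["P+", "P-"] = "P+"


class FrontBias(BaseModel):
    """Outward radial drift applied to P- cells close to the expanding front."""

    drift_um_per_frame: float = Field(0.6, ge=0)
    activation_distance_um: float = Field(3.0, gt=0)


class FluorescenceParams(BaseModel):
    """Per-cell reporter parameters: equilibrium intensity and maturation rate."""

    I0: float = Field(50.0, gt=0, description="equilibrium intensity per cell, a.u.")
    k_deg: float = Field(0.02, gt=0, description="fluorophore degradation rate, 1/min")


class IlluminationParams(BaseModel):
    """Smooth multiplicative illumination field (low-order radial polynomial)."""

    amplitude: float = Field(0.15, ge=0, lt=1.0)


class NoiseParams(BaseModel):
    sigma_brightfield: float = Field(2.0, ge=0)
    sigma_fluorescence: float = Field(0.05, ge=0)


class ColonySimConfig(BaseModel):
    """Parameters of the synthetic time-lapse microcolony movie.

    The defaults emulate the study conditions: 15 min frame interval, a grid
    of 120 imaging positions, exponentially growing colony radii.  Pixel size
    (0.32 µm/px) is a documented package default, not an experimentally
    reported value.
    """

    image_shape: Tuple[int, int] = (384, 384)
    pixel_size: float = Field(0.32, gt=0, description="µm per pixel")
    frame_interval: float = Field(15.0, gt=0, description="min between frames")
    n_frames: int = Field(20, ge=1)
    grid_shape: Tuple[int, int] = (10, 12)
    generation_time: float = Field(49.0, gt=0, description="τ, min per doubling")
    radius_doubling_time: Optional[float] = Field(
        None, gt=0, description="min; defaults to 2·τ (area ∝ cell number)"
    )
    initial_radius: float = Field(4.0, gt=0, description="colony radius at t=0, µm")
    clone_events: Tuple[CloneEvent, ...] = ()
    diffusion: float = Field(0.5, ge=0, description="cell mobility D, µm²/generation")
    front_bias: FrontBias = FrontBias()
    fluorescence: FluorescenceParams = FluorescenceParams()
    illumination: IlluminationParams = IlluminationParams()
    noise: NoiseParams = NoiseParams()
    seed: int = 0

    @property
    def radius_doubling(self) -> float:
        return self.radius_doubling_time if self.radius_doubling_time is not None else 2.0 * self.generation_time

    @property
    def duration(self) -> float:
        """Total simulated time, min (last frame time)."""
        return (self.n_frames - 1) * self.frame_interval

    @model_validator(mode="after")
    def _check(self) -> "ColonySimConfig":
        for ev in self.clone_events:
            if ev.t0 > self.duration:
                raise ValueError(
                    f"clone onset t0={ev.t0} min lies beyond the simulated interval "
                    f"({self.duration} min)"
                )
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid_shape entries must be >= 1")
        return self


class TrapSimConfig(BaseModel):
    """Parameters of the synthetic optical-trap deflection recording.

    Defaults mirror the measurement conditions: 20 kHz sampling, trap
    stiffness 0.14 pN/nm, 1 µm bead (monococcus) at 310 K.  The viscosity
    default is water at 37 °C.
    """

    sampling_rate: float = Field(20_000.0, gt=0, description="Hz")
    stiffness: float = Field(0.14, gt=0, description="pN/nm")
    temperature: float = Field(310.0, gt=0, description="K")
    bead_diameter: float = Field(1.0, gt=0, description="µm")
    viscosity: float = Field(7.0e-4, gt=0, description="Pa·s")
    retraction_speed: float = Field(1000.0, gt=0, description="nm/s pilus retraction")
    event_rate: float = Field(0.2, ge=0, description="retraction events per second")
    force_preset: Literal["wt/wt", "G-/G-", "G-/wt", "custom"] = "wt/wt"
    force_mean: Optional[float] = Field(None, gt=0, description="pN, custom preset")
    force_sd: Optional[float] = Field(None, ge=0, description="pN, custom preset")
    duration: float = Field(60.0, gt=0, description="s")
    n_events: Optional[int] = Field(
        None, ge=0,
        description="fixed event count; events are laid out sequentially with "
        "Exp(event_rate) gaps and duration is derived",
    )
    noise_scale: float = Field(1.0, ge=0, description="scales thermal noise; 0 = noiseless")
    seed: int = 0

    @property
    def drag(self) -> float:
        """Stokes drag γ = 3π·η·d in pN·s/nm."""
        # N·s/m -> pN·s/nm is a factor 1e3
        return 3.0 * 3.141592653589793 * self.viscosity * (self.bead_diameter * 1e-6) * 1e3

    @property
    def corner_frequency(self) -> float:
        """Trap corner frequency f_c = k/(2πγ), Hz."""
        import math

        return self.stiffness / (2.0 * math.pi * self.drag)

    @property
    def force_distribution(self) -> Tuple[float, float]:
        if self.force_preset == "custom":
            if self.force_mean is None:
                raise ValueError("custom force preset requires force_mean")
            return self.force_mean, self.force_sd if self.force_sd is not None else 0.0
        return FORCE_PRESETS[self.force_preset]

    @model_validator(mode="after")
    def _check(self) -> "TrapSimConfig":
        if self.sampling_rate <= 2.0 * self.corner_frequency:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz must exceed twice the trap "
                f"corner frequency ({self.corner_frequency:.0f} Hz)"
            )
        mu, sd = self.force_distribution
        if mu <= 0 or sd < 0:
            raise ValueError("rupture-force distribution needs µ_F > 0 and σ_F >= 0")
        return self


def colony_preset(phenotype: str, **overrides) -> ColonySimConfig:
    """Colony configuration for a named reporter strain phenotype.

    ``"P-"`` uses the non-piliated generation time and activates the outward
    front bias for its clones; ``"P+"`` uses the wild-type-like generation
    time with no bias.
    """
    if phenotype not in ("P-", "P+"):
        raise ValueError(f"unknown colony preset {phenotype!r}")
    tau = STRAIN_GENERATION_TIMES["P- green" if phenotype == "P-" else "P+ green"]
    defaults = dict(
        generation_time=tau,
        clone_events=(CloneEvent(t0=60.0, r_norm=0.8, theta=0.8, phenotype=phenotype),),
    )
    defaults.update(overrides)
    return ColonySimConfig(**defaults)
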