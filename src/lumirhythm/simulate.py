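"""Synthetic Per2::luc plate generator.

Emulates the signal class produced by dexamethasone-synchronized reporter
cells in a plate luminometer: a damped sinusoid riding on a decaying
baseline, sampled every 12 minutes (0.2 h) for three days or more, with
additive Gaussian measurement noise and optional phase noise.  Per well,

    y(tᵢ) = baseline_floor + baseline0·e^(−baseline_decay·tᵢ)
            + amplitude0·e^(−λ·tᵢ)·sin(2π(tᵢ − φᵢ)/period_h) + εᵢ,

where φᵢ = phase0_h + (one per-well synchronization jitter draw)
+ (a cumulative Gaussian random walk with per-step sd
phase_diffusion_sd_h_per_sqrt_h·√dt), and εᵢ ~ N(0, noise_sd²) i.i.d.

Synchronization is modeled as small across-well phase jitter at t = 0
(the operational effect of a dexamethasone pulse on ensemble coherence);
``desync=True`` instead draws each well's phase uniformly on [0, T).

Cell-line presets anchor the true periods to the reported values for the
three cancer lines (MC38 26.3 h, E0771 27.2 h, LLC 28.3 h); the NIH3T3
fibroblast period, never printed, defaults to a 24.0 h placeholder (see
docs/methods.md).  Knockdown of the core clock genes Per1/Per2 is modeled
phenomenologically via :func:`knockdown_scenario`.

Determinism: per-well seeds are derived from the preset seed with
``numpy.random.SeedSequence(seed).generate_state(n_wells)``, so a plate is
reproducible well-by-well; identical seeds give bit-identical traces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .trace import LuminescenceTrace, PlateRecording


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for one well.

    Units: hours for times and periods, luminescence counts for levels,
    per-hour for decay rates, hours/√hour for the phase-diffusion scale.
    """

    period_h: float = 24.0
    amplitude0: float = 50.0
    damping_per_h: float = 0.01
    baseline0: float = 200.0
    baseline_decay_per_h: float = 0.03
    baseline_floor: float = 50.0
    noise_sd: float = 10.0
    phase0_h: float = 0.0
    phase_jitter_sd_h: float = 0.5
    phase_diffusion_sd_h_per_sqrt_h: float = 0.0
    duration_h: float = 72.0
    dt_h: float = 0.2
    seed: int = 0
    desync: bool = False

    def __post_init__(self) -> None:
        positive = {"period_h": self.period_h, "dt_h": self.dt_h}
        for name, v in positive.items():
            if not v > 0:
                raise ParameterError(f"{name} must be positive, got {v}")
        nonneg = {
            "amplitude0": self.amplitude0,
            "damping_per_h": self.damping_per_h,
            "baseline0": self.baseline0,
            "baseline_decay_per_h": self.baseline_decay_per_h,
            "baseline_floor": self.baseline_floor,
            "noise_sd": self.noise_sd,
            "phase_jitter_sd_h": self.phase_jitter_sd_h,
            "phase_diffusion_sd_h_per_sqrt_h":
                self.phase_diffusion_sd_h_per_sqrt_h,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ParameterError(f"{name} must be non-negative, got {v}")
        if not self.dt_h < self.period_h / 8:
            raise ParameterError(
                f"dt_h must be < period_h/8 for safe sampling "
                f"(dt_h={self.dt_h}, period_h={self.period_h})"
            )
        if self.duration_h < 48:
            raise ParameterError(
                f"duration_h must be ≥ 48, got {self.duration_h}"
            )
        if self.duration_h < 2 * self.period_h:
            raise ParameterError(
                f"duration_h must cover ≥ 2 periods "
                f"(duration_h={self.duration_h}, period_h={self.period_h})"
            )


@dataclass(frozen=True)
class ScenarioPreset:
    """A named simulation scenario: per-well parameters plus well count."""

    name: str
    params: SimulationParams
    n_wells: int = 3

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ParameterError(f"n_wells must be ≥ 1, got {self.n_wells}")


def simulate_trace(
    params: SimulationParams, well_id: str = "W1"
) -> LuminescenceTrace:
    """Generate one well's trace from the damped-sinusoid model."""
    n = int(round(params.duration_h / params.dt_h)) + 1
    t = np.arange(n) * params.dt_h
    rng = np.random.default_rng(params.seed)
    # Fixed draw order keeps traces bit-identical for equal seeds regardless
    # of which noise terms are switched off.
    jitter = rng.normal(0.0, params.phase_jitter_sd_h)
    uniform_phase = rng.uniform(0.0, params.period_h)
    steps = rng.normal(
        0.0,
        params.phase_diffusion_sd_h_per_sqrt_h * np.sqrt(params.dt_h),
        n - 1,
    )
    walk = np.concatenate(([0.0], np.cumsum(steps)))
    noise = rng.normal(0.0, 1.0, n) * params.noise_sd

    phase = (uniform_phase if params.desync else params.phase0_h + jitter)
    phi = phase + walk
    baseline = params.baseline_floor + params.baseline0 * np.exp(
        -params.baseline_decay_per_h * t
    )
    osc = (
        params.amplitude0
        * np.exp(-params.damping_per_h * t)
        * np.sin(2.0 * np.pi * (t - phi) / params.period_h)
    )
    return LuminescenceTrace(well_id, t, baseline + osc + noise)


def simulate_plate(preset: ScenarioPreset) -> PlateRecording:
    """Generate ``n_wells`` independent wells under one preset.

    Well seeds derive deterministically from the preset seed via
    ``SeedSequence.generate_state``; metadata carries the preset name and
    1-based replicate indices.
    """
    well_seeds = np.random.SeedSequence(preset.params.seed).generate_state(
        preset.n_wells
    )
    traces = []
    conditions: dict[str, str] = {}
    replicates: dict[str, int] = {}
    for i, ws in enumerate(well_seeds):
        well = f"{preset.name}-{i + 1:02d}"
        p = replace(preset.params, seed=int(ws) & 0x7FFFFFFF)
        traces.append(simulate_trace(p, well_id=well))
        conditions[well] = preset.name
        replicates[well] = i + 1
    return PlateRecording(tuple(traces), conditions, replicates)


def knockdown_scenario(
    base: SimulationParams, efficiency: float
) -> SimulationParams:
    """Phenomenological siRNA knockdown of the clock.

    Efficiency ``e ∈ [0, 1]`` scales amplitude by ``1 − 0.6e``, damping by
    ``1 + 2e`` and phase diffusion by ``1 + 4e``; ``e = 0`` is the identity.
    The mapping captures the observed flattening of averaged curves after
    Per1/Per2 loss, not a mechanistic model.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ParameterError(
            f"efficiency must be in [0, 1], got {efficiency}"
        )
    return replace(
        base,
        amplitude0=base.amplitude0 * (1.0 - 0.6 * efficiency),
        damping_per_h=base.damping_per_h * (1.0 + 2.0 * efficiency),
        phase_diffusion_sd_h_per_sqrt_h=(
            base.phase_diffusion_sd_h_per_sqrt_h * (1.0 + 4.0 * efficiency)
        ),
    )


def _fibroblast(seed: int) -> SimulationParams:
    # Preset damping is kept low (0.005/h) so preset periods remain
    # recoverable to ±0.2 h by the undamped fitted model; stronger damping
    # biases the period of a constant-amplitude sinusoid fit (see
    # docs/methods.md, "Damping and period bias").
    return SimulationParams(
        period_h=24.0,
        damping_per_h=0.005,
        phase_diffusion_sd_h_per_sqrt_h=0.01,
        seed=seed,
    )


def _cancer_line(period_h: float, diffusion: float, seed: int
                 ) -> SimulationParams:
    # Cancer lines: reported period, weaker ensemble coherence than NIH3T3
    # (more phase diffusion → lower R²), same gentle population damping.
    return SimulationParams(
        period_h=period_h,
        damping_per_h=0.005,
        phase_diffusion_sd_h_per_sqrt_h=diffusion,
        seed=seed,
    )


def get_preset(
    name: str, n_wells: int | None = None, seed: int | None = None
) -> ScenarioPreset:
    """Look up a named scenario, optionally overriding wells and seed.

    Available presets: NIH3T3, MC38, E0771, LLC, siControl, siPer1, siPer2,
    siPer1Per2, unsync.
    """
    base_seed = 20 + sum(map(ord, name)) % 1000  # stable per-name default
    builders = {
        "NIH3T3": lambda s: _fibroblast(s),
        "MC38": lambda s: _cancer_line(26.3, 0.04, s),
        "E0771": lambda s: _cancer_line(27.2, 0.025, s),
        "LLC": lambda s: _cancer_line(28.3, 0.05, s),
        "siControl": lambda s: _fibroblast(s),
        "siPer1": lambda s: knockdown_scenario(_fibroblast(s), 0.6),
        "siPer2": lambda s: knockdown_scenario(_fibroblast(s), 0.6),
        "siPer1Per2": lambda s: knockdown_scenario(_fibroblast(s), 0.8),
        "unsync": lambda s: replace(_fibroblast(s), desync=True),
    }
    if name not in builders:
        raise ParameterError(
            f"unknown preset {name!r}; available: {', '.join(builders)}"
        )
    params = builders[name](base_seed if seed is None else seed)
    return ScenarioPreset(name, params, 3 if n_wells is None else n_wells)


PRESET_NAMES = (
    "NIH3T3", "MC38", "E0771", "LLC",
    "siControl", "siPer1", "siPer2", "siPer1Per2", "unsync",
)
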