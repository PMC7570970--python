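"""Synthetic walk-over weight traces with known ground truth.

A simulated passage is a trapezoidal load curve: a monotone step-on ramp
from zero, an all-hooves-on plateau centred on the true weight, and a
monotone step-off ramp back to zero.  The plateau carries a gait
oscillation (a fundamental sinusoid at the step frequency plus a
half-amplitude second harmonic, each with random phase) and additive
Gaussian sensor noise.  Oscillation amplitude and crossing speed depend
on the activity grade, so segment features computed downstream separate
the grades the way field data do.

Implementation notes:

* The oscillation frequency is snapped to an integer number of cycles
  over the plateau, so the oscillation contributes exactly zero to the
  plateau sample mean and the plateau mean is an unbiased estimate of
  the true weight.
* Ramps are linear, quantised to whole samples and aligned to the
  sampling grid; at the default ramp fraction the ramp samples stay
  below the 80 % detection threshold, so the extracted valid segment is
  the plateau itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import WeightTrace

__all__ = ["SimConfig", "InvalidConfigError", "GRADE_NAMES", "GRADE_SPEEDS",
           "GRADE_AMPLITUDES", "simulate_trace", "simulate_labelled_dataset"]

GRADE_NAMES = ("low", "medium", "high")

# Mean crossing speed per grade (m/s): a calm animal ambles, an agitated
# one trots across.
GRADE_SPEEDS = {0: 0.75, 1: 1.25, 2: 1.67}

# Fundamental gait-oscillation amplitude per grade (kg), calibrated by
# Monte-Carlo so the mean simulated segment range R lands near 24 / 60 /
# 108 kg for low / medium / high activity.
GRADE_AMPLITUDES = {0: 8.3, 1: 25.6, 2: 48.3}


class InvalidConfigError(ValueError):
    """A simulation parameter is outside its valid range."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated passage.

    ``speed_m_s`` and ``oscillation_amplitude_kg`` default to the values
    for ``grade`` when left as ``None``.
    """

    true_weight_kg: float = 600.0
    grade: int = 1                       # 0 = low, 1 = medium, 2 = high
    platform_length_m: float = 2.5
    sampling_interval_s: float = 0.1
    speed_m_s: float | None = None
    oscillation_amplitude_kg: float | None = None
    step_frequency_hz: float = 2.0
    noise_sd_kg: float = 2.0
    ramp_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.grade not in (0, 1, 2):
            raise InvalidConfigError(f"grade must be 0, 1 or 2, got {self.grade!r}")
        if self.speed_m_s is None:
            object.__setattr__(self, "speed_m_s", GRADE_SPEEDS[self.grade])
        if self.oscillation_amplitude_kg is None:
            object.__setattr__(self, "oscillation_amplitude_kg",
                               GRADE_AMPLITUDES[self.grade])
        if self.true_weight_kg <= 0:
            raise InvalidConfigError("true_weight_kg must be positive")
        if self.speed_m_s <= 0:
            raise InvalidConfigError("speed_m_s must be positive")
        if self.platform_length_m <= 0 or self.sampling_interval_s <= 0:
            raise InvalidConfigError("platform length and sampling interval must be positive")
        if self.oscillation_amplitude_kg < 0 or self.noise_sd_kg < 0:
            raise InvalidConfigError("amplitude and noise SD must be nonnegative")
        if not 0 <= self.ramp_fraction < 1:
            raise InvalidConfigError("ramp_fraction must lie in [0, 1)")
        if self.step_frequency_hz <= 0:
            raise InvalidConfigError("step_frequency_hz must be positive")

    @property
    def plateau_duration_s(self) -> float:
        return self.platform_length_m / self.speed_m_s


def _gait_oscillation(n: int, cycles: int, amplitude: float, rng) -> np.ndarray:
    """Fundamental + half-amplitude second harmonic over ``cycles`` periods."""
    j = np.arange(n)
    phase1, phase2 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    osc = amplitude * np.sin(2.0 * np.pi * cycles * j / n + phase1)
    osc += 0.5 * amplitude * np.sin(4.0 * np.pi * cycles * j / n + phase2)
    return osc


def simulate_trace(config: SimConfig, animal_id: str | None = None) -> WeightTrace:
    """Simulate one passage and return its weight trace.

    The plateau has ``round(plateau_duration / dt)`` samples; each ramp
    spans ``ramp_fraction / 2`` of the passage, rounded to whole samples.
    Three zero samples pad each end so edge detection sees a clean
    baseline.  All weights are clipped at zero.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.sampling_interval_s
    w = config.true_weight_kg

    n_plateau = max(1, round(config.plateau_duration_s / dt))
    total_s = config.plateau_duration_s / (1.0 - config.ramp_fraction)
    n_ramp = max(1, round((total_s - config.plateau_duration_s) / 2.0 / dt))

    ramp_up = w * np.arange(1, n_ramp) / n_ramp  # excludes 0 and w endpoints
    plateau = np.full(n_plateau, w)
    if config.oscillation_amplitude_kg > 0 and n_plateau >= 4:
        cycles = int(round(config.step_frequency_hz * n_plateau * dt))
        cycles = max(1, min(cycles, (n_plateau - 1) // 2))  # harmonic below Nyquist
        plateau = plateau + _gait_oscillation(
            n_plateau, cycles, config.oscillation_amplitude_kg, rng)
    if config.noise_sd_kg > 0:
        plateau = plateau + rng.normal(0.0, config.noise_sd_kg, size=n_plateau)

    pad = np.zeros(3)
    weights = np.concatenate([pad, ramp_up, plateau, ramp_up[::-1], pad])
    weights = np.clip(weights, 0.0, None)
    times = np.arange(weights.size) * dt
    return WeightTrace(times=times, weights=weights, sampling_interval_s=dt,
                       animal_id=animal_id)


def simulate_labelled_dataset(n_per_grade: int, base_config: SimConfig | None = None,
                              seed: int = 0):
    """Simulate ``n_per_grade`` passages for each activity grade.

    Per-trace speed and oscillation amplitude are drawn from per-grade
    Gaussian distributions (SD 0.08 m/s and 15 % of the grade amplitude)
    and the true weight varies uniformly within +/- 80 kg of the base
    weight, so features overlap a little between grades as they do in a
    real herd.  Returns a list of ``(trace, grade_label, true_weight_kg)``
    triples, reproducible under a fixed seed.
    """
    if n_per_grade < 1:
        raise InvalidConfigError("n_per_grade must be >= 1")
    base = base_config if base_config is not None else SimConfig()
    rng = np.random.default_rng(seed)
    out = []
    for grade in (0, 1, 2):
        for i in range(n_per_grade):
            speed = max(0.2, rng.normal(GRADE_SPEEDS[grade], 0.08))
            amp = max(0.0, rng.normal(GRADE_AMPLITUDES[grade],
                                      0.15 * GRADE_AMPLITUDES[grade]))
            weight = rng.uniform(base.true_weight_kg - 80.0,
                                 base.true_weight_kg + 80.0)
            cfg = replace(base, grade=grade, speed_m_s=speed,
                          oscillation_amplitude_kg=amp, true_weight_kg=weight,
                          seed=int(rng.integers(2**31)))
            trace = simulate_trace(cfg, animal_id=f"sim-{grade}-{i:04d}")
            out.append((trace, grade, weight))
    return out
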