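"""Synthetic waveforms for exercising the feature/pattern analytics
independently of the ODE model.

Four families mimic the dynamic-pattern taxonomy: ``constant`` (flat /
non-responding), ``saturating_exponential`` (monotonic-increasing),
``damped_cosine`` (oscillation whose per-cycle peak amplitude decays by
exp(−period/decay)) and ``sustained_sine`` (undamped oscillation).  All
oscillatory families start at the baseline and peak first at t = period/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SyntheticSignalSpec", "generate_synthetic_signal", "FAMILIES"]

FAMILIES = ("constant", "saturating_exponential", "damped_cosine", "sustained_sine")


@dataclass(frozen=True)
class SyntheticSignalSpec:
    """Waveform family plus shape, duration and noise parameters (hours)."""

    family: str = "damped_cosine"
    amplitude: float = 1.0
    period_h: float = 2.0
    decay_h: float = math.inf   # peak-envelope e-folding time
    baseline: float = 0.0
    duration_h: float = 10.0
    dt_h: float = 0.01
    noise: float = 0.0          # additive Gaussian sd

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown waveform family {self.family!r}; valid: {FAMILIES}")
        if self.duration_h <= 0 or self.dt_h <= 0:
            raise ValueError("duration_h and dt_h must be > 0")
        if self.noise < 0:
            raise ValueError("noise amplitude must be >= 0")


def generate_synthetic_signal(
    spec: SyntheticSignalSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic waveform plus seeded Gaussian noise; returns (t_h, y)."""
    t = np.arange(0.0, spec.duration_h + 0.5 * spec.dt_h, spec.dt_h)
    if spec.family == "constant":
        y = np.full_like(t, spec.baseline)
    elif spec.family == "saturating_exponential":
        tau = spec.decay_h if math.isfinite(spec.decay_h) else spec.period_h
        y = spec.baseline + spec.amplitude * (1.0 - np.exp(-t / tau))
    else:
        envelope = (
            np.exp(-t / spec.decay_h) if math.isfinite(spec.decay_h) else np.ones_like(t)
        )
        y = spec.baseline + spec.amplitude * envelope * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * t / spec.period_h)
        )
    if spec.noise > 0:
        y = y + np.random.default_rng(seed).normal(0.0, spec.noise, t.size)
    return t, y
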