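"""Generative emulation of the electrical observables.

During pulsed ablation the tissue progressively permeabilizes, so the
per-pulse current amplitude climbs and saturates over the train (from
about 12.5 A on the first pulse to ~15 A by the 17th at the strongest
setting), and the low-frequency (10 Hz) conductivity measured before vs
after pulsing increases roughly linearly with field strength.  The
hardware measurement itself is out of scope; this module generates
seeded synthetic records with those shapes so the correlation layer has
matched electrical covariates for every synthetic slice.

The saturating train is
``I_k = I_inf - (I_inf - I_1) * exp(-(k - 1) / kappa)``,
with ``I_1`` and ``I_inf`` scaling linearly with the field setting
relative to the 1500 V/cm anchors — an ohmic simplification between
solves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PulseProtocol",
    "CurrentTrace",
    "ConductivityRecord",
    "ElectricalParams",
    "simulate_current_train",
    "conductivity_change_ratio",
    "generate_conductivity",
]

#: Field setting at which the current anchors are defined, V/cm.
REFERENCE_FIELD_VCM = 1500.0


@dataclass(frozen=True)
class PulseProtocol:
    """Pulse-train protocol: 100-us square pulses, 2000-us delay, 32 pulses."""

    field_setting: float
    pulse_width_us: float = 100.0
    interpulse_delay_us: float = 2000.0
    pulse_count: int = 32

    def __post_init__(self) -> None:
        if self.field_setting < 0:
            raise ValueError("field_setting must be non-negative")
        if self.pulse_width_us <= 0 or self.interpulse_delay_us <= 0:
            raise ValueError("pulse timing must be positive")
        if not isinstance(self.pulse_count, (int, np.integer)) or self.pulse_count < 1:
            raise ValueError("pulse_count must be a positive integer")


@dataclass
class CurrentTrace:
    """Per-pulse current amplitudes, amperes."""

    per_pulse_amplitude: np.ndarray
    protocol: PulseProtocol


@dataclass
class ConductivityRecord:
    """Pre/post-pulsing conductivity at 10 Hz, S/m, and their ratio."""

    sigma_before: float
    sigma_after: float

    @property
    def ratio(self) -> float:
        return self.sigma_after / self.sigma_before


@dataclass(frozen=True)
class ElectricalParams:
    """Anchors and noise of the generative electrical model.

    i_first_A / i_sat_A
        First-pulse and saturated current at the reference 1500 V/cm
        setting; both scale linearly with field setting.
    kappa_pulses
        Saturation constant of the exponential approach; the default 5
        puts pulse 17 at >= 99% of the saturated amplitude.
    sigma_baseline_S_per_m
        Nominal pre-pulse conductivity at 10 Hz.  Only the change
        *ratio* is interpreted downstream; absolute values are nominal.
    ratio_slope_per_vcm
        Linear growth of the conductivity change ratio with field
        setting; the default puts the 1500 V/cm ratio at 2.
    meas_noise_cv
        Multiplicative lognormal measurement noise on currents and
        conductivities.
    """

    i_first_A: float = 12.5
    i_sat_A: float = 15.0
    kappa_pulses: float = 5.0
    sigma_baseline_S_per_m: float = 0.05
    ratio_slope_per_vcm: float = 1.0 / REFERENCE_FIELD_VCM
    meas_noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.i_first_A < self.i_sat_A:
            raise ValueError("require 0 < i_first_A < i_sat_A")
        if self.kappa_pulses <= 0:
            raise ValueError("kappa_pulses must be positive")
        if self.sigma_baseline_S_per_m <= 0:
            raise ValueError("baseline conductivity must be positive")
        if self.meas_noise_cv < 0:
            raise ValueError("meas_noise_cv must be non-negative")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))


def simulate_current_train(
    protocol: PulseProtocol,
    params: ElectricalParams | None = None,
    seed: int = 0,
) -> CurrentTrace:
    """Saturating per-pulse current train with seeded measurement noise."""
    params = params or ElectricalParams()
    scale = protocol.field_setting / REFERENCE_FIELD_VCM
    i1 = params.i_first_A * scale
    i_inf = params.i_sat_A * scale
    k = np.arange(1, protocol.pulse_count + 1, dtype=float)
    amps = i_inf - (i_inf - i1) * np.exp(-(k - 1.0) / params.kappa_pulses)
    rng = np.random.default_rng(seed)
    amps = amps * _lognormal_factors(rng, params.meas_noise_cv, amps.size)
    return CurrentTrace(per_pulse_amplitude=amps, protocol=protocol)


def conductivity_change_ratio(before: float, after: float) -> float:
    """Post/pre conductivity ratio; ``before`` must be positive."""
    if before <= 0:
        raise ValueError("pre-pulse conductivity must be positive")
    return after / before


def generate_conductivity(
    field_setting: float,
    params: ElectricalParams | None = None,
    seed: int = 0,
) -> ConductivityRecord:
    """Seeded pre/post conductivity pair with a field-linear true ratio.

    The underlying change ratio is ``1 + slope * E``; both readings carry
    independent lognormal noise and the reported ratio is recomputed from
    the noisy pair, as a real instrument would.
    """
    if field_setting < 0:
        raise ValueError("field_setting must be non-negative")
    params = params or ElectricalParams()
    ratio_truth = 1.0 + params.ratio_slope_per_vcm * field_setting
    rng = np.random.default_rng(seed)
    eps = _lognormal_factors(rng, params.meas_noise_cv, 2)
    before = params.sigma_baseline_S_per_m * eps[0]
    after = params.sigma_baseline_S_per_m * ratio_truth * eps[1]
    return ConductivityRecord(sigma_before=float(before), sigma_after=float(after))
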