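"""Closed-form Hyper-CEST exchange model.

Free hyperpolarized xenon (pool A) exchanges with xenon reversibly caged in
one or more host molecules (bound pools B_j, e.g. cryptophanes).  Continuous
rf saturation near a bound-pool resonance depolarizes pool A through two
channels:

* a *direct* channel — the off-resonance rf tilts the free-pool magnetization
  by ``theta = arctan(omega1/|Delta|)`` and mixes longitudinal and transverse
  relaxation, ``lambda_direct = R1A cos^2(theta) + R2A sin^2(theta)``;
* a *CEST* channel — saturation of the dilute bound pool is carried to pool A
  by chemical exchange.  On resonance with pool B the depolarization rate is
  ``lambda_on = f k_out omega1^2 / (omega1^2 + k_out^2)`` and, as a function
  of the rf offset, it follows a Lorentzian of full width at half maximum
  ``Gamma = 2 sqrt(omega1^2 + k_out^2)``.

Because the magnetization is hyperpolarized there is no recovery toward
thermal equilibrium: the observable signal after a saturation of duration
``t_sat`` is a pure exponential, ``Z = M0A exp(-lambda t_sat)``.

All rates and angular frequencies are carried internally in rad/s; chemical
shifts enter and leave the API in ppm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np

__all__ = [
    "AxisKind",
    "Trace1D",
    "FieldConfig",
    "FreePool",
    "BoundPool",
    "SaturationScheme",
    "ExchangeSystem",
    "ppm_to_rad",
    "rad_to_ppm",
    "tilt_angle",
    "lambda_direct",
    "lambda_on",
    "gamma_fwhm",
    "lambda_cest",
    "lambda_total",
    "z_value",
    "z_spectrum",
]


class AxisKind(str, enum.Enum):
    """What the abscissa of a :class:`Trace1D` means."""

    OFFSET_PPM = "offset_ppm"
    POSITION_M = "position_m"
    APPARENT_PPM = "apparent_ppm"


@dataclass(frozen=True)
class Trace1D:
    """A sampled 1-D curve (Z spectrum, tube profile or UFZ spectrum)."""

    axis: np.ndarray
    intensity: np.ndarray
    kind: AxisKind

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "kind", AxisKind(self.kind))
        if axis.ndim != 1 or intensity.ndim != 1:
            raise ValueError("Trace1D arrays must be one-dimensional")
        if axis.size != intensity.size:
            raise ValueError("axis and intensity must have equal length")
        if axis.size == 0:
            raise ValueError("Trace1D must contain at least one point")
        d = np.diff(axis)
        if axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("Trace1D axis must be strictly monotone")

    def __len__(self) -> int:
        return int(self.axis.size)


@dataclass(frozen=True)
class FieldConfig:
    """Static-field configuration owning all ppm <-> Hz <-> rad/s conversions.

    Parameters
    ----------
    larmor_mhz:
        129Xe Larmor frequency in MHz (12.09 on the benchtop magnet,
        138.36 on the 11.7 T spectrometer).
    gamma_bar_mhz_t:
        Magnitude of the reduced gyromagnetic ratio in MHz/T (11.79 for
        129Xe).  The sign is carried separately because most bounds use the
        magnitude while gradient encoding needs the signed value.
    gamma_sign:
        +1 or -1 (129Xe has a negative gyromagnetic ratio).
    """

    larmor_mhz: float
    gamma_bar_mhz_t: float = 11.79
    gamma_sign: int = -1

    def __post_init__(self) -> None:
        if self.larmor_mhz <= 0:
            raise ValueError("larmor_mhz must be positive")
        if self.gamma_bar_mhz_t <= 0:
            raise ValueError("gamma_bar_mhz_t must be positive")
        if self.gamma_sign not in (-1, +1):
            raise ValueError("gamma_sign must be +1 or -1")

    @property
    def gamma_bar_hz_t(self) -> float:
        """Unsigned gyromagnetic ratio in Hz/T."""
        return self.gamma_bar_mhz_t * 1e6

    @property
    def gamma_signed_hz_t(self) -> float:
        """Signed gyromagnetic ratio in Hz/T."""
        return self.gamma_sign * self.gamma_bar_mhz_t * 1e6

    def ppm_to_hz(self, shift_ppm) -> np.ndarray | float:
        return np.multiply(shift_ppm, self.larmor_mhz)

    def hz_to_ppm(self, freq_hz) -> np.ndarray | float:
        return np.divide(freq_hz, self.larmor_mhz)


def ppm_to_rad(field: FieldConfig, shift_ppm) -> np.ndarray | float:
    """Convert a chemical shift (ppm) to angular frequency (rad/s)."""
    return 2.0 * math.pi * field.ppm_to_hz(shift_ppm)


def rad_to_ppm(field: FieldConfig, omega_rad_s) -> np.ndarray | float:
    """Inverse of :func:`ppm_to_rad`."""
    return field.hz_to_ppm(np.divide(omega_rad_s, 2.0 * math.pi))


@dataclass(frozen=True)
class FreePool:
    """Free dissolved xenon (pool A)."""

    delta_ppm: float
    r1: float
    r2: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("relaxation rates must be non-negative")
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")


@dataclass(frozen=True)
class BoundPool:
    """Xenon bound in a host cage (pool B).

    ``f`` is the caged fraction M0B/M0A; ``k_out`` the cage exit rate.
    ``r1``/``r2`` default to the free-pool R1 and to ``k_out/100``
    respectively when a scenario does not state them (the analytic model
    assumes ``k_out >> R2B``).
    """

    f: float
    k_out: float
    delta_ppm: float
    r1: float | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise ValueError("caged fraction f must lie in (0, 1)")
        if self.k_out <= 0:
            raise ValueError("k_out must be positive")
        for r in (self.r1, self.r2):
            if r is not None and r < 0:
                raise ValueError("relaxation rates must be non-negative")

    @property
    def k_in(self) -> float:
        """Entry rate, ``k_in = f * k_out`` (steady-state balance)."""
        return self.f * self.k_out

    def resolved_r1(self, free: FreePool) -> float:
        return self.r1 if self.r1 is not None else free.r1

    def resolved_r2(self, free: FreePool) -> float:
        return self.r2 if self.r2 is not None else self.k_out / 100.0


@dataclass(frozen=True)
class SaturationScheme:
    """CW rf saturation: amplitude ``omega1`` (rad/s), offset (ppm), duration (s)."""

    omega1: float
    offset_ppm: float
    t_sat: float

    def __post_init__(self) -> None:
        if self.omega1 < 0:
            raise ValueError("omega1 must be non-negative")
        if self.t_sat < 0:
            raise ValueError("t_sat must be non-negative")

    def b1_ut(self, field: FieldConfig) -> float:
        """Equivalent B1 amplitude in microtesla (display value)."""
        return self.omega1 / (2.0 * math.pi * field.gamma_bar_hz_t) * 1e6


@dataclass(frozen=True)
class ExchangeSystem:
    """A free pool plus zero or more dilute bound pools at a given field."""

    field: FieldConfig
    free: FreePool
    bound: tuple[BoundPool, ...] = dataclass_field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bound", tuple(self.bound))
        if sum(p.f for p in self.bound) >= 1.0:
            raise ValueError("total caged fraction must be < 1")
        for p in self.bound:
            if p.delta_ppm == self.free.delta_ppm:
                raise ValueError(
                    "bound-pool shift must differ from the free-pool shift"
                )

    @property
    def effective_r1(self) -> float:
        """Population-weighted R1 = (1-f)R1A + sum f_j R1B_j (Eqs. of the slow-
        exchange relaxation average; the lumped correction is ~f and usually
        negligible)."""
        f_tot = sum(p.f for p in self.bound)
        return (1.0 - f_tot) * self.free.r1 + sum(
            p.f * p.resolved_r1(self.free) for p in self.bound
        )

    @property
    def effective_r2(self) -> float:
        f_tot = sum(p.f for p in self.bound)
        return (1.0 - f_tot) * self.free.r2 + sum(
            p.f * p.resolved_r2(self.free) for p in self.bound
        )


# ---------------------------------------------------------------------------
# Depolarization rates
# ---------------------------------------------------------------------------

def tilt_angle(omega1: float, delta_i) -> np.ndarray | float:
    """Tilt angle of the effective field, ``arctan(omega1/|delta_i|)``.

    ``delta_i`` is the rf offset from the free-pool resonance in rad/s.
    Returns pi/2 on resonance (delta_i = 0) for omega1 > 0; raises if both
    arguments are zero (the angle is undefined).
    """
    delta = np.abs(np.asarray(delta_i, dtype=float))
    if omega1 == 0.0 and np.any(delta == 0.0):
        raise ValueError("tilt angle undefined for omega1 = 0 on resonance")
    out = np.arctan2(omega1, delta)
    return float(out) if out.ndim == 0 else out


def lambda_direct(
    free: FreePool, omega1: float, delta_i, *, weighted_rates: tuple[float, float] | None = None
) -> np.ndarray | float:
    """Direct (exchange-free) depolarization rate of the free pool.

    ``R1A cos^2(theta) + R2A sin^2(theta)`` with theta from
    :func:`tilt_angle`.  ``weighted_rates`` optionally substitutes the
    f-weighted effective (R1, R2) pair in place of the bare free-pool rates.
    """
    r1, r2 = (free.r1, free.r2) if weighted_rates is None else weighted_rates
    theta = tilt_angle(omega1, delta_i)
    s2 = np.sin(theta) ** 2
    out = r1 * (1.0 - s2) + r2 * s2
    return float(out) if np.ndim(out) == 0 else out


def lambda_on(pool: BoundPool, omega1: float) -> float:
    """Peak (on-resonance) CEST depolarization rate.

    ``f k_out omega1^2 / (omega1^2 + k_out^2)``; increases monotonically with
    omega1 toward the asymptote ``f k_out``.
    """
    if omega1 < 0:
        raise ValueError("omega1 must be non-negative")
    w2 = omega1 * omega1
    return pool.f * pool.k_out * w2 / (w2 + pool.k_out * pool.k_out)


def gamma_fwhm(pool: BoundPool, omega1: float) -> float:
    """Full width at half maximum of the CEST dip, ``2 sqrt(omega1^2+k_out^2)``
    in rad/s."""
    if omega1 < 0:
        raise ValueError("omega1 must be non-negative")
    return 2.0 * math.hypot(omega1, pool.k_out)


def lambda_cest(
    pool: BoundPool, field: FieldConfig, omega1: float, offset_ppm
) -> np.ndarray | float:
    """Lorentzian CEST depolarization rate at rf offset ``offset_ppm``.

    Peaks at ``lambda_on`` when the rf sits on the bound-pool resonance and
    has half maximum at |offset - delta_B| = Gamma/2.
    """
    amp = lambda_on(pool, omega1)
    hwhm = gamma_fwhm(pool, omega1) / 2.0
    detune = ppm_to_rad(field, np.subtract(offset_ppm, pool.delta_ppm))
    out = amp * hwhm**2 / (hwhm**2 + np.square(detune))
    return float(out) if np.ndim(out) == 0 else out


def lambda_total(
    system: ExchangeSystem,
    sat: SaturationScheme,
    *,
    offset_ppm=None,
    high_field: bool = False,
    weighted_relaxation: bool = False,
) -> np.ndarray | float:
    """Total depolarization rate: direct term plus one CEST Lorentzian per pool.

    With ``high_field=True`` the simplified form valid for
    ``|omega_i - omega_A| >> omega1`` is used: the direct term collapses to
    R1A and only the CEST Lorentzians remain.  ``weighted_relaxation``
    switches the direct term to the f-weighted effective rates.
    """
    offset = sat.offset_ppm if offset_ppm is None else offset_ppm
    cest = 0.0
    for pool in system.bound:
        cest = cest + lambda_cest(pool, system.field, sat.omega1, offset)
    if high_field:
        r1 = system.effective_r1 if weighted_relaxation else system.free.r1
        out = r1 + cest
    else:
        delta_i = ppm_to_rad(
            system.field, np.subtract(offset, system.free.delta_ppm)
        )
        rates = (
            (system.effective_r1, system.effective_r2)
            if weighted_relaxation
            else None
        )
        out = lambda_direct(
            system.free, sat.omega1, delta_i, weighted_rates=rates
        ) + cest
    return float(out) if np.ndim(out) == 0 else out


def z_value(
    system: ExchangeSystem, sat: SaturationScheme, *, offset_ppm=None, **kwargs
) -> np.ndarray | float:
    """Free-pool longitudinal magnetization after saturation,
    ``M0A exp(-lambda t_sat)``."""
    lam = lambda_total(system, sat, offset_ppm=offset_ppm, **kwargs)
    out = system.free.m0 * np.exp(-np.multiply(lam, sat.t_sat))
    return float(out) if np.ndim(out) == 0 else out


def z_spectrum(
    system: ExchangeSystem,
    omega1: float,
    t_sat: float,
    offsets_ppm: Sequence[float],
    **kwargs,
) -> Trace1D:
    """Z spectrum: ``z_value`` evaluated over a grid of rf offsets (ppm)."""
    offsets = np.asarray(offsets_ppm, dtype=float)
    if offsets.size == 0:
        raise ValueError("offsets_ppm must be non-empty")
    sat = SaturationScheme(omega1=omega1, offset_ppm=0.0, t_sat=t_sat)
    z = z_value(system, sat, offset_ppm=offsets, **kwargs)
    return Trace1D(axis=offsets, intensity=np.atleast_1d(z), kind=AxisKind.OFFSET_PPM)
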