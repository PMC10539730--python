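"""Ultra-fast Z (UFZ) spectroscopy simulator.

In the UFZ experiment the CW saturation is applied in the presence of a
magnetic-field gradient ``G_sat``, so the rf offset seen by the spins varies
linearly with position across the tube: only a thin slice is saturated for
each resonance.  A read pulse followed by acquisition under a second gradient
``G_acq`` maps position back to frequency, so a single shot yields the whole
Z spectrum as dips carved into the 1-D density profile of the tube (the
chord-length projection of the circular cross-section for a transverse
gradient).  Subtracting the saturated (*on*) profile from an unsaturated
(*off*) profile isolates the dips.

A true chemical-shift splitting ``d`` between two bound pools appears on the
UFZ axis magnified by the gradient ratio: ``d_apparent = d |G_acq/G_sat|``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exchange import (
    AxisKind,
    ExchangeSystem,
    FieldConfig,
    SaturationScheme,
    Trace1D,
    lambda_total,
)

__all__ = [
    "TubeGeometry",
    "GradientScheme",
    "UfzExperiment",
    "density_profile",
    "local_offset",
    "dip_position",
    "simulate_profiles",
    "acquire_ufz",
    "ufz_dip_centers",
    "apparent_splitting",
    "apparent_to_true_ppm",
    "envelope_exit_check",
    "make_fixtures",
]


@dataclass(frozen=True)
class TubeGeometry:
    """Sample tube cross-section.

    ``inner_diameter_m`` is the tube bore; ``extent_m`` is the sample
    dimension along the gradient axis (defaults to the diameter, the case of
    a transverse gradient on a cylindrical tube).
    """

    inner_diameter_m: float
    extent_m: float | None = None

    def __post_init__(self) -> None:
        if self.inner_diameter_m <= 0:
            raise ValueError("inner_diameter_m must be positive")
        if self.extent_m is not None and self.extent_m <= 0:
            raise ValueError("extent_m must be positive")

    @property
    def r_m(self) -> float:
        return self.extent_m if self.extent_m is not None else self.inner_diameter_m


@dataclass(frozen=True)
class GradientScheme:
    """Saturation and acquisition gradients in T/m (signed)."""

    g_sat: float
    g_acq: float

    def __post_init__(self) -> None:
        if self.g_acq == 0:
            raise ValueError("g_acq must be non-zero")

    @property
    def ratio(self) -> float:
        """|G_acq / G_sat| — the apparent-splitting magnification."""
        if self.g_sat == 0:
            raise ZeroDivisionError("g_sat is zero: apparent splitting undefined")
        return abs(self.g_acq / self.g_sat)


@dataclass(frozen=True)
class UfzExperiment:
    """A complete single-shot UFZ experiment description."""

    system: ExchangeSystem
    sat: SaturationScheme
    geometry: TubeGeometry
    gradients: GradientScheme
    n_positions: int = 512
    noise_sigma: float = 0.0
    off_scale: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positions < 32:
            raise ValueError("n_positions must be at least 32")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.off_scale <= 0:
            raise ValueError("off_scale must be positive")


def density_profile(geometry: TubeGeometry, n_positions: int) -> Trace1D:
    """Chord-length projection of the tube cross-section.

    ``rho(x) = sqrt((r/2)^2 - x^2)`` on ``|x| <= r/2`` (zero outside),
    normalized to unit maximum; symmetric with its maximum at the tube axis.
    """
    half = geometry.r_m / 2.0
    x = np.linspace(-half, half, n_positions)
    rho = np.sqrt(np.clip(half * half - x * x, 0.0, None)) / half
    return Trace1D(axis=x, intensity=rho, kind=AxisKind.POSITION_M)


def local_offset(
    x_m, rf_offset_ppm: float, gradients: GradientScheme, field: FieldConfig
):
    """Effective rf offset (ppm) seen at position ``x`` during saturation.

    Under the saturation gradient the rf appears shifted by
    ``-gamma G_sat x`` relative to every pool, so a pool B is exactly on
    resonance at ``x_B = (nu_rf - nu_B) / (gamma G_sat)``.
    """
    shift_hz = field.gamma_signed_hz_t * gradients.g_sat * np.asarray(x_m, dtype=float)
    out = rf_offset_ppm - field.hz_to_ppm(shift_hz)
    return float(out) if np.ndim(out) == 0 else out


def dip_position(
    rf_offset_ppm: float,
    delta_b_ppm: float,
    gradients: GradientScheme,
    field: FieldConfig,
) -> float:
    """Position (m) at which a bound pool at ``delta_b_ppm`` is on resonance."""
    if gradients.g_sat == 0:
        raise ZeroDivisionError("g_sat is zero: no spatial encoding")
    dnu_hz = field.ppm_to_hz(rf_offset_ppm - delta_b_ppm)
    return float(dnu_hz / (field.gamma_signed_hz_t * gradients.g_sat))


def simulate_profiles(experiment: UfzExperiment) -> tuple[Trace1D, Trace1D]:
    """Simulate the saturated (*on*) and unsaturated (*off*) tube profiles.

    ``off(x) = off_scale * rho(x)``, ``on(x) = rho(x) exp(-lambda(x) t_sat)``
    where ``lambda(x)`` is the full analytic depolarization rate evaluated at
    the position-dependent effective rf offset; independent relative Gaussian
    noise (seeded) is applied per point to each profile.
    """
    rho = density_profile(experiment.geometry, experiment.n_positions)
    x = rho.axis
    eff_offset = local_offset(
        x, experiment.sat.offset_ppm, experiment.gradients, experiment.system.field
    )
    lam = lambda_total(experiment.system, experiment.sat, offset_ppm=eff_offset)
    attenuation = np.exp(-np.asarray(lam) * experiment.sat.t_sat)
    rng = np.random.default_rng(experiment.rng_seed)
    on_vals = rho.intensity * attenuation
    off_vals = experiment.off_scale * rho.intensity
    if experiment.noise_sigma > 0:
        on_vals = on_vals * (
            1.0 + experiment.noise_sigma * rng.standard_normal(x.size)
        )
        off_vals = off_vals * (
            1.0 + experiment.noise_sigma * rng.standard_normal(x.size)
        )
    on = Trace1D(axis=x, intensity=on_vals, kind=AxisKind.POSITION_M)
    off = Trace1D(axis=x, intensity=off_vals, kind=AxisKind.POSITION_M)
    return on, off


def acquire_ufz(
    on: Trace1D,
    off: Trace1D,
    gradients: GradientScheme,
    field: FieldConfig,
    *,
    off_scale: float = 1.0,
) -> Trace1D:
    """Form the UFZ spectrum: off-minus-on on the detected-frequency axis.

    The acquisition gradient maps position to frequency,
    ``nu(x) = gamma G_acq x``, spreading the profile over ``gamma G_acq r``
    hertz; the result is expressed in apparent ppm at the configured Larmor
    frequency.  The axis runs backwards when the two gradients have opposite
    effective signs.  ``off_scale`` divides the off profile before
    subtraction (the scale applied when it was generated).
    """
    if on.kind != off.kind or on.axis.shape != off.axis.shape or not np.allclose(
        on.axis, off.axis
    ):
        raise ValueError("on and off traces must share the same axis")
    diff = off.intensity / off_scale - on.intensity
    nu_hz = field.gamma_signed_hz_t * gradients.g_acq * on.axis
    apparent_ppm = np.asarray(field.hz_to_ppm(nu_hz), dtype=float)
    return Trace1D(axis=apparent_ppm, intensity=diff, kind=AxisKind.APPARENT_PPM)


def ufz_dip_centers(
    on: Trace1D,
    off: Trace1D,
    gradients: GradientScheme,
    field: FieldConfig,
    n_dips: int,
    *,
    off_scale: float = 1.0,
    support_fraction: float = 0.1,
) -> np.ndarray:
    """Apparent-ppm positions of the ``n_dips`` deepest saturation dips.

    Works on the pointwise ratio ``Z(x) = on/(off/off_scale)`` rather than on
    the off-minus-on difference: the ratio removes the density envelope, so a
    dip minimum falls exactly at the position where its pool is on resonance
    even when the dip sits on the sloping edge of the envelope.  Minima are
    refined to sub-bin precision by a parabolic fit through the three points
    around each sampled minimum.
    """
    from scipy.signal import find_peaks

    if on.axis.shape != off.axis.shape or not np.allclose(on.axis, off.axis):
        raise ValueError("on and off traces must share the same axis")
    envelope = off.intensity / off_scale
    support = envelope > support_fraction * np.max(envelope)
    z = np.where(support, on.intensity / np.where(support, envelope, 1.0), np.nan)
    depth = np.nanmax(z) - z
    depth_filled = np.where(np.isnan(depth), 0.0, depth)
    peaks, props = find_peaks(depth_filled, prominence=0.0)
    if peaks.size < n_dips:
        raise ValueError(f"found only {peaks.size} dips, expected {n_dips}")
    chosen = peaks[np.argsort(props["prominences"])[::-1][:n_dips]]
    nu_hz = field.gamma_signed_hz_t * gradients.g_acq * on.axis
    apparent = np.asarray(field.hz_to_ppm(nu_hz), dtype=float)
    centers = []
    for i in sorted(chosen):
        if 0 < i < len(depth_filled) - 1:
            y0, y1, y2 = depth_filled[i - 1 : i + 2]
            denom = y0 - 2 * y1 + y2
            frac = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            centers.append(
                apparent[i] + frac * (apparent[min(i + 1, len(apparent) - 1)] - apparent[i])
            )
        else:
            centers.append(apparent[i])
    return np.array(centers)


def apparent_splitting(
    delta_b1_ppm: float, delta_b2_ppm: float, gradients: GradientScheme
) -> float:
    """Apparent UFZ splitting of two resonances:
    ``|delta_B1 - delta_B2| |G_acq/G_sat|``."""
    return abs(delta_b1_ppm - delta_b2_ppm) * gradients.ratio


def apparent_to_true_ppm(
    trace: Trace1D, gradients: GradientScheme, rf_offset_ppm: float
) -> Trace1D:
    """Map a UFZ apparent-ppm axis back to true chemical shift.

    Inverse of the gradient-ratio magnification: a dip at apparent position
    ``a`` sits at true shift ``rf_offset - a (G_sat/G_acq)`` (signed, so the
    mapping also undoes an axis reversal)."""
    if trace.kind != AxisKind.APPARENT_PPM:
        raise ValueError("expected an apparent-ppm trace")
    true_axis = rf_offset_ppm - trace.axis * (gradients.g_sat / gradients.g_acq)
    order = np.argsort(true_axis)
    return Trace1D(
        axis=true_axis[order],
        intensity=trace.intensity[order],
        kind=AxisKind.OFFSET_PPM,
    )


def envelope_exit_check(
    rf_offset_ppm: float,
    delta_b_ppm: float,
    g_sat: float,
    geometry: TubeGeometry,
    field: FieldConfig,
) -> bool:
    """True iff the dip of a pool at ``delta_b_ppm`` falls outside the
    magnetization envelope, i.e. ``2|nu_rf - nu_B|/|G_sat| > gamma r``."""
    if g_sat == 0:
        raise ZeroDivisionError("g_sat is zero: no spatial encoding")
    dnu_hz = abs(field.ppm_to_hz(rf_offset_ppm - delta_b_ppm))
    return 2.0 * dnu_hz / abs(g_sat) > field.gamma_bar_hz_t * geometry.r_m


def make_fixtures(
    out_dir,
    experiment: UfzExperiment,
    n_replicates: int = 20,
    seed: int = 0,
):
    """Write noisy UFZ on/off profile pairs plus a ground-truth sidecar.

    Each replicate re-seeds the experiment noise from ``seed + i`` and writes
    ``rep<i>_on.csv`` / ``rep<i>_off.csv``; ``truth.json`` records the pool
    parameters, saturation and gradients needed to score fits against the
    generating truth.  Returns the list of replicate seeds used.
    """
    import json
    from pathlib import Path

    from .fileio import write_trace

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = []
    for i in range(n_replicates):
        rep = replace(experiment, rng_seed=seed + i)
        on, off = simulate_profiles(rep)
        write_trace(on, out / f"rep{i:03d}_on.csv", fmt="csv")
        write_trace(off, out / f"rep{i:03d}_off.csv", fmt="csv")
        seeds.append(seed + i)
    truth = {
        "pools": [
            {"f": p.f, "k_out_s": p.k_out, "delta_ppm": p.delta_ppm}
            for p in experiment.system.bound
        ],
        "omega1_rad_s": experiment.sat.omega1,
        "rf_offset_ppm": experiment.sat.offset_ppm,
        "tsat_s": experiment.sat.t_sat,
        "gsat_t_m": experiment.gradients.g_sat,
        "gacq_t_m": experiment.gradients.g_acq,
        "off_scale": experiment.off_scale,
        "noise_sigma": experiment.noise_sigma,
        "larmor_mhz": experiment.system.field.larmor_mhz,
        "seeds": seeds,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return seeds
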