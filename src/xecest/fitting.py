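"""Inversion of Z/UFZ data back to exchange parameters.

Pipeline: the on/off profile pair is converted to a depolarization-rate
trace (``lambda_hat = -ln(on/off)/t_sat``), a Lorentzian-plus-baseline model
is least-squares fitted to each dip in the rate domain (rates are additive,
so baselines separate linearly there), and the fitted amplitude/width pair
is inverted algebraically for the exchange parameters:

    k_out = sqrt(Gamma^2/4 - omega1^2)
    f     = lambda_on (omega1^2 + k_out^2) / (k_out omega1^2)

The width-based inversion is only identifiable when Gamma/2 > omega1; below
that boundary the fit cannot distinguish rf broadening from exchange
broadening and an error is raised rather than silently clipping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.optimize import curve_fit

from .exchange import AxisKind, FieldConfig, Trace1D, ppm_to_rad

__all__ = [
    "DipFit",
    "ExchangeEstimate",
    "FitFailureError",
    "UnidentifiableRegimeError",
    "saturation_ratio",
    "fit_dip",
    "invert_exchange",
]


class FitFailureError(RuntimeError):
    """Least-squares dip fit failed to converge."""


class UnidentifiableRegimeError(ValueError):
    """Fitted width is not larger than the rf broadening: k_out unidentifiable."""


@dataclass(frozen=True)
class DipFit:
    """One fitted CEST dip (in the depolarization-rate domain)."""

    center_ppm: float
    lambda_on_hat: float  # peak rate above baseline, 1/s
    gamma_hat: float  # FWHM in rad/s (axis units if no field was supplied)
    baseline_rate_hat: float  # 1/s
    goodness: float  # residual 2-norm
    degenerate: bool = False
    stderr: dict | None = dataclass_field(default=None, compare=False)


@dataclass(frozen=True)
class ExchangeEstimate:
    """Recovered exchange parameters with curvature-based uncertainties."""

    f_hat: float
    k_out_hat: float
    f_err: float = float("nan")
    k_out_err: float = float("nan")


def saturation_ratio(
    on: Trace1D,
    off: Trace1D,
    off_scale: float,
    t_sat: float,
    *,
    support_fraction: float = 0.1,
) -> Trace1D:
    """Depolarization-rate trace from an on/off profile pair.

    ``lambda_hat = -ln(on / (off / off_scale)) / t_sat``, where ``off_scale``
    is the factor the off profile was scaled by when acquired/generated.
    Points where the (unscaled) off profile falls below ``support_fraction``
    of its maximum are excluded — the ratio blows up at the envelope edges.
    Non-positive ratios inside the support are clipped to the smallest
    positive ratio present and reported via a warning.
    """
    if t_sat <= 0:
        raise ValueError("t_sat must be positive")
    if on.axis.shape != off.axis.shape or not np.allclose(on.axis, off.axis):
        raise ValueError("on and off traces must share the same axis")
    envelope = off.intensity / off_scale
    support = envelope > support_fraction * np.max(envelope)
    if not np.any(support):
        raise ValueError("no points above the support threshold")
    ratio = on.intensity[support] / envelope[support]
    bad = ratio <= 0
    if np.any(bad):
        floor = np.min(ratio[~bad]) if np.any(~bad) else np.finfo(float).tiny
        ratio = np.where(bad, floor, ratio)
        warnings.warn(
            f"{int(bad.sum())} non-positive on/off ratios clipped inside support",
            RuntimeWarning,
            stacklevel=2,
        )
    lam = -np.log(ratio) / t_sat
    return Trace1D(axis=on.axis[support], intensity=lam, kind=on.kind)


def _lorentzians(u, baseline, *params):
    out = np.full_like(np.asarray(u, dtype=float), baseline)
    for j in range(len(params) // 3):
        amp, center, hwhm = params[3 * j : 3 * j + 3]
        out = out + amp * hwhm**2 / (hwhm**2 + (u - center) ** 2)
    return out


def _initial_guesses(axis, lam, n_components):
    baseline = float(np.median(lam))
    resid = lam - baseline
    span = axis.max() - axis.min()
    guesses = []
    work = resid.copy()
    for _ in range(n_components):
        i = int(np.argmax(work))
        amp = max(float(work[i]), 1e-12)
        center = float(axis[i])
        # half-height crossing width around the peak
        half = amp / 2.0
        above = work >= half
        hwhm = span / 20.0
        if above[i]:
            left = i
            while left > 0 and above[left - 1]:
                left -= 1
            right = i
            while right < len(axis) - 1 and above[right + 1]:
                right += 1
            if right > left:
                hwhm = max((axis[right] - axis[left]) / 2.0, span / len(axis))
        guesses.extend([amp, center, hwhm])
        # suppress this peak before seeking the next one
        work = work - amp * hwhm**2 / (hwhm**2 + (axis - center) ** 2)
    return baseline, guesses


def fit_dip(
    lambda_trace: Trace1D,
    field: FieldConfig | None = None,
    *,
    n_components: int = 1,
):
    """Least-squares baseline-plus-Lorentzian fit of a rate trace.

    The trace axis must be a chemical-shift axis in ppm (convert UFZ traces
    with :func:`xecest.ufz.apparent_to_true_ppm` first).  With ``field``
    supplied the fitted FWHM is returned in rad/s, ready for
    :func:`invert_exchange`; otherwise it stays in axis units.

    Returns a single :class:`DipFit` for ``n_components=1``, else a list
    ordered by center position.
    """
    if len(lambda_trace) < 8:
        raise ValueError("need at least 8 points across the dip to fit")
    axis = lambda_trace.axis.astype(float)
    lam = lambda_trace.intensity.astype(float)
    baseline0, guesses = _initial_guesses(axis, lam, n_components)
    p0 = [baseline0] + guesses
    span = axis.max() - axis.min()
    lower = [-np.inf] + [0.0, axis.min() - span, 0.0] * n_components
    upper = [np.inf] + [np.inf, axis.max() + span, np.inf] * n_components
    try:
        popt, pcov = curve_fit(
            _lorentzians, axis, lam, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            f"dip fit did not converge (n_components={n_components}, "
            f"n_points={len(axis)}, init={p0}): {exc}"
        ) from exc
    residual = lam - _lorentzians(axis, *popt)
    goodness = float(np.linalg.norm(residual))
    perr = np.sqrt(np.abs(np.diag(pcov)))
    noise = float(np.std(residual))
    fits = []
    for j in range(n_components):
        amp, center, hwhm = popt[1 + 3 * j : 4 + 3 * j]
        amp_err, center_err, hwhm_err = perr[1 + 3 * j : 4 + 3 * j]
        fwhm = 2.0 * hwhm
        fwhm_err = 2.0 * hwhm_err
        if field is not None:
            fwhm = float(ppm_to_rad(field, fwhm))
            fwhm_err = float(ppm_to_rad(field, fwhm_err))
        degenerate = amp <= max(3.0 * noise, 1e-10 * max(1.0, abs(popt[0])))
        fits.append(
            DipFit(
                center_ppm=float(center),
                lambda_on_hat=float(amp),
                gamma_hat=fwhm,
                baseline_rate_hat=float(popt[0]),
                goodness=goodness,
                degenerate=bool(degenerate),
                stderr={
                    "lambda_on": float(amp_err),
                    "center": float(center_err),
                    "gamma": fwhm_err,
                    "baseline": float(perr[0]),
                },
            )
        )
    fits.sort(key=lambda d: d.center_ppm)
    return fits[0] if n_components == 1 else fits


def invert_exchange(fit: DipFit, omega1: float) -> ExchangeEstimate:
    """Solve the amplitude/width pair for (f, k_out).

    Exact algebraic inverse of the forward rate model; raises
    :class:`UnidentifiableRegimeError` when ``gamma_hat/2 <= omega1``.
    """
    if omega1 <= 0:
        raise ValueError("omega1 must be positive")
    hwhm = fit.gamma_hat / 2.0
    if hwhm <= omega1:
        raise UnidentifiableRegimeError(
            f"fitted half-width {hwhm:.4g} rad/s does not exceed omega1 "
            f"{omega1:.4g} rad/s: k_out is not identifiable"
        )
    k_out = float(np.sqrt(hwhm * hwhm - omega1 * omega1))
    w2 = omega1 * omega1
    f_hat = float(fit.lambda_on_hat * (w2 + k_out * k_out) / (k_out * w2))
    f_err = k_err = float("nan")
    if fit.stderr is not None:
        g_err = fit.stderr.get("gamma", float("nan")) / 2.0
        a_err = fit.stderr.get("lambda_on", float("nan"))
        # delta method through k = sqrt(h^2 - w1^2), f = a (w1^2+k^2)/(k w1^2)
        dk_dh = hwhm / k_out
        k_err = abs(dk_dh) * g_err
        df_da = (w2 + k_out * k_out) / (k_out * w2)
        df_dk = fit.lambda_on_hat * (k_out * k_out - w2) / (k_out * k_out * w2)
        f_err = float(np.hypot(df_da * a_err, df_dk * k_err))
    return ExchangeEstimate(
        f_hat=f_hat, k_out_hat=k_out, f_err=f_err, k_out_err=float(k_err)
    )
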