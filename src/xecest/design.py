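"""Experiment-design calculators for UFZ Hyper-CEST.

Planning logic for a gradient-encoded saturation experiment: the largest
usable saturation gradient (the encoded spectral width across the tube must
stay below the free/bound frequency difference, otherwise the saturation
slice of the free pool enters the sample), classification of the saturation
strength relative to the exchange rate, and grid scans over omega1 and
t_sat that trade dip depth against baseline level and dip separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exchange import (
    BoundPool,
    ExchangeSystem,
    FieldConfig,
    SaturationScheme,
    lambda_direct,
    lambda_on,
    ppm_to_rad,
    z_value,
)
from .ufz import TubeGeometry

__all__ = [
    "RegimeResult",
    "DesignReport",
    "TsatTradeoff",
    "gsat_bound",
    "regime_classify",
    "omega1_scan",
    "tsat_tradeoff",
]


@dataclass(frozen=True)
class RegimeResult:
    """Saturation-strength regime of one bound pool at a given omega1."""

    label: str  # "saturated" | "intermediate" | "parabolic"
    lambda_on: float  # 1/s, from the exact rate expression


@dataclass(frozen=True)
class DesignReport:
    """Output of an omega1 scan (optionally enriched by the CLI with the
    gradient bound and per-pool regimes)."""

    scan: list[dict]
    recommended_window_rad_s: tuple[float, float] | None
    g_sat_max_t_m: float | None = None
    regimes: tuple[RegimeResult, ...] | None = None


@dataclass(frozen=True)
class TsatTradeoff:
    """Dip depth versus saturation duration at a weak-rf working point."""

    tsat_s: np.ndarray
    depth: np.ndarray
    reference_depth: float
    crossover_tsat_s: float | None  # smallest t_sat with depth >= 90% of ref


def gsat_bound(
    field: FieldConfig,
    geometry: TubeGeometry,
    delta_a_ppm: float | None = None,
    delta_b_ppm: float | None = None,
    *,
    delta_nu_hz: float | None = None,
) -> float:
    """Largest saturation gradient keeping the encoded width inside the
    free/bound splitting: ``G_sat < |nu_A - nu_B| / (gamma_bar d)`` (T/m).

    The splitting may be given as a shift pair (ppm) or directly in Hz via
    ``delta_nu_hz`` (overrides the pair when both are supplied).
    """
    if delta_nu_hz is None:
        if delta_a_ppm is None or delta_b_ppm is None:
            raise ValueError("supply delta_a_ppm/delta_b_ppm or delta_nu_hz")
        delta_nu_hz = abs(field.ppm_to_hz(delta_a_ppm - delta_b_ppm))
    return abs(delta_nu_hz) / (field.gamma_bar_hz_t * geometry.inner_diameter_m)


def regime_classify(pool: BoundPool, omega1: float) -> RegimeResult:
    """Classify the saturation strength against the cage exit rate.

    ``omega1 >= 10 k_out`` -> "saturated" (rate at its ceiling f k_out,
    within 1 %); ``omega1 <= k_out/10`` -> "parabolic" (rate grows as
    (f/k_out) omega1^2); otherwise "intermediate" (exactly half the ceiling
    at omega1 = k_out).  The exact rate is attached in all cases.
    """
    if omega1 < 0:
        raise ValueError("omega1 must be non-negative")
    ratio = omega1 / pool.k_out
    if ratio >= 10.0:
        label = "saturated"
    elif ratio <= 0.1:
        label = "parabolic"
    else:
        label = "intermediate"
    return RegimeResult(label=label, lambda_on=lambda_on(pool, omega1))


def _dip_windows(system: ExchangeSystem, offsets: np.ndarray) -> list[np.ndarray]:
    """Boolean offset masks around each bound-pool shift, split halfway
    between neighbouring pools."""
    shifts = np.array([p.delta_ppm for p in system.bound])
    masks = []
    for j, s in enumerate(shifts):
        dist_self = np.abs(offsets - s)
        dist_other = np.full_like(offsets, np.inf)
        for s2 in np.delete(shifts, j):
            dist_other = np.minimum(dist_other, np.abs(offsets - s2))
        masks.append(dist_self <= dist_other)
    return masks


def _dip_metrics(system: ExchangeSystem, omega1: float, t_sat: float, offsets):
    """Per-pool (depth, baseline) of the analytic Z spectrum plus a
    separation-resolved flag, all normalized by M0A."""
    offsets = np.asarray(offsets, dtype=float)
    sat = SaturationScheme(omega1=omega1, offset_ppm=0.0, t_sat=t_sat)
    m0 = system.free.m0
    z = np.asarray(z_value(system, sat, offset_ppm=offsets)) / m0
    depths, baselines, minima_pos = [], [], []
    for pool, mask in zip(system.bound, _dip_windows(system, offsets)):
        delta_i = ppm_to_rad(system.field, pool.delta_ppm - system.free.delta_ppm)
        lam_dir = lambda_direct(system.free, omega1, delta_i)
        baseline = float(np.exp(-lam_dir * t_sat))
        zmin_idx = np.flatnonzero(mask)[np.argmin(z[mask])]
        depths.append(baseline - float(z[zmin_idx]))
        baselines.append(baseline)
        minima_pos.append(float(offsets[zmin_idx]))
    # resolved: every adjacent dip pair separated by a saddle at least 10% of
    # the deeper dip above both minima
    resolved = True
    order = np.argsort(minima_pos)
    for a, b in zip(order[:-1], order[1:]):
        lo, hi = minima_pos[a], minima_pos[b]
        between = (offsets > lo) & (offsets < hi)
        if not np.any(between):
            resolved = False
            continue
        z_saddle = float(np.max(z[between]))
        z_min_a = baselines[a] - depths[a]
        z_min_b = baselines[b] - depths[b]
        margin = 0.1 * max(depths[a], depths[b])
        if (z_saddle - z_min_a) < margin or (z_saddle - z_min_b) < margin:
            resolved = False
    return depths, baselines, resolved


def omega1_scan(
    system: ExchangeSystem,
    t_sat: float,
    omega1_grid,
    *,
    offsets_ppm=None,
) -> DesignReport:
    """Scan saturation strength, scoring dip contrast against separation.

    For each omega1 the analytic Z spectrum over the bound-pool region gives
    per-dip depth (direct-only baseline minus dip minimum), the baseline
    level, and whether the dips are mutually resolved.  The score is
    ``min-dip-depth x resolved``; the recommended window is all omega1 whose
    score reaches 90 % of the best score.
    """
    grid = np.asarray(omega1_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("omega1_grid must be non-empty")
    if not system.bound:
        raise ValueError("omega1_scan needs at least one bound pool")
    if offsets_ppm is None:
        shifts = [p.delta_ppm for p in system.bound]
        offsets_ppm = np.arange(min(shifts) - 15.0, max(shifts) + 15.0, 0.1)
    rows = []
    for w1 in grid:
        depths, baselines, resolved = _dip_metrics(system, float(w1), t_sat, offsets_ppm)
        score = min(depths) * (1.0 if resolved else 0.0)
        rows.append(
            {
                "omega1_rad_s": float(w1),
                "dip_depths": depths,
                "baselines": baselines,
                "resolved": resolved,
                "score": score,
            }
        )
    best = max(row["score"] for row in rows)
    window = None
    if best > 0:
        good = [row["omega1_rad_s"] for row in rows if row["score"] >= 0.9 * best]
        window = (min(good), max(good))
    return DesignReport(scan=rows, recommended_window_rad_s=window)


def tsat_tradeoff(
    system: ExchangeSystem,
    omega1_low: float,
    tsat_grid,
    reference: tuple[float, float],
    *,
    reference_system: ExchangeSystem | None = None,
    pool_index: int = 0,
) -> TsatTradeoff:
    """Dip depth versus t_sat at a weak rf, against a strong-rf reference.

    ``reference = (omega1_high, tsat_high)`` is evaluated on
    ``reference_system`` (default: the same system) — the two working points
    may legitimately differ in field and relaxation.  Reports the smallest
    t_sat whose depth reaches at least 90 % of the reference depth.
    """
    grid = np.asarray(tsat_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("tsat_grid must be non-empty")
    ref_sys = reference_system if reference_system is not None else system
    w1_ref, t_ref = reference
    pool_ref = ref_sys.bound[pool_index]
    win_ref = np.arange(pool_ref.delta_ppm - 10.0, pool_ref.delta_ppm + 10.0, 0.05)
    ref_depths, _, _ = _dip_metrics(ref_sys, w1_ref, t_ref, win_ref)
    ref_depth = ref_depths[pool_index]
    pool = system.bound[pool_index]
    win = np.arange(pool.delta_ppm - 10.0, pool.delta_ppm + 10.0, 0.05)
    depths = np.empty_like(grid)
    for i, t in enumerate(grid):
        d, _, _ = _dip_metrics(system, omega1_low, float(t), win)
        depths[i] = d[pool_index]
    crossing = np.flatnonzero(depths >= 0.9 * ref_depth)
    crossover = float(grid[crossing[0]]) if crossing.size else None
    return TsatTradeoff(
        tsat_s=grid,
        depth=depths,
        reference_depth=float(ref_depth),
        crossover_tsat_s=crossover,
    )
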