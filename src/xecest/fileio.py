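"""Configuration files, trace I/O (CSV and minimal JCAMP-DX), presets.

Experiment configs are flat YAML key/value documents with units encoded in
the key names (``omega1_rad_s``, ``gsat_t_m``, ...), which keeps the
rad-per-second / hertz / ppm bookkeeping explicit at the file boundary.
Unknown keys are rejected.

JCAMP-DX support is intentionally minimal: single block, AFFN numeric form,
``XYPOINTS=(XY..XY)`` on write and additionally ``XYDATA=(X++(Y..Y))`` on
read.  That is enough for format interchange of 1-D traces; no compressed
(SQZ/DIF) forms.
"""

from __future__ import annotations

import csv
import math
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .exchange import (
    AxisKind,
    BoundPool,
    ExchangeSystem,
    FieldConfig,
    FreePool,
    SaturationScheme,
    Trace1D,
)
from .ufz import GradientScheme, TubeGeometry, UfzExperiment

__all__ = [
    "ConfigError",
    "TraceParseError",
    "read_config",
    "load_preset",
    "list_presets",
    "build_field",
    "build_system",
    "build_saturation",
    "build_offsets",
    "build_ufz_experiment",
    "write_trace",
    "read_trace",
]

MAX_POOLS = 9

_SCALAR_KEYS = {
    # field
    "larmor_mhz": float,
    "gamma_bar_mhz_t": float,
    "gamma_sign": int,
    # free pool
    "delta_a_ppm": float,
    "r1a_s": float,
    "r2a_s": float,
    "m0a": float,
    # saturation
    "omega1_rad_s": float,
    "offset_ppm": float,
    "tsat_s": float,
    # ufz
    "tube_diameter_m": float,
    "tube_extent_m": float,
    "gsat_t_m": float,
    "gacq_t_m": float,
    "n_positions": int,
    "noise_sigma": float,
    "off_scale": float,
    "seed": int,
}
_POOL_SUFFIXES = {
    "f": float,
    "kout_s": float,
    "delta_ppm": float,
    "r1b_s": float,
    "r2b_s": float,
}


class ConfigError(ValueError):
    """Invalid experiment configuration (message names the offending key)."""


class TraceParseError(ValueError):
    """Malformed trace file (message includes the line number)."""


def _known_keys() -> set[str]:
    keys = set(_SCALAR_KEYS) | {"offsets_ppm"}
    for n in range(1, MAX_POOLS + 1):
        keys |= {f"pool{n}_{suffix}" for suffix in _POOL_SUFFIXES}
    return keys


def read_config(path) -> dict:
    """Load and validate a flat YAML experiment config.

    Checks that the document is a flat mapping, that every key is known, and
    that values have the right type and obvious physical sign; which keys are
    *required* depends on what is built from the config (the ``build_*``
    helpers raise a :class:`ConfigError` naming any missing key).
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is None:
        raise ConfigError(f"{path}: empty config file")
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a flat key/value mapping")
    known = _known_keys()
    cfg: dict = {}
    for key, value in doc.items():
        if key not in known:
            raise ConfigError(f"unknown config key: {key!r}")
        if key == "offsets_ppm":
            cfg[key] = _parse_offsets(value)
            continue
        caster = _SCALAR_KEYS.get(key)
        if caster is None:  # pool key
            caster = _POOL_SUFFIXES[key.split("_", 1)[1]]
        if isinstance(value, (list, dict)):
            raise ConfigError(f"config key {key!r} must be a scalar")
        try:
            cfg[key] = caster(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config key {key!r}: {exc}") from exc
    _validate_physics(cfg)
    return cfg


def _parse_offsets(value) -> np.ndarray:
    """Offsets as an explicit list or a 'start:stop:count' string."""
    if isinstance(value, str):
        parts = value.split(":")
        if len(parts) != 3:
            raise ConfigError(
                "offsets_ppm string must be 'start:stop:count'"
            )
        start, stop, count = float(parts[0]), float(parts[1]), int(parts[2])
        if count < 1:
            raise ConfigError("offsets_ppm count must be >= 1")
        return np.linspace(start, stop, count)
    if isinstance(value, (list, tuple)):
        arr = np.asarray([float(v) for v in value])
        if arr.size == 0:
            raise ConfigError("offsets_ppm list must be non-empty")
        return arr
    raise ConfigError("offsets_ppm must be a list or 'start:stop:count'")


def _validate_physics(cfg: dict) -> None:
    positive = ["larmor_mhz", "gamma_bar_mhz_t", "m0a", "tube_diameter_m",
                "tube_extent_m", "off_scale"]
    non_negative = ["r1a_s", "r2a_s", "omega1_rad_s", "tsat_s", "noise_sigma"]
    for key in positive:
        if key in cfg and cfg[key] <= 0:
            raise ConfigError(f"config key {key!r} must be positive")
    for key in non_negative:
        if key in cfg and cfg[key] < 0:
            raise ConfigError(f"config key {key!r} must be non-negative")
    if "gamma_sign" in cfg and cfg["gamma_sign"] not in (-1, 1):
        raise ConfigError("config key 'gamma_sign' must be +1 or -1")
    if "n_positions" in cfg and cfg["n_positions"] < 32:
        raise ConfigError("config key 'n_positions' must be at least 32")
    for n in range(1, MAX_POOLS + 1):
        fkey, kkey = f"pool{n}_f", f"pool{n}_kout_s"
        if fkey in cfg and not 0.0 < cfg[fkey] < 1.0:
            raise ConfigError(f"config key {fkey!r} must lie in (0, 1)")
        if kkey in cfg and cfg[kkey] <= 0:
            raise ConfigError(f"config key {kkey!r} must be positive")


def _require(cfg: dict, *keys: str) -> None:
    missing = [k for k in keys if k not in cfg]
    if missing:
        raise ConfigError(f"missing required config key(s): {', '.join(missing)}")


def build_field(cfg: dict) -> FieldConfig:
    _require(cfg, "larmor_mhz")
    return FieldConfig(
        larmor_mhz=cfg["larmor_mhz"],
        gamma_bar_mhz_t=cfg.get("gamma_bar_mhz_t", 11.79),
        gamma_sign=cfg.get("gamma_sign", -1),
    )


def build_system(cfg: dict) -> ExchangeSystem:
    _require(cfg, "delta_a_ppm", "r1a_s", "r2a_s")
    free = FreePool(
        delta_ppm=cfg["delta_a_ppm"],
        r1=cfg["r1a_s"],
        r2=cfg["r2a_s"],
        m0=cfg.get("m0a", 1.0),
    )
    pools = []
    for n in range(1, MAX_POOLS + 1):
        present = [s for s in _POOL_SUFFIXES if f"pool{n}_{s}" in cfg]
        if not present:
            continue
        _require(cfg, f"pool{n}_f", f"pool{n}_kout_s", f"pool{n}_delta_ppm")
        pools.append(
            BoundPool(
                f=cfg[f"pool{n}_f"],
                k_out=cfg[f"pool{n}_kout_s"],
                delta_ppm=cfg[f"pool{n}_delta_ppm"],
                r1=cfg.get(f"pool{n}_r1b_s"),
                r2=cfg.get(f"pool{n}_r2b_s"),
            )
        )
    return ExchangeSystem(field=build_field(cfg), free=free, bound=tuple(pools))


def build_saturation(cfg: dict) -> SaturationScheme:
    _require(cfg, "omega1_rad_s", "offset_ppm", "tsat_s")
    return SaturationScheme(
        omega1=cfg["omega1_rad_s"],
        offset_ppm=cfg["offset_ppm"],
        t_sat=cfg["tsat_s"],
    )


def build_offsets(cfg: dict) -> np.ndarray:
    _require(cfg, "offsets_ppm")
    return cfg["offsets_ppm"]


def build_ufz_experiment(cfg: dict, *, seed: int | None = None) -> UfzExperiment:
    _require(cfg, "tube_diameter_m", "gsat_t_m", "gacq_t_m")
    return UfzExperiment(
        system=build_system(cfg),
        sat=build_saturation(cfg),
        geometry=TubeGeometry(
            inner_diameter_m=cfg["tube_diameter_m"],
            extent_m=cfg.get("tube_extent_m"),
        ),
        gradients=GradientScheme(g_sat=cfg["gsat_t_m"], g_acq=cfg["gacq_t_m"]),
        n_positions=cfg.get("n_positions", 512),
        noise_sigma=cfg.get("noise_sigma", 0.0),
        off_scale=cfg.get("off_scale", 1.0),
        rng_seed=seed if seed is not None else cfg.get("seed", 0),
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def list_presets() -> list[str]:
    """Names of the bundled example configurations."""
    root = resources.files("xecest") / "presets"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> dict:
    """Load a bundled preset by name (see :func:`list_presets`)."""
    root = resources.files("xecest") / "presets"
    path = root / f"{name}.yaml"
    if not path.is_file():
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}"
        )
    return read_config(path)


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------

_JCAMP_XUNITS = {
    AxisKind.OFFSET_PPM: "PPM",
    AxisKind.APPARENT_PPM: "APPARENT PPM",
    AxisKind.POSITION_M: "METERS",
}
_JCAMP_XUNITS_BACK = {v: k for k, v in _JCAMP_XUNITS.items()}


def write_trace(trace: Trace1D, path, fmt: str = "csv") -> None:
    """Write a trace as CSV (exact round-trip) or minimal JCAMP-DX."""
    path = Path(path)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([trace.kind.value, "intensity"])
            for x, y in zip(trace.axis, trace.intensity):
                writer.writerow([format(x, ".17g"), format(y, ".17g")])
    elif fmt == "jcamp":
        lines = [
            "##TITLE=xecest trace",
            "##JCAMP-DX=4.24",
            "##DATA TYPE=SPECTRUM",
            "##ORIGIN=xecest",
            "##OWNER=",
            f"##XUNITS={_JCAMP_XUNITS[trace.kind]}",
            "##YUNITS=ARBITRARY UNITS",
            f"##NPOINTS={len(trace)}",
            f"##FIRSTX={trace.axis[0]:.10g}",
            f"##LASTX={trace.axis[-1]:.10g}",
            f"##FIRSTY={trace.intensity[0]:.10g}",
            "##XYPOINTS=(XY..XY)",
        ]
        lines += [
            f"{x:.10g}, {y:.10g}" for x, y in zip(trace.axis, trace.intensity)
        ]
        lines.append("##END=")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported trace format: {fmt!r}")


def read_trace(path) -> Trace1D:
    """Read a trace written by :func:`write_trace` (CSV or JCAMP-DX).

    The axis kind is inferred from the CSV header or the JCAMP ``##XUNITS``
    record.  Malformed numeric content raises :class:`TraceParseError` with
    the offending line number.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("##"):
        return _read_jcamp(text, path)
    return _read_csv(text, path)


def _read_csv(text: str, path) -> Trace1D:
    lines = text.splitlines()
    if not lines:
        raise TraceParseError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    try:
        kind = AxisKind(header[0])
    except ValueError as exc:
        raise TraceParseError(
            f"{path}:1: unrecognized axis header {header[0]!r}"
        ) from exc
    xs, ys = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except (IndexError, ValueError) as exc:
            raise TraceParseError(f"{path}:{lineno}: malformed row {line!r}") from exc
    if not xs:
        raise TraceParseError(f"{path}: no data rows")
    return Trace1D(axis=np.array(xs), intensity=np.array(ys), kind=kind)


def _read_jcamp(text: str, path) -> Trace1D:
    kind = AxisKind.OFFSET_PPM
    xs: list[float] = []
    ys: list[float] = []
    mode = None  # None | "xypoints" | "xydata"
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            value = value.strip()
            if label == "XUNITS":
                kind = _JCAMP_XUNITS_BACK.get(value.upper(), AxisKind.OFFSET_PPM)
            elif label == "XYPOINTS":
                mode = "xypoints"
            elif label == "XYDATA":
                mode = "xydata"
            elif label == "END":
                mode = None
            continue
        if mode is None:
            continue
        try:
            fields = [float(tok) for tok in line.replace(",", " ").split()]
        except ValueError as exc:
            raise TraceParseError(f"{path}:{lineno}: malformed AFFN line {line!r}") from exc
        if mode == "xypoints":
            if len(fields) % 2 != 0:
                raise TraceParseError(
                    f"{path}:{lineno}: odd number of values in XY pairs"
                )
            xs.extend(fields[0::2])
            ys.extend(fields[1::2])
        else:  # xydata (X++(Y..Y)): first value is X of the first Y
            if len(fields) < 2:
                raise TraceParseError(f"{path}:{lineno}: XYDATA line too short")
            xs.append(fields[0])
            ys.extend(fields[1:])
    if len(xs) != len(ys):
        # X++(Y..Y): xs holds one line-start abscissa per data line; rebuild
        # the uniform grid from consecutive line starts
        if len(xs) < 2:
            raise TraceParseError(f"{path}: cannot infer XYDATA abscissa grid")
        n = len(ys)
        per_line = math.ceil(n / len(xs))
        dx = (xs[1] - xs[0]) / per_line
        xs = [xs[0] + i * dx for i in range(n)]
    if not ys:
        raise TraceParseError(f"{path}: no data found")
    return Trace1D(axis=np.array(xs), intensity=np.array(ys), kind=kind)
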