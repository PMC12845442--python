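"""Structured-text (YAML) run configuration.

A run configuration has up to five sections::

    physiology:   # OralPhysiology fields, user units; values may be bare
                  # numbers or "value unit" strings checked per key
    formulation:  # family, coefficients, dose [µg]
    dosing:       # list of {route, amount, start, duration}
    simulation:   # t_end, dt_out, n_x, rtol, atol, far_boundary
    pkpd:         # mic, interval, site, effect-model parameters

Unknown keys are rejected with the offending key named.  Physiology values
are resolved to the canonical unit system on parsing; ``write_config``
writes a round-trippable file back in user units.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import (
    DoseEvent,
    OralPhysiology,
    USER_UNITS,
    from_canonical,
    to_canonical,
)
from .pbpk import SimulationGrid
from .release import ReleaseModel

__all__ = ["RunConfig", "ConfigError", "parse_config", "write_config"]


class ConfigError(ValueError):
    """A malformed configuration; the message names the offending key."""


_TOP_KEYS = {"physiology", "formulation", "dosing", "simulation", "pkpd"}
_SIM_KEYS = {"t_end", "dt_out", "n_x", "rtol", "atol", "far_boundary"}
_FORM_KEYS = {"family", "coefficients", "dose"}
_DOSE_KEYS = {"route", "amount", "start", "duration"}
_PKPD_KEYS = {"mic", "interval", "site", "Emax", "EC50", "h", "k_in", "k_out",
              "k_e0", "Imax", "growth_rate", "mode"}


def _norm_unit(u: str) -> str:
    u = u.strip().replace("µ", "u").replace("²", "^2").replace("·", "*")
    u = re.sub(r"\s+", "", u)
    # mL·cm⁻²·min⁻¹ style -> mL/cm^2/min
    u = u.replace("*cm^-2", "/cm^2").replace("*min^-1", "/min").replace("*s^-1", "/s")
    u = u.replace("min^-1", "1/min").replace("s^-1", "1/s")
    return u


def _physiology_value(key: str, raw) -> float:
    expected = _norm_unit(USER_UNITS[key])
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        return float(raw)
    if isinstance(raw, str):
        m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*(.*)", raw)
        if not m:
            raise ConfigError(f"physiology.{key}: cannot parse value {raw!r}")
        value, unit = m.groups()
        if unit and _norm_unit(unit) != expected:
            raise ConfigError(
                f"physiology.{key}: unit mismatch, expected {USER_UNITS[key]!r} "
                f"got {unit.strip()!r}"
            )
        try:
            return float(value)
        except ValueError as exc:
            raise ConfigError(f"physiology.{key}: {exc}") from exc
    raise ConfigError(f"physiology.{key}: expected number or 'value unit' string")


@dataclass(frozen=True)
class RunConfig:
    """A fully validated, unit-resolved run configuration."""

    physiology: OralPhysiology | None  # canonical units
    release: ReleaseModel | None
    doses: tuple[DoseEvent, ...]
    grid: SimulationGrid | None
    far_boundary: str | None
    mic: float | None
    interval: tuple[float, float] | None
    site: str
    pkpd_params: dict[str, float] = field(default_factory=dict)


def _check_keys(section: str, mapping: dict, allowed: set[str]) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key {section}.{sorted(unknown)[0]!r} "
            f"(allowed: {sorted(allowed)})"
        )


def parse_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not parseable YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key {sorted(unknown)[0]!r}")

    physiology = None
    if "physiology" in raw:
        sect = raw["physiology"]
        _check_keys("physiology", sect, set(USER_UNITS))
        try:
            physiology = to_canonical(
                OralPhysiology(**{k: _physiology_value(k, v) for k, v in sect.items()})
            )
        except ConfigError:
            raise
        except TypeError as exc:  # missing required field
            raise ConfigError(f"physiology: {exc}") from exc
        except ValueError as exc:
            raise ConfigError(f"physiology: {exc}") from exc

    release = None
    if "formulation" in raw:
        sect = raw["formulation"]
        _check_keys("formulation", sect, _FORM_KEYS)
        for req in ("family", "coefficients"):
            if req not in sect:
                raise ConfigError(f"formulation.{req} is required")
        try:
            release = ReleaseModel(
                sect["family"],
                {k: float(v) for k, v in sect["coefficients"].items()},
                float(sect.get("dose", 1.0)),
            )
        except ValueError as exc:
            raise ConfigError(f"formulation: {exc}") from exc

    doses: list[DoseEvent] = []
    if "dosing" in raw:
        if not isinstance(raw["dosing"], list):
            raise ConfigError("dosing must be a list of dose events")
        for i, ev in enumerate(raw["dosing"]):
            _check_keys(f"dosing[{i}]", ev, _DOSE_KEYS)
            try:
                doses.append(
                    DoseEvent(
                        amount=float(ev["amount"]),
                        route=ev.get("route", "saliva_bolus"),
                        start=float(ev.get("start", 0.0)),
                        duration=float(ev.get("duration", 0.0)),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"dosing[{i}]: {exc}") from exc

    grid = None
    far_boundary = None
    if "simulation" in raw:
        sect = raw["simulation"]
        _check_keys("simulation", sect, _SIM_KEYS)
        far_boundary = sect.get("far_boundary")
        if far_boundary is not None and far_boundary not in ("sealed", "coupled"):
            raise ConfigError(
                f"simulation.far_boundary must be 'sealed' or 'coupled', got {far_boundary!r}"
            )
        if "t_end" not in sect:
            raise ConfigError("simulation.t_end is required")
        try:
            grid = SimulationGrid(
                t_end=float(sect["t_end"]),
                dt_out=float(sect.get("dt_out", 1.0)),
                n_x=int(sect.get("n_x", 200)),
                rtol=float(sect.get("rtol", 1e-8)),
                atol=float(sect.get("atol", 1e-10)),
            )
        except ValueError as exc:
            raise ConfigError(f"simulation: {exc}") from exc

    mic = None
    interval = None
    site = "pocket"
    pkpd_params: dict[str, float] = {}
    if "pkpd" in raw:
        sect = raw["pkpd"]
        _check_keys("pkpd", sect, _PKPD_KEYS)
        if "mic" in sect:
            mic = float(sect["mic"])
        if "interval" in sect:
            iv = sect["interval"]
            if not (isinstance(iv, list) and len(iv) == 2):
                raise ConfigError("pkpd.interval must be a two-element list")
            interval = (float(iv[0]), float(iv[1]))
        site = sect.get("site", "pocket")
        for k in sect:
            if k not in ("mic", "interval", "site", "mode"):
                pkpd_params[k] = float(sect[k])
        if "mode" in sect:
            pkpd_params["mode"] = sect["mode"]

    return RunConfig(
        physiology=physiology,
        release=release,
        doses=tuple(doses),
        grid=grid,
        far_boundary=far_boundary,
        mic=mic,
        interval=interval,
        site=site,
        pkpd_params=pkpd_params,
    )


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a configuration back as YAML (user units); round-trips exactly."""
    out: dict = {}
    if cfg.physiology is not None:
        user = from_canonical(cfg.physiology)
        out["physiology"] = {k: float(v) for k, v in user.items()}
    if cfg.release is not None:
        out["formulation"] = {
            "family": cfg.release.family,
            "coefficients": {k: float(v) for k, v in cfg.release.coefficients.items()},
            "dose": float(cfg.release.m_inf),
        }
    if cfg.doses:
        out["dosing"] = [
            {
                "route": d.route.value,
                "amount": float(d.amount),
                "start": float(d.start),
                "duration": float(d.duration),
            }
            for d in cfg.doses
        ]
    if cfg.grid is not None or cfg.far_boundary is not None:
        sim: dict = {}
        if cfg.grid is not None:
            sim.update(
                t_end=float(cfg.grid.t_end),
                dt_out=float(cfg.grid.dt_out),
                n_x=int(cfg.grid.n_x),
                rtol=float(cfg.grid.rtol),
                atol=float(cfg.grid.atol),
            )
        if cfg.far_boundary is not None:
            sim["far_boundary"] = cfg.far_boundary
        out["simulation"] = sim
    pk: dict = {}
    if cfg.mic is not None:
        pk["mic"] = float(cfg.mic)
    if cfg.interval is not None:
        pk["interval"] = [float(cfg.interval[0]), float(cfg.interval[1])]
    if cfg.site != "pocket":
        pk["site"] = cfg.site
    for k, v in cfg.pkpd_params.items():
        pk[k] = v
    if pk:
        out["pkpd"] = pk
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
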