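"""Declarative simulation configs (YAML) -> state grid + device ring.

A config declares the state (box dimensions or a geometry file), global
variables, and the ordered device list; device names and parameter
names mirror the script vocabulary (k_func, diff, euler, ...).  String
macros of the form ``[name]`` are substituted textually before parsing,
and command-line parameter overrides replace global values.
"""

from __future__ import annotations

import yaml

from .engine import DEVICE_REGISTRY, DeviceRing, EngineError, StateGrid
from .geometry import read_bbg

__all__ = ["load_config", "build_simulation"]

_KEY_ALIASES = {"list": "expressions"}


def _substitute_macros(obj, macros: dict[str, str]):
    if isinstance(obj, str):
        for key, val in macros.items():
            obj = obj.replace(f"[{key}]", str(val))
        return obj
    if isinstance(obj, dict):
        return {k: _substitute_macros(v, macros) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_substitute_macros(v, macros) for v in obj]
    return obj


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "devices" not in cfg or "state" not in cfg:
        raise EngineError(f"{path}: config needs 'state' and 'devices'")
    return cfg


def build_simulation(cfg: dict, overrides: dict | None = None):
    """Instantiate ``(state, ring)`` from a parsed config mapping."""
    macros = {str(k): v for k, v in (cfg.get("macros") or {}).items()}
    cfg = _substitute_macros(cfg, macros)

    st = cfg["state"]
    vmax = int(st.get("vmax", 1))
    if "geometry" in st:
        geom = read_bbg(
            st["geometry"], h=float(st.get("hx", 1.0)),
            anisotropy=bool(st.get("anisotropy", True)),
        )
        state = StateGrid.from_geometry(geom, vmax)
    else:
        state = StateGrid.from_box(
            int(st["xmax"]), int(st["ymax"]), int(st.get("zmax", 1)),
            vmax, h=float(st.get("hx", 1.0)),
        )

    for name, val in (cfg.get("globals") or {}).items():
        state.globals[str(name)] = float(val)
    for name, val in (overrides or {}).items():
        state.globals[str(name)] = float(val)

    ring = DeviceRing()
    for i, spec in enumerate(cfg["devices"]):
        spec = dict(spec)
        try:
            kind = spec.pop("device")
        except KeyError:
            raise EngineError(f"devices[{i}]: missing 'device' key") from None
        try:
            cls = DEVICE_REGISTRY[kind]
        except KeyError:
            raise EngineError(
                f"devices[{i}]: unknown device {kind!r}; "
                f"known: {sorted(DEVICE_REGISTRY)}"
            ) from None
        kwargs = {_KEY_ALIASES.get(k, k): v for k, v in spec.items()}
        ring.append(cls(**kwargs))
    return state, ring
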