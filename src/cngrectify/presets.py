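"""Shipped channel-model presets.

Each preset is a small key-value config file (INI syntax, schema version 1)
describing one recording condition: the two-Boltzmann open-probability law,
the relaxation rate law, the open-pore permeation law, the channel count
and open-channel noise ratio, plus a two-state voltage-sensor section for
gating-current work.  Presets are calibrated to the qualitative
conductance/open-probability ratios of the different permeant ions
(Li⁺/Na⁺-like ohmic, Rb⁺/Cs⁺-like inward pore rectification, MA⁺/DMA⁺/EA⁺
gating-dominated outward rectification) rather than fitted to raw traces.
"""

from __future__ import annotations

import configparser
from importlib import resources
from pathlib import Path

from .channel_model import (
    BoltzmannComponent,
    ChannelModel,
    PermeationLaw,
    RateLaw,
    TwoBoltzmann,
)
from .errors import ParameterError
from .synthetic_patch import SensorSpec

__all__ = ["list_presets", "load_preset", "load_sensor", "preset_path"]

_SCHEMA = 1


def _preset_dir():
    return resources.files("cngrectify") / "presets"


def list_presets() -> list[str]:
    """Names of all shipped presets."""
    return sorted(p.name[: -len(".cfg")] for p in _preset_dir().iterdir() if p.name.endswith(".cfg"))


def preset_path(name: str) -> Path:
    p = _preset_dir() / f"{name}.cfg"
    if not p.is_file():
        raise ParameterError(
            f"unknown preset {name!r}; shipped presets: {', '.join(list_presets())}"
        )
    return Path(str(p))


def _read(name_or_path) -> configparser.ConfigParser:
    path = Path(name_or_path)
    if not path.suffix:
        path = preset_path(str(name_or_path))
    if not path.is_file():
        raise ParameterError(f"preset file {path} does not exist")
    cfg = configparser.ConfigParser()
    cfg.read(path)
    schema = cfg.getint("meta", "schema", fallback=None)
    if schema != _SCHEMA:
        raise ParameterError(f"preset {path} declares schema {schema}, expected {_SCHEMA}")
    return cfg


def load_preset(name_or_path, N: int | None = None) -> ChannelModel:
    """Load a ChannelModel from a shipped preset name or a config-file path.

    ``N`` overrides the preset's channel count (handy for switching between
    macroscopic and single-channel simulations of the same condition).
    """
    cfg = _read(name_or_path)
    po = TwoBoltzmann(
        A=cfg.getfloat("po", "A"),
        c1=BoltzmannComponent(cfg.getfloat("po", "vmid1_mV"), cfg.getfloat("po", "k1_mV")),
        c2=BoltzmannComponent(cfg.getfloat("po", "vmid2_mV"), cfg.getfloat("po", "k2_mV")),
    )
    rates = RateLaw(
        a0=cfg.getfloat("rates", "a0_per_ms"),
        za=cfg.getfloat("rates", "za_e0"),
        b0=cfg.getfloat("rates", "b0_per_ms"),
        zb=cfg.getfloat("rates", "zb_e0"),
    )
    perm = PermeationLaw(
        g_plus=cfg.getfloat("permeation", "g_plus_pS"),
        g_minus=cfg.getfloat("permeation", "g_minus_pS"),
        V_s=cfg.getfloat("permeation", "v_s_mV"),
    )
    return ChannelModel(
        po_law=po,
        rate_law=rates,
        perm=perm,
        N=N if N is not None else cfg.getint("channel", "n_channels"),
        sigma_o_over_i=cfg.getfloat("channel", "sigma_o_over_i", fallback=0.0),
        name=cfg.get("meta", "name", fallback=str(name_or_path)),
    )


def load_sensor(name_or_path) -> SensorSpec:
    """Load the voltage-sensor section of a preset as a SensorSpec."""
    cfg = _read(name_or_path)
    if not cfg.has_section("sensor"):
        raise ParameterError(f"preset {name_or_path!r} has no [sensor] section")
    return SensorSpec(
        z=cfg.getfloat("sensor", "z_e0"),
        tau_law=RateLaw(
            a0=cfg.getfloat("sensor", "a0_per_ms"),
            za=cfg.getfloat("sensor", "za_e0"),
            b0=cfg.getfloat("sensor", "b0_per_ms"),
            zb=cfg.getfloat("sensor", "zb_e0"),
        ),
        N=cfg.getint("sensor", "n_channels"),
    )
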