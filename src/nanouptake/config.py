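"""YAML/JSON configuration parsing for the command-line workflows."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .dosimetry import ExposureSetup, ParticleSpecies, SizeDistribution
from .synthdata import SceneSpec, UptakeSpec


class ConfigError(ValueError):
    """Malformed configuration; the message lists the offending keys."""


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _require(block: dict, keys: list[str], where: str) -> None:
    missing = [k for k in keys if k not in block]
    if missing:
        raise ConfigError(f"{where}: missing keys {missing}")


def parse_species(block: dict) -> ParticleSpecies:
    _require(
        block,
        ["name", "d_core_mean_nm", "d_h_mean_nm", "core_density_g_cm3"],
        f"species {block.get('name', '?')!r}",
    )
    return ParticleSpecies(
        name=block["name"],
        core_density=block["core_density_g_cm3"],
        shell_density=block.get("shell_density_g_cm3", 1.0),
        core_radius=SizeDistribution.from_diameter(
            block["d_core_mean_nm"], block.get("d_core_sd_nm", 0.0)
        ),
        hydrodynamic_radius=SizeDistribution.from_diameter(
            block["d_h_mean_nm"], block.get("d_h_sd_nm", 0.0)
        ),
        mass_concentration=block.get("conc_ug_ml", 0.0),
        channel=block.get("channel", ""),
    )


def parse_setup(block: dict | None) -> ExposureSetup:
    block = block or {}
    return ExposureSetup(
        well_area=block.get("area_cm2", 1.7),
        medium_volume=block.get("volume_ml", 0.4),
        temperature=block.get("temp_K", 310.0),
        viscosity=block.get("viscosity_Pa_s", 6.9e-4),
        medium_density=block.get("medium_density_g_cm3", 1.00),
    )


def parse_times(block) -> np.ndarray:
    """`times:` as an explicit list (s) or {start, stop, n, spacing}."""
    if block is None:
        raise ConfigError("times: block is required")
    if isinstance(block, (list, tuple)):
        return np.asarray(block, dtype=float)
    _require(block, ["start", "stop", "n"], "times")
    spacing = block.get("spacing", "linear")
    if spacing == "linear":
        return np.linspace(block["start"], block["stop"], block["n"])
    if spacing == "log":
        start = max(block["start"], 1e-3)
        return np.geomspace(start, block["stop"], block["n"])
    raise ConfigError(f"times: unknown spacing {spacing!r}")


def parse_scene(block: dict | None, seed: int | None = None) -> SceneSpec:
    block = dict(block or {})
    if seed is not None:
        block["seed"] = seed
    known = {f for f in SceneSpec.__dataclass_fields__}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"scene: unknown keys {sorted(unknown)}")
    if "shape" in block:
        block["shape"] = tuple(block["shape"])
    if "cell_radius_um" in block:
        block["cell_radius_um"] = tuple(block["cell_radius_um"])
    return SceneSpec(**block)


def parse_uptake(block: dict | None) -> UptakeSpec:
    block = dict(block or {})
    known = {f for f in UptakeSpec.__dataclass_fields__}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"uptake: unknown keys {sorted(unknown)}")
    return UptakeSpec(**block)
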