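"""YAML configuration: one file, every model symbol under its usual name.

Sections mirror the parameter blocks: ``habitat`` (alpha1, alpha2, phi,
kappa, delta, L_w, alpha0_mean, alpha0_var), ``demography`` (T_L, mu_J,
mu_A, theta, beta, max_adult_age), ``aestivation`` (psi, mu_E, t_A1..t_A4),
``movement`` (d, L_D, d_M, mu_M, t_D1..t_D4), ``engine`` (years,
burnin_years, replicates, seed, ...) and ``landscape`` (either a synthetic
preset + seed, or file paths for the three geographic layers).

NOTE on defaults: mu_A = 0.125 and beta = 100 are fixed by the model's
description; the remaining life-history and carrying-capacity constants
(T_L, mu_J, theta, alpha1, alpha2, phi, kappa, delta, L_w, L_D and the
seasonal window dates) are calibration placeholders chosen at
literature scale and should be re-fitted before any real-data use.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .demography import AestivationParams, DemographyParams
from .engine import SimulationConfig
from .geodata import Landscape, SimulationBounds, load_rainfall, load_settlements, load_water_courses
from .habitat import HabitatParams
from .movement import MovementParams
from .synthetic_landscape import LandscapeSpec, generate_landscape, read_landscape, reference_scenarios

_BLOCKS = {
    "demography": DemographyParams,
    "habitat": HabitatParams,
    "movement": MovementParams,
    "aestivation": AestivationParams,
}


def default_config() -> dict:
    """The full default configuration as a plain dict."""
    cfg = {name: asdict(cls()) for name, cls in _BLOCKS.items()}
    eng = asdict(SimulationConfig())
    for name in _BLOCKS:
        eng.pop(name)
    cfg["engine"] = eng
    cfg["landscape"] = {"preset": "arid-north", "seed": 0}
    return cfg


def simulation_config(cfg: dict) -> SimulationConfig:
    """Build a validated SimulationConfig from a (possibly partial) dict."""
    merged = default_config()
    for section, values in (cfg or {}).items():
        if section == "landscape":
            merged[section] = dict(values)
        elif section in merged:
            merged[section].update(values or {})
        else:
            raise ValueError(f"unknown config section {section!r}")
    blocks = {name: cls(**merged[name]) for name, cls in _BLOCKS.items()}
    return SimulationConfig(**blocks, **merged["engine"])


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def landscape_from_config(cfg: dict) -> Landscape:
    """Resolve the landscape section: preset, written directory, or files."""
    merged = default_config()
    merged["landscape"].update((cfg or {}).get("landscape", {}))
    ls = merged["landscape"]
    if "dir" in ls:
        return read_landscape(ls["dir"])
    if "preset" in ls and "settlements" not in ls:
        presets = reference_scenarios()
        if ls["preset"] not in presets:
            raise ValueError(f"unknown preset {ls['preset']!r}; "
                             f"choose from {sorted(presets)}")
        spec = presets[ls["preset"]]
        overrides = {k: v for k, v in ls.items() if k != "preset"
                     and k in LandscapeSpec.__dataclass_fields__}
        if overrides:
            from dataclasses import replace
            spec = replace(spec, **overrides)
        return generate_landscape(spec)
    bounds = SimulationBounds(**ls.get("bounds", {}))
    settlements = load_settlements(ls["settlements"], bounds,
                                   lon_col=ls.get("lon_col", "lon"),
                                   lat_col=ls.get("lat_col", "lat"))
    water = load_water_courses(ls["water"], bounds,
                               class_attr=ls.get("class_attr", "class"))
    rain = load_rainfall(ls["rainfall"], bounds,
                         cell_size_deg=ls.get("cell_size_deg", 0.5),
                         start_doy=ls.get("start_doy"))
    return Landscape(settlements, water, rain, bounds)
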