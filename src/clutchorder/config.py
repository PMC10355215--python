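"""YAML configuration loading/saving for simulations and sweeps.

A simulation YAML mirrors :class:`~clutchorder.clutch_sim.SimulationConfig`
field names, with an optional ``bonds:`` section overriding the rate laws::

    young_modulus: 6.0
    ligand_density: 100
    p_a_max: 0.5
    bonds:
      integrin_fibronectin: {a1: 2.0, b1: 0.064, a2: 5.0e-5, b2: 0.26}

A sweep YAML holds a ``base:`` mapping plus a ``grid:`` of lists that is
expanded as a Cartesian product, and optionally ``replicates:``.
"""

from __future__ import annotations

import itertools
from dataclasses import fields

import yaml

from .clutch_sim import SimulationConfig
from .kinetics import (
    BOND_PRESETS,
    VinculinRecruitmentRule,
    bonds_from_dict,
    bonds_to_dict,
)

__all__ = ["load_sim_config", "dump_sim_config", "load_sweep"]

_BOND_FIELDS = {
    "integrin_fibronectin": "integrin_bond",
    "vinculin_directional": "directional_bond",
    "vinculin_nondirectional": "nondirectional_bond",
}


def _config_from_mapping(data: dict) -> SimulationConfig:
    data = dict(data)
    kwargs = {}
    bond_section = data.pop("bonds", None)
    if bond_section:
        for label, bond in bonds_from_dict(bond_section).items():
            if label in _BOND_FIELDS:
                kwargs[_BOND_FIELDS[label]] = bond
            elif label in BOND_PRESETS:
                # calibrated presets can be selected by restating their values
                kwargs.setdefault("directional_bond", bond)
            else:
                raise ValueError(f"unknown bond label {label!r} in config")
    recruit = data.pop("recruitment", None)
    if recruit:
        kwargs["recruitment"] = VinculinRecruitmentRule(
            tuple(recruit["force_thresholds"]), tuple(recruit["counts"])
        )
    valid = {f.name for f in fields(SimulationConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs.update(data)
    return SimulationConfig(**kwargs)


def load_sim_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _config_from_mapping(data)


def dump_sim_config(config: SimulationConfig, path) -> None:
    data = config.to_dict()
    bonds = {
        "integrin_fibronectin": data.pop("integrin_bond"),
        "vinculin_directional": data.pop("directional_bond"),
        "vinculin_nondirectional": data.pop("nondirectional_bond"),
    }
    for d in bonds.values():
        d.pop("label", None)
    data["bonds"] = bonds
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_sweep(path) -> tuple[list[SimulationConfig], int]:
    """Expand a sweep YAML into configs and a replicate count."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    base = data.get("base", {})
    grid = data.get("grid", {})
    replicates = int(data.get("replicates", 1))
    keys = sorted(grid)
    configs = []
    for combo in itertools.product(*(grid[k] for k in keys)) if keys else [()]:
        mapping = {**base, **dict(zip(keys, combo))}
        configs.append(_config_from_mapping(mapping))
    return configs, replicates
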