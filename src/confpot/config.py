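"""TOML configuration: one document with [mbtr], [emlm], [selection] and
[synthetic] blocks, each mirroring the corresponding dataclass field-for-field.

Example::

    [mbtr]
    element_set = ["C", "H", "O"]
    [mbtr.k2]
    sigma = 0.025
    scale = 0.5

    [emlm]
    reference_fraction = 0.25

    [selection]
    solvent = "water"
    keep_fraction = 0.5

    [synthetic]
    n_molecules = 50
    seed = 1
    [synthetic.solvents.water]
    slope = 1.5
    intercept = -6.0
    noise = 0.5

Missing blocks and missing keys fall back to the package defaults.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .conformer_select import SelectionPolicy
from .mbtr import KBlockConfig, MBTRConfig
from .synthetic import SolventParams, SyntheticSpec

__all__ = ["load_config", "build_mbtr_config", "build_selection_policy",
           "build_synthetic_spec"]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def build_mbtr_config(cfg: dict) -> MBTRConfig:
    block = cfg.get("mbtr", {})
    kwargs: dict = {}
    if "element_set" in block:
        kwargs["element_set"] = tuple(block["element_set"])
    defaults = MBTRConfig()
    for k in ("k1", "k2", "k3"):
        if k in block:
            merged = {**getattr(defaults, k).__dict__, **block[k]}
            kwargs[k] = KBlockConfig(**merged)
    return MBTRConfig(**kwargs)


def build_selection_policy(cfg: dict) -> SelectionPolicy:
    block = dict(cfg.get("selection", {}))
    if "top_n" in block:
        block.setdefault("keep_fraction", None)
        return SelectionPolicy(**block)
    return SelectionPolicy(**block)


def build_synthetic_spec(cfg: dict, seed: int | None = None) -> SyntheticSpec:
    block = dict(cfg.get("synthetic", {}))
    solvents = block.pop("solvents", None)
    kwargs: dict = {}
    for key in ("n_molecules", "conformers_per_molecule", "carbonyl_probability",
                "hbond_cutoff_A", "hbond_covalent_A", "seed"):
        if key in block:
            kwargs[key] = block[key]
    for key in ("chain_length_range", "torsion_count_range", "hydroxyl_range"):
        if key in block:
            kwargs[key] = tuple(block[key])
    if solvents:
        kwargs["solvent_params"] = {
            name: SolventParams(**params) for name, params in solvents.items()
        }
    if seed is not None:
        kwargs["seed"] = seed
    return SyntheticSpec(**kwargs)


def emlm_options(cfg: dict) -> dict:
    block = dict(cfg.get("emlm", {}))
    out = {
        "reference_fraction": block.get("reference_fraction", 0.25),
        "ridge_lambda": block.get("ridge_lambda", 0.0),
        "include_bias": block.get("include_bias", False),
    }
    return out
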