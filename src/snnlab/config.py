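"""YAML configuration loading for simulations and experiments.

A config file mirrors the parameter tables the simulator uses, e.g.::

    lif:      {EL: -70.0, Vth: -55.0, Vreset: -70.0, Cm: 250.0, tau_m: 10.0}
    noise:    {mean_pA: 8.0, std_pA: 0.0, seed: 0}
    stdp:     {A_plus: 0.005, tau_plus: 20.0}
    encoding: {T_start: 0.0, T_stop: 10.0}

Unknown keys inside each block are ignored so that NEST-style parameter
dumps can be pasted in directly.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .encoding import EncodingParams
from .lif import LIFParams
from .noise import NoiseParams
from .stdp import STDPParams

__all__ = ["load_config", "params_from_config"]


def load_config(path) -> dict:
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    return cfg


def _filtered(cls, block: dict):
    fields = cls.__dataclass_fields__
    return cls(**{k: v for k, v in block.items() if k in fields})


def params_from_config(cfg: dict) -> dict:
    """Instantiate parameter objects from the blocks present in ``cfg``."""
    out = {}
    if "lif" in cfg:
        out["lif"] = LIFParams.from_config(cfg["lif"])
    if "noise" in cfg:
        out["noise"] = NoiseParams.from_config(cfg["noise"])
    if "stdp" in cfg:
        out["stdp"] = _filtered(STDPParams, cfg["stdp"])
    if "encoding" in cfg:
        out["encoding"] = _filtered(EncodingParams, cfg["encoding"])
    return out
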