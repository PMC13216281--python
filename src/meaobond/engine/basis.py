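"""Gaussian basis-set library (JSON data shipped with the package)."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = ["load_basis", "available_bases", "normalize_basis_name"]

_ALIASES = {
    "cc-pvdz": "cc-pvdz",
    "ccpvdz": "cc-pvdz",
    "aug-cc-pvdz": "aug-cc-pvdz",
    "augccpvdz": "aug-cc-pvdz",
    "6-311++g(d,p)": "6-311ppgdp",
    "6-311++g**": "6-311ppgdp",
    "6-311ppgdp": "6-311ppgdp",
    "sto-3g": "sto-3g",
    "sto3g": "sto-3g",
    "minao": "minao",
    "def2-universal-jkfit": "def2-universal-jkfit",
}


def normalize_basis_name(name: str) -> str:
    key = name.strip().lower()
    if key not in _ALIASES:
        raise KeyError(
            f"unknown basis {name!r}; available: {sorted(set(_ALIASES.values()))}"
        )
    return _ALIASES[key]


def available_bases() -> list[str]:
    return sorted(set(_ALIASES.values()))


@lru_cache(maxsize=16)
def load_basis(name: str) -> dict:
    """Return {element: [(l, exps, coefs), ...]} for a shipped basis set."""
    fname = normalize_basis_name(name) + ".json"
    path = resources.files("meaobond.data.basis").joinpath(fname)
    with path.open() as f:
        raw = json.load(f)
    out = {}
    for el, shells in raw.items():
        out[el] = [
            (int(s["l"]), np.asarray(s["exp"], float), np.asarray(s["coef"], float))
            for s in shells
        ]
    return out
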