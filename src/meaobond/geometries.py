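"""Bundled reference geometries (plain-text XYZ).

Experimental equilibrium structures come from the NIST CCCBDB; the
optimized structures were produced by the stated level of theory with an
external engine at build time and are shipped as inputs (provenance in each
file's comment line).
"""

from __future__ import annotations

from importlib import resources

__all__ = ["geometry_path", "available_geometries", "GEOMETRIES"]

GEOMETRIES = {
    "ch4": "ch4_exp.xyz",
    "n2": "n2_exp.xyz",
    "lih": "lih_exp.xyz",
    "li2": "li2_exp.xyz",
    "he2": "he2.xyz",
    "c2h4": "c2h4_exp.xyz",
    "benzene-exp": "benzene_exp.xyz",
    "benzene-b3lyp": "benzene_b3lyp.xyz",
    "c2h5-cation": "c2h5_cation_b3lyp.xyz",
    "c3h5-anion": "c3h5_anion_b3lyp.xyz",
    "li3-cation": "li3_cation_ccsd.xyz",
    "cyclohexane": "cyclohexane_b3lyp.xyz",
}


def available_geometries() -> list[str]:
    return sorted(GEOMETRIES)


def geometry_path(name: str) -> str:
    """Filesystem path of a bundled XYZ geometry."""
    key = name.strip().lower()
    if key not in GEOMETRIES:
        raise KeyError(f"unknown geometry {name!r}; available: {available_geometries()}")
    return str(resources.files("meaobond.data.geometries").joinpath(GEOMETRIES[key]))
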