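"""Bundled radical-pair presets and config-file loading.

Two reference systems are shipped:

``FAD-TrpH``
    The flavin–tryptophan pair of cryptochrome reduced to its three
    largest isotropic hyperfine couplings: N5 and N10 of the flavin
    radical (523 and 189 μT, electron A) and N1 of the tryptophan cation
    radical (322 μT, electron B).  All three nitrogens are spin-1, so the
    Hilbert space is 4·27 = 108 dimensional.

``FAD-Z``
    The same flavin radical paired with a hypothetical partner Z• that
    carries no hyperfine couplings at all; such maximally asymmetric
    pairs show the largest low-field effects.  Dimension 4·9 = 36.

Custom systems load from YAML or JSON files with the same schema:
``{name: ..., nuclei: [{label, spin, coupling_uT, electron}, ...]}``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .spin_core import Nucleus, RadicalPairSystem

__all__ = ["PRESET_NAMES", "load_preset", "load_system", "system_from_dict"]

PRESET_NAMES = ("FAD-TrpH", "FAD-Z")

_PRESET_FILES = {
    "FAD-TrpH": "fad_trph.yaml",
    "FAD-Z": "fad_z.yaml",
}


def system_from_dict(data: dict) -> RadicalPairSystem:
    """Build a :class:`RadicalPairSystem` from a parsed config mapping."""
    nuclei = [
        Nucleus(
            label=str(n["label"]),
            spin=float(n["spin"]),
            coupling_uT=float(n["coupling_uT"]),
            electron=str(n["electron"]),
        )
        for n in data.get("nuclei", [])
    ]
    return RadicalPairSystem(name=str(data["name"]), nuclei=nuclei)


def load_system(path: str | Path) -> RadicalPairSystem:
    """Load a radical-pair system from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return system_from_dict(data)


def load_preset(name: str) -> RadicalPairSystem:
    """Load one of the bundled presets by name (case-insensitive)."""
    canonical = {k.lower(): k for k in _PRESET_FILES}
    key = canonical.get(name.lower().replace("_", "-"))
    if key is None:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    ref = resources.files("radpair").joinpath("presets", _PRESET_FILES[key])
    data = yaml.safe_load(ref.read_text())
    return system_from_dict(data)
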