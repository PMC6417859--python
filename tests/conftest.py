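"""Shared fixtures: bundled presets and seeded random small spin systems."""

from __future__ import annotations

import numpy as np
import pytest

from radpair import Nucleus, RadicalPairSystem, load_preset


def make_random_system(rng: np.random.Generator, max_nuclei: int = 3,
                       name: str = "random") -> RadicalPairSystem:
    """A small random radical pair: 1-3 nuclei of spin 1/2 or 1, couplings
    50-600 μT, each attached to a random electron."""
    n = int(rng.integers(1, max_nuclei + 1))
    nuclei = [
        Nucleus(
            label=f"n{i}",
            spin=float(rng.choice([0.5, 1.0])),
            coupling_uT=float(rng.uniform(50.0, 600.0)),
            electron=str(rng.choice(["A", "B"])),
        )
        for i in range(n)
    ]
    return RadicalPairSystem(name=name, nuclei=nuclei)


@pytest.fixture(scope="session")
def fad_trph() -> RadicalPairSystem:
    return load_preset("FAD-TrpH")


@pytest.fixture(scope="session")
def fad_z() -> RadicalPairSystem:
    return load_preset("FAD-Z")


@pytest.fixture(scope="session")
def bare_pair() -> RadicalPairSystem:
    """A radical pair with no hyperfine couplings (field-independent)."""
    return RadicalPairSystem("bare", [])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
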