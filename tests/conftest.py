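"""Shared fixtures: small synthetic systems built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from ldhtraj.model import Atom, Frame, Topology, Trajectory
from ldhtraj.synthgen import SyntheticConfig, generate_trajectory


@pytest.fixture(scope="session")
def gas_trajectory():
    """Homogeneous ideal gas of 1000 'water_O' atoms, 100 frames, 30 Å box."""
    rng = np.random.default_rng(2024)
    n, box = 1000, 30.0
    atoms = [Atom("O", 0.0, i, "water_O") for i in range(n)]
    top = Topology(atoms=atoms)
    frames = [
        Frame(coordinates=rng.uniform(0, box, (n, 3)), box=np.array([box] * 3), time=float(t))
        for t in range(100)
    ]
    return Trajectory(topology=top, frames=frames, dt=1.0)


@pytest.fixture(scope="session")
def spectra_trajectory():
    """Band-gap-grade synthetic run: 8 anions, 8192 frames, S/AS at 1400/1600."""
    cfg = SyntheticConfig(
        anion_type="ASP",
        n_formula_units=8,
        n_frames=8192,
        dt=0.5,
        nu_S=1400.0,
        nu_AS=1600.0,
        p_parallel=0.5,
        state_dwell_frames=4000.0,  # 2 ps: reorientation slower than dephasing
        seed=11,
    )
    return generate_trajectory(cfg)


def ensemble_config(**overrides) -> SyntheticConfig:
    """2000-anion, 2-frame ensemble for population-recovery checks."""
    base = dict(
        anion_type="ASP",
        n_formula_units=2000,
        n_frames=2,
        spacing_d=12.10,
        p_parallel=0.55,
        seed=17,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture
def tiny_config():
    """Small, fast generator configuration for structural smoke tests."""
    return SyntheticConfig(
        anion_type="SUC", n_formula_units=6, n_frames=50, p_parallel=1.0, seed=5
    )
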