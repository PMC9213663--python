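"""Shared fixtures: one brain-plan study case and water-tank runs reused
across the suite to keep total runtime modest."""

from __future__ import annotations

import numpy as np
import pytest

from oofdose import fixtures as fx
from oofdose.transport import TransportConfig, run_transport


@pytest.fixture(scope="session")
def machine_db():
    return fx.make_machine_database()


@pytest.fixture(scope="session")
def brain_case():
    """Full synthetic study: 3-field brain plan on the child phantom."""
    spec = fx.FixtureSpec(seed=11, histories=60_000, spacing_cm=0.5)
    plan, phantom, readings, maps = fx.make_synthetic_case(spec)
    return {
        "spec": spec,
        "plan": plan,
        "phantom": phantom,
        "readings": readings,
        "maps": maps,
    }


@pytest.fixture(scope="session")
def watertank_run(machine_db):
    """Single 150 MeV spot in a water tank on the native 0.2 cm grid."""
    phantom = fx.make_water_tank(spacing=0.2, shape=(40, 110, 40))
    plan = fx.make_single_spot_plan(150.0)
    cfg = TransportConfig(histories=25_000, seed=5)
    maps = run_transport(plan, machine_db, phantom, cfg)
    return {"phantom": phantom, "plan": plan, "maps": maps, "config": cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
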