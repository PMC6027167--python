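"""Shared fixtures.

The desk-scale vesicle simulations are expensive (minutes each), so they run
once per session and are shared by the qualitative-behaviour and PMF tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from lipocap.box import BoxSpec
from lipocap.dpd_engine import (
    BondParams,
    DPDParams,
    InteractionMatrix,
    SimulationState,
    thermalize_velocities,
)
from lipocap.pipeline import ExperimentConfig, run_experiment
from lipocap.system_builder import BuildConfig


def make_fluid_state(n: int, L: float, seed: int, kT: float = 1.0) -> SimulationState:
    """Uniform pure-solvent (W) fluid with Maxwell-Boltzmann velocities."""
    rng = np.random.default_rng(seed)
    state = SimulationState(
        positions=rng.uniform(0.0, L, (n, 3)),
        velocities=np.zeros((n, 3)),
        types=np.full(n, 8, dtype=np.int64),  # W
        molecule_ids=np.arange(n, dtype=np.int64),
        bonds=np.empty((0, 2), dtype=np.int64),
        box=BoxSpec.cubic(L),
        molecule_species=tuple(["water"] * n),
    )
    thermalize_velocities(state, kT, rng)
    return state


@pytest.fixture(scope="session")
def engine_defaults():
    return InteractionMatrix(), BondParams(), DPDParams()


# -- desk-scale vesicle experiments (shared across acceptance tests) --------

#: Production lengths for the desk-scale runs.  The 5-chain run is the main
#: qualitative experiment; the 10-chain run only feeds the PMF concentration
#: comparison, which uses matched step windows of the two runs.
VESICLE_STEPS = 40_000
VESICLE_STEPS_HIGH_CS = 20_000


@pytest.fixture(scope="session")
def vesicle_run5():
    cfg = ExperimentConfig(
        build=BuildConfig.reduced_demo(),
        pre_steps=1000,
        steps=VESICLE_STEPS,
        snapshot_interval=500,
        burn_in=0.5,
        rng_seed=11,
    )
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def vesicle_run10():
    cfg = ExperimentConfig(
        build=BuildConfig.reduced_demo(n_chitosan=10),
        pre_steps=1000,
        steps=VESICLE_STEPS_HIGH_CS,
        snapshot_interval=500,
        burn_in=0.5,
        rng_seed=11,
    )
    return run_experiment(cfg)


def frames_in_step_window(traj, lo: int, hi: int) -> list[int]:
    """Frame indices whose step counter lies in [lo, hi]."""
    return [i for i, f in enumerate(traj.frames) if lo <= f.step <= hi]
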