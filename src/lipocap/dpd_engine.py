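"""Dissipative-particle-dynamics engine.

The equations of motion are the standard DPD ones: between every pair of
beads closer than the cutoff r_c = 1 act

* a soft conservative repulsion   F_C = a_ij (1 - r) r_hat,
* a dissipative drag              F_D = -gamma (1 - r)^2 (r_hat . v_ij) r_hat,
* a random kick                   F_R = sigma (1 - r) theta_ij r_hat / sqrt(dt),

with theta_ij a symmetric unit-variance variate redrawn each step.  The
fluctuation-dissipation relation sigma^2 = 2 gamma kT makes the pair
(F_D, F_R) a momentum-conserving thermostat at temperature kT.  Bonded beads
additionally feel a harmonic spring -k (r - r0) r_hat.

Integration uses the modified velocity-Verlet scheme with velocity-prediction
factor lambda (default 0.65): positions advance with the current forces,
forces are recomputed at the predicted velocities, then velocities are
corrected with the average force.

Everything is in reduced units: r_c = 1, m = 1, kT = 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from lipocap import _kernels
from lipocap.box import BoxSpec
from lipocap.cg_models import BEAD_TYPES, bead_index

logger = logging.getLogger(__name__)

__all__ = [
    "DPDParams",
    "BondParams",
    "InteractionMatrix",
    "SimulationState",
    "Trajectory",
    "conservative_pair_force",
    "dissipative_random_pair_force",
    "bond_force",
    "neighbor_pairs",
    "compute_forces",
    "integrate_step",
    "instantaneous_temperature",
    "thermalize_velocities",
    "pre_equilibrate",
    "run",
]


@dataclass(frozen=True)
class DPDParams:
    """Thermostat and integrator constants.

    sigma is derived from gamma and kT via the fluctuation-dissipation
    relation sigma^2 = 2 gamma kT; passing an inconsistent explicit sigma is
    rejected.  Defaults are the standard choices for reduced density 3:
    gamma = 4.5 (so sigma = 3 at kT = 1), dt = 0.03, lambda = 0.65.
    """

    gamma: float = 4.5
    kT: float = 1.0
    dt: float = 0.03
    lam: float = 0.65
    r_c: float = 1.0
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.r_c <= 0 or self.gamma < 0 or self.kT < 0:
            raise ValueError("dt and r_c must be positive; gamma and kT non-negative")
        target = math.sqrt(2.0 * self.gamma * self.kT)
        if self.sigma is None:
            object.__setattr__(self, "sigma", target)
        elif abs(self.sigma**2 - 2.0 * self.gamma * self.kT) > 1e-10 * max(1.0, target**2):
            raise ValueError(
                f"fluctuation-dissipation violated: sigma^2 = {self.sigma**2:.6g} "
                f"!= 2 gamma kT = {2 * self.gamma * self.kT:.6g}"
            )


@dataclass(frozen=True)
class BondParams:
    """Harmonic bond: U = k/2 (r - r0)^2, in kT and r_c units."""

    k_spring: float = 100.0
    r0: float = 0.7

    def __post_init__(self) -> None:
        if self.k_spring < 0 or self.r0 < 0:
            raise ValueError("k_spring and r0 must be non-negative")


class InteractionMatrix:
    """Symmetric table of maximum conservative repulsions a_ij (kT/r_c).

    Indexed over the nine bead types L1, L2, L3, C1, C2, C3, G, A, W.  The
    default table follows the compressibility rule a_ii = 25 at reduced
    density 3 for like species, with hydrophobic/hydrophilic contrasts chosen
    to reproduce the qualitative physics of the system: water strongly repels
    the lecithin and capsaicin tails, head groups and glucosamine are
    water-like, and glucosamine is mildly attracted (relative to water) to
    the lecithin head group so that chitosan adsorbs onto the vesicle
    surface.  Acetyl-glucosamine is slightly hydrophobic and slightly
    self-associating, which carries the acetylation-pattern effect.  All
    entries are overridable.
    """

    #: (type, type) -> a_ij overrides of the 25 baseline, symmetric.
    DEFAULT_OVERRIDES: dict[tuple[str, str], float] = {
        ("W", "L2"): 50.0, ("W", "L3"): 80.0,
        ("W", "C1"): 30.0, ("W", "C2"): 45.0, ("W", "C3"): 80.0,
        ("W", "A"): 35.0,
        ("L1", "L2"): 30.0, ("L1", "L3"): 80.0,
        ("L1", "C1"): 28.0, ("L1", "C2"): 40.0, ("L1", "C3"): 75.0,
        ("L1", "G"): 18.0, ("L1", "A"): 24.0,
        ("L2", "L3"): 35.0, ("L2", "C1"): 35.0, ("L2", "C2"): 30.0,
        ("L2", "C3"): 45.0, ("L2", "G"): 40.0, ("L2", "A"): 38.0,
        ("L3", "C1"): 70.0, ("L3", "C2"): 40.0,
        ("L3", "G"): 80.0, ("L3", "A"): 65.0,
        ("C1", "C2"): 30.0, ("C1", "C3"): 60.0,
        ("C1", "G"): 28.0, ("C1", "A"): 26.0,
        ("C2", "C3"): 30.0, ("C2", "G"): 45.0, ("C2", "A"): 40.0,
        ("C3", "G"): 80.0, ("C3", "A"): 60.0,
        ("A", "A"): 22.0,
    }

    def __init__(self, a: np.ndarray | None = None):
        if a is None:
            a = np.full((9, 9), 25.0)
            for (u, v), val in self.DEFAULT_OVERRIDES.items():
                i, j = bead_index(u), bead_index(v)
                a[i, j] = a[j, i] = val
        a = np.asarray(a, dtype=np.float64)
        if a.shape != (9, 9):
            raise ValueError("interaction matrix must be 9x9 over the bead types")
        if not np.allclose(a, a.T):
            raise ValueError("interaction matrix must be symmetric")
        if (a < 0).any():
            raise ValueError("repulsion parameters must be non-negative")
        self.a = a

    def get(self, u: str, v: str) -> float:
        return float(self.a[bead_index(u), bead_index(v)])

    def set(self, u: str, v: str, value: float) -> None:
        if value < 0:
            raise ValueError("repulsion parameter must be non-negative")
        i, j = bead_index(u), bead_index(v)
        self.a[i, j] = self.a[j, i] = float(value)

    def to_dict(self) -> dict:
        """Upper-triangle entries keyed 'T1-T2', for config serialization."""
        out = {}
        for i, u in enumerate(BEAD_TYPES):
            for j, v in enumerate(BEAD_TYPES[i:], start=i):
                out[f"{u}-{v}"] = float(self.a[i, j])
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionMatrix":
        m = cls()
        for key, val in d.items():
            u, v = key.split("-")
            m.set(u, v, float(val))
        return m


@dataclass
class SimulationState:
    """Positions, velocities, types and bonding of all beads in a periodic box.

    Coordinates are wrapped into [0, L) after every step; pair vectors use
    the minimum-image convention.  ``molecule_ids`` assigns every bead to a
    molecule (solvent beads are single-bead molecules); ``molecule_species``
    maps molecule id -> species label.  The bond list is immutable during a
    run.  ``step`` is a global counter that also keys the per-pair noise, so
    a restarted run continues the identical noise stream.
    """

    positions: np.ndarray
    velocities: np.ndarray
    types: np.ndarray
    molecule_ids: np.ndarray
    bonds: np.ndarray
    box: BoxSpec
    molecule_species: tuple[str, ...] = ()
    step: int = 0
    forces: np.ndarray | None = None
    _parent: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.types = np.ascontiguousarray(self.types, dtype=np.int64)
        self.molecule_ids = np.ascontiguousarray(self.molecule_ids, dtype=np.int64)
        self.bonds = np.ascontiguousarray(
            self.bonds if len(self.bonds) else np.empty((0, 2)), dtype=np.int64
        )
        n = len(self.positions)
        if self.velocities.shape != (n, 3) or self.types.shape != (n,):
            raise ValueError("inconsistent state array shapes")
        _kernels.wrap_positions(self.positions, self.box.array)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def parent_array(self) -> np.ndarray:
        """Per-bead parent for periodic unwrapping (-1 for molecule roots).

        Relies on builders emitting bonds with the lower index first and
        every non-root bead bonded to at least one earlier bead.
        """
        if self._parent is None:
            parent = np.full(self.n_beads, -1, dtype=np.int64)
            for i, j in self.bonds:
                i, j = int(min(i, j)), int(max(i, j))
                if parent[j] < 0 or i < parent[j]:
                    parent[j] = i
            self._parent = parent
        return self._parent

    def unwrapped_positions(self) -> np.ndarray:
        out = np.empty_like(self.positions)
        _kernels.unwrap_by_parent(self.positions, self.parent_array(), self.box.array, out)
        return out

    def species_labels(self) -> np.ndarray:
        """Bead-type names, aligned with the canonical type codes."""
        return np.asarray(BEAD_TYPES, dtype=object)[self.types]

    def copy(self) -> "SimulationState":
        return SimulationState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            types=self.types.copy(),
            molecule_ids=self.molecule_ids.copy(),
            bonds=self.bonds.copy(),
            box=self.box,
            molecule_species=self.molecule_species,
            step=self.step,
            forces=None if self.forces is None else self.forces.copy(),
        )


@dataclass
class Frame:
    """One trajectory snapshot (positions are wrapped coordinates)."""

    step: int
    positions: np.ndarray


@dataclass
class Trajectory:
    """Ordered snapshots of a run plus the per-bead metadata shared by all."""

    frames: list[Frame]
    types: np.ndarray
    molecule_ids: np.ndarray
    bonds: np.ndarray
    box: BoxSpec
    molecule_species: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def steps(self) -> list[int]:
        return [f.step for f in self.frames]

    def parent_array(self) -> np.ndarray:
        parent = np.full(len(self.types), -1, dtype=np.int64)
        for i, j in self.bonds:
            i, j = int(min(i, j)), int(max(i, j))
            if parent[j] < 0 or i < parent[j]:
                parent[j] = i
        return parent


# --------------------------------------------------------------------------
# reference single-pair forces (the kernels implement the same expressions)
# --------------------------------------------------------------------------

def conservative_pair_force(a_ij: float, r_vec: np.ndarray, r_c: float = 1.0) -> np.ndarray:
    """Soft repulsion F = a_ij (1 - r/r_c) r_hat on particle i, zero beyond r_c.

    ``r_vec`` is the minimum-image displacement x_i - x_j.  A coincident pair
    (r = 0) has no defined direction and returns zero force by convention.
    """
    r = float(np.linalg.norm(r_vec))
    if r >= r_c or r == 0.0:
        return np.zeros(3)
    return a_ij * (1.0 - r / r_c) * (np.asarray(r_vec, dtype=float) / r)


def dissipative_random_pair_force(
    params: DPDParams, r_vec: np.ndarray, v_rel: np.ndarray, noise: float
) -> np.ndarray:
    """Thermostat pair force F_D + F_R on particle i.

    F_D = -gamma w_D(r) (r_hat . v_rel) r_hat with w_D = (1 - r/r_c)^2, and
    F_R = sigma w_R(r) theta r_hat / sqrt(dt) with w_R = (1 - r/r_c), so that
    w_D = w_R^2 as fluctuation-dissipation requires.  ``noise`` is the
    symmetric unit-variance variate theta_ij shared by the pair.
    """
    r = float(np.linalg.norm(r_vec))
    if r >= params.r_c or r == 0.0:
        return np.zeros(3)
    e = np.asarray(r_vec, dtype=float) / r
    w = 1.0 - r / params.r_c
    fd = -params.gamma * w * w * float(np.dot(e, np.asarray(v_rel, dtype=float)))
    fr = params.sigma * w * noise / math.sqrt(params.dt)
    return (fd + fr) * e


def bond_force(bp: BondParams, r_vec: np.ndarray) -> np.ndarray:
    """Harmonic restoring force -k (r - r0) r_hat on particle i."""
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        return np.zeros(3)
    return -bp.k_spring * (r - bp.r0) * (np.asarray(r_vec, dtype=float) / r)


# --------------------------------------------------------------------------
# engine
# --------------------------------------------------------------------------

def neighbor_pairs(state: SimulationState, r_c: float = 1.0) -> np.ndarray:
    """All minimum-image pairs (i < j) with r < r_c, as an (M, 2) array.

    Uses a cell list when every box side admits at least three r_c-sized
    cells, and an all-pairs sweep otherwise; the result is identical.
    """
    if r_c != 1.0:
        # kernels are specialized to r_c = 1; rescale coordinates instead
        pos = state.positions / r_c
        box = state.box.array / r_c
        pairs = _kernels.neighbor_pairs_kernel(np.ascontiguousarray(pos), box)
    else:
        pairs = _kernels.neighbor_pairs_kernel(state.positions, state.box.array)
    order = np.lexsort((pairs[:, 1], pairs[:, 0])) if len(pairs) else []
    return pairs[order] if len(pairs) else pairs.reshape(0, 2)


# scratch arrays for the pair kernel, keyed by (N, box cells); reused across
# steps so the force loop runs allocation-free
_WORKSPACES: dict[tuple[int, int, int], tuple] = {}


def _workspace_for(state: SimulationState) -> tuple:
    key = (state.n_beads, max(int(state.box.lengths[0]), 1), max(int(state.box.lengths[1]), 1))
    ws = _WORKSPACES.get(key)
    if ws is None:
        if len(_WORKSPACES) > 8:
            _WORKSPACES.clear()
        ws = _kernels.make_workspace(state.n_beads, state.box.array)
        _WORKSPACES[key] = ws
    return ws


def compute_forces(
    state: SimulationState,
    im: InteractionMatrix,
    bp: BondParams,
    params: DPDParams,
    seed: int,
    velocities: np.ndarray | None = None,
    fmax: float = -1.0,
) -> np.ndarray:
    """Total forces at the current positions (and given velocities)."""
    vel = state.velocities if velocities is None else velocities
    forces = np.zeros_like(state.positions)
    _kernels.nonbonded_forces(
        state.positions, vel, state.types, im.a,
        params.gamma, params.sigma, 1.0 / math.sqrt(params.dt),
        state.box.array, np.uint64(seed & 0x7FFFFFFF), np.uint64(state.step),
        fmax, forces, *_workspace_for(state),
    )
    if len(state.bonds):
        _kernels.bond_forces(state.positions, state.bonds, bp.k_spring, bp.r0,
                             state.box.array, forces)
    return forces


def integrate_step(
    state: SimulationState,
    im: InteractionMatrix,
    bp: BondParams,
    params: DPDParams,
    seed: int,
    fmax: float = -1.0,
) -> SimulationState:
    """Advance the state by one time step (modified velocity-Verlet), in place.

    Sequence: half-kick positions with the cached forces, predict velocities
    with factor lambda, recompute forces, correct velocities with the mean of
    old and new forces.  Pair antisymmetry makes the step momentum-conserving
    to floating-point rounding.
    """
    dt = params.dt
    if state.forces is None:
        state.forces = compute_forces(state, im, bp, params, seed, fmax=fmax)
    f_old = state.forces
    _kernels.advance_positions(state.positions, state.velocities, f_old, dt, state.box.array)
    v_pred = state.velocities + params.lam * dt * f_old
    state.step += 1
    f_new = compute_forces(state, im, bp, params, seed, velocities=v_pred, fmax=fmax)
    state.velocities += 0.5 * dt * (f_old + f_new)
    state.forces = f_new
    return state


def instantaneous_temperature(state: SimulationState | np.ndarray) -> float:
    """Kinetic temperature kT = sum m v'^2 / (3 (N - 1)).

    The centre-of-mass drift is removed first, so the estimator is invariant
    under a uniform velocity boost; the 3(N - 1) denominator accounts for the
    three conserved momentum components.
    """
    vel = state if isinstance(state, np.ndarray) else state.velocities
    n = len(vel)
    if n < 2:
        raise ValueError("temperature needs at least two beads")
    v = vel - vel.mean(axis=0)
    return float((v * v).sum() / (3.0 * (n - 1)))


def thermalize_velocities(state: SimulationState, kT: float, rng: np.random.Generator) -> None:
    """Draw Maxwell-Boltzmann velocities at kT and remove the COM drift."""
    v = rng.normal(0.0, math.sqrt(kT), size=state.velocities.shape)
    state.velocities = v - v.mean(axis=0)
    state.forces = None


def pre_equilibrate(
    state: SimulationState,
    im: InteractionMatrix,
    bp: BondParams,
    params: DPDParams,
    n_steps: int = 1000,
    seed: int = 0,
    fmax: float = 30.0,
) -> SimulationState:
    """Relax a freshly built configuration with capped nonbonded forces.

    Soft potentials tolerate build-time overlaps, but the force clamp keeps
    the first few hundred steps gentle.  The thermostat stays active.
    """
    for _ in range(n_steps):
        integrate_step(state, im, bp, params, seed, fmax=fmax)
    state.forces = None  # next run starts from uncapped forces
    return state


def run(
    state: SimulationState,
    im: InteractionMatrix,
    bp: BondParams,
    params: DPDParams,
    n_steps: int,
    seed: int = 0,
    snapshot_interval: int = 1000,
    observers: Sequence[tuple[int, Callable[[SimulationState, int], None]]] = (),
    check_interval: int = 100,
) -> Trajectory:
    """Advance ``n_steps`` steps, collecting snapshots every ``snapshot_interval``.

    Frames are recorded at run-relative steps 0, interval, 2*interval, ...
    including the final step when it lands on the grid.  ``observers`` is a
    sequence of (interval, callback) pairs; callbacks receive the live state
    and the run-relative step.  Non-finite coordinates abort with a
    diagnostic naming the step and the first offending bead.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    frames = [Frame(state.step, state.positions.copy())]
    for k in range(1, n_steps + 1):
        integrate_step(state, im, bp, params, seed)
        if check_interval and k % check_interval == 0:
            bad = ~np.isfinite(state.positions).all(axis=1)
            if bad.any():
                b = int(np.argmax(bad))
                raise FloatingPointError(
                    f"non-finite coordinate at step {state.step}, bead {b} "
                    f"(type {BEAD_TYPES[state.types[b]]})"
                )
        for interval, cb in observers:
            if interval and k % interval == 0:
                cb(state, k)
        if k % snapshot_interval == 0:
            frames.append(Frame(state.step, state.positions.copy()))
    return Trajectory(
        frames=frames,
        types=state.types.copy(),
        molecule_ids=state.molecule_ids.copy(),
        bonds=state.bonds.copy(),
        box=state.box,
        molecule_species=state.molecule_species,
    )
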