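"""Initial-configuration builder.

Builds the study system: a preformed spherical lecithin bilayer (two leaflets
of lipids on concentric spheres, tails toward the bilayer mid-surface),
capsaicin molecules and chitosan chains scattered at random outside the
vesicle, and explicit solvent beads filled in so that the global reduced
number density is exactly 3.

The physical box volume is calibrated from the chain-count <-> molar
concentration correspondence (50 chitosan 50-mers in the box = 6 mM, hence
100 = 12 mM, 150 = 18 mM, 200 = 24 mM in the same box), converted to reduced
units via the configurable length scale (default r_c = 0.646 nm, the
3-waters-per-bead mapping).

Because DPD potentials are soft, no overlap exclusion is attempted at build
time; a short capped-force pre-equilibration in the engine relaxes the
configuration instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from lipocap.box import BoxSpec, DEFAULT_LENGTH_SCALE_NM, N_AVOGADRO
from lipocap.cg_models import (
    ChitosanSequence,
    MoleculeTopology,
    bead_index,
    builtin_sequence,
    capsaicin_topology,
    chitosan_topology,
    lecithin_topology,
)
from lipocap.dpd_engine import SimulationState

__all__ = [
    "BoxSpec",
    "BuildConfig",
    "volume_from_calibration",
    "concentration_of",
    "calibrated_box",
    "build_vesicle",
    "scatter_solutes",
    "fill_solvent",
    "build_system",
]

#: The chain-count <-> concentration anchor printed for the study system.
CALIBRATION_CHAINS = 50
CALIBRATION_MM = 6.0


def volume_from_calibration(n_chains: int, concentration_mM: float) -> float:
    """Physical volume (nm^3) containing ``n_chains`` solute molecules at the
    given molar concentration.

    V = N / (N_A * c); 1 mM = 1 mol/m^3.  The four study systems (50 chains
    at 6 mM ... 200 chains at 24 mM) all yield the same volume.
    """
    if n_chains <= 0 or concentration_mM <= 0:
        raise ValueError("chain count and concentration must be positive")
    v_m3 = n_chains / (N_AVOGADRO * concentration_mM)  # mM == mol/m^3
    return v_m3 * 1e27


def concentration_of(n_chains: int, box: BoxSpec) -> float:
    """Molar concentration (mM) of ``n_chains`` molecules in a box.

    Inverse of :func:`volume_from_calibration`.
    """
    if n_chains < 0:
        raise ValueError("chain count must be non-negative")
    v_nm3 = box.volume_nm3
    if v_nm3 <= 0:
        raise ValueError("box volume must be positive")
    return n_chains / (N_AVOGADRO * v_nm3 * 1e-27)


def calibrated_box(length_scale: float = DEFAULT_LENGTH_SCALE_NM) -> BoxSpec:
    """Cubic box whose volume realizes the 50-chains = 6 mM calibration."""
    v_nm3 = volume_from_calibration(CALIBRATION_CHAINS, CALIBRATION_MM)
    L = v_nm3 ** (1.0 / 3.0) / length_scale
    return BoxSpec.cubic(L, length_scale)


@dataclass(frozen=True)
class BuildConfig:
    """Everything needed to construct one initial configuration.

    Lengths in r_c.  Defaults are the full study system: the
    concentration-calibrated box, a vesicle whose relaxed diameter lands near
    18 nm at the default length scale, 250 capsaicin molecules and 50
    chitosan 50-mers (6 mM).
    """

    r_out: float = 13.9
    thickness: float = 4.0
    area_per_lipid: float = 1.25
    n_capsaicin: int = 250
    n_chitosan: int = 50
    sequence: str | ChitosanSequence = "S1"
    target_density: float = 3.0
    rng_seed: int = 0
    box: BoxSpec | None = None
    length_scale: float = DEFAULT_LENGTH_SCALE_NM

    def __post_init__(self) -> None:
        if not (self.r_out > self.thickness > 0):
            raise ValueError("need vesicle radius > bilayer thickness > 0")
        if self.area_per_lipid <= 0:
            raise ValueError("area per lipid must be positive")
        if self.n_capsaicin < 0 or self.n_chitosan < 0:
            raise ValueError("solute counts must be non-negative")
        if self.target_density <= 0:
            raise ValueError("target density must be positive")
        if self.box is None:
            object.__setattr__(self, "box", calibrated_box(self.length_scale))

    @property
    def chitosan_sequence(self) -> ChitosanSequence:
        if isinstance(self.sequence, ChitosanSequence):
            return self.sequence
        return builtin_sequence(self.sequence)

    @classmethod
    def reduced_demo(cls, **overrides) -> "BuildConfig":
        """Desk-scale system: R_out = 8 (≈ 900 lipids), 25 capsaicin,
        5 chitosan chains, box scaled from the calibrated one by 8/13.9."""
        factor = 8.0 / 13.9
        base = calibrated_box()
        box = BoxSpec.cubic(base.lengths[0] * factor, base.length_scale)
        kw = dict(
            r_out=8.0,
            thickness=3.0,
            n_capsaicin=25,
            n_chitosan=5,
            box=box,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PlacedMolecules:
    """A set of molecules of one species with per-molecule bead coordinates."""

    topology: MoleculeTopology
    coords: list[np.ndarray] = field(default_factory=list)  # each (n_beads, 3)

    @property
    def n_molecules(self) -> int:
        return len(self.coords)

    @property
    def n_beads(self) -> int:
        return self.n_molecules * self.topology.n_beads


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors from the golden-spiral (Fibonacci) lattice."""
    k = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(normal, a)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(normal, t1)


def _leaflet(
    n_lipids: int,
    r_head: float,
    r_mid: float,
    center: np.ndarray,
    topology: MoleculeTopology,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Place one leaflet: heads on the sphere of radius ``r_head``, chains
    along the local normal toward the mid-surface radius ``r_mid``."""
    n_beads = topology.n_beads
    n_tails = sum(1 for i, j in topology.bonds if i == 1 and j > 1)
    beads_per_tail = (n_beads - 2) // max(n_tails, 1)
    n_layers = 2 + beads_per_tail
    spacing = abs(r_head - r_mid) / max(n_layers - 1, 1)
    direction = -1.0 if r_mid < r_head else 1.0  # radial sense of the chain

    normals = _fibonacci_sphere(n_lipids)
    # a random rotation decorrelates the two leaflets' lattices
    q = rng.normal(size=(3, 3))
    qr, _ = np.linalg.qr(q)
    if np.linalg.det(qr) < 0:
        qr[:, 0] *= -1
    normals = normals @ qr.T

    out = []
    for nrm in normals:
        t1, t2 = _tangent_basis(nrm)
        pos = np.empty((n_beads, 3))
        pos[0] = center + r_head * nrm                      # L1 head
        pos[1] = center + (r_head + direction * spacing) * nrm  # L2 neck
        b = 2
        for t in range(n_tails):
            off = 0.3 * t1 * (1.0 if t % 2 == 0 else -1.0) * (1 + t // 2)
            for k in range(beads_per_tail):
                rad = r_head + direction * spacing * (2 + k)
                pos[b] = center + rad * nrm + off
                b += 1
        out.append(pos)
    return out


def build_vesicle(config: BuildConfig, topology: MoleculeTopology | None = None) -> PlacedMolecules:
    """Construct the preformed bilayer vesicle at the box centre.

    Lipid count per leaflet is round(4 pi R^2 / area_per_lipid) with R the
    leaflet's head-sphere radius (outer R_out, inner R_out - thickness).
    Chains of both leaflets point toward the mid-surface.  Deterministic
    given ``config.rng_seed``.
    """
    if topology is None:
        topology = lecithin_topology()
    box = config.box
    if config.r_out + 1.0 > min(box.lengths) / 2.0:
        raise ValueError(
            f"vesicle (R_out={config.r_out}) does not fit box {box.lengths} "
            "with >= 1 r_c clearance"
        )
    r_in = config.r_out - config.thickness
    r_mid = config.r_out - 0.5 * config.thickness
    n_outer = round(4.0 * math.pi * config.r_out**2 / config.area_per_lipid)
    n_inner = round(4.0 * math.pi * r_in**2 / config.area_per_lipid)
    if n_outer < 1 or n_inner < 1:
        raise ValueError("vesicle too small for even one lipid per leaflet")
    rng = np.random.default_rng([config.rng_seed, 0x7E51])
    center = box.array / 2.0
    coords = _leaflet(n_outer, config.r_out, r_mid, center, topology, rng)
    coords += _leaflet(n_inner, r_in, r_mid, center, topology, rng)
    return PlacedMolecules(topology, coords)


def _random_walk_molecule(
    topology: MoleculeTopology,
    start: np.ndarray,
    bond_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Place one molecule as a free random walk over its bond tree."""
    n = topology.n_beads
    pos = np.empty((n, 3))
    pos[0] = start
    parent = [-1] * n
    for i, j in topology.bonds:
        if parent[j] == -1:
            parent[j] = i
    for k in range(1, n):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pos[k] = pos[parent[k]] + bond_length * u
    return pos


def scatter_solutes(
    config: BuildConfig,
    topologies: dict[str, tuple[MoleculeTopology, int]] | None = None,
    bond_length: float = 0.7,
    max_retries: int = 500,
) -> dict[str, PlacedMolecules]:
    """Scatter solute molecules randomly outside the vesicle.

    Each molecule is grown as a free random walk with steps of the
    equilibrium bond length, started at a uniform random point; a placement
    is rejected (and retried) if any bead falls within R_out + 1 r_c of the
    vesicle centre.  Reproducible given ``config.rng_seed``.
    """
    if topologies is None:
        topologies = {
            "capsaicin": (capsaicin_topology(), config.n_capsaicin),
            "chitosan": (chitosan_topology(config.chitosan_sequence), config.n_chitosan),
        }
    rng = np.random.default_rng([config.rng_seed, 0x50D1])
    box = config.box
    center = box.array / 2.0
    excluded = config.r_out + 1.0
    out: dict[str, PlacedMolecules] = {}
    for species, (topo, count) in topologies.items():
        placed = PlacedMolecules(topo)
        for _ in range(count):
            for attempt in range(max_retries):
                start = rng.uniform(0.0, 1.0, size=3) * box.array
                pos = _random_walk_molecule(topo, start, bond_length, rng)
                d = box.minimum_image(pos - center)
                if (np.linalg.norm(d, axis=1) > excluded).all():
                    placed.coords.append(pos)
                    break
            else:
                raise RuntimeError(
                    f"could not place {species} molecule outside the vesicle "
                    f"after {max_retries} attempts; box too crowded"
                )
        out[species] = placed
    return out


def fill_solvent(n_current: int, config: BuildConfig) -> np.ndarray:
    """Uniform random W-bead positions topping the system up to the target
    density.  Soft potentials permit overlaps, so no exclusion is applied."""
    n_target = round(config.target_density * config.box.volume)
    n_w = n_target - n_current
    if n_w < 0:
        raise ValueError(
            f"target density already exceeded: {n_current} beads present, "
            f"target total {n_target}"
        )
    rng = np.random.default_rng([config.rng_seed, 0x5017])
    return rng.uniform(0.0, 1.0, size=(n_w, 3)) * config.box.array


def build_system(
    config: BuildConfig,
    lecithin: MoleculeTopology | None = None,
    kT: float = 1.0,
) -> SimulationState:
    """Compose vesicle + solutes + solvent into a simulation state.

    Beads are ordered lecithin, capsaicin, chitosan, solvent; molecule ids
    are consecutive in that order (every solvent bead its own molecule).
    Initial velocities are Maxwell-Boltzmann at ``kT`` with zero total
    momentum.  Bitwise deterministic given ``config.rng_seed``.
    """
    vesicle = build_vesicle(config, lecithin)
    solutes = scatter_solutes(config)

    species_sets: list[tuple[str, PlacedMolecules]] = [("lecithin", vesicle)]
    for name in ("capsaicin", "chitosan"):
        if name in solutes:
            species_sets.append((name, solutes[name]))

    pos_parts: list[np.ndarray] = []
    types: list[int] = []
    molids: list[int] = []
    bonds: list[tuple[int, int]] = []
    mol_species: list[str] = []
    offset = 0
    mol = 0
    for name, placed in species_sets:
        t_codes = [bead_index(b) for b in placed.topology.beads]
        for coords in placed.coords:
            pos_parts.append(coords)
            types.extend(t_codes)
            molids.extend([mol] * placed.topology.n_beads)
            bonds.extend((offset + i, offset + j) for i, j in placed.topology.bonds)
            mol_species.append(name)
            offset += placed.topology.n_beads
            mol += 1

    solvent = fill_solvent(offset, config)
    pos_parts.append(solvent)
    w_code = bead_index("W")
    for k in range(len(solvent)):
        types.append(w_code)
        molids.append(mol)
        mol_species.append("water")
        mol += 1

    positions = np.concatenate(pos_parts) if pos_parts else np.empty((0, 3))
    n = len(positions)
    rng = np.random.default_rng([config.rng_seed, 0xFEE1])
    vel = rng.normal(0.0, math.sqrt(kT), size=(n, 3))
    vel -= vel.mean(axis=0)

    return SimulationState(
        positions=positions,
        velocities=vel,
        types=np.asarray(types, dtype=np.int64),
        molecule_ids=np.asarray(molids, dtype=np.int64),
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        box=config.box,
        molecule_species=tuple(mol_species),
    )
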