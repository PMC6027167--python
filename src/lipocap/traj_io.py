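"""Extended-XYZ trajectory I/O.

One frame per block::

    <N>
    Lattice="Lx 0 0 0 Ly 0 0 0 Lz" Properties=species:S:1:molid:I:1:pos:R:3 step=<s>
    L1 0 1.2345 2.3456 3.4567
    ...

Coordinates are wrapped, in reduced units; the species column is the bead
type.  Molecule species (lecithin/capsaicin/chitosan/water) are recoverable
from the bead types, so a round-tripped trajectory supports the full
analysis layer.
"""

from __future__ import annotations

import re
from pathlib import Path
import numpy as np

from lipocap.box import BoxSpec
from lipocap.cg_models import BEAD_TYPES, bead_index
from lipocap.dpd_engine import Frame, Trajectory

__all__ = ["write_extxyz", "read_extxyz", "molecule_species_from_types"]

_BEAD_TO_MOLECULE = {
    "L1": "lecithin", "L2": "lecithin", "L3": "lecithin",
    "C1": "capsaicin", "C2": "capsaicin", "C3": "capsaicin",
    "G": "chitosan", "A": "chitosan",
    "W": "water",
}


def molecule_species_from_types(types: np.ndarray, molecule_ids: np.ndarray) -> tuple[str, ...]:
    """Reconstruct molecule-id -> species labels from bead types."""
    n_mol = int(molecule_ids.max()) + 1 if len(molecule_ids) else 0
    species = [""] * n_mol
    for t, m in zip(types, molecule_ids):
        if not species[m]:
            species[m] = _BEAD_TO_MOLECULE[BEAD_TYPES[t]]
    return tuple(species)


def write_extxyz(path: str | Path, traj: Trajectory, precision: int = 5) -> None:
    """Write all frames of a trajectory to an extended-XYZ file."""
    Lx, Ly, Lz = traj.box.lengths
    names = np.asarray(BEAD_TYPES, dtype=object)[traj.types]
    fmt = f"%s %d %.{precision}f %.{precision}f %.{precision}f\n"
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"{len(frame.positions)}\n")
            fh.write(
                f'Lattice="{Lx:g} 0 0 0 {Ly:g} 0 0 0 {Lz:g}" '
                f"Properties=species:S:1:molid:I:1:pos:R:3 "
                f"step={frame.step} length_scale_nm={traj.box.length_scale:g}\n"
            )
            for name, mol, (x, y, z) in zip(names, traj.molecule_ids, frame.positions):
                fh.write(fmt % (name, mol, x, y, z))


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_STEP_RE = re.compile(r"step=(\d+)")
_SCALE_RE = re.compile(r"length_scale_nm=([0-9.eE+-]+)")


def read_extxyz(path: str | Path) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_extxyz`.

    The bond list is not stored in the file; for the analyses that unwrap
    molecules across the periodic boundary, links between consecutive beads
    of the same molecule are synthesized instead.  This is sufficient for
    unwrapping because consecutive beads of one molecule are always far
    closer than half a box length, even across the branch point of a lipid.
    """
    frames: list[Frame] = []
    types = molids = None
    box = None
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            m = _LATTICE_RE.search(comment)
            if m is None:
                raise ValueError("missing Lattice in extended-XYZ comment line")
            lat = [float(x) for x in m.group(1).split()]
            lengths = (lat[0], lat[4], lat[8])
            sm = _SCALE_RE.search(comment)
            scale = float(sm.group(1)) if sm else BoxSpec.cubic(1.0).length_scale
            step_m = _STEP_RE.search(comment)
            step = int(step_m.group(1)) if step_m else len(frames)
            pos = np.empty((n, 3))
            t = np.empty(n, dtype=np.int64)
            mol = np.empty(n, dtype=np.int64)
            for k in range(n):
                parts = fh.readline().split()
                t[k] = bead_index(parts[0])
                mol[k] = int(parts[1])
                pos[k] = [float(parts[2]), float(parts[3]), float(parts[4])]
            if box is None:
                box = BoxSpec(lengths, scale)
                types, molids = t, mol
            frames.append(Frame(step, pos))
    if box is None:
        raise ValueError(f"no frames found in {path}")
    same_mol = molids[1:] == molids[:-1]
    idx = np.flatnonzero(same_mol)
    links = np.column_stack([idx, idx + 1]).astype(np.int64)
    return Trajectory(
        frames=frames,
        types=types,
        molecule_ids=molids,
        bonds=links,
        box=box,
        molecule_species=molecule_species_from_types(types, molids),
    )
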