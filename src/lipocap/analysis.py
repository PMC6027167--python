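"""Observables: density maps, radial profiles, PMFs, vesicle size, EE.

All estimators take a :class:`~lipocap.dpd_engine.Trajectory` and average
over its frames.  Species selectors accept either a molecule species
("lecithin", "capsaicin", "chitosan", "water") or a single bead type
("L1", ..., "W").  Centre-of-mass quantities unwrap each molecule across the
periodic boundary before averaging its beads (equal masses), then wrap the
result back into the box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from lipocap import _kernels
from lipocap.cg_models import BEAD_TYPES, bead_index
from lipocap.dpd_engine import Trajectory

__all__ = [
    "DensityMap",
    "RadialProfile",
    "PMFCurve",
    "molecule_com",
    "density_map_xy",
    "radial_density_profile",
    "pair_gr",
    "pmf_from_gr",
    "encapsulation_efficiency",
    "count_free_capsaicin",
    "free_capsaicin_boundary",
    "outer_half_max_radius",
    "mean_diameter",
    "vesicle_center",
]


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class DensityMap:
    """Time-averaged local number density on an xy grid within a z-slab."""

    grid: np.ndarray          # (nx, ny), beads per r_c^3
    bin_width: float
    slab: tuple[float, float]
    species: str
    n_frames: int

    def to_csv(self, path: str | Path, extra_header: str = "") -> None:
        header = (
            f"# density map, species={self.species}, bin_width={self.bin_width} r_c, "
            f"slab=[{self.slab[0]:.3f},{self.slab[1]:.3f}] r_c, frames={self.n_frames}\n"
            "# rows = x bins, columns = y bins, values = beads per r_c^3\n"
        )
        with open(path, "w") as fh:
            if extra_header:
                fh.write(extra_header)
            fh.write(header)
            np.savetxt(fh, self.grid, delimiter=",", fmt="%.6g")


@dataclass
class RadialProfile:
    """Spherically averaged number density around a reference centre."""

    r: np.ndarray             # bin centres, r_c
    density: np.ndarray       # beads per r_c^3
    species: str
    n_frames: int

    @property
    def bin_width(self) -> float:
        return float(self.r[1] - self.r[0]) if len(self.r) > 1 else float(2 * self.r[0])

    def integral(self) -> float:
        """Volume integral sum 4 pi r^2 rho dr (should recover the count)."""
        edges = np.concatenate([[self.r[0] - self.bin_width / 2], self.r + self.bin_width / 2])
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        return float((self.density * shell).sum())

    def to_csv(self, path: str | Path, extra_header: str = "") -> None:
        with open(path, "w") as fh:
            if extra_header:
                fh.write(extra_header)
            fh.write(
                f"# radial density profile, species={self.species}, "
                f"bin_width={self.bin_width:g} r_c, frames={self.n_frames}\n"
                "r_rc,density\n"
            )
            np.savetxt(fh, np.column_stack([self.r, self.density]), delimiter=",", fmt="%.6g")


@dataclass
class PMFCurve:
    """Potential of mean force w(r) = -kT ln g(r) between molecular COMs.

    Anchored so the mean over the outermost 10% of sampled bins is zero;
    bins where g(r) = 0 are NaN (the PMF is undefined there).
    """

    r: np.ndarray
    w: np.ndarray             # kT
    pair: tuple[str, str]

    def well_depth(self) -> float:
        """Most negative w(r) value (0 if the curve is purely repulsive)."""
        finite = self.w[np.isfinite(self.w)]
        if len(finite) == 0:
            raise ValueError("PMF has no defined bins")
        return float(min(finite.min(), 0.0))

    def to_csv(self, path: str | Path, extra_header: str = "") -> None:
        with open(path, "w") as fh:
            if extra_header:
                fh.write(extra_header)
            fh.write(f"# PMF, pair={self.pair[0]}-{self.pair[1]}, units kT and r_c\n")
            fh.write("r_rc,w_kT\n")
            np.savetxt(fh, np.column_stack([self.r, self.w]), delimiter=",", fmt="%.6g")


# --------------------------------------------------------------------------
# selection helpers
# --------------------------------------------------------------------------

def _bead_mask(traj: Trajectory, species: str) -> np.ndarray:
    if species in BEAD_TYPES:
        mask = traj.types == bead_index(species)
    else:
        mol_species = np.asarray(traj.molecule_species, dtype=object)
        if len(mol_species) == 0:
            raise ValueError("trajectory carries no molecule species labels")
        mask = mol_species[traj.molecule_ids] == species
    if not mask.any():
        raise ValueError(f"species {species!r} absent from trajectory")
    return mask


def _molecule_rows(traj: Trajectory, species: str) -> tuple[np.ndarray, np.ndarray]:
    """(bead mask, sorted unique molecule ids) for a molecule species."""
    mask = _bead_mask(traj, species)
    mols = np.unique(traj.molecule_ids[mask])
    return mask, mols


def _unwrap(traj: Trajectory, positions: np.ndarray, parent: np.ndarray) -> np.ndarray:
    out = np.empty_like(positions)
    _kernels.unwrap_by_parent(
        np.ascontiguousarray(positions), parent, traj.box.array, out
    )
    return out


def molecule_com(
    traj: Trajectory, frame_index: int, species: str, wrap: bool = True
) -> np.ndarray:
    """Centres of mass of all molecules of a species in one frame.

    Each molecule is unwrapped across the periodic boundary (walking its bond
    tree), its beads averaged with equal mass, and the COM wrapped back into
    the box (unless ``wrap=False``).
    """
    mask, mols = _molecule_rows(traj, species)
    parent = traj.parent_array()
    pos = _unwrap(traj, traj.frames[frame_index].positions, parent)
    ids = traj.molecule_ids[mask]
    order = np.argsort(ids, kind="stable")
    sel = pos[mask][order]
    ids_sorted = ids[order]
    counts = np.bincount(ids_sorted - ids_sorted.min())
    counts = counts[counts > 0]
    cuts = np.cumsum(counts)[:-1]
    coms = np.array([c.mean(axis=0) for c in np.split(sel, cuts)])
    if wrap:
        coms = traj.box.wrap(coms)
    return coms


def vesicle_center(traj: Trajectory, frame_index: int, species: str = "lecithin") -> np.ndarray:
    """Mean position of all beads of the vesicle species in one frame.

    The vesicle is built at the box centre and, being a compact object, never
    straddles the boundary in the runs this package performs; the plain mean
    of wrapped coordinates is then the correct centre.
    """
    mask = _bead_mask(traj, species)
    return traj.frames[frame_index].positions[mask].mean(axis=0)


# --------------------------------------------------------------------------
# density estimators
# --------------------------------------------------------------------------

def density_map_xy(
    traj: Trajectory,
    species: str,
    bin_width: float = 0.5,
    slab: tuple[float, float] | None = None,
    frames: Sequence[int] | None = None,
) -> DensityMap:
    """Time-averaged xy number-density map of a species within a z-slab.

    Default slab: a central slice of thickness 2 r_c through the box centre
    (which is where the vesicle sits), showing the cross-section with its
    low-density aqueous core.  Normalization: counts / (bin area x slab
    thickness x n_frames), so integrating the map over the plane recovers
    the mean in-slab bead count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    Lx, Ly, Lz = traj.box.lengths
    if slab is None:
        slab = (Lz / 2.0 - 1.0, Lz / 2.0 + 1.0)
    z0, z1 = slab
    if not z1 > z0:
        raise ValueError("empty slab")
    try:
        mask = _bead_mask(traj, species)
    except ValueError:
        mask = np.zeros(len(traj.types), dtype=bool)  # all-zero map for absent species
    idx = frames if frames is not None else range(len(traj.frames))
    nx = max(1, int(round(Lx / bin_width)))
    ny = max(1, int(round(Ly / bin_width)))
    grid = np.zeros((nx, ny))
    n_used = 0
    for fi in idx:
        pos = traj.frames[fi].positions[mask]
        in_slab = (pos[:, 2] >= z0) & (pos[:, 2] < z1) if len(pos) else np.empty(0, bool)
        p = pos[in_slab]
        h, _, _ = np.histogram2d(p[:, 0], p[:, 1], bins=(nx, ny), range=((0, Lx), (0, Ly)))
        grid += h
        n_used += 1
    if n_used == 0:
        raise ValueError("no frames selected")
    bin_area = (Lx / nx) * (Ly / ny)
    grid /= bin_area * (z1 - z0) * n_used
    return DensityMap(grid, bin_width, (z0, z1), species, n_used)


def radial_density_profile(
    traj: Trajectory,
    species: str,
    center: np.ndarray | None = None,
    bin_width: float = 0.25,
    r_max: float | None = None,
    frames: Sequence[int] | None = None,
) -> RadialProfile:
    """Spherical-shell density of a species around the vesicle centre.

    The centre is recomputed per frame from the lecithin beads unless an
    explicit fixed centre is given.  Shell counts are normalized by shell
    volume and frame count.
    """
    if r_max is None:
        r_max = min(traj.box.lengths) / 2.0
    nbins = max(1, int(round(r_max / bin_width)))
    edges = np.linspace(0.0, nbins * bin_width, nbins + 1)
    hist = np.zeros(nbins)
    idx = frames if frames is not None else range(len(traj.frames))
    mask = _bead_mask(traj, species)
    n_used = 0
    for fi in idx:
        c = vesicle_center(traj, fi) if center is None else np.asarray(center)
        pos = traj.frames[fi].positions[mask]
        d = np.linalg.norm(traj.box.minimum_image(pos - c), axis=1)
        h, _ = np.histogram(d, bins=edges)
        hist += h
        n_used += 1
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    density = hist / (shell * n_used)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RadialProfile(centers, density, species, n_used)


# --------------------------------------------------------------------------
# pair correlations and PMF
# --------------------------------------------------------------------------

def pair_gr(
    traj: Trajectory,
    species_a: str,
    species_b: str,
    bin_width: float = 0.1,
    r_max: float | None = None,
    frames: Sequence[int] | None = None,
) -> RadialProfile:
    """Radial distribution function of COM separations between two species.

    Distances use the minimum image and bins stop at L/2 (beyond which the
    minimum-image metric is invalid).  Self-pairs are excluded when the two
    species coincide.  Normalized by the ideal-gas expectation, so two
    uncorrelated uniform species give g ~ 1.
    """
    half_l = min(traj.box.lengths) / 2.0
    if r_max is None or r_max > half_l:
        r_max = half_l
    nbins = max(1, int(r_max / bin_width))
    edges = np.linspace(0.0, nbins * bin_width, nbins + 1)
    hist = np.zeros(nbins)
    idx = list(frames) if frames is not None else list(range(len(traj.frames)))
    same = species_a == species_b
    n_pairs = None
    for fi in idx:
        ca = molecule_com(traj, fi, species_a)
        cb = ca if same else molecule_com(traj, fi, species_b)
        if same:
            if len(ca) < 2:
                raise ValueError("need at least two molecules for a self g(r)")
            iu, ju = np.triu_indices(len(ca), k=1)
            d = np.linalg.norm(traj.box.minimum_image(ca[iu] - ca[ju]), axis=1)
            n_pairs = len(ca) * (len(ca) - 1) / 2.0
        else:
            diff = ca[:, None, :] - cb[None, :, :]
            d = np.linalg.norm(traj.box.minimum_image(diff.reshape(-1, 3)), axis=1)
            n_pairs = float(len(ca) * len(cb))
        h, _ = np.histogram(d, bins=edges)
        hist += h
    if n_pairs is None or n_pairs == 0:
        raise ValueError("fewer than two molecules available for g(r)")
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_pairs * shell / traj.box.volume
    g = hist / (ideal * len(idx))
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RadialProfile(centers, g, f"g({species_a},{species_b})", len(idx))


def pmf_from_gr(gr: RadialProfile, kT: float = 1.0, tail_fraction: float = 0.1) -> PMFCurve:
    """w(r) = -kT ln g(r), anchored to zero over the outer tail.

    The anchor subtracts the mean of w over the outermost ``tail_fraction``
    of bins with g > 0.  Bins with g = 0 are NaN (undefined PMF).
    """
    g = np.asarray(gr.density, dtype=float)
    if (g < 0).any():
        raise ValueError("g(r) must be non-negative")
    if not (g > 0).any():
        raise ValueError("g(r) is identically zero; PMF undefined everywhere")
    with np.errstate(divide="ignore"):
        w = np.where(g > 0, -kT * np.log(np.where(g > 0, g, 1.0)), np.nan)
    defined = np.flatnonzero(g > 0)
    n_tail = max(1, int(math.ceil(tail_fraction * len(defined))))
    shift = np.nanmean(w[defined[-n_tail:]])
    w = w - shift
    pair = tuple(gr.species[2:-1].split(",")) if gr.species.startswith("g(") else ("", "")
    return PMFCurve(np.asarray(gr.r), w, pair)  # type: ignore[arg-type]


# --------------------------------------------------------------------------
# encapsulation efficiency and vesicle size
# --------------------------------------------------------------------------

def encapsulation_efficiency(caps_total: float, caps_free: float) -> float:
    """EE = ((CapsT - CapsF) / CapsT) x 100, in percent."""
    if caps_total <= 0:
        raise ValueError("total capsaicin count must be positive")
    if caps_free < 0 or caps_free > caps_total:
        raise ValueError("free capsaicin must lie in [0, total]")
    return (caps_total - caps_free) / caps_total * 100.0


def outer_half_max_radius(profile: RadialProfile, peak_factor: float = 2.0) -> float:
    """Outermost radius where the density falls to half its peak value.

    Requires a membrane peak: maximum density > ``peak_factor`` x the
    far-field level (mean over the outer 10% of bins).  Linear interpolation
    between the bracketing bins.
    """
    rho = profile.density
    n_tail = max(1, len(rho) // 10)
    far = float(rho[-n_tail:].mean())
    peak = float(rho.max())
    if peak <= peak_factor * max(far, 1e-12):
        raise ValueError("no membrane peak in the density profile")
    half = peak / 2.0
    above = np.flatnonzero(rho >= half)
    k = above[-1]
    if k == len(rho) - 1:
        return float(profile.r[k])
    r0, r1 = profile.r[k], profile.r[k + 1]
    y0, y1 = rho[k], rho[k + 1]
    return float(r0 + (y0 - half) / (y0 - y1) * (r1 - r0))


def mean_diameter(
    profile: RadialProfile, length_scale: float | None = None
) -> tuple[float, float]:
    """Vesicle diameter (reduced, physical-nm) from the lecithin profile.

    Diameter = 2 x the outermost half-maximum radius of the membrane peak.
    ``length_scale`` (nm per r_c) converts to nm; by default the package's
    standard mapping is used.
    """
    from lipocap.box import DEFAULT_LENGTH_SCALE_NM

    scale = DEFAULT_LENGTH_SCALE_NM if length_scale is None else length_scale
    d_rc = 2.0 * outer_half_max_radius(profile)
    return d_rc, d_rc * scale


def free_capsaicin_boundary(traj: Trajectory, margin: float = 1.0, **profile_kw) -> float:
    """Default free/encapsulated boundary: lecithin outer half-max radius + margin.

    Clamped just below L/2, where the minimum-image distance stops being
    meaningful (relevant only for very small boxes).
    """
    prof = radial_density_profile(traj, "lecithin", **profile_kw)
    limit = min(traj.box.lengths) / 2.0 - 1e-9
    return min(outer_half_max_radius(prof) + margin, limit)


def count_free_capsaicin(
    traj: Trajectory,
    boundary_radius: float | None = None,
    frames: Sequence[int] | None = None,
) -> float:
    """Mean number of capsaicin molecules whose COM lies outside the boundary.

    The boundary defaults to the measured membrane edge (lecithin outer
    half-maximum radius) + 1 r_c and must not exceed L/2.
    """
    if boundary_radius is None:
        boundary_radius = free_capsaicin_boundary(traj, frames=frames)
    if boundary_radius <= 0:
        raise ValueError("boundary radius must be positive")
    if boundary_radius > min(traj.box.lengths) / 2.0:
        raise ValueError("boundary radius exceeds half the box")
    idx = list(frames) if frames is not None else list(range(len(traj.frames)))
    total = 0.0
    for fi in idx:
        c = vesicle_center(traj, fi)
        coms = molecule_com(traj, fi, "capsaicin")
        d = np.linalg.norm(traj.box.minimum_image(coms - c), axis=1)
        total += int((d > boundary_radius).sum())
    return total / len(idx)
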