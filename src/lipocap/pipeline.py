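"""Experiment driver: build -> pre-equilibrate -> run -> analyze.

One :class:`ExperimentConfig` fully determines a run (including every random
stream); rerunning with the same config and seed reproduces the summary
byte-for-byte.  Outputs per run: an extended-XYZ trajectory (optional), a
temperature log, density maps for lecithin/chitosan/capsaicin, radial
profiles, the three species-species PMFs, and a one-row summary (vesicle
size +/- block std, EE +/- block std) mirroring the study's results table.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lipocap import analysis as an
from lipocap.box import BoxSpec
from lipocap.cg_models import ChitosanSequence
from lipocap.dpd_engine import (
    BondParams,
    DPDParams,
    InteractionMatrix,
    SimulationState,
    Trajectory,
    instantaneous_temperature,
    pre_equilibrate,
    run,
)
from lipocap.system_builder import BuildConfig, build_system, concentration_of
from lipocap.traj_io import write_extxyz

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "scale_preset",
           "cs_sweep_preset", "sequence_preset"]

#: Minimum vesicle radius (r_c) below which a scaled system is rejected.
MIN_VESICLE_RADIUS = 4.0


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete, serializable description of one experiment."""

    build: BuildConfig = field(default_factory=BuildConfig)
    dpd: DPDParams = field(default_factory=DPDParams)
    bonds: BondParams = field(default_factory=BondParams)
    interactions: InteractionMatrix = field(default_factory=InteractionMatrix)
    pre_steps: int = 1000
    pre_fmax: float = 30.0
    steps: int = 100_000
    snapshot_interval: int = 1000
    burn_in: float = 0.5
    map_bin: float = 0.5
    gr_bin: float = 0.1
    profile_bin: float = 0.25
    rng_seed: int = 0
    write_trajectory: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.steps < 1 or self.pre_steps < 0:
            raise ValueError("step counts must be positive")
        if not (0.0 <= self.burn_in < 1.0):
            raise ValueError("burn_in must be a fraction in [0, 1)")
        # the experiment seed overrides the build seed so one knob controls all
        if self.build.rng_seed != self.rng_seed:
            object.__setattr__(self, "build", replace(self.build, rng_seed=self.rng_seed))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        b = self.build
        seq = b.sequence.to_string() if isinstance(b.sequence, ChitosanSequence) else b.sequence
        return {
            "build": {
                "r_out": b.r_out,
                "thickness": b.thickness,
                "area_per_lipid": b.area_per_lipid,
                "n_capsaicin": b.n_capsaicin,
                "n_chitosan": b.n_chitosan,
                "sequence": seq,
                "target_density": b.target_density,
                "box_lengths": list(b.box.lengths),
                "length_scale_nm": b.box.length_scale,
            },
            "dpd": {"gamma": self.dpd.gamma, "kT": self.dpd.kT, "dt": self.dpd.dt,
                    "lambda": self.dpd.lam},
            "bonds": {"k_spring": self.bonds.k_spring, "r0": self.bonds.r0},
            "interactions": self.interactions.to_dict(),
            "run": {"pre_steps": self.pre_steps, "pre_fmax": self.pre_fmax,
                    "steps": self.steps, "snapshot_interval": self.snapshot_interval,
                    "burn_in": self.burn_in},
            "analysis": {"map_bin": self.map_bin, "gr_bin": self.gr_bin,
                         "profile_bin": self.profile_bin},
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        bd = d.get("build", {})
        box = None
        if "box_lengths" in bd:
            box = BoxSpec(tuple(bd["box_lengths"]),
                          bd.get("length_scale_nm", BoxSpec.cubic(1).length_scale))
        seq = bd.get("sequence", "S1")
        if seq not in ("S1", "S2"):
            seq = ChitosanSequence.from_string(seq)
        build = BuildConfig(
            r_out=bd.get("r_out", 13.9),
            thickness=bd.get("thickness", 4.0),
            area_per_lipid=bd.get("area_per_lipid", 1.25),
            n_capsaicin=bd.get("n_capsaicin", 250),
            n_chitosan=bd.get("n_chitosan", 50),
            sequence=seq,
            target_density=bd.get("target_density", 3.0),
            box=box,
            rng_seed=d.get("rng_seed", 0),
        )
        dd = d.get("dpd", {})
        dpd = DPDParams(gamma=dd.get("gamma", 4.5), kT=dd.get("kT", 1.0),
                        dt=dd.get("dt", 0.03), lam=dd.get("lambda", 0.65))
        bb = d.get("bonds", {})
        bonds = BondParams(k_spring=bb.get("k_spring", 100.0), r0=bb.get("r0", 0.7))
        im = (InteractionMatrix.from_dict(d["interactions"])
              if "interactions" in d else InteractionMatrix())
        rd = d.get("run", {})
        ad = d.get("analysis", {})
        return cls(
            build=build, dpd=dpd, bonds=bonds, interactions=im,
            pre_steps=rd.get("pre_steps", 1000), pre_fmax=rd.get("pre_fmax", 30.0),
            steps=rd.get("steps", 100_000),
            snapshot_interval=rd.get("snapshot_interval", 1000),
            burn_in=rd.get("burn_in", 0.5),
            map_bin=ad.get("map_bin", 0.5), gr_bin=ad.get("gr_bin", 0.1),
            profile_bin=ad.get("profile_bin", 0.25),
            rng_seed=d.get("rng_seed", 0),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ExperimentResult:
    """Bundle of everything one run produces."""

    config: ExperimentConfig
    trajectory: Trajectory
    temperature_log: pd.DataFrame
    density_maps: dict[str, an.DensityMap]
    profiles: dict[str, an.RadialProfile]
    pmfs: dict[str, an.PMFCurve]
    summary: pd.DataFrame

    def analysis_frames(self) -> list[int]:
        n = len(self.trajectory)
        first = int(math.floor(self.config.burn_in * (n - 1)))
        return list(range(first, n))


def _block_stats(values: np.ndarray) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0


def analyze_trajectory(traj: Trajectory, config: ExperimentConfig,
                       n_blocks: int = 4) -> tuple[dict, dict, dict, pd.DataFrame]:
    """Compute maps, profiles, PMFs and the summary row from a trajectory.

    Uses the frames after burn-in; size and EE uncertainties are standard
    deviations over ``n_blocks`` equal frame blocks.
    """
    n = len(traj)
    first = int(math.floor(config.burn_in * (n - 1)))
    frames = list(range(first, n))

    species3 = ["lecithin", "chitosan", "capsaicin"]
    maps = {s: an.density_map_xy(traj, s, bin_width=config.map_bin, frames=frames)
            for s in species3}
    profiles = {s: an.radial_density_profile(traj, s, bin_width=config.profile_bin,
                                             frames=frames)
                for s in species3}
    profiles["W"] = an.radial_density_profile(traj, "W", bin_width=config.profile_bin,
                                              frames=frames)

    pmfs = {}
    pair_map = {
        "lecithin-chitosan": ("lecithin", "chitosan"),
        "lecithin-capsaicin": ("lecithin", "capsaicin"),
        "capsaicin-chitosan": ("capsaicin", "chitosan"),
    }
    for name, (a, b) in pair_map.items():
        try:
            gr = an.pair_gr(traj, a, b, bin_width=config.gr_bin, frames=frames)
            pmfs[name] = an.pmf_from_gr(gr)
        except ValueError:
            logger.warning("PMF %s skipped (insufficient molecules)", name)

    boundary = an.free_capsaicin_boundary(traj, frames=frames)
    n_caps = config.build.n_capsaicin
    blocks = np.array_split(np.asarray(frames), min(n_blocks, len(frames)))
    d_rc_blocks, ee_blocks = [], []
    for blk in blocks:
        if len(blk) == 0:
            continue
        prof = an.radial_density_profile(traj, "lecithin", bin_width=config.profile_bin,
                                         frames=list(blk))
        d_rc_blocks.append(2.0 * an.outer_half_max_radius(prof))
        free = an.count_free_capsaicin(traj, boundary_radius=boundary, frames=list(blk))
        ee_blocks.append(an.encapsulation_efficiency(n_caps, free))
    d_rc, d_rc_sd = _block_stats(np.array(d_rc_blocks))
    ee, ee_sd = _block_stats(np.array(ee_blocks))
    scale = traj.box.length_scale

    summary = pd.DataFrame([{
        "n_chitosan": config.build.n_chitosan,
        "concentration_mM": round(concentration_of(config.build.n_chitosan, traj.box), 6),
        "sequence": (config.build.sequence if isinstance(config.build.sequence, str)
                     else "custom"),
        "n_capsaicin": n_caps,
        "diameter_rc": round(d_rc, 4),
        "diameter_nm": round(d_rc * scale, 4),
        "diameter_sd_nm": round(d_rc_sd * scale, 4),
        "ee_pct": round(ee, 4),
        "ee_sd_pct": round(ee_sd, 4),
        "free_boundary_rc": round(boundary, 4),
        "seed": config.rng_seed,
        "config_hash": config.config_hash(),
    }])
    return maps, profiles, pmfs, summary


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute one full experiment: build, relax, produce, analyze, write.

    Stage failures are re-raised with the stage name; outputs are written to
    ``config.outdir`` when set (summary.csv, temperature.csv, per-species
    density maps and profiles, per-pair PMFs, config.yaml, and the
    trajectory when ``write_trajectory``).
    """
    stage = "build"
    try:
        state = build_system(config.build)
        stage = "pre-equilibrate"
        if config.pre_steps:
            pre_equilibrate(state, config.interactions, config.bonds, config.dpd,
                            n_steps=config.pre_steps, seed=config.rng_seed,
                            fmax=config.pre_fmax)
        stage = "production"
        temp_records: list[tuple[int, float]] = []

        def temp_observer(s: SimulationState, k: int) -> None:
            kt = instantaneous_temperature(s)
            temp_records.append((s.step, kt))
            if abs(kt - config.dpd.kT) > 0.1 * config.dpd.kT:
                logger.warning("kT=%.3f deviates >10%% from target at step %d", kt, s.step)

        log_interval = min(1000, config.snapshot_interval)
        traj = run(state, config.interactions, config.bonds, config.dpd,
                   n_steps=config.steps, seed=config.rng_seed,
                   snapshot_interval=config.snapshot_interval,
                   observers=[(log_interval, temp_observer)])
        stage = "analysis"
        maps, profiles, pmfs, summary = analyze_trajectory(traj, config)
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage '{stage}' "
                           f"(step {locals().get('state').step if 'state' in locals() else 0})"
                           ) from exc

    temperature_log = pd.DataFrame(temp_records, columns=["step", "kT"])
    result = ExperimentResult(config, traj, temperature_log, maps, profiles, pmfs, summary)

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        header = f"# seed={config.rng_seed} config_hash={config.config_hash()}\n"
        with open(out / "summary.csv", "w") as fh:
            fh.write(header)
            summary.to_csv(fh, index=False)
        with open(out / "temperature.csv", "w") as fh:
            fh.write(header)
            temperature_log.to_csv(fh, index=False)
        for name, m in maps.items():
            m.to_csv(out / f"density_map_{name}.csv", extra_header=header)
        for name, p in profiles.items():
            p.to_csv(out / f"radial_profile_{name}.csv", extra_header=header)
        for name, p in pmfs.items():
            p.to_csv(out / f"pmf_{name}.csv", extra_header=header)
        if config.write_trajectory:
            write_extxyz(out / "trajectory.extxyz", traj)
    return result


def scale_preset(config: ExperimentConfig, factor: float) -> ExperimentConfig:
    """Shrink an experiment to desk scale.

    Box lengths and vesicle radius scale by ``factor``; solute counts scale
    with the volume (factor cubed, rounded) so that molar concentrations are
    preserved, which the returned config satisfies by construction.  The
    bilayer thickness is a membrane property and is left unchanged.
    """
    if not (0.0 < factor <= 1.0):
        raise ValueError("scale factor must be in (0, 1]")
    if factor == 1.0:
        return config
    b = config.build
    new_r = b.r_out * factor
    if new_r < MIN_VESICLE_RADIUS:
        raise ValueError(
            f"scaled vesicle radius {new_r:.2f} r_c below the minimum viable "
            f"{MIN_VESICLE_RADIUS} r_c")
    vol_factor = factor**3
    box = BoxSpec(tuple(L * factor for L in b.box.lengths), b.box.length_scale)
    build = replace(
        b,
        r_out=new_r,
        n_capsaicin=round(b.n_capsaicin * vol_factor),
        n_chitosan=round(b.n_chitosan * vol_factor),
        box=box,
    )
    return replace(config, build=build)


def cs_sweep_preset(base: ExperimentConfig,
                    chain_counts: tuple[int, ...] = (50, 100, 150, 200)) -> list[ExperimentConfig]:
    """The chitosan-concentration sweep: fixed capsaicin, rising chain count."""
    out = []
    for n in chain_counts:
        build = replace(base.build, n_chitosan=n)
        outdir = None if base.outdir is None else str(Path(base.outdir) / f"cs_{n}")
        out.append(replace(base, build=build, outdir=outdir))
    return out


def sequence_preset(base: ExperimentConfig) -> list[ExperimentConfig]:
    """The acetylation-pattern comparison: S1 vs S2 at the base chain count."""
    out = []
    for seq in ("S1", "S2"):
        build = replace(base.build, sequence=seq)
        outdir = None if base.outdir is None else str(Path(base.outdir) / f"seq_{seq}")
        out.append(replace(base, build=build, outdir=outdir))
    return out
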