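"""On-disk artifacts: PDB input, HDF5 containers for pulses, trajectories,
pattern sets, volumes, densities and curves, structured YAML configuration,
and the splittable-seed scheme that makes every stage item individually
reproducible.
"""
from __future__ import annotations

import logging
from pathlib import Path

import gemmi
import h5py
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .atomic import AtomicSystem, atomic_weight
from .damage import DamageTrajectory, Snapshot
from .diffraction import DetectorGeometry, DiffractionPattern
from .emc import IntensityVolume
from .metrics import ShellCurve
from .phasing import DensityVolume, SupportMask
from .pulse import Pulse

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------- seeds --

def child_seed(master: int, *path) -> int:
    """Deterministic per-stage, per-item child seed (< 2^31) derived from a
    single master seed and a path of stage labels / item indices."""
    tokens = [int(master)]
    for p in path:
        if isinstance(p, str):
            tokens.append(int.from_bytes(p.encode()[:8], "little") % (2**31))
        else:
            tokens.append(int(p))
    ss = np.random.SeedSequence(tokens)
    return int(ss.generate_state(1)[0] % (2**31))


# ----------------------------------------------------------------- PDB ---

def read_pdb(path) -> AtomicSystem:
    """Read ATOM/HETATM records into an AtomicSystem.

    Hydrogens are excluded from the scattering atom list but their mass is
    added to ``molecular_mass``; water molecules are flagged in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_structure(str(path))
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
    elements, positions = [], []
    h_mass = 0.0
    n_water = 0
    for model in structure:
        for chain in model:
            for residue in chain:
                if residue.is_water():
                    n_water += len(residue)
                for atom in residue:
                    z = atom.element.atomic_number
                    if z == 0:
                        raise ValueError(
                            f"unidentifiable element for atom {atom.name!r} "
                            f"in residue {residue.name!r}")
                    if z == 1:
                        h_mass += atom.element.weight
                        continue
                    elements.append(z)
                    positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    if not elements:
        raise ValueError(f"no non-hydrogen atoms found in {path}")
    if n_water:
        logger.info("read_pdb: %d water atoms flagged as solvent", n_water)
    system = AtomicSystem(elements=np.array(elements),
                          positions=np.array(positions))
    system.molecular_mass = float(system.masses.sum() + h_mass)
    logger.info("read_pdb: %d non-hydrogen atoms", system.n_atoms)
    return system


# -------------------------------------------------------------- config ---

class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PulseConfig(_Section):
    fdhm_fs: float = 9.0
    mean_photons: float = 13e11
    jitter_rel: float = 0.25 / 13.0
    photon_energy_ev: float = 5000.0
    n_spikes: int = 36
    dt_fs: float = 0.1


class BeamConfig(_Section):
    transmission_factor: float = 2.3
    fwhm_x_nm: float = 250.0
    fwhm_y_nm: float = 160.0


class DamageConfig(_Section):
    n_slices: int = 100
    md_dt_fs: float = 0.01


class DetectorConfig(_Section):
    n_pixels: int = 81
    pixel_size_m: float = 300e-6
    gap_rows: int = 7
    corner_resolution_a: float = 3.0


class OrientConfig(_Section):
    n_rotations: int = 150
    n_iterations: int = 50
    tolerance: float = 1e-4
    grid_n: int = 33
    friedel: bool = True


class PhaseConfig(_Section):
    n_rounds: int = 3
    n_recons: int = 16
    beta: float = 0.85
    n_iterations: int = 300
    select_frac: float = 0.2
    threshold_frac: float = 0.1


class MetricsConfig(_Section):
    population_std: bool = True


class PipelineConfig(_Section):
    """Structured pipeline configuration; unknown keys are rejected."""

    schema_version: str = SCHEMA_VERSION
    seed: int = 0
    pulse: PulseConfig = Field(default_factory=PulseConfig)
    beam: BeamConfig = Field(default_factory=BeamConfig)
    damage: DamageConfig = Field(default_factory=DamageConfig)
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    orient: OrientConfig = Field(default_factory=OrientConfig)
    phase: PhaseConfig = Field(default_factory=PhaseConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


# ---------------------------------------------------------------- HDF5 ---

def _check_version(group):
    v = group.attrs.get("spisim_schema")
    if v != SCHEMA_VERSION:
        raise ValueError(f"schema version mismatch: file has {v!r}, "
                         f"expected {SCHEMA_VERSION!r}")


def _stamp(group):
    group.attrs["spisim_schema"] = SCHEMA_VERSION


def write_pulses(path, pulses) -> None:
    with h5py.File(path, "w") as fh:
        root = fh.create_group("pulses")
        _stamp(fh)
        for i, p in enumerate(pulses):
            g = root.create_group(str(i))
            g.create_dataset("times", data=p.times)
            g.create_dataset("flux", data=p.flux)
            g.attrs["photon_energy"] = p.photon_energy
            g.attrs["seed"] = p.seed


def read_pulses(path):
    out = []
    with h5py.File(path, "r") as fh:
        _check_version(fh)
        root = fh["pulses"]
        for key in sorted(root, key=int):
            g = root[key]
            times = g["times"][...]
            flux = g["flux"][...]
            out.append(Pulse(times=times, flux=flux,
                             photon_energy=float(g.attrs["photon_energy"]),
                             n_photons=float(flux.sum()
                                             * (times[1] - times[0])),
                             seed=int(g.attrs["seed"])))
    return out


def write_trajectory(path, traj: DamageTrajectory) -> None:
    with h5py.File(path, "w") as fh:
        _stamp(fh)
        g = fh.create_group("traj/0")
        g.attrs["n_photoionisations"] = traj.n_photoionisations
        g.attrs["seed"] = traj.seed
        for k, s in enumerate(traj.snapshots):
            sg = g.create_group(f"snap_{k:04d}")
            sg.attrs["time"] = s.time
            sg.attrs["weight"] = s.weight
            sg.attrs["n_free"] = s.n_free
            sg.attrs["n_escaped"] = s.n_escaped
            sg.create_dataset("positions", data=s.positions)
            sg.create_dataset("bound_electrons", data=s.bound_electrons)


def read_trajectory(path) -> DamageTrajectory:
    with h5py.File(path, "r") as fh:
        _check_version(fh)
        g = fh["traj/0"]
        snaps = []
        for key in sorted(g):
            sg = g[key]
            snaps.append(Snapshot(
                time=float(sg.attrs["time"]),
                positions=sg["positions"][...],
                bound_electrons=sg["bound_electrons"][...],
                n_free=int(sg.attrs["n_free"]),
                weight=float(sg.attrs["weight"]),
                n_escaped=int(sg.attrs["n_escaped"])))
        return DamageTrajectory(snapshots=snaps,
                                n_photoionisations=int(
                                    g.attrs["n_photoionisations"]),
                                seed=int(g.attrs["seed"]))


def write_patterns(path, patterns, geom: DetectorGeometry) -> None:
    patterns = list(patterns)
    with h5py.File(path, "w") as fh:
        _stamp(fh)
        g = fh.create_group("patterns")
        g.create_dataset("counts",
                         data=np.stack([p.counts for p in patterns]),
                         compression="gzip")
        g.create_dataset("mask", data=patterns[0].mask)
        g.create_dataset("seeds", data=[p.seed for p in patterns])
        if all(p.true_quaternion is not None for p in patterns):
            g.create_dataset("true_quaternions",
                             data=np.stack([p.true_quaternion
                                            for p in patterns]))
        geo = fh.create_group("geometry")
        geo.attrs["n_fast"] = geom.n_fast
        geo.attrs["n_slow"] = geom.n_slow
        geo.attrs["pixel_size"] = geom.pixel_size
        geo.attrs["distance"] = geom.distance
        geo.attrs["gap_rows"] = geom.gap_rows
        geo.attrs["wavelength"] = geom.wavelength


def read_patterns(path):
    with h5py.File(path, "r") as fh:
        _check_version(fh)
        g = fh["patterns"]
        counts = g["counts"][...]
        mask = g["mask"][...].astype(bool)
        seeds = g["seeds"][...]
        quats = g["true_quaternions"][...] if "true_quaternions" in g else None
        geo = fh["geometry"]
        geom = DetectorGeometry(
            n_fast=int(geo.attrs["n_fast"]), n_slow=int(geo.attrs["n_slow"]),
            pixel_size=float(geo.attrs["pixel_size"]),
            distance=float(geo.attrs["distance"]),
            gap_rows=int(geo.attrs["gap_rows"]),
            wavelength=float(geo.attrs["wavelength"]), mask=mask)
    patterns = [DiffractionPattern(
        counts=counts[i], mask=mask,
        true_quaternion=None if quats is None else quats[i],
        seed=int(seeds[i])) for i in range(len(counts))]
    return patterns, geom


def write_volume(path, volume: IntensityVolume, trace=None) -> None:
    if not np.all(np.isfinite(volume.grid)):
        raise ValueError("refusing to write non-finite intensity volume")
    with h5py.File(path, "w") as fh:
        _stamp(fh)
        g = fh.create_group("volume")
        g.create_dataset("intensity", data=volume.grid)
        g.create_dataset("measured", data=volume.measured)
        g.attrs["dq"] = volume.dq
        if trace is not None:
            g.create_dataset("trace", data=np.asarray(trace))


def read_volume(path):
    with h5py.File(path, "r") as fh:
        _check_version(fh)
        g = fh["volume"]
        vol = IntensityVolume(grid=g["intensity"][...],
                              dq=float(g.attrs["dq"]),
                              measured=g["measured"][...].astype(bool))
        trace = g["trace"][...] if "trace" in g else None
    return vol, trace


def write_density(path, density: DensityVolume, curve: ShellCurve = None) -> None:
    if not np.all(np.isfinite(density.grid)):
        raise ValueError("refusing to write non-finite density volume")
    with h5py.File(path, "w") as fh:
        _stamp(fh)
        g = fh.create_group("density")
        g.create_dataset("grid", data=density.grid)
        g.create_dataset("support", data=density.support.grid)
        if curve is not None:
            write_curve_group(g.create_group("prtf"), curve)


def read_density(path):
    with h5py.File(path, "r") as fh:
        _check_version(fh)
        g = fh["density"]
        dens = DensityVolume(grid=g["grid"][...],
                             support=SupportMask(grid=g["support"][...]))
        curve = read_curve_group(g["prtf"]) if "prtf" in g else None
    return dens, curve


def write_curve_group(group, curve: ShellCurve) -> None:
    group.create_dataset("q", data=curve.q_centers)
    group.create_dataset("value", data=curve.values)
    group.create_dataset("error", data=curve.errors)
    group.create_dataset("count", data=curve.counts)


def read_curve_group(group) -> ShellCurve:
    return ShellCurve(q_centers=group["q"][...], values=group["value"][...],
                      errors=group["error"][...], counts=group["count"][...])


def write_curve(path, curve: ShellCurve) -> None:
    with h5py.File(path, "w") as fh:
        _stamp(fh)
        write_curve_group(fh.create_group("curve"), curve)


def read_curve(path) -> ShellCurve:
    with h5py.File(path, "r") as fh:
        _check_version(fh)
        return read_curve_group(fh["curve"])
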