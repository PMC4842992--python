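"""Forward diffraction model: detector geometry, Ewald-sphere q-map,
coherent (Rayleigh) and incoherent (Compton) intensities, fluence-weighted
time integration over a damage trajectory, and Poisson photon sampling.

Conventions: q in 1/Angstrom with the 2*pi convention; the incident beam
runs along +z; pixel indexing is 0-based with the fast axis = x
(horizontal); polarization is horizontal linear.  The effective elastic
form factor of a damaged atom is (bound/Z) * f_neutral (uniform depletion);
the bound-electron Compton term scales the same way, and each free electron
contributes a flat (Thomson-like) unit term.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import atomic
from .atomic import AtomicSystem
from .damage import DamageTrajectory, Snapshot
from .pulse import BeamAtSample, Pulse

DEFAULT_N_PIXELS = 81
DEFAULT_PIXEL_SIZE_M = 300e-6
DEFAULT_GAP_ROWS = 7
DEFAULT_CORNER_RESOLUTION_A = 3.0


@dataclass
class DetectorGeometry:
    """Flat square detector normal to the beam with a central row gap."""

    n_fast: int
    n_slow: int
    pixel_size: float        # m
    distance: float          # m
    gap_rows: int            # central unusable rows
    wavelength: float        # Angstrom
    mask: np.ndarray = None  # (n_slow, n_fast) bool, True = usable

    def __post_init__(self):
        if self.pixel_size <= 0 or self.distance <= 0:
            raise ValueError("pixel_size and distance must be positive")
        gap_mask = np.ones((self.n_slow, self.n_fast), dtype=bool)
        if self.gap_rows > 0:
            c = (self.n_slow - 1) / 2.0
            half = self.gap_rows / 2.0
            rows = np.arange(self.n_slow)
            gap_mask[np.abs(rows - c) < half, :] = False
        if self.mask is None:
            self.mask = gap_mask
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & gap_mask

    @classmethod
    def from_corner_resolution(cls, n: int = DEFAULT_N_PIXELS,
                               pixel_size: float = DEFAULT_PIXEL_SIZE_M,
                               photon_energy: float = 5000.0,
                               corner_resolution: float = DEFAULT_CORNER_RESOLUTION_A,
                               gap_rows: int = DEFAULT_GAP_ROWS) -> "DetectorGeometry":
        """Choose the sample-detector distance so the detector's diagonal
        corner reaches the given full-period resolution (Angstrom)."""
        lam = atomic.wavelength_angstrom(photon_energy)
        sin_theta = lam / (2.0 * corner_resolution)
        if sin_theta >= 1.0:
            raise ValueError("corner resolution finer than the wavelength limit")
        two_theta = 2.0 * np.arcsin(sin_theta)
        r_corner = (n - 1) / 2.0 * pixel_size * np.sqrt(2.0)
        distance = r_corner / np.tan(two_theta)
        return cls(n_fast=n, n_slow=n, pixel_size=pixel_size,
                   distance=distance, gap_rows=gap_rows, wavelength=lam)


@dataclass
class QMap:
    """Per-pixel scattering vectors, solid angles and polarization."""

    q_vectors: np.ndarray    # (n_slow, n_fast, 3), 1/Angstrom
    solid_angle: np.ndarray  # (n_slow, n_fast), sr
    polarization: np.ndarray  # (n_slow, n_fast), in (0, 1]
    wavelength: float

    @property
    def q_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.q_vectors, axis=-1)

    @property
    def q_max(self) -> float:
        return float(self.q_magnitude.max())


def build_qmap(geom: DetectorGeometry) -> QMap:
    """Ewald-sphere mapping: q = (2 pi / lambda)(k_out - k_in) at pixel
    centres, solid angle = A cos^3(theta) / L^2, horizontal-polarization
    factor 1 - (k_out . x)^2.
    """
    cy = (geom.n_slow - 1) / 2.0
    cx = (geom.n_fast - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(geom.n_slow), np.arange(geom.n_fast),
                         indexing="ij")
    x = (ii - cx) * geom.pixel_size
    y = (jj - cy) * geom.pixel_size
    z = np.full_like(x, geom.distance)
    norm = np.sqrt(x**2 + y**2 + z**2)
    kout = np.stack([x / norm, y / norm, z / norm], axis=-1)
    kin = np.array([0.0, 0.0, 1.0])
    q = (2.0 * np.pi / geom.wavelength) * (kout - kin)
    cos_theta = z / norm
    solid = geom.pixel_size**2 * cos_theta**3 / geom.distance**2
    pol = 1.0 - kout[..., 0] ** 2
    return QMap(q_vectors=q, solid_angle=solid, polarization=pol,
                wavelength=geom.wavelength)


def quaternion_to_matrix(quat) -> np.ndarray:
    """Rotation matrix from a (w, x, y, z) unit quaternion."""
    quat = np.asarray(quat, dtype=float)
    n = np.linalg.norm(quat)
    if abs(n - 1.0) > 1e-6:
        raise ValueError("orientation must be a unit quaternion")
    w, x, y, z = quat / n
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _element_tables(system: AtomicSystem, q_abs: np.ndarray, table):
    """Per-unique-element lookup of a |q|-dependent table, returned as a
    dict z -> array shaped like q_abs."""
    return {int(z): table(int(z), q_abs) for z in np.unique(system.elements)}


def coherent_amplitude(snapshot: Snapshot | None, system: AtomicSystem,
                       qmap: QMap, orientation,
                       chunk: int = 512) -> np.ndarray:
    """Complex coherent scattering amplitude F(q) per pixel (electrons)."""
    rot = quaternion_to_matrix(orientation)
    pos = snapshot.positions if snapshot is not None else system.positions
    bound = (snapshot.bound_electrons if snapshot is not None
             else system.bound_electrons)
    shape = qmap.q_vectors.shape[:-1]
    qv = qmap.q_vectors.reshape(-1, 3) @ rot  # q . (R r) = (R^T q) . r
    q_abs = np.linalg.norm(qv, axis=1)
    ff = _element_tables(system, q_abs, atomic.form_factor)
    amp = np.zeros(qv.shape[0], dtype=complex)
    occ = bound / system.elements
    for start in range(0, system.n_atoms, chunk):
        sl = slice(start, start + chunk)
        phase = np.exp(1j * (qv @ pos[sl].T))  # (n_pix, n_atoms_chunk)
        w = np.stack([ff[int(z)] for z in system.elements[sl]], axis=1) \
            * occ[sl][None, :]
        amp += (phase * w).sum(axis=1)
    return amp.reshape(shape)


def coherent_intensity(snapshot: Snapshot | None, system: AtomicSystem,
                       qmap: QMap, orientation) -> np.ndarray:
    """Per-pixel coherent intensity per unit fluence (photons per
    photon/nm^2): r_e^2 * dOmega * P * |F|^2."""
    amp = coherent_amplitude(snapshot, system, qmap, orientation)
    return atomic.R_E_NM**2 * qmap.solid_angle * qmap.polarization \
        * np.abs(amp) ** 2


def incoherent_intensity(snapshot: Snapshot | None, system: AtomicSystem,
                         qmap: QMap) -> np.ndarray:
    """Per-pixel incoherent (Compton) intensity per unit fluence:
    r_e^2 * dOmega * P * [sum_j (bound_j/Z_j) S_j(|q|) + n_free].
    Azimuthally isotropic up to the polarization factor."""
    q_abs = qmap.q_magnitude
    bound = (snapshot.bound_electrons if snapshot is not None
             else system.bound_electrons)
    n_free = snapshot.n_free if snapshot is not None else 0
    tables = _element_tables(system, q_abs, atomic.incoherent_structure_factor)
    s_tot = np.zeros_like(q_abs)
    occ = bound / system.elements
    for z in np.unique(system.elements):
        sel = system.elements == z
        s_tot += occ[sel].sum() * tables[int(z)]
    s_tot += float(n_free)
    return atomic.R_E_NM**2 * qmap.solid_angle * qmap.polarization * s_tot


def pattern_expectation(traj: DamageTrajectory, system: AtomicSystem,
                        pulse: Pulse, beam: BeamAtSample,
                        geom: DetectorGeometry, orientation,
                        include_compton: bool = True,
                        qmap: QMap | None = None) -> np.ndarray:
    """Per-pixel mean photon count for one shot: the fluence-weighted sum of
    per-snapshot coherent (+ optional incoherent) intensities, zeroed on
    masked pixels."""
    times = np.array([s.time for s in traj.snapshots])
    if times[0] < pulse.times[0] - pulse.dt or \
            times[-1] > pulse.times[-1] + pulse.dt:
        raise ValueError("trajectory and pulse cover different time windows")
    if qmap is None:
        qmap = build_qmap(geom)
    total = np.zeros(qmap.solid_angle.shape)
    for snap in traj.snapshots:
        fl = snap.weight * beam.peak_fluence
        if fl == 0:
            continue
        contrib = coherent_intensity(snap, system, qmap, orientation)
        if include_compton:
            contrib = contrib + incoherent_intensity(snap, system, qmap)
        total += fl * contrib
    total[~geom.mask] = 0.0
    return total


@dataclass
class DiffractionPattern:
    """Integer photon counts on a gapped detector."""

    counts: np.ndarray              # (n_slow, n_fast) int
    mask: np.ndarray                # True = usable
    true_quaternion: np.ndarray = None  # (w, x, y, z), optional
    expected: np.ndarray = None     # per-pixel means, optional
    seed: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts[~self.mask] != 0):
            raise ValueError("masked pixels must have zero counts")


def sample_pattern(expected: np.ndarray, seed: int = 0,
                   mask: np.ndarray = None,
                   true_quaternion=None) -> DiffractionPattern:
    """Independent Poisson draw per unmasked pixel; deterministic per seed."""
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected photon counts must be non-negative")
    if mask is None:
        mask = np.ones(expected.shape, dtype=bool)
    rng = np.random.default_rng(seed)
    counts = np.zeros(expected.shape, dtype=np.int64)
    counts[mask] = rng.poisson(expected[mask])
    return DiffractionPattern(counts=counts, mask=mask,
                              true_quaternion=None if true_quaternion is None
                              else np.asarray(true_quaternion, dtype=float),
                              expected=expected, seed=seed)
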