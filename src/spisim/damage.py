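"""Radiation-damage engine: stochastic ionisation plus classical dynamics.

A reduced atomistic model.  Per fluence slice, photoionisation events
are drawn per atom as Poisson with mean sigma(Z, charge) * slice fluence,
where the cross section scales linearly with the remaining bound-electron
count (uniform depletion).  Each event ejects one bound electron (K shell
preferred when energetically allowed); a K core hole schedules an Auger
ejection after an exponential lifetime.  Ions and free electrons are
advanced by velocity-Verlet under softened Coulomb forces; electrons beyond
the escape radius with positive total energy are removed and counted as
escaped.  Everything is deterministic for a fixed seed.

This engine targets desk-scale systems (tens of atoms); the frozen-atom
closed form :func:`estimate_photoionisations` covers full-size molecules.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from . import atomic
from .atomic import AtomicSystem
from .pulse import BeamAtSample, Pulse, fluence_in_slice

DEFAULT_N_SLICES = 100
DEFAULT_MD_DT_FS = 0.010        # 10 attoseconds
COULOMB_SOFTENING_A = 0.1       # Angstrom
ESCAPE_RADIUS_FACTOR = 1.5
MIN_ESCAPE_RADIUS_A = 5.0


@dataclass
class Snapshot:
    """Sample state in one fluence slice."""

    time: float                    # fs (slice midpoint)
    positions: np.ndarray          # Angstrom, (n, 3)
    bound_electrons: np.ndarray    # (n,)
    n_free: int                    # free electrons still inside the sample region
    weight: float                  # fraction of the total fluence in this slice
    n_escaped: int = 0             # electrons removed so far


@dataclass
class DamageTrajectory:
    snapshots: list
    n_photoionisations: int
    seed: int = 0

    def __post_init__(self):
        t = [s.time for s in self.snapshots]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("snapshot times must be strictly increasing")


def dose_ggy(n_events: float, photon_energy: float,
             molecular_mass: float) -> float:
    """Absorbed dose in GGy if every absorbed photon's energy stays in the
    sample: n_events * E_photon / mass.
    """
    if molecular_mass <= 0:
        raise ValueError("molecular mass must be positive")
    if photon_energy <= 0:
        raise ValueError("photon energy must be positive")
    if n_events < 0:
        raise ValueError("event count must be non-negative")
    joules = n_events * photon_energy * atomic.EV_J
    kg = molecular_mass * atomic.DA_KG
    return joules / kg / 1e9


def estimate_photoionisations(system: AtomicSystem,
                              beam: BeamAtSample) -> float:
    """Frozen-atom (no depletion) expected photoionisation count for one
    shot at the peak of the focus: sum_j sigma(Z_j) * F_peak.

    Overestimates a damage simulation because ionised atoms absorb less.
    """
    sig = np.array([atomic.photo_cross_section_nm2(z, beam.photon_energy)
                    for z in system.elements])
    occ = system.bound_electrons / system.elements
    return float((sig * occ).sum() * beam.peak_fluence)


class _State:
    """Mutable particle state during a trajectory run."""

    def __init__(self, system: AtomicSystem, rng: np.random.Generator):
        self.rng = rng
        self.z = system.elements.copy()
        self.pos = system.positions.astype(float).copy()
        self.vel = np.zeros_like(self.pos)
        self.bound = system.bound_electrons.astype(float).copy()
        self.k_occ = np.minimum(2, self.z).astype(float)
        self.masses = system.masses.copy()
        self.e_pos = np.zeros((0, 3))
        self.e_vel = np.zeros((0, 3))
        self.n_escaped = 0
        self.auger_queue: list = []   # heap of (due_time, counter, atom)
        self._auger_counter = 0
        center = self.pos.mean(axis=0) if len(self.pos) else np.zeros(3)
        self.center = center
        self.escape_radius = max(MIN_ESCAPE_RADIUS_A,
                                 ESCAPE_RADIUS_FACTOR * _radius(self.pos, center))

    @property
    def charges(self) -> np.ndarray:
        return self.z - self.bound

    def eject(self, j: int, kinetic_ev: float, from_k: bool):
        """Remove one bound electron from atom j and spawn a free electron."""
        self.bound[j] -= 1.0
        if from_k:
            self.k_occ[j] -= 1.0
        direction = self.rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        speed = np.sqrt(max(2.0 * kinetic_ev * atomic.ACC_EV_A_DA
                            / atomic.ELECTRON_MASS_DA, 0.0))
        self.e_pos = np.vstack([self.e_pos, self.pos[j] + 0.05 * direction])
        self.e_vel = np.vstack([self.e_vel, speed * direction])


def _radius(pos: np.ndarray, center: np.ndarray) -> float:
    if len(pos) == 0:
        return 0.0
    return float(np.linalg.norm(pos - center, axis=1).max())


def _forces(state: _State):
    """Softened Coulomb forces on ions and free electrons (eV/Angstrom)."""
    q = np.concatenate([state.charges, -np.ones(len(state.e_pos))])
    r = np.vstack([state.pos, state.e_pos])
    n = len(q)
    if n == 0 or not np.any(q):
        return np.zeros_like(state.pos), np.zeros_like(state.e_pos)
    diff = r[:, None, :] - r[None, :, :]
    d2 = (diff ** 2).sum(-1) + COULOMB_SOFTENING_A ** 2
    np.fill_diagonal(d2, np.inf)
    f = atomic.K_COULOMB * (q[:, None] * q[None, :])[..., None] \
        * diff / d2[..., None] ** 1.5
    ftot = f.sum(axis=1)
    na = len(state.pos)
    return ftot[:na], ftot[na:]


def _potential_energy_of_electron(state: _State, i: int) -> float:
    q = np.concatenate([state.charges, -np.ones(len(state.e_pos))])
    r = np.vstack([state.pos, state.e_pos])
    me = len(state.pos) + i
    d = np.linalg.norm(r - r[me], axis=1)
    d[me] = np.inf
    return float(atomic.K_COULOMB * (-1.0) *
                 (q / np.sqrt(d**2 + COULOMB_SOFTENING_A**2)).sum())


def _md_advance(state: _State, t0: float, t1: float, dt: float):
    """Velocity-Verlet from t0 to t1.  Exactly static while nothing is
    charged (the zero-fluence limit)."""
    if not np.any(state.charges) and len(state.e_pos) == 0:
        return
    n_steps = max(1, int(np.ceil((t1 - t0) / dt)))
    h = (t1 - t0) / n_steps
    fa, fe = _forces(state)
    inv_ma = atomic.ACC_EV_A_DA / state.masses[:, None]
    inv_me = atomic.ACC_EV_A_DA / atomic.ELECTRON_MASS_DA
    for _ in range(n_steps):
        state.vel += 0.5 * h * fa * inv_ma
        state.pos += h * state.vel
        if len(state.e_pos):
            state.e_vel += 0.5 * h * fe * inv_me
            state.e_pos += h * state.e_vel
        fa, fe = _forces(state)
        state.vel += 0.5 * h * fa * inv_ma
        if len(state.e_pos):
            state.e_vel += 0.5 * h * fe * inv_me
    _remove_escaped(state)


def _remove_escaped(state: _State):
    if not len(state.e_pos):
        return
    keep = np.ones(len(state.e_pos), dtype=bool)
    dist = np.linalg.norm(state.e_pos - state.center, axis=1)
    for i in np.nonzero(dist > state.escape_radius)[0]:
        ke = 0.5 * atomic.ELECTRON_MASS_DA \
            * (state.e_vel[i] ** 2).sum() / atomic.ACC_EV_A_DA
        if ke + _potential_energy_of_electron(state, i) > 0:
            keep[i] = False
    state.n_escaped += int((~keep).sum())
    state.e_pos = state.e_pos[keep]
    state.e_vel = state.e_vel[keep]


def _apply_auger(state: _State, now: float):
    while state.auger_queue and state.auger_queue[0][0] <= now:
        _, _, j = heapq.heappop(state.auger_queue)
        # hole may have been refilled/emptied by later events
        if state.k_occ[j] >= 2 or state.bound[j] < 2:
            continue
        e_kin = max(atomic.K_BINDING_EV.get(int(state.z[j]), 0.0) - 40.0, 10.0)
        state.k_occ[j] += 1.0      # one valence electron fills the hole ...
        state.eject(j, e_kin, from_k=False)  # ... another is ejected


def run_trajectory(system: AtomicSystem, pulse: Pulse, beam: BeamAtSample,
                   n_slices: int = DEFAULT_N_SLICES, seed: int = 0,
                   md_dt: float = DEFAULT_MD_DT_FS) -> DamageTrajectory:
    """Monte-Carlo ionisation + molecular dynamics over one pulse.

    Snapshots are taken at slice midpoints, each weighted by the fraction of
    the total fluence delivered in its slice.
    """
    if system.n_atoms == 0:
        raise ValueError("system must contain at least one atom")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    rng = np.random.default_rng(seed)
    state = _State(system, rng)
    edges = np.linspace(pulse.times[0], pulse.times[-1] + pulse.dt,
                        n_slices + 1)
    sigma0 = np.array([atomic.photo_cross_section_nm2(z, beam.photon_energy)
                       for z in system.elements])
    tau = np.array([atomic.AUGER_LIFETIME_FS.get(int(z), np.inf)
                    for z in system.elements])
    snapshots = []
    n_events_total = 0
    t_prev = edges[0]
    for s in range(n_slices):
        t0, t1 = edges[s], edges[s + 1]
        fl = fluence_in_slice(pulse, beam, t0, t1)
        # zero-intensity pulse: fall back to uniform time weights so the
        # trajectory still integrates to one
        weight = fl / beam.peak_fluence if beam.peak_fluence > 0 \
            else 1.0 / n_slices
        mean = sigma0 * (state.bound / state.z) * fl
        n_events = rng.poisson(mean)
        # events applied in atom-index order (slice-level tie-break)
        for j in np.nonzero(n_events)[0]:
            for _ in range(int(n_events[j])):
                if state.bound[j] < 1:
                    continue
                n_events_total += 1
                from_k = (state.k_occ[j] > 0 and beam.photon_energy
                          > atomic.K_BINDING_EV.get(int(state.z[j]), 1e9))
                e_kin = beam.photon_energy - atomic.binding_energy_ev(
                    int(state.z[j]), beam.photon_energy)
                state.eject(j, max(e_kin, 1.0), from_k=from_k)
                if from_k and np.isfinite(tau[j]) and state.bound[j] >= 2:
                    due = t0 + rng.exponential(tau[j])
                    heapq.heappush(state.auger_queue,
                                   (due, state._auger_counter, j))
                    state._auger_counter += 1
        _apply_auger(state, t1)
        _md_advance(state, t_prev, t1, md_dt)
        t_prev = t1
        snapshots.append(Snapshot(
            time=0.5 * (t0 + t1),
            positions=state.pos.copy(),
            bound_electrons=state.bound.copy(),
            n_free=len(state.e_pos),
            weight=float(weight),
            n_escaped=state.n_escaped,
        ))
    return DamageTrajectory(snapshots=snapshots,
                            n_photoionisations=n_events_total, seed=seed)


def damage_diagnostics(traj: DamageTrajectory, system: AtomicSystem) -> dict:
    """Per-element mean displacement (Angstrom) and mean bound-electron
    count per snapshot; keys are atomic numbers, values dicts with
    ``times``, ``displacement`` and ``bound_electrons`` arrays.
    """
    if not traj.snapshots:
        raise ValueError("trajectory has no snapshots")
    times = np.array([s.time for s in traj.snapshots])
    out = {}
    for z in np.unique(system.elements):
        sel = system.elements == z
        ref = system.positions[sel]
        disp = np.array([np.linalg.norm(s.positions[sel] - ref, axis=1).mean()
                         for s in traj.snapshots])
        nb = np.array([s.bound_electrons[sel].mean() for s in traj.snapshots])
        out[int(z)] = {"times": times, "displacement": disp,
                       "bound_electrons": nb}
    return out
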