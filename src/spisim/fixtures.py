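"""Deterministic synthetic inputs: toy molecules, a synthetic 64 kDa
protein-scale composition, and known-orientation photon-limited pattern
sets for orientation-recovery benchmarks.  Nothing here requires a
download.
"""
from __future__ import annotations

import numpy as np

from .atomic import AtomicSystem
from .diffraction import (DetectorGeometry, build_qmap, coherent_intensity,
                          incoherent_intensity, sample_pattern)
from .emc import quaternion_multiply, sample_rotations

# desk-scale defaults (scaled-down stand-ins for a 4,735-atom molecule,
# 200,000 patterns and a 77^3 merge grid)
DESK_N_ATOMS = 20
DESK_CLUSTER_RADIUS_A = 8.0
DESK_DETECTOR_N = 41
DESK_N_PATTERNS = 2000
DESK_GRID_N = 33
# a 150-rotation quadrature (~38 deg spacing) is too coarse to discriminate
# tomograms on this detector; 600 (~26 deg) recovers orientations reliably
DESK_N_ROTATIONS = 600
DESK_PHOTONS_PER_PATTERN = 200.0

#: protein-like heavy-atom composition by count (C : N : O : S)
PROTEIN_COMPOSITION = {6: 32, 7: 9, 8: 10, 16: 1}

#: synthetic stand-in for a 64 kDa iron-protein: 4,735 non-hydrogen atoms
#: with a 4Fe-4S-like metal content; hydrogens enter only via the mass.
PROTEIN_64KDA = {"n_atoms": 4735,
                 "counts": {6: 2993, 7: 810, 8: 904, 16: 24, 26: 4},
                 "molecular_mass": 64000.0}


def _cluster(n: int, radius: float, counts: dict,
             rng: np.random.Generator) -> AtomicSystem:
    probs = np.array(list(counts.values()), dtype=float)
    elements = rng.choice(list(counts.keys()), size=n, p=probs / probs.sum())
    # uniform in a ball
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return AtomicSystem(elements=elements, positions=d * r[:, None])


def make_fixture(name: str, seed: int = 0, n: int = DESK_N_ATOMS,
                 radius: float = DESK_CLUSTER_RADIUS_A) -> AtomicSystem:
    """Named deterministic toy molecules.

    point          one C atom at the origin
    pair           two C atoms 10 Angstrom apart along x
    tetrahedron    four C atoms, all pairwise distances 5 Angstrom
    random-cluster n atoms uniform in a sphere, protein C:N:O:S = 32:9:10:1
    protein-64kda  synthetic 4,735-atom, 64 kDa stand-in composition
    """
    rng = np.random.default_rng(seed)
    if name == "point":
        return AtomicSystem(elements=[6], positions=[[0.0, 0.0, 0.0]])
    if name == "pair":
        return AtomicSystem(elements=[6, 6],
                            positions=[[-5.0, 0, 0], [5.0, 0, 0]])
    if name == "tetrahedron":
        e = 5.0
        verts = e / np.sqrt(2.0) / 2.0 * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        return AtomicSystem(elements=[6] * 4, positions=verts)
    if name == "random-cluster":
        return _cluster(n, radius, PROTEIN_COMPOSITION, rng)
    if name == "protein-64kda":
        recipe = PROTEIN_64KDA
        vol = recipe["n_atoms"] * 9.9  # ~1 heavy atom per 9.9 A^3 of protein
        r = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        elements = np.concatenate([np.full(c, z)
                                   for z, c in recipe["counts"].items()])
        rng.shuffle(elements)
        d = rng.normal(size=(len(elements), 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        rr = r * rng.random(len(elements)) ** (1.0 / 3.0)
        return AtomicSystem(elements=elements, positions=d * rr[:, None],
                            molecular_mass=recipe["molecular_mass"])
    raise ValueError(
        f"unknown fixture {name!r}; known: point, pair, tetrahedron, "
        "random-cluster, protein-64kda")


def desk_detector(n: int = DESK_DETECTOR_N) -> DetectorGeometry:
    """The desk-scale detector: n x n pixels, 7-row central gap, corner at
    ~3 Angstrom full-period resolution for 5 keV photons."""
    return DetectorGeometry.from_corner_resolution(n=n)


def make_known_orientation_patterns(system: AtomicSystem,
                                    geom: DetectorGeometry,
                                    n_patterns: int = DESK_N_PATTERNS,
                                    photons_per_pattern: float = DESK_PHOTONS_PER_PATTERN,
                                    seed: int = 0,
                                    include_compton: bool = False):
    """Undamaged, single-snapshot patterns at known orientations.

    Orientations are quasi-uniform over SO(3) (randomly re-oriented as an
    ensemble per seed); intensities are scaled so the mean expected photon
    count per pattern equals ``photons_per_pattern``, then Poisson sampled.
    Returns a list of DiffractionPattern with ``true_quaternion`` set.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    if photons_per_pattern < 0:
        raise ValueError("photons_per_pattern must be >= 0")
    rng = np.random.default_rng(seed)
    qmap = build_qmap(geom)
    quats = sample_rotations(n_patterns, scheme="quasi-uniform").quaternions
    # random global re-orientation keeps the set quasi-uniform but seeded
    u1, u2, u3 = rng.random(3)
    g = np.array([np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
                  np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
                  np.sqrt(u1) * np.sin(2 * np.pi * u3),
                  np.sqrt(u1) * np.cos(2 * np.pi * u3)])
    quats = np.array([quaternion_multiply(g, q) for q in quats])
    base = incoherent_intensity(None, system, qmap) if include_compton else 0.0
    expectations = []
    for quat in quats:
        exp = coherent_intensity(None, system, qmap, quat) + base
        exp[~geom.mask] = 0.0
        expectations.append(exp)
    mean_total = np.mean([e.sum() for e in expectations])
    scale = photons_per_pattern / mean_total if mean_total > 0 else 0.0
    seeds = np.random.SeedSequence(seed).generate_state(n_patterns) % (2**31)
    return [sample_pattern(e * scale, seed=int(s), mask=geom.mask,
                           true_quaternion=q)
            for e, s, q in zip(expectations, seeds, quats)]
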