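"""Figures of merit: mutual volume alignment, the q-resolved coefficient of
variation across independent reconstructions, the phase-retrieval transfer
function (PRTF), and the resolution at half-PRTF.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .emc import IntensityVolume, RotationSet, geodesic_angle

logger = logging.getLogger(__name__)


@dataclass
class ShellCurve:
    """A shell-averaged radial curve with per-shell scatter and counts."""

    q_centers: np.ndarray   # 1/Angstrom, increasing
    values: np.ndarray
    errors: np.ndarray      # per-shell standard deviation
    counts: np.ndarray      # voxels per shell

    def __post_init__(self):
        if np.any(np.diff(self.q_centers) <= 0):
            raise ValueError("q_centers must be increasing")


def _shell_index(n: int, dq: float):
    c = (n - 1) // 2
    ax = np.arange(n) - c
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    q = dq * np.sqrt(gx**2 + gy**2 + gz**2)
    return np.rint(q / dq).astype(int), q


def shell_average(values: np.ndarray, dq: float,
                  include: np.ndarray = None) -> ShellCurve:
    """Azimuthal average over one-voxel-wide resolution shells, with the
    per-shell standard deviation as the error bar."""
    n = values.shape[0]
    shell, _ = _shell_index(n, dq)
    if include is None:
        include = np.ones(values.shape, dtype=bool)
    n_shell = shell.max() + 1
    qc, val, err, cnt = [], [], [], []
    for s in range(n_shell):
        sel = (shell == s) & include
        m = int(sel.sum())
        if m == 0:
            continue
        v = values[sel]
        qc.append(s * dq)
        val.append(v.mean())
        err.append(v.std())
        cnt.append(m)
    return ShellCurve(q_centers=np.array(qc), values=np.array(val),
                      errors=np.array(err), counts=np.array(cnt, dtype=int))


def _rotate_grid(grid: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Resample a centred cubic grid under a rotation (trilinear)."""
    n = grid.shape[0]
    c = (n - 1) / 2.0
    offset = c - rot.T @ np.full(3, c)
    return ndimage.affine_transform(grid, rot.T, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def _corr(a: np.ndarray, b: np.ndarray, mask: np.ndarray = None) -> float:
    if mask is not None:
        a, b = a[mask], b[mask]
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / den) if den > 0 else 0.0


def _ball_mask(n: int) -> np.ndarray:
    """Inscribed ball: rotations resample it without clipping corners."""
    c = (n - 1) / 2.0
    ax = np.arange(n) - c
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    return gx**2 + gy**2 + gz**2 <= c**2


def align_volumes(volumes, rotations: RotationSet, refine: bool = True):
    """Mutually align intensity volumes to the first by searching the
    rotation quadrature (plus the inversion branch and an optional local
    refinement) for the maximum real-space correlation.

    Returns ``(aligned_volumes, chosen)`` where ``chosen`` is a list of
    (quaternion, inverted) per volume.
    """
    volumes = list(volumes)
    if len(volumes) < 2:
        raise ValueError("need at least two volumes to align")
    n = volumes[0].n
    if any(v.n != n or not np.isclose(v.dq, volumes[0].dq) for v in volumes):
        raise ValueError("volumes must share one grid")
    ref = volumes[0].grid
    ball = _ball_mask(n)
    aligned = [volumes[0]]
    chosen = [(np.array([1.0, 0, 0, 0]), False)]
    # search the quadrature, its inverses and the identity so that an applied
    # quadrature misrotation (or none) is recovered exactly
    identity = np.array([[1.0, 0.0, 0.0, 0.0]])
    inverses = rotations.quaternions * np.array([1.0, -1.0, -1.0, -1.0])
    candidates = np.vstack([identity, rotations.quaternions, inverses])
    for vol in volumes[1:]:
        best = (-np.inf, None, False, None)
        for inverted in (False, True):
            g = vol.grid[::-1, ::-1, ::-1] if inverted else vol.grid
            for quat in candidates:
                rot = Rotation.from_quat(quat, scalar_first=True).as_matrix()
                cand = _rotate_grid(g, rot)
                c = _corr(ref, cand, ball)
                if c > best[0]:
                    best = (c, quat, inverted, cand)
        c0, quat, inverted, cand = best
        if refine:
            g = vol.grid[::-1, ::-1, ::-1] if inverted else vol.grid
            rot0 = Rotation.from_quat(quat, scalar_first=True)

            def neg_corr(delta):
                r = (Rotation.from_rotvec(delta) * rot0).as_matrix()
                return -_corr(ref, _rotate_grid(g, r), ball)

            res = optimize.minimize(neg_corr, np.zeros(3), method="Powell",
                                    options={"maxiter": 200, "xtol": 1e-4})
            if -res.fun > c0:
                rfin = Rotation.from_rotvec(res.x) * rot0
                quat = rfin.as_quat(scalar_first=True)
                cand = _rotate_grid(g, rfin.as_matrix())
        aligned.append(IntensityVolume(grid=np.maximum(cand, 0.0),
                                       dq=vol.dq))
        chosen.append((quat, inverted))
    return aligned, chosen


def coefficient_of_variation(volumes, population_std: bool = True):
    """q-resolved coefficient of variation across aligned reconstructions.

    Per voxel, sigma(q) = std_n I_n(q) / mean_n I_n(q); voxels with zero
    mean are excluded from the shell average (their count is logged).
    Returns ``(per_voxel_sigma, ShellCurve)``.
    """
    volumes = list(volumes)
    if len(volumes) < 2:
        raise ValueError("need at least two volumes")
    stack = np.stack([v.grid for v in volumes])
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=0 if population_std else 1)
    ok = mean > 0
    sigma = np.zeros_like(mean)
    sigma[ok] = std[ok] / mean[ok]
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("coefficient_of_variation: %d zero-mean voxels excluded",
                    n_excluded)
    curve = shell_average(sigma, volumes[0].dq, include=ok)
    return sigma, curve


def prtf(transforms, dq: float) -> ShellCurve:
    """Phase-retrieval transfer function: the shell-averaged modulus of the
    mean unit phasor over aligned reconstructions' Fourier transforms.

    ``transforms`` are centred (q = 0 at the central voxel) complex grids.
    Zero-amplitude voxels are excluded (logged).
    """
    transforms = list(transforms)
    if len(transforms) < 2:
        raise ValueError("PRTF needs at least two reconstructions")
    stack = np.stack(transforms)
    amp = np.abs(stack)
    ok = np.all(amp > 0, axis=0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("prtf: %d zero-amplitude voxels excluded", n_excluded)
    phasors = np.zeros_like(stack)
    np.divide(stack, amp, out=phasors, where=amp > 0)
    val = np.abs(phasors.mean(axis=0))
    return shell_average(val, dq, include=ok)


def resolution_at_half_prtf(curve: ShellCurve, dq: float = None):
    """Full-period resolution 2*pi/q* at the first 0.5 crossing of the PRTF
    (linear interpolation between shells).

    Returns ``(resolution_A, limited)``; ``limited`` is False when the curve
    never drops below 0.5, in which case the grid-edge resolution is given.
    """
    if len(curve.q_centers) == 0:
        raise ValueError("empty curve")
    v = curve.values
    q = curve.q_centers
    below = np.nonzero(v < 0.5)[0]
    if len(below) == 0 or below[0] == 0:
        if len(below) and below[0] == 0 and len(v) > 1:
            # starts below 0.5: resolution undefined beyond the first shell
            return 2.0 * np.pi / max(q[1], q[-1] * 1e-9), True
        q_edge = q[-1]
        return 2.0 * np.pi / q_edge, False
    i = below[0]
    q0, q1, v0, v1 = q[i - 1], q[i], v[i - 1], v[i]
    q_star = q0 + (v0 - 0.5) * (q1 - q0) / (v0 - v1)
    return 2.0 * np.pi / q_star, True


def acquisition_time_hours(n_patterns: int, rep_rate_hz: float,
                           hit_rate: float) -> float:
    """Beam time needed to collect n_patterns hits at a given pulse rate and
    hit fraction."""
    if rep_rate_hz <= 0 or not 0 < hit_rate <= 1:
        raise ValueError("need rep_rate_hz > 0 and hit_rate in (0, 1]")
    return n_patterns / (rep_rate_hz * hit_rate) / 3600.0
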