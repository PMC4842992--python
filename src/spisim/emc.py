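"""EMC orientation recovery: assemble photon-count patterns of unknown
orientation into a 3D intensity volume by expectation-maximisation over a
fixed SO(3) quadrature.

E-step: Poisson log-likelihood of each pattern against each rotation's
tomogram, log-domain and max-subtracted.  M-step + compression: instead of
the classic scatter/normalise heuristic, the 3D volume is updated by a few
Richardson-Lucy multiplicative steps of the EM Q-function under the linear
trilinear-expansion operator, started from the previous volume.  Each such
step provably does not decrease Q, so the data log-likelihood trace is
non-decreasing (up to floating point).  Friedel symmetrisation, on by
default, is folded into the linear operator and preserves this guarantee.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import logsumexp

from .diffraction import DiffractionPattern, QMap, quaternion_to_matrix

logger = logging.getLogger(__name__)

DEFAULT_N_ITER = 50
DEFAULT_TOL = 1e-4
DEFAULT_N_INNER = 8
DEFAULT_N_STARTS = 8       # random initialisations burnt in per run
DEFAULT_N_BURN = 12        # burn-in iterations before keeping the best
MIN_VOXEL_COVERAGE = 2.0   # summed trilinear weight per voxel
SUPER_FIB_PHI = np.sqrt(2.0)
SUPER_FIB_PSI = 1.533751168755204288118041


@dataclass
class RotationSet:
    """SO(3) quadrature: unit quaternions (w, x, y, z) with prior weights."""

    quaternions: np.ndarray   # (n_rot, 4)
    weights: np.ndarray       # (n_rot,), sums to 1

    def __post_init__(self):
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("quaternions must be unit-norm")
        if np.any(self.weights < 0) or \
                abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    @property
    def n_rot(self) -> int:
        return len(self.quaternions)


@dataclass
class IntensityVolume:
    """Cubic reciprocal-space intensity grid with q = 0 at the centre voxel."""

    grid: np.ndarray          # (n, n, n), non-negative
    dq: float                 # voxel spacing, 1/Angstrom
    measured: np.ndarray = None  # optional bool mask of constrained voxels

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        n = self.grid.shape[0]
        if self.grid.shape != (n, n, n) or n % 2 == 0:
            raise ValueError("grid must be cubic with odd edge length")
        if np.any(self.grid < 0):
            raise ValueError("intensities must be non-negative")
        if self.measured is None:
            self.measured = np.ones(self.grid.shape, dtype=bool)

    @property
    def n(self) -> int:
        return self.grid.shape[0]

    @property
    def center(self) -> int:
        return (self.n - 1) // 2


@dataclass
class OrientationPosterior:
    """Per-pattern probabilities over the rotation set."""

    probabilities: np.ndarray  # (n_patterns, n_rot)
    most_likely: np.ndarray    # (n_patterns,) rotation indices

    def __post_init__(self):
        s = self.probabilities.sum(axis=1)
        if np.any(np.abs(s - 1.0) > 1e-9):
            raise ValueError("posterior rows must sum to 1")


def geodesic_angle(q1, q2) -> np.ndarray:
    """Rotation angle (radians) between quaternions, double-cover aware."""
    dot = np.abs(np.sum(np.asarray(q1) * np.asarray(q2), axis=-1))
    return 2.0 * np.arccos(np.clip(dot, -1.0, 1.0))


def quaternion_multiply(a, b) -> np.ndarray:
    """Hamilton product of (w, x, y, z) quaternions."""
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2])


def quaternion_conjugate(q) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def orientation_errors(assigned, true_quaternions) -> np.ndarray:
    """Per-pattern angular errors (radians) between assigned and true
    orientations after removing the global rotation gauge.

    An EMC reconstruction is defined only up to one global rotation S; the
    assignments then satisfy assigned_d ~ true_d * g for a fixed right-gauge
    quaternion g.  Candidate gauges are taken from a subsample of patterns
    and the one minimising the median error is used.
    """
    assigned = np.asarray(assigned, dtype=float)
    true_quaternions = np.asarray(true_quaternions, dtype=float)
    best_err = None
    best_med = np.inf
    step = max(1, len(assigned) // 16)
    for i in range(0, len(assigned), step):
        g = quaternion_multiply(quaternion_conjugate(true_quaternions[i]),
                                assigned[i])
        pred = np.array([quaternion_multiply(t, g)
                         for t in true_quaternions])
        err = geodesic_angle(assigned, pred)
        med = float(np.median(err))
        if med < best_med:
            best_med, best_err = med, err
    return best_err


def sample_rotations(n_rot: int, scheme: str = "quasi-uniform",
                     seed: int = 0) -> RotationSet:
    """Unit quaternions covering SO(3) with uniform prior weights.

    'quasi-uniform' uses the deterministic super-Fibonacci spiral; 'random'
    draws Haar-uniform rotations (Shoemake) from the seed.
    """
    if n_rot < 1:
        raise ValueError("n_rot must be >= 1")
    if n_rot == 1:
        quats = np.array([[1.0, 0.0, 0.0, 0.0]])
    elif scheme == "quasi-uniform":
        i = np.arange(n_rot)
        s = i + 0.5
        t = s / n_rot
        d = 2.0 * np.pi * s
        r = np.sqrt(t)
        big_r = np.sqrt(1.0 - t)
        alpha = d / SUPER_FIB_PHI
        beta = d / SUPER_FIB_PSI
        quats = np.stack([r * np.sin(alpha), r * np.cos(alpha),
                          big_r * np.sin(beta), big_r * np.cos(beta)], axis=1)
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        u1, u2, u3 = rng.random((3, n_rot))
        quats = np.stack([
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3)], axis=1)
    else:
        raise ValueError(f"unknown rotation scheme: {scheme!r}")
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    weights = np.full(n_rot, 1.0 / n_rot)
    return RotationSet(quaternions=quats, weights=weights)


def volume_for_qmap(qmap: QMap, n: int = 33,
                    pad: float = 1.0) -> IntensityVolume:
    """An empty volume whose grid encloses the rotated detector q-range."""
    dq = pad * qmap.q_max / ((n - 1) / 2.0)
    return IntensityVolume(grid=np.zeros((n, n, n)), dq=dq)


def _trilinear_entries(points: np.ndarray, n: int):
    """Indices and weights of the 8 surrounding voxels for each point given
    in fractional grid coordinates; out-of-grid corners get weight 0."""
    base = np.floor(points).astype(int)
    frac = points - base
    n_pts = len(points)
    idx = np.empty((n_pts, 8), dtype=np.int64)
    wgt = np.empty((n_pts, 8))
    corner = 0
    for dx in (0, 1):
        wx = (1 - frac[:, 0]) if dx == 0 else frac[:, 0]
        for dy in (0, 1):
            wy = (1 - frac[:, 1]) if dy == 0 else frac[:, 1]
            for dz in (0, 1):
                wz = (1 - frac[:, 2]) if dz == 0 else frac[:, 2]
                gx, gy, gz = base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz
                inside = ((gx >= 0) & (gx < n) & (gy >= 0) & (gy < n)
                          & (gz >= 0) & (gz < n))
                flat = np.where(inside, (gx * n + gy) * n + gz, 0)
                idx[:, corner] = flat
                wgt[:, corner] = np.where(inside, wx * wy * wz, 0.0)
                corner += 1
    return idx, wgt


def build_expand_operator(rotations: RotationSet, qmap: QMap, n: int,
                          dq: float, pixel_mask: np.ndarray = None):
    """Sparse (n_rot * n_pix, n^3) trilinear sampling operator T such that
    W = T V evaluates the volume at every rotation's pixel q-vectors.

    Pixels whose rotated q falls outside the grid contribute zero (their
    dropped-weight count is logged).
    """
    qv = qmap.q_vectors.reshape(-1, 3)
    if pixel_mask is not None:
        qv = qv[pixel_mask.ravel()]
    n_pix = len(qv)
    center = (n - 1) / 2.0
    rows, cols, vals = [], [], []
    clipped = 0
    for r, quat in enumerate(rotations.quaternions):
        rot = quaternion_to_matrix(quat)
        pts = (qv @ rot) / dq + center     # molecule-frame coords R^T q
        idx, wgt = _trilinear_entries(pts, n)
        clipped += int(np.sum(wgt.sum(axis=1) < 1 - 1e-9))
        pix = np.repeat(np.arange(n_pix) + r * n_pix, 8)
        rows.append(pix)
        cols.append(idx.ravel())
        vals.append(wgt.ravel())
    if clipped:
        logger.info("expand operator: %d pixel samples partially outside "
                    "the grid (clamped to 0)", clipped)
    T = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(rotations.n_rot * n_pix, n * n * n))
    return T


def expand(volume: IntensityVolume, rotations: RotationSet,
           qmap: QMap) -> np.ndarray:
    """Tomograms W_rk: trilinear samples of the volume at every rotation's
    pixel q-vectors, shape (n_rot, n_slow, n_fast)."""
    T = build_expand_operator(rotations, qmap, volume.n, volume.dq)
    w = T @ volume.grid.ravel()
    return w.reshape(rotations.n_rot, *qmap.solid_angle.shape)


def friedel_symmetrize(grid: np.ndarray) -> np.ndarray:
    """Average the grid with its inversion through the central voxel."""
    return 0.5 * (grid + grid[::-1, ::-1, ::-1])


def emc_iterate(patterns, volume: IntensityVolume | None,
                rotations: RotationSet, qmap: QMap,
                n_iter: int = DEFAULT_N_ITER, tol: float = DEFAULT_TOL,
                seed: int = 0, friedel: bool = True,
                n_inner: int = DEFAULT_N_INNER, n_grid: int = 33,
                n_starts: int = DEFAULT_N_STARTS,
                n_burn: int = DEFAULT_N_BURN):
    """Run EMC.

    Parameters
    ----------
    patterns : sequence of DiffractionPattern sharing one geometry/mask.
    volume : starting IntensityVolume, or None for a random positive start
        (uniform in [0.5, 1.5) x mean counts per unmasked pixel, seeded).
    n_starts, n_burn : with a random start, ``n_starts`` independent
        initialisations are burnt in for ``n_burn`` iterations each and the
        one with the highest data log-likelihood is continued — EM can lock
        into a poor local optimum from an unlucky start, and the likelihood
        itself identifies such runs.

    Returns ``(volume, posterior, loglik_trace)``.  The trace is the total
    data log-likelihood (up to the pattern-factorial constant) at each
    iteration's E-step and is non-decreasing.
    """
    if volume is None and n_starts > 1 and n_iter > n_burn:
        ss = np.random.SeedSequence(seed)
        burn_seeds = ss.generate_state(n_starts).astype(np.int64) % (2**31)
        best = None
        for s in burn_seeds:
            cand = emc_iterate(patterns, None, rotations, qmap,
                               n_iter=n_burn, tol=0.0, seed=int(s),
                               friedel=friedel, n_inner=n_inner,
                               n_grid=n_grid, n_starts=1)
            if best is None or cand[2][-1] > best[2][-1]:
                best = cand
        vol, _, burn_trace = best
        vol, posterior, trace = emc_iterate(
            patterns, vol, rotations, qmap, n_iter=n_iter - n_burn,
            tol=tol, seed=seed, friedel=friedel, n_inner=n_inner,
            n_grid=n_grid, n_starts=1)
        logger.info("multi-start: best of %d burn-ins at loglik %.6g",
                    n_starts, burn_trace[-1])
        return vol, posterior, np.concatenate([burn_trace, trace])
    patterns = list(patterns)
    if not patterns:
        raise ValueError("need at least one pattern")
    mask = patterns[0].mask
    K = np.stack([p.counts[mask] for p in patterns]).astype(float)
    n_pat, n_pix = K.shape
    # per-pixel geometric factor (solid angle x polarization): pixel-
    # dependent but rotation-independent, so it multiplies the tomograms
    # rather than being absorbed into the volume
    fac = (qmap.solid_angle * qmap.polarization)[mask]
    fac = fac / fac.mean()

    if volume is None:
        volume = volume_for_qmap(qmap, n=n_grid)
        rng = np.random.default_rng(seed)
        mean_per_pix = max(K.mean(), 1e-3)
        grid = mean_per_pix * rng.uniform(0.5, 1.5, size=volume.grid.shape)
        volume = IntensityVolume(grid=grid, dq=volume.dq)
    n = volume.n

    T = build_expand_operator(rotations, qmap, n, volume.dq, pixel_mask=mask)
    # voxels accumulating less than ~2 pixel-samples of interpolation
    # weight are effectively unmeasured: fixing them to zero keeps the
    # multiplicative updates from overfitting single stray photons at the
    # sparsely sampled rim of the volume
    coverage = np.asarray(T.sum(axis=0)).ravel()
    if friedel:
        coverage = friedel_symmetrize(coverage.reshape(n, n, n)).ravel()
    # adaptive cut: degenerate quadratures (few rotations) have low
    # coverage everywhere, so the cut never exceeds a tenth of the median
    cut = min(MIN_VOXEL_COVERAGE,
              0.1 * np.median(coverage[coverage > 0]))
    covered = coverage > cut
    v = volume.grid.ravel().copy()
    if friedel:
        v = friedel_symmetrize(v.reshape(n, n, n)).ravel()
    v[~covered] = 0.0

    log_w = np.log(rotations.weights)
    trace = []
    P = None
    floor = 1e-300
    for it in range(n_iter):
        U = (T @ v).reshape(rotations.n_rot, n_pix)
        W = fac[None, :] * U
        logW = np.log(np.maximum(W, floor))
        # E-step (log-domain): ll_dr = sum_k K_dk log W_rk - W_rk
        ll = K @ logW.T - W.sum(axis=1)[None, :]
        ll += log_w[None, :]
        trace.append(float(logsumexp(ll, axis=1).sum()))
        mx = ll.max(axis=1, keepdims=True)
        P = np.exp(ll - mx)
        P /= P.sum(axis=1, keepdims=True)

        # M-step + compression: Richardson-Lucy ascent of
        # Q(v) = sum_rk A_rk log(fac_k (T v)_rk) - B_r fac_k (T v)_rk
        A = (P.T @ K).ravel()                       # (n_rot * n_pix,)
        B = (P.sum(axis=0)[:, None] * fac[None, :]).ravel()
        denom = T.T @ B
        if friedel:
            denom = friedel_symmetrize(denom.reshape(n, n, n)).ravel()
        v_old = v
        for _ in range(n_inner):
            u_flat = np.maximum(T @ v, floor)
            num = T.T @ (A / u_flat)
            if friedel:
                num = friedel_symmetrize(num.reshape(n, n, n)).ravel()
            factor = np.divide(num, denom, out=np.ones_like(num),
                               where=denom > 0)
            v = v * factor
        change = np.abs(v - v_old).mean() / max(v.mean(), floor)
        if change < tol:
            break

    out = IntensityVolume(grid=v.reshape(n, n, n), dq=volume.dq,
                          measured=covered.reshape(n, n, n))
    posterior = OrientationPosterior(probabilities=P,
                                     most_likely=np.argmax(P, axis=1))
    return out, posterior, np.array(trace)
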