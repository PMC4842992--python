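"""Phase retrieval of the 3D intensity volume: Difference Map iterations
with support + positivity constraints, an autocorrelation-derived initial
support, and the average-threshold-blur shrinkwrap support update over an
ensemble of randomly initialised reconstructions.

All real/reciprocal grids are kept in "centred" order (the object and q = 0
at the central voxel); FFTs wrap/unwrap internally.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .emc import IntensityVolume
from .metrics import ShellCurve, prtf, resolution_at_half_prtf

logger = logging.getLogger(__name__)

DEFAULT_BETA = 0.85
DEFAULT_N_ITER = 300
DEFAULT_N_RECONS = 16
DEFAULT_SELECT_FRAC = 0.2
DEFAULT_THRESHOLD_FRAC = 0.1
BLUR_KERNEL = 5  # voxels, uniform (boxcar) kernel per side


@dataclass
class SupportMask:
    """Binary real-space support (centred grid)."""

    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if not self.grid.any():
            raise ValueError("support must be non-empty")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class DensityVolume:
    """Real-space electron-density estimate constrained by a support."""

    grid: np.ndarray
    support: SupportMask


@dataclass
class DifferenceMapResult:
    density: DensityVolume
    transform: np.ndarray     # centred complex Fourier transform of density
    error_trace: np.ndarray   # Fourier-magnitude error per iteration

    @property
    def final_error(self) -> float:
        return float(self.error_trace[-1])


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def initial_support(volume: IntensityVolume,
                    threshold_frac: float = DEFAULT_THRESHOLD_FRAC) -> SupportMask:
    """Support from the autocorrelation: |IFFT(intensities)| thresholded at
    ``threshold_frac`` of its maximum, largest connected component."""
    ac = np.abs(np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(volume.grid))))
    mask = ac > threshold_frac * ac.max()
    if not mask.any():
        raise ValueError("empty support; lower threshold_frac")
    return SupportMask(grid=_largest_component(mask))


def p_support(x: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Support + positivity projector: real part, clipped non-negative
    inside the support, zero outside.  Idempotent."""
    out = np.where(support, np.clip(x.real, 0.0, None), 0.0)
    return out.astype(complex)


def p_modulus(x: np.ndarray, sqrt_i: np.ndarray,
              measured: np.ndarray) -> np.ndarray:
    """Fourier-magnitude projector: replace |F| by sqrt(I) at measured
    voxels, leave unmeasured (gap) voxels free.  Idempotent."""
    f = np.fft.fftn(x)
    amp = np.abs(f)
    phase = np.divide(f, amp, out=np.ones_like(f), where=amp > 0)
    f_new = np.where(measured, sqrt_i * phase, f)
    return np.fft.ifftn(f_new)


def _magnitude_error(x: np.ndarray, sqrt_i: np.ndarray,
                     measured: np.ndarray) -> float:
    f = np.fft.fftn(x)
    num = np.linalg.norm((np.abs(f) - sqrt_i)[measured])
    den = np.linalg.norm(sqrt_i[measured])
    return float(num / den) if den > 0 else 0.0


def difference_map_run(volume: IntensityVolume, support: SupportMask,
                       beta: float = DEFAULT_BETA,
                       n_iter: int = DEFAULT_N_ITER,
                       seed: int = 0) -> DifferenceMapResult:
    """One randomly initialised Difference Map reconstruction.

    Iterates x <- x + beta [P_S(f_M(x)) - P_M(f_S(x))] with the standard
    estimates f_M = (1 + 1/beta) P_M - (1/beta) I and
    f_S = (1 - 1/beta) P_S + (1/beta) I; the returned density is P_S of the
    final iterate.  The error trace is the relative Fourier-magnitude error
    of P_S(x) per iteration.
    """
    if beta == 0:
        raise ValueError("beta must be non-zero")
    measured = np.fft.ifftshift(volume.measured)
    if not measured.any():
        raise ValueError("no measured voxels to constrain")
    sqrt_i = np.fft.ifftshift(np.sqrt(np.maximum(volume.grid, 0.0)))
    sup = np.fft.ifftshift(support.grid)
    rng = np.random.default_rng(seed)
    # random-phase start: magnitudes sqrt(I), uniform random phases
    phases = np.exp(2j * np.pi * rng.random(sqrt_i.shape))
    x = np.fft.ifftn(np.where(measured, sqrt_i * phases, 0.0))
    errors = np.empty(n_iter)
    for it in range(n_iter):
        pm = p_modulus(x, sqrt_i, measured)
        fm = (1.0 + 1.0 / beta) * pm - (1.0 / beta) * x
        ps = p_support(x, sup)
        fs = (1.0 - 1.0 / beta) * ps + (1.0 / beta) * x
        x = x + beta * (p_support(fm, sup) - p_modulus(fs, sqrt_i, measured))
        errors[it] = _magnitude_error(p_support(x, sup), sqrt_i, measured)
    final = p_support(x, sup)
    density = np.fft.fftshift(final.real)
    transform = np.fft.fftshift(np.fft.fftn(final))
    return DifferenceMapResult(
        density=DensityVolume(grid=density, support=support),
        transform=transform, error_trace=errors)


def _best_shift_and_inversion(ref: np.ndarray, g: np.ndarray):
    """Integer shift (and inversion branch) maximising cross-correlation."""
    best = (-np.inf, None)
    fref = np.fft.fftn(np.fft.ifftshift(ref)).conj()
    for inverted in (False, True):
        cand = g[::-1, ::-1, ::-1] if inverted else g
        cc = np.fft.ifftn(fref * np.fft.fftn(np.fft.ifftshift(cand))).real
        peak = np.unravel_index(np.argmax(cc), cc.shape)
        if cc[peak] > best[0]:
            best = (cc[peak], (inverted, peak))
    inverted, peak = best[1]
    cand = g[::-1, ::-1, ::-1] if inverted else g
    aligned = np.fft.fftshift(np.roll(np.fft.ifftshift(cand),
                                      [-p for p in peak], axis=(0, 1, 2)))
    return aligned


def align_densities(densities, ref: np.ndarray = None):
    """Align density grids to a reference by inversion + integer translation
    (FFT cross-correlation)."""
    grids = [d.grid if isinstance(d, DensityVolume) else d for d in densities]
    if ref is None:
        ref = grids[0]
    return [_best_shift_and_inversion(ref, g) for g in grids]


def shrinkwrap_update(results, select_frac: float = DEFAULT_SELECT_FRAC,
                      threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
                      previous: SupportMask = None) -> SupportMask:
    """Average-threshold-blur support update.

    The reconstructions (DifferenceMapResult) are ranked by final
    Fourier-magnitude error; the best ``select_frac`` are aligned
    (inversion + translation), averaged, thresholded at ``threshold_frac``
    of the maximum, blurred by a uniform 5x5x5 kernel and re-thresholded
    above zero.  The new support never grows beyond the blurred previous
    support and keeps its largest connected component.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("need at least two reconstructions")
    order = np.argsort([r.final_error for r in results])
    n_keep = max(2, int(np.ceil(select_frac * len(results))))
    kept = [results[i].density for i in order[:n_keep]]
    aligned = align_densities(kept)
    avg = np.mean(aligned, axis=0)
    mask = avg > threshold_frac * avg.max()
    if not mask.any():
        raise ValueError("empty support after threshold; lower threshold_frac")
    # one true voxel in the 5^3 box contributes 1/125; the cut at half that
    # keeps the exact dilation while rejecting float rounding dust
    eps = 0.5 / BLUR_KERNEL**3
    blurred = ndimage.uniform_filter(mask.astype(float), size=BLUR_KERNEL,
                                     mode="constant")
    new = blurred > eps
    if previous is not None:
        prev_blur = ndimage.uniform_filter(previous.grid.astype(float),
                                           size=BLUR_KERNEL, mode="constant")
        new &= prev_blur > eps
    if not new.any():
        raise ValueError("empty support after shrinkwrap update")
    return SupportMask(grid=_largest_component(new))


def phase_pipeline(volume: IntensityVolume, n_rounds: int = 3,
                   n_recons: int = DEFAULT_N_RECONS,
                   beta: float = DEFAULT_BETA,
                   n_iter: int = DEFAULT_N_ITER, seed: int = 0,
                   support: SupportMask = None,
                   select_frac: float = DEFAULT_SELECT_FRAC,
                   threshold_frac: float = DEFAULT_THRESHOLD_FRAC):
    """Alternate Difference-Map ensembles and shrinkwrap updates.

    Runs ``n_rounds`` shrinkwrap rounds (0 = phase once with the initial
    support), then a final ensemble from which the best ``select_frac``
    reconstructions are aligned and averaged.  Returns
    ``(average DensityVolume, PRTF ShellCurve, (resolution_A, limited))``.
    """
    if support is None:
        support = initial_support(volume, threshold_frac)
    seeds = np.random.SeedSequence(seed).generate_state(
        (n_rounds + 1) * n_recons).astype(np.int64) % (2**31)
    round_results = None
    for rnd in range(n_rounds + 1):
        round_results = [
            difference_map_run(volume, support, beta=beta, n_iter=n_iter,
                               seed=int(seeds[rnd * n_recons + i]))
            for i in range(n_recons)]
        if rnd < n_rounds:
            support = shrinkwrap_update(round_results,
                                        select_frac=select_frac,
                                        threshold_frac=threshold_frac,
                                        previous=support)
    order = np.argsort([r.final_error for r in round_results])
    n_keep = max(2, int(np.ceil(select_frac * len(round_results))))
    kept = [round_results[i] for i in order[:n_keep]]
    aligned = align_densities([r.density for r in kept])
    avg = DensityVolume(grid=np.mean(aligned, axis=0), support=support)
    transforms = [np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(a)))
                  for a in aligned]
    curve = prtf(transforms, volume.dq)
    resolution = resolution_at_half_prtf(curve)
    return avg, curve, resolution
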