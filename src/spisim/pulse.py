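"""SASE pulse generation and the parametric beamline.

The temporal structure of a SASE shot is modelled phenomenologically: a
train of short Gaussian intensity spikes (width ~ the coherence time) with
exponentially distributed amplitudes, whose centres are drawn from a
Gaussian chosen so that the *seed-ensemble mean* profile is a Gaussian with
exactly the requested FDHM.  The beamline is reduced to a scalar
transmission factor (default 2.3) and a Gaussian focus (default
250 x 160 nm^2 FWHM), which preserve the temporal structure of the shot.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548

DEFAULT_TRANSMISSION = 2.3
DEFAULT_FWHM_X_NM = 250.0
DEFAULT_FWHM_Y_NM = 160.0
DEFAULT_DT_FS = 0.1
DEFAULT_SPIKE_WIDTH_FS = 0.25
#: the time grid extends +- this multiple of the FDHM (full simulated
#: window ~5.1x the FDHM, the ratio of the stated full durations to the FDHM)
GRID_HALF_SPAN_FDHM = 2.55


@dataclass
class Pulse:
    """One SASE shot: instantaneous photon flux on a uniform fs grid."""

    times: np.ndarray        # fs, uniform spacing, strictly increasing
    flux: np.ndarray         # photons/fs
    photon_energy: float     # eV
    n_photons: float         # total photons = sum(flux * dt)
    seed: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("times must be a 1-D grid of >= 2 points")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("times must be uniformly spaced")
        if np.any(self.flux < 0):
            raise ValueError("flux must be non-negative")
        total = float(np.sum(self.flux) * self.dt)
        if self.n_photons > 0 and not np.isclose(total, self.n_photons,
                                                 rtol=1e-9):
            raise ValueError("n_photons inconsistent with flux integral")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class BeamAtSample:
    """Effective beam at the interaction point (Gaussian focus)."""

    fwhm_x: float            # nm
    fwhm_y: float            # nm
    n_photons_at_sample: float
    photon_energy: float     # eV

    @property
    def peak_fluence(self) -> float:
        """Peak on-axis fluence, photons/nm^2: N / (2 pi sigma_x sigma_y)."""
        sx = self.fwhm_x / FWHM_SIGMA
        sy = self.fwhm_y / FWHM_SIGMA
        return self.n_photons_at_sample / (2.0 * np.pi * sx * sy)


def generate_sase_pulse(fdhm: float, mean_photons: float,
                        jitter_rel: float = 0.0,
                        photon_energy: float = 5000.0,
                        n_spikes: int = 36,
                        dt: float = DEFAULT_DT_FS,
                        seed: int = 0,
                        spike_width: float = DEFAULT_SPIKE_WIDTH_FS) -> Pulse:
    """Generate one synthetic SASE shot.

    ``fdhm`` is the full duration at half maximum (fs) of the ensemble-mean
    envelope; ``mean_photons`` the ensemble-mean photon count, with per-shot
    totals drawn as mean_photons * (1 + Normal(0, jitter_rel)).  With
    ``n_spikes=1`` the degenerate smooth single-envelope pulse is returned.
    Deterministic for a fixed seed.
    """
    if fdhm <= 0 or dt <= 0:
        raise ValueError("fdhm and dt must be positive")
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    if spike_width <= 0:
        raise ValueError("spike_width must be positive")
    rng = np.random.default_rng(seed)
    half_span = GRID_HALF_SPAN_FDHM * fdhm
    n_t = int(np.ceil(2.0 * half_span / dt)) + 1
    times = (np.arange(n_t) - (n_t - 1) / 2.0) * dt

    n_shot = mean_photons * (1.0 + rng.normal(0.0, jitter_rel)) \
        if jitter_rel > 0 else mean_photons
    n_shot = max(n_shot, 0.0)

    sigma_env = fdhm / FWHM_SIGMA
    if n_spikes == 1:
        flux = np.exp(-0.5 * (times / sigma_env) ** 2)
    else:
        # centre variance chosen so the ensemble-mean profile (centre pdf
        # convolved with the spike kernel) has exactly the requested FDHM
        sigma_c = np.sqrt(max(sigma_env**2 - spike_width**2, 1e-12))
        centers = rng.normal(0.0, sigma_c, size=n_spikes)
        widths = spike_width * rng.uniform(0.7, 1.3, size=n_spikes)
        amps = rng.exponential(1.0, size=n_spikes)
        flux = np.zeros_like(times)
        for c, w, a in zip(centers, widths, amps):
            flux += a * np.exp(-0.5 * ((times - c) / w) ** 2)
    total = flux.sum() * dt
    flux = flux * (n_shot / total) if total > 0 else flux
    return Pulse(times=times, flux=flux, photon_energy=photon_energy,
                 n_photons=float(flux.sum() * dt), seed=seed)


def apply_beamline(pulse: Pulse, transmission_factor: float = DEFAULT_TRANSMISSION,
                   fwhm_x: float = DEFAULT_FWHM_X_NM,
                   fwhm_y: float = DEFAULT_FWHM_Y_NM) -> tuple[Pulse, BeamAtSample]:
    """Propagate through the optics: scalar loss + Gaussian focus.

    The pulse energy decreases by ``transmission_factor`` (>= 1) while the
    temporal structure is inherited unchanged.
    """
    if transmission_factor < 1:
        raise ValueError("transmission_factor must be >= 1")
    flux = pulse.flux / transmission_factor
    out = Pulse(times=pulse.times.copy(), flux=flux,
                photon_energy=pulse.photon_energy,
                n_photons=float(flux.sum() * pulse.dt), seed=pulse.seed)
    beam = BeamAtSample(fwhm_x=fwhm_x, fwhm_y=fwhm_y,
                        n_photons_at_sample=out.n_photons,
                        photon_energy=pulse.photon_energy)
    return out, beam


def fluence_in_slice(pulse: Pulse, beam: BeamAtSample,
                     t0: float, t1: float) -> float:
    """Peak on-axis fluence (photons/nm^2) delivered in [t0, t1).

    Each flux sample at time t_j represents the half-open bin [t_j, t_j+dt);
    summing over a partition of the full grid reproduces
    ``beam.peak_fluence`` exactly.
    """
    if t0 > t1:
        raise ValueError("need t0 <= t1")
    lo = pulse.times[0]
    hi = pulse.times[-1] + pulse.dt
    if t1 < lo - 1e-9 or t0 > hi + 1e-9:
        raise ValueError("interval outside the pulse time grid")
    sel = (pulse.times >= t0) & (pulse.times < t1)
    if pulse.n_photons <= 0:
        return 0.0
    frac = float(pulse.flux[sel].sum() * pulse.dt) / pulse.n_photons
    return frac * beam.peak_fluence
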