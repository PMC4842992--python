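"""Small shared oracles for the test suite."""
import numpy as np


def ncc(a, b):
    """Normalised cross-correlation of two arrays."""
    a = np.ravel(a) - np.mean(a)
    b = np.ravel(b) - np.mean(b)
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def fdhm_of(times, values):
    """Full duration at half maximum by linear interpolation."""
    half = values.max() / 2.0
    above = values >= half
    i0 = np.argmax(above)
    i1 = len(values) - np.argmax(above[::-1]) - 1

    def cross(i, j):
        if i == j or values[j] == values[i]:
            return times[i]
        return times[i] + (half - values[i]) * (times[j] - times[i]) \
            / (values[j] - values[i])

    left = cross(i0 - 1, i0) if i0 > 0 else times[0]
    right = cross(i1, i1 + 1) if i1 < len(values) - 1 else times[-1]
    return right - left


def gaussian_blobs(n=33, seed=3, n_blobs=5, extent=4.0):
    """A smooth positive toy density inside a compact ball."""
    rng = np.random.default_rng(seed)
    ax = np.arange(n) - (n - 1) // 2
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    rho = np.zeros((n, n, n))
    for _ in range(n_blobs):
        c = rng.uniform(-extent, extent, 3)
        w = rng.uniform(1.2, 2.5)
        rho += np.exp(-(((x - c[0]) ** 2 + (y - c[1]) ** 2
                         + (z - c[2]) ** 2) / (2 * w ** 2)))
    rho *= (x ** 2 + y ** 2 + z ** 2) <= (extent * 2) ** 2
    return rho


def intensities_of(rho):
    """Centred |FFT|^2 of a centred real-space grid."""
    f = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(rho)))
    return np.abs(f) ** 2
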