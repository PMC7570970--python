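"""1-D empirical wavelet transform (EWT).

The EWT is an adaptive filter-bank decomposition: band edges are chosen
from the analysed signal's own Fourier magnitude spectrum, and each band
is realised with a Meyer-style smooth filter (Littlewood-Paley
construction).  Because the squared filter responses form a partition of
unity on the frequency axis, the transform is a tight frame and the sum
of the components reconstructs the signal to machine precision.

In walk-over weighing the lowest band (the scale/approximation component
``f0``) carries the weight trend; the detail bands carry the gait
oscillation and sensor noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft
from scipy.ndimage import uniform_filter1d

__all__ = [
    "MagnitudeSpectrum",
    "SpectrumPartition",
    "EwtFilterBank",
    "EwtDecomposition",
    "beta",
    "compute_spectrum",
    "detect_boundaries",
    "evaluate_filters",
    "build_filter_bank",
    "ewt_decompose",
    "periodic_extend",
]


def beta(x):
    """Meyer auxiliary polynomial ``x^4 (35 - 84 x + 70 x^2 - 20 x^3)``.

    Clamped to 0 below ``x = 0`` and 1 above ``x = 1`` so it can be
    evaluated on whole frequency grids.  Satisfies ``beta(x) + beta(1 - x)
    = 1`` on [0, 1], which is what makes the cos/sin filter transitions
    sum to one.
    """
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    return x**4 * (35.0 - 84.0 * x + 70.0 * x**2 - 20.0 * x**3)


@dataclass(frozen=True)
class MagnitudeSpectrum:
    """One-sided magnitude spectrum on the normalised axis [0, pi]."""

    frequencies: np.ndarray  # in [0, pi], ascending
    magnitude: np.ndarray    # nonnegative, same length
    signal_length: int


@dataclass(frozen=True)
class SpectrumPartition:
    """A partition of [0, pi] into contiguous frequency segments.

    ``boundaries`` is ``[0, w1, ..., w_{N-1}, pi]`` (strictly increasing);
    segment ``n`` is ``[w_{n-1}, w_n]`` and the segments cover [0, pi].
    """

    spectrum: MagnitudeSpectrum
    boundaries: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.boundaries) - 1

    @property
    def segments(self):
        b = self.boundaries
        return [(b[i], b[i + 1]) for i in range(len(b) - 1)]

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b[0] != 0.0 or not np.isclose(b[-1], np.pi):
            raise ValueError("boundaries must start at 0 and end at pi")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)


@dataclass(frozen=True)
class EwtFilterBank:
    """Meyer-type filters sampled on a signal's full FFT grid.

    ``responses[0]`` is the scale (low-pass) filter; the remaining rows
    are the band-pass wavelet filters, ordered by frequency.  Squared
    responses sum to one at every FFT bin (tight frame).
    """

    partition: SpectrumPartition
    gamma: float
    responses: np.ndarray  # (n_modes, signal_length), real

    @property
    def signal_length(self) -> int:
        return self.responses.shape[1]

    @property
    def n_modes(self) -> int:
        return self.responses.shape[0]

    def partition_of_unity_error(self) -> float:
        return float(np.max(np.abs(np.sum(self.responses**2, axis=0) - 1.0)))


@dataclass(frozen=True)
class EwtDecomposition:
    """Components and coefficients of one EWT analysis.

    ``components[0]`` is the approximation/trend ``f0``; summing all rows
    of ``components`` reconstructs the analysed signal.
    """

    components: np.ndarray    # (n_modes, signal_length)
    coefficients: np.ndarray  # (n_modes, signal_length)
    filter_bank: EwtFilterBank

    @property
    def f0(self) -> np.ndarray:
        return self.components[0]

    def reconstruct(self) -> np.ndarray:
        return self.components.sum(axis=0)


def compute_spectrum(values) -> MagnitudeSpectrum:
    """Magnitude spectrum of ``values`` on the normalised axis [0, pi].

    Bin ``k`` of the length-``n`` DFT maps to angular frequency
    ``2 pi k / n``; only bins in [0, pi] are kept.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need a 1-D signal with at least 4 samples")
    n = x.size
    n_half = n // 2 + 1
    mag = np.abs(fft(x)[:n_half])
    freqs = 2.0 * np.pi * np.arange(n_half) / n
    return MagnitudeSpectrum(frequencies=freqs, magnitude=mag, signal_length=n)


def _local_maxima(mag: np.ndarray) -> np.ndarray:
    """Indices of local maxima, endpoints included."""
    idx = []
    m = len(mag)
    for i in range(m):
        left = mag[i - 1] if i > 0 else -np.inf
        right = mag[i + 1] if i < m - 1 else -np.inf
        if mag[i] > left and mag[i] >= right:
            idx.append(i)
    return np.asarray(idx, dtype=int)


def detect_boundaries(spectrum: MagnitudeSpectrum, n_modes: int = 3) -> SpectrumPartition:
    """Place segment boundaries between the spectrum's dominant maxima.

    The ``n_modes`` largest local maxima of a lightly smoothed magnitude
    spectrum are retained; each interior boundary sits at the minimum of
    the raw spectrum between two consecutive retained maxima.  If the
    spectrum does not resolve enough maxima the partition falls back to
    equal-width segments (with a warning).
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    freqs, mag = spectrum.frequencies, spectrum.magnitude
    if n_modes == 1:
        return SpectrumPartition(spectrum, np.array([0.0, np.pi]))

    smooth = uniform_filter1d(mag, size=3, mode="nearest")
    maxima = _local_maxima(smooth)
    if len(maxima) < n_modes:
        warnings.warn(
            f"spectrum resolves only {len(maxima)} maxima for {n_modes} modes; "
            "falling back to an equal-width partition",
            stacklevel=2,
        )
        bounds = np.linspace(0.0, np.pi, n_modes + 1)
        return SpectrumPartition(spectrum, bounds)

    top = maxima[np.argsort(smooth[maxima])[::-1][:n_modes]]
    top = np.sort(top)
    interior = []
    for i, j in zip(top[:-1], top[1:]):
        if j - i < 2:  # adjacent maxima: no strict interior bin, use midpoint
            interior.append(0.5 * (freqs[i] + freqs[j]))
        else:
            valley = mag[i + 1 : j]
            # centre of the minimal plateau: a numerically flat valley
            # (e.g. a noise floor) should split midway, not at an
            # arbitrary rounding-determined bin next to a peak
            near_min = np.flatnonzero(valley <= valley.min() + 1e-9 * mag.max())
            k = i + 1 + int(np.median(near_min))
            interior.append(freqs[k])
    bounds = np.concatenate(([0.0], np.asarray(interior), [np.pi]))
    if np.any(np.diff(bounds) <= 0):  # degenerate placement near the ends
        warnings.warn("degenerate boundary placement; using equal-width partition",
                      stacklevel=2)
        bounds = np.linspace(0.0, np.pi, n_modes + 1)
    return SpectrumPartition(spectrum, bounds)


def _admissibility_bound(boundaries: np.ndarray) -> float:
    # min over consecutive boundary pairs of (w2 - w1)/(w2 + w1); the pair
    # with w1 = 0 gives 1 and never binds.
    b = boundaries
    ratios = (b[1:] - b[:-1]) / (b[1:] + b[:-1])
    return float(np.min(ratios))


def _roll_off(w: np.ndarray, b: float, gamma: float) -> np.ndarray:
    """cos-beta step: 1 below (1-gamma) b, 0 above (1+gamma) b."""
    return np.cos(0.5 * np.pi * beta((w - (1 - gamma) * b) / (2 * gamma * b)))


def _roll_on(w: np.ndarray, b: float, gamma: float) -> np.ndarray:
    """sin-beta step: 0 below (1-gamma) b, 1 above (1+gamma) b."""
    return np.sin(0.5 * np.pi * beta((w - (1 - gamma) * b) / (2 * gamma * b)))


def evaluate_filters(boundaries, gamma: float, w) -> np.ndarray:
    """Sample the Meyer filter responses at arbitrary frequencies ``w``.

    Row 0 is the scale filter, the rest the wavelet filters.  ``w`` is
    interpreted as |angular frequency| in [0, pi].
    """
    w = np.abs(np.asarray(w, dtype=float))
    interior = np.asarray(boundaries, dtype=float)[1:-1]
    if interior.size == 0:
        return np.ones((1, w.size))
    responses = np.empty((interior.size + 1, w.size))
    responses[0] = _roll_off(w, interior[0], gamma)
    for i in range(len(interior)):
        resp = _roll_on(w, interior[i], gamma)
        if i + 1 < len(interior):
            resp = resp * _roll_off(w, interior[i + 1], gamma)
        responses[i + 1] = resp
    return responses


def build_filter_bank(partition: SpectrumPartition, gamma: float | None = None) -> EwtFilterBank:
    """Build the Meyer filter bank for a spectrum partition.

    ``gamma`` controls the relative half-width of each transition band and
    must satisfy ``gamma < min_n (w_{n+1} - w_n) / (w_{n+1} + w_n)`` so
    that neighbouring transitions do not overlap; ``None`` picks half that
    bound.  Filters are sampled on the full FFT grid of the signal the
    partition was computed from, so they can multiply its spectrum
    directly.
    """
    bounds = partition.boundaries
    n = partition.spectrum.signal_length
    w = np.abs(2.0 * np.pi * np.fft.fftfreq(n))  # |angular freq| in [0, pi]

    if partition.n_modes == 1:
        return EwtFilterBank(partition, gamma=0.0 if gamma is None else gamma,
                             responses=np.ones((1, n)))

    limit = _admissibility_bound(bounds)
    if gamma is None:
        gamma = 0.5 * limit
    if not 0 < gamma < limit:
        raise ValueError(
            f"gamma={gamma} violates the admissibility bound "
            f"min (w2-w1)/(w2+w1) = {limit:.6g}"
        )
    return EwtFilterBank(partition, gamma=float(gamma),
                         responses=evaluate_filters(bounds, gamma, w))


def ewt_decompose(values, filter_bank: EwtFilterBank) -> EwtDecomposition:
    """Forward EWT and component reconstruction.

    Coefficients are inverse transforms of the spectrum multiplied by the
    conjugate filter responses; component ``i`` is the coefficient
    filtered once more by its own band, so that the components sum back
    to the input exactly (tight frame).
    """
    x = np.asarray(values, dtype=float)
    n_sig = filter_bank.signal_length
    if x.size != n_sig:
        raise ValueError(f"signal length {x.size} != filter-bank length {n_sig}")
    spectrum = fft(x)
    resp = filter_bank.responses  # real, symmetric in |w|
    coeffs = np.real(ifft(spectrum[None, :] * resp, axis=1))
    components = np.real(ifft(spectrum[None, :] * resp**2, axis=1))
    return EwtDecomposition(components=components, coefficients=coeffs,
                            filter_bank=filter_bank)


def periodic_extend(values, filter_length: int):
    """Periodic continuation: wrap the head of the signal onto its tail.

    For a signal of length ``N`` and filter length ``M`` the extension has
    length ``N + M - 1``: samples ``0..N-1`` are the signal itself and
    sample ``N + j`` repeats sample ``j``.  Used to suppress edge
    artefacts when transforming short high-activity segments.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot extend an empty signal")
    if filter_length < 1:
        raise ValueError("filter_length must be >= 1")
    extra = np.arange(filter_length - 1) % x.size
    return np.concatenate([x, x[extra]])
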