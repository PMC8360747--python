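"""Six analytic mother wavelets and a continuous wavelet transform engine.

The wavelet family matches the bases used for PPG scalogram generation:

==========  ======================================================  ========
name        psi(t)                                                  complex
==========  ======================================================  ========
fbsp        sqrt(F_b) * sinc(F_b t / m)^m * exp(2 i pi F_c t)       yes
shan        sqrt(F_b) * sinc(F_b t)     * exp(2 i pi F_c t)         yes
cgau1       C_1 * d/dt [ exp(-i t) exp(-t^2) ]                      yes
morl        exp(-t^2 / 2) * cos(5 t)                                no
mexh        (2 / (sqrt(3) pi^{1/4})) * exp(-t^2/2) * (1 - t^2)      no
gaus1       C_1 * d/dt [ exp(-t^2) ]                                no
==========  ======================================================  ========

sinc(x) = sin(pi x)/(pi x).  For cgau1 and gaus1 the constant C_1 is fixed
analytically so the continuous 2-norm of psi equals 1:
C_1(cgau1) = (2 pi)^{-1/4}, C_1(gaus1) = (2/pi)^{1/4}.

The transform uses the L2 convention

    W(a, b) = a^{-1/2} * sum_t x[t] * conj(psi((t - b) / a))

with scales a in samples and unit sample spacing; pseudo-frequency of a
scale is f = F_c_eff * fs / a where F_c_eff is the wavelet's spectral peak.
``cwt`` evaluates this by FFT convolution per scale; ``cwt_oracle`` is the
literal double-loop summation used to verify it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve

WAVELET_NAMES = ("fbsp", "shan", "cgau1", "morl", "mexh", "gaus1")

# |psi| below this fraction of its peak is treated as zero (kernel support).
_SUPPORT_EPS = 1e-8
# sinc tails decay like 1/t; cap the support of fbsp/shan at +/- this many
# periods of the complex carrier exp(2 i pi F_c t).
_SINC_SUPPORT_PERIODS = 8.0


@dataclass(frozen=True)
class WaveletSpec:
    """A named mother wavelet with its parameters."""

    name: str
    F_b: float | None = None
    F_c: float | None = None
    m: int | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.name not in WAVELET_NAMES:
            raise ValueError(
                f"unknown wavelet {self.name!r}; expected one of {WAVELET_NAMES}"
            )

    @property
    def is_complex(self) -> bool:
        return self.name in ("fbsp", "shan", "cgau1")


def make_spec(name: str) -> WaveletSpec:
    """Default parameterizations: fbsp1-15-1, shan15-1, cgau1, morl, mexh, gaus1."""
    if name == "fbsp":
        return WaveletSpec("fbsp", F_b=15.0, F_c=1.0, m=1)
    if name == "shan":
        spec = WaveletSpec("shan", F_b=15.0, F_c=1.0)
        if spec.F_c <= spec.F_b / 2:
            warnings.warn(
                "shan parameters F_b=15, F_c=1 violate the admissibility "
                "condition F_c > F_b/2; using them as specified",
                UserWarning,
                stacklevel=2,
            )
        return spec
    if name in ("cgau1", "gaus1"):
        return WaveletSpec(name, n=1)
    if name in ("morl", "mexh"):
        return WaveletSpec(name)
    raise ValueError(f"unknown wavelet {name!r}")


def _sinc(x: np.ndarray) -> np.ndarray:
    """Normalized sinc, sin(pi x)/(pi x)."""
    return np.sinc(x)


# analytic unit-2-norm constants for the derivative-of-Gaussian wavelets
_C1_CGAU = (2.0 * np.pi) ** -0.25
_C1_GAUS = (2.0 / np.pi) ** 0.25


def wavelet_function(spec: WaveletSpec, t: np.ndarray) -> np.ndarray:
    """Evaluate the mother wavelet on a time grid (wavelet time units)."""
    t = np.asarray(t, dtype=float)
    name = spec.name
    if name == "fbsp":
        return (
            np.sqrt(spec.F_b)
            * _sinc(spec.F_b * t / spec.m) ** spec.m
            * np.exp(2j * np.pi * spec.F_c * t)
        )
    if name == "shan":
        return np.sqrt(spec.F_b) * _sinc(spec.F_b * t) * np.exp(2j * np.pi * spec.F_c * t)
    if name == "cgau1":
        # d/dt [exp(-i t) exp(-t^2)] = (-i - 2 t) exp(-i t - t^2)
        return _C1_CGAU * (-1j - 2.0 * t) * np.exp(-1j * t - t**2)
    if name == "morl":
        return np.exp(-(t**2) / 2.0) * np.cos(5.0 * t)
    if name == "mexh":
        return (2.0 / (np.sqrt(3.0) * np.pi**0.25)) * np.exp(-(t**2) / 2.0) * (1.0 - t**2)
    if name == "gaus1":
        # d/dt [exp(-t^2)] = -2 t exp(-t^2)
        return _C1_GAUS * (-2.0 * t) * np.exp(-(t**2))
    raise ValueError(f"unknown wavelet {name!r}")


def support_radius(spec: WaveletSpec) -> float:
    """Half-width of the effective support of psi in wavelet time units.

    Gaussian-windowed wavelets are truncated where |psi| drops below 1e-8
    of the peak; the slowly decaying sinc-windowed fbsp/shan are capped at
    +/- 8 carrier periods.
    """
    if spec.name in ("fbsp", "shan"):
        return _SINC_SUPPORT_PERIODS / spec.F_c
    t = np.linspace(0.0, 16.0, 4001)
    mag = np.abs(wavelet_function(spec, t))
    peak = mag.max()
    inside = np.nonzero(mag > _SUPPORT_EPS * peak)[0]
    return float(t[inside[-1]])


@lru_cache(maxsize=32)
def _center_frequency_cached(name: str) -> float:
    spec = make_spec(name)
    r = support_radius(spec)
    n = 1 << 14
    t, dt = np.linspace(-r, r, n, retstep=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        psi = wavelet_function(spec, t)
    spec_mag = np.abs(np.fft.fft(psi))
    freqs = np.fft.fftfreq(n, d=dt)
    if not spec.is_complex:
        spec_mag = spec_mag[: n // 2]  # real wavelets: positive band only
        freqs = freqs[: n // 2]
    return float(abs(freqs[int(np.argmax(spec_mag))]))


def center_frequency(spec: WaveletSpec) -> float:
    """Nominal center frequency of psi in wavelet time units.

    Wavelets with an explicit F_c parameter (fbsp, shan) use it directly —
    their spectrum is flat across the F_b band, so a spectral argmax would
    be arbitrary.  The others use the spectral peak, computed by FFT of a
    densely sampled psi.
    """
    if spec.F_c is not None:
        return float(spec.F_c)
    return _center_frequency_cached(spec.name)


@dataclass
class CWTResult:
    """CWT coefficients, scales-by-time, with the grid that produced them."""

    coeffs: np.ndarray
    scales: np.ndarray
    fs: float
    spec: WaveletSpec

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        if self.coeffs.shape[0] != self.scales.size:
            raise ValueError("coeffs rows must match number of scales")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")

    @property
    def pseudo_frequencies(self) -> np.ndarray:
        return center_frequency(self.spec) * self.fs / self.scales


def default_scales(
    segment_len: int,
    fs: float,
    spec: WaveletSpec,
    n_scales: int = 64,
    f_min: float = 0.5,
    f_max: float = 20.0,
) -> np.ndarray:
    """Geometric scale grid covering pseudo-frequencies f_max down to f_min Hz."""
    if segment_len < 16:
        raise ValueError("segment_len must be >= 16")
    fc = center_frequency(spec)
    freqs = np.geomspace(f_max, f_min, n_scales)
    return fc * fs / freqs  # strictly increasing in scale


def _kernel(spec: WaveletSpec, scale: float) -> np.ndarray:
    """Sampled conj(psi(-v/a)) on integer v, for convolution with x.

    (x * h)[b] with h[v] = conj(psi(-v/a)) equals
    sum_t x[t] conj(psi((t-b)/a)), the correlation the transform needs.
    """
    radius = int(np.ceil(support_radius(spec) * scale))
    v = np.arange(-radius, radius + 1)
    return np.conj(wavelet_function(spec, -v / scale))


def _validate_cwt_args(x: np.ndarray, scales: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    scales = np.atleast_1d(np.asarray(scales, dtype=float))
    if x.size == 0:
        raise ValueError("input signal is empty")
    if scales.size == 0:
        raise ValueError("scales must be nonempty")
    if np.any(scales < 1.0):
        raise ValueError("scales must be >= 1 sample")
    return x, scales


def cwt(
    x: np.ndarray, scales: np.ndarray, spec: WaveletSpec, fs: float
) -> CWTResult:
    """Continuous wavelet transform by per-scale FFT convolution.

    Implements W(a,b) = a^{-1/2} sum_t x[t] conj(psi((t-b)/a)) with the
    kernel truncated at the wavelet's effective support; the signal is
    implicitly zero-padded, and coefficients are returned for the original
    time span only.
    """
    x, scales = _validate_cwt_args(x, scales)
    dtype = complex if spec.is_complex else float
    out = np.empty((scales.size, x.size), dtype=dtype)
    for i, a in enumerate(scales):
        h = _kernel(spec, a)
        full = fftconvolve(x, h, mode="full")
        radius = (h.size - 1) // 2
        row = full[radius : radius + x.size] / np.sqrt(a)
        out[i] = row if spec.is_complex else row.real
    return CWTResult(coeffs=out, scales=scales, fs=fs, spec=spec)


def cwt_oracle(
    x: np.ndarray, scales: np.ndarray, spec: WaveletSpec, fs: float
) -> CWTResult:
    """Literal double-loop evaluation of the CWT sum; for short inputs only."""
    x, scales = _validate_cwt_args(x, scales)
    n = x.size
    dtype = complex if spec.is_complex else float
    out = np.zeros((scales.size, n), dtype=dtype)
    t_idx = np.arange(n)
    for i, a in enumerate(scales):
        radius = int(np.ceil(support_radius(spec) * a))
        for b in range(n):
            lo = max(0, b - radius)
            hi = min(n, b + radius + 1)
            psi = wavelet_function(spec, (t_idx[lo:hi] - b) / a)
            val = np.sum(x[lo:hi] * np.conj(psi)) / np.sqrt(a)
            out[i, b] = val if spec.is_complex else val.real
    return CWTResult(coeffs=out, scales=scales, fs=fs, spec=spec)
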