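"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive — O(N^2) Fourier sums, explicit
matrix construction from textbook formulas, direct peak picking — and
shares no code with the package's FFT-based implementation.
"""

import itertools

import numpy as np


def naive_power_spectrum(frame: np.ndarray, n_fft: int) -> np.ndarray:
    """|DFT|^2 by the O(N^2) definition, bins 0..n_fft//2."""
    x = np.zeros(n_fft)
    x[:frame.size] = frame
    n = np.arange(n_fft)
    out = np.empty(n_fft // 2 + 1)
    for k in range(n_fft // 2 + 1):
        re = np.sum(x * np.cos(-2 * np.pi * k * n / n_fft))
        im = np.sum(x * np.sin(-2 * np.pi * k * n / n_fft))
        out[k] = re**2 + im**2
    return out


def triangle_weights(n_filters, n_fft, rate, fmin, fmax):
    """Mel-triangle filterbank built from the textbook formula."""
    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    edges = imel(np.linspace(mel(fmin), mel(fmax), n_filters + 2))
    freqs = np.arange(n_fft // 2 + 1) * rate / n_fft
    W = np.zeros((n_filters, freqs.size))
    for j, f in enumerate(freqs):
        for k in range(n_filters):
            lo, c, hi = edges[k], edges[k + 1], edges[k + 2]
            if lo < f < c:
                W[k, j] = (f - lo) / (c - lo)
            elif c <= f < hi:
                W[k, j] = (hi - f) / (hi - c)
            elif f == c:
                W[k, j] = 1.0
    return W


def gammatone_weights(n_filters, n_fft, rate, fmin, fmax):
    """4th-order gammatone power responses on the ERB-rate scale."""
    def erb_rate(f):
        return 21.4 * np.log10(1.0 + 0.00437 * f)

    def inv(e):
        return (10.0 ** (e / 21.4) - 1.0) / 0.00437

    centers = inv(np.linspace(erb_rate(fmin), erb_rate(fmax), n_filters))
    freqs = np.arange(n_fft // 2 + 1) * rate / n_fft
    W = np.zeros((n_filters, freqs.size))
    for k, fc in enumerate(centers):
        b = 1.019 * 24.7 * (4.37 * fc / 1000.0 + 1.0)
        for j, f in enumerate(freqs):
            W[k, j] = (1.0 + ((f - fc) / b) ** 2) ** -4
    return W


def dct2_matrix(m: int) -> np.ndarray:
    """Orthonormal type-II DCT matrix from the cosine definition."""
    D = np.zeros((m, m))
    for k in range(m):
        for n in range(m):
            D[k, n] = np.sqrt(2.0 / m) * np.cos(np.pi * (n + 0.5) * k / m)
    D[0] *= 1.0 / np.sqrt(2.0)
    return D


def oracle_cepstra(frame, rate, kind, n_filters, n_coeffs, fmin, fmax,
                   log_floor=1e-10):
    """Full cepstral pipeline by explicit sums and matrix products."""
    n_fft = 1 << (frame.size - 1).bit_length()
    power = naive_power_spectrum(frame, n_fft)
    if kind == "mel":
        W = triangle_weights(n_filters, n_fft, rate, fmin, fmax)
    else:
        W = gammatone_weights(n_filters, n_fft, rate, fmin, fmax)
    energies = W @ power
    logE = np.log(np.maximum(energies, log_floor))
    D = dct2_matrix(n_filters)
    return (D @ logE)[:n_coeffs]


def estimate_jitter_shimmer(pulse_train: np.ndarray) -> tuple[float, float]:
    """Re-measure jitter/shimmer from a pulse train by peak picking.

    Jitter = coefficient of variation of inter-pulse periods, percent;
    shimmer = coefficient of variation of pulse amplitudes, percent.
    """
    pos = np.flatnonzero(pulse_train)
    periods = np.diff(pos)
    amps = pulse_train[pos]
    jitter = 100.0 * periods.std() / periods.mean()
    shimmer = 100.0 * amps.std() / np.abs(amps).mean()
    return float(jitter), float(shimmer)


def spectral_centroid(x: np.ndarray, rate: int) -> float:
    """Power-weighted mean frequency (FFT is fine: not under test here)."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / rate)
    return float(np.sum(freqs * spec) / np.sum(spec))


def exact_permutation_pvalue(a, b) -> float:
    """Two-sided exact permutation p for the difference of means."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = a.size
    observed = abs(a.mean() - b.mean())
    count = 0
    total = 0
    for idx in itertools.combinations(range(pooled.size), na):
        mask = np.zeros(pooled.size, bool)
        mask[list(idx)] = True
        diff = abs(pooled[mask].mean() - pooled[~mask].mean())
        count += diff >= observed - 1e-12
        total += 1
    return count / total


def brute_force_frame_count(n: int, frame_len: int, hop: int) -> int:
    """Count full frames by explicit enumeration of start offsets."""
    count = 0
    start = 0
    while start + frame_len <= n:
        count += 1
        start += hop
    return count
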