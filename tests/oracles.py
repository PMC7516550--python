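"""Independent brute-force reference implementations for the entropy
estimators and metrics.

Everything here is written with plain Python loops and elementary numpy,
deliberately sharing no code path with the package, so agreement between
the two routes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def permutation_entropy_oracle(x, order: int, delay: int) -> float:
    """Count ordinal patterns one window at a time; ties by temporal order."""
    x = list(map(float, x))
    n_windows = len(x) - (order - 1) * delay
    counts: dict[tuple, int] = {}
    for i in range(n_windows):
        window = [x[i + j * delay] for j in range(order)]
        # stable ranking: sort positions by (value, position)
        pattern = tuple(sorted(range(order), key=lambda j: (window[j], j)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def shannon_entropy_oracle(x, n_bins: int) -> float:
    """Equal-width histogram entropy in bits, binned by hand."""
    x = list(map(float, x))
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    counts = [0] * n_bins
    width = (hi - lo) / n_bins
    for v in x:
        idx = min(int((v - lo) / width), n_bins - 1)
        counts[idx] += 1
    total = len(x)
    return -sum((c / total) * math.log2(c / total) for c in counts if c)


def spectral_entropy_oracle(x, rate: float, n_components: int) -> float:
    """Periodogram folded into equal frequency bins, natural-log entropy.

    The periodogram is computed from the DFT definition directly, after
    removing the mean (the DC offset is not an oscillation).
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    spectrum = np.fft.rfft(x)
    # One-sided periodogram density matching scipy's default scaling
    psd = (np.abs(spectrum) ** 2) / (rate * n)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.arange(psd.size) * rate / n
    total = psd.sum()
    if total <= 0:
        return 0.0
    nyquist = rate / 2.0
    binned = [0.0] * n_components
    for f, p in zip(freqs, psd):
        idx = int(f / nyquist * n_components)
        idx = min(idx, n_components - 1)
        binned[idx] += p
    return -sum((p / total) * math.log(p / total) for p in binned if p > 0)


def _cheb(a, b) -> float:
    return max(abs(u - v) for u, v in zip(a, b))


def approximate_entropy_oracle(x, m: int, r_frac: float, tau: int) -> float:
    """Pincus ApEn with self-matches, O(N^2) double loop."""
    x = list(map(float, x))
    sd = float(np.std(x))
    if sd == 0:
        return 0.0
    r = r_frac * sd

    def phi(order: int) -> float:
        n_t = len(x) - (order - 1) * tau
        templates = [
            [x[i + j * tau] for j in range(order)] for i in range(n_t)
        ]
        logs = []
        for a in templates:
            count = sum(1 for b in templates if _cheb(a, b) <= r)
            logs.append(math.log(count / n_t))
        return sum(logs) / n_t

    return phi(m) - phi(m + 1)


def sample_entropy_oracle(x, m: int, r_frac: float, tau: int) -> float:
    """Richman-Moorman SampEn excluding self-matches, O(N^2)."""
    x = list(map(float, x))
    sd = float(np.std(x))
    if sd == 0:
        return math.nan
    r = r_frac * sd
    n_t = len(x) - m * tau  # both m and m+1 templates exist at these starts

    def count(order: int) -> int:
        templates = [
            [x[i + j * tau] for j in range(order)] for i in range(n_t)
        ]
        hits = 0
        for i in range(n_t):
            for j in range(n_t):
                if i != j and _cheb(templates[i], templates[j]) <= r:
                    hits += 1
        return hits

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def svd_entropy_oracle(x, order: int, delay: int) -> float:
    """Singular values via eigenvalues of the dense Gram matrix Y^T Y."""
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        return 0.0
    rows = x.size - (order - 1) * delay
    y = np.empty((rows, order))
    for i in range(rows):
        for j in range(order):
            y[i, j] = x[i + j * delay]
    eigvals = np.linalg.eigvalsh(y.T @ y)
    sv = np.sqrt(np.clip(eigvals, 0.0, None))
    total = sv.sum()
    sbar = [s / total for s in sv if s / total > 0]
    return -sum(s * math.log2(s) for s in sbar)


def confusion_oracle(labels, predictions, positive):
    """Four-way enumeration of a binary confusion table."""
    tp = fp = tn = fn = 0
    for t, p in zip(labels, predictions):
        if t == positive and p == positive:
            tp += 1
        elif t != positive and p == positive:
            fp += 1
        elif t != positive and p != positive:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn
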