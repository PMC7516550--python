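"""Empirical mode decomposition and its noise-assisted ensemble variants.

EMD splits a series into intrinsic mode functions (IMFs) — oscillations
whose zero-crossing and extrema counts differ by at most one and whose
local envelope mean is near zero — plus a residual trend.  Sifting
repeatedly subtracts the mean of cubic-spline envelopes through the local
maxima and minima until a Cauchy-type criterion is met.

EEMD averages EMD runs over independent white-noise perturbations to
suppress mode mixing; CEEMD uses complementary ±noise pairs so the added
noise cancels in the averaged modes, giving a cleaner reconstruction at
the same ensemble size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "DecomposeConfig",
    "Decomposition",
    "InsufficientExtremaError",
    "find_extrema",
    "envelope_mean",
    "sift",
    "is_imf",
    "max_imf_count",
    "emd",
    "eemd",
    "ceemd",
]


class InsufficientExtremaError(ValueError):
    """The series is monotone or too flat to build both envelopes."""


@dataclass(frozen=True)
class DecomposeConfig:
    """Knobs for sifting and the noise ensembles.

    max_imfs: IMF cap; ``None`` means the automatic floor(log2 n) rule.
    noise_amplitude: ensemble noise sd as a fraction of the input sd.
    n_pairs: complementary noise pairs (CEEMD) or realizations (EEMD).
    sift_sd_threshold: Cauchy-type stop, Σ(h_prev−h)²/Σh_prev² below this.
    max_sift_iters: hard cap on sifting iterations per IMF.
    boundary: end-effect handling; only extrema mirroring is implemented.
    """

    max_imfs: Optional[int] = None
    noise_amplitude: float = 0.2
    n_pairs: int = 50
    sift_sd_threshold: float = 0.2
    max_sift_iters: int = 100
    boundary: str = "mirror"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.sift_sd_threshold <= 0:
            raise ValueError("sift_sd_threshold must be > 0")
        if self.boundary != "mirror":
            raise ValueError(f"unsupported boundary mode {self.boundary!r}")


@dataclass
class Decomposition:
    """Ordered IMFs (highest frequency first) plus the residual trend.

    ``ensemble_residue`` holds the average of the per-member EMD residues
    for eemd/ceemd (before the exact-reconstruction subtraction step);
    it is ``None`` for plain emd.
    """

    imfs: list[np.ndarray]
    residue: np.ndarray
    source_n: int
    method: str
    config: DecomposeConfig
    degenerate: bool = False
    ensemble_residue: Optional[np.ndarray] = None

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def components(self) -> dict[str, np.ndarray]:
        """Named components: imf_1..imf_M then residue."""
        out = {f"imf_{j + 1}": imf for j, imf in enumerate(self.imfs)}
        out["residue"] = self.residue
        return out

    def reconstruction(self) -> np.ndarray:
        return np.sum(self.imfs, axis=0) + self.residue if self.imfs else self.residue

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({k: v for k, v in self.components().items()})


# ---------------------------------------------------------------------------
# Extrema and envelopes
# ---------------------------------------------------------------------------


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima, in ascending order.

    A flat plateau that forms a peak or trough contributes the midpoint
    index of its tied samples (floored for even plateau lengths).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to find interior extrema")
    dx = np.diff(x)
    nz = np.flatnonzero(dx)
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = np.sign(dx[nz])
    chg = np.flatnonzero(s[:-1] != s[1:])
    if chg.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    # A run of equal samples between slopes nz[c]+1 .. nz[c+1]; midpoint.
    mids = (nz[chg] + 1 + nz[chg + 1]) // 2
    rising = s[chg] > 0
    return mids[rising], mids[~rising]


def _mirrored_knots(
    idx: np.ndarray, values: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extend extrema by reflecting the two nearest each end across it."""
    left_pos = -idx[1::-1]
    left_val = values[1::-1]
    right_pos = 2 * (n - 1) - idx[:-3:-1]
    right_val = values[:-3:-1]
    pos = np.concatenate([left_pos, idx, right_pos])
    val = np.concatenate([left_val, values, right_val])
    # Drop any duplicate knot created when an extremum sits on an endpoint.
    keep = np.concatenate([[True], np.diff(pos) > 0])
    return pos[keep], val[keep]


def envelope_mean(x: np.ndarray, boundary: str = "mirror") -> np.ndarray:
    """Pointwise mean of the cubic-spline upper and lower envelopes.

    Raises :class:`InsufficientExtremaError` when fewer than two maxima or
    two minima exist — the signal for sifting to stop.
    """
    if boundary != "mirror":
        raise ValueError(f"unsupported boundary mode {boundary!r}")
    x = np.asarray(x, dtype=float)
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise InsufficientExtremaError(
            f"{maxima.size} maxima / {minima.size} minima: cannot build envelopes"
        )
    t = np.arange(x.size)
    up_pos, up_val = _mirrored_knots(maxima, x[maxima], x.size)
    lo_pos, lo_val = _mirrored_knots(minima, x[minima], x.size)
    upper = CubicSpline(up_pos, up_val)(t)
    lower = CubicSpline(lo_pos, lo_val)(t)
    return (upper + lower) / 2.0


# ---------------------------------------------------------------------------
# Sifting
# ---------------------------------------------------------------------------


def sift(x: np.ndarray, config: DecomposeConfig = DecomposeConfig()) -> np.ndarray:
    """Extract one candidate IMF by iterated envelope-mean subtraction.

    Stops when the normalized squared change Σ(h_prev−h)²/Σh_prev² drops
    below ``sift_sd_threshold`` and the candidate satisfies the IMF
    conditions (:func:`is_imf`), when extrema run out, or at the
    iteration cap.
    """
    h = np.asarray(x, dtype=float).copy()
    if not np.any(h):
        return h
    for _ in range(config.max_sift_iters):
        try:
            maxima, minima = find_extrema(h)
        except ValueError:
            break
        if maxima.size < 2 or minima.size < 2:
            break
        try:
            m = envelope_mean(h, config.boundary)
        except InsufficientExtremaError:
            break
        denom = np.sum(h * h)
        if denom == 0:
            break
        sd = np.sum(m * m) / denom  # since h_new = h − m
        h -= m
        if sd < config.sift_sd_threshold and is_imf(h):
            break
    return h


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]  # exact zeros join the neighbouring sign
    return int(np.count_nonzero(s[:-1] != s[1:])) if s.size > 1 else 0


def is_imf(x: np.ndarray, tolerance: int = 1) -> bool:
    """Check the two IMF conditions.

    Zero-crossing and extrema counts must differ by at most ``tolerance``,
    and the envelope mean must stay within 10% of the peak amplitude.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3 or not np.any(x):
        return False
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    if n_ext == 0:
        return False
    if abs(_zero_crossings(x) - n_ext) > tolerance:
        return False
    try:
        m = envelope_mean(x)
    except InsufficientExtremaError:
        return False
    return float(np.max(np.abs(m))) <= 0.1 * float(np.max(np.abs(x)))


def max_imf_count(n: int) -> int:
    """Automatic IMF cap: floor(log2 n).

    Reproduces the dyadic-filter-bank expectation that each successive IMF
    roughly halves in frequency (4097 → 12, 17 664 → 14).
    """
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    return int(n).bit_length() - 1


# ---------------------------------------------------------------------------
# EMD and the noise ensembles
# ---------------------------------------------------------------------------


def _as_vector(x) -> np.ndarray:
    samples = getattr(x, "samples", x)
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 2:
        if arr.shape[0] != 1:
            raise ValueError(
                "decomposition expects a single-channel series; "
                "flatten multi-channel segments first"
            )
        arr = arr[0]
    return arr


def emd(x, config: DecomposeConfig = DecomposeConfig()) -> Decomposition:
    """Plain empirical mode decomposition with exact reconstruction."""
    data = _as_vector(x)
    n = data.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    cap = config.max_imfs if config.max_imfs is not None else max_imf_count(n)
    residue = data.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < cap:
        try:
            maxima, minima = find_extrema(residue)
        except ValueError:
            break
        if maxima.size < 2 or minima.size < 2:
            break
        imf = sift(residue, config)
        if not np.any(imf):
            break
        imfs.append(imf)
        residue = residue - imf
    if not imfs:
        return Decomposition([], data.copy(), n, "emd", config, degenerate=True)
    return Decomposition(imfs, residue, n, "emd", config)


def _padded_imfs(dec: Decomposition, m: int, n: int) -> np.ndarray:
    """Member IMFs as an (m, n) array, zero-padded when the run stopped early."""
    out = np.zeros((m, n))
    for j, imf in enumerate(dec.imfs[:m]):
        out[j] = imf
    return out


def _ensemble(
    x, config: DecomposeConfig, method: str
) -> Decomposition:
    data = _as_vector(x)
    n = data.size
    cap = config.max_imfs if config.max_imfs is not None else max_imf_count(n)
    member_cfg = replace(config, max_imfs=cap)
    sd = float(np.std(data))
    if config.noise_amplitude == 0 or sd == 0:
        warnings.warn(
            f"{method} with zero noise collapses to plain EMD", stacklevel=3
        )
        base = emd(data, member_cfg)
        return Decomposition(
            base.imfs, base.residue, n, method, config,
            degenerate=base.degenerate,
            ensemble_residue=base.residue.copy(),
        )
    scale = config.noise_amplitude * sd
    # Per-pair substreams: adding pairs never reshuffles earlier ones.
    children = np.random.SeedSequence(config.seed).spawn(config.n_pairs)
    acc = np.zeros((cap, n))
    res_acc = np.zeros(n)
    members = 0
    for child in children:
        rng = np.random.default_rng(child)
        w = rng.standard_normal(n) * scale
        perturbations = (w, -w) if method == "ceemd" else (w,)
        for noise in perturbations:
            dec = emd(data + noise, member_cfg)
            acc += _padded_imfs(dec, cap, n)
            res_acc += dec.residue
            members += 1
    imfs = list(acc / members)
    residue = data - np.sum(acc, axis=0) / members
    return Decomposition(
        imfs, residue, n, method, config, ensemble_residue=res_acc / members
    )


def ceemd(x, config: DecomposeConfig = DecomposeConfig()) -> Decomposition:
    """Complementary EEMD: averages EMD over ±white-noise pairs.

    Each of the ``n_pairs`` pairs contributes two ensemble members
    (signal + w and signal − w); member decompositions are truncated or
    zero-padded to the common IMF cap before averaging, and the residue is
    defined by subtraction so reconstruction is exact.
    """
    return _ensemble(x, config, "ceemd")


def eemd(x, config: DecomposeConfig = DecomposeConfig()) -> Decomposition:
    """Ensemble EMD with ``n_pairs`` independent (unpaired) noise draws."""
    return _ensemble(x, config, "eemd")
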