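"""Multi-domain feature extraction from raw signals and decomposed modes.

Four feature families are computed on the raw series and on every IMF and
residue of its decomposition: time-domain statistics, Fourier-domain
coefficients and spectral aggregates, Ricker-wavelet time-frequency
coefficients, and six entropy estimators (permutation, Shannon, spectral,
approximate, sample, and singular-value-decomposition entropy).

Logarithm bases follow the estimator definitions: Shannon and SVD entropy
are in bits (log2); permutation, spectral, approximate and sample entropy
use the natural log.

Feature names carry provenance: ``<component>__<feature>`` with component
one of ``raw``, ``imf_1``..``imf_M``, ``residue``.  Values that are
undefined for a given series (e.g. sample entropy with no template
matches) are reported as NaN rather than aborting the vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .decompose import DecomposeConfig, Decomposition, ceemd
from .signal_io import SegmentSet, Signal, flatten_multichannel

__all__ = [
    "EntropyConfig",
    "permutation_entropy",
    "shannon_entropy",
    "spectral_entropy",
    "approximate_entropy",
    "sample_entropy",
    "svd_entropy",
    "catalogue_features",
    "entropy_features",
    "extract_all",
    "extract_table",
    "feature_registry",
    "parse_feature_name",
    "COMPONENT_SEPARATOR",
]

COMPONENT_SEPARATOR = "__"

#: Quantile corridors for the change_quantiles features (low, high).
CHANGE_QUANTILE_CORRIDORS = (
    (0.0, 0.6),
    (0.1, 0.2),
    (0.2, 0.4),
    (0.2, 1.0),
    (0.4, 0.6),
    (0.8, 1.0),
)
CWT_WIDTHS = (2, 5, 10, 20)
N_FFT_COEFFICIENTS = 20
N_CHUNKS = 10


@dataclass(frozen=True)
class EntropyConfig:
    """Parameters of the six entropy estimators.

    Defaults: permutation order 3 at delay 1; approximate entropy with
    m = 2, r = 0.15·sd, delay 1; sample entropy with m = 2, r = 0.2·sd,
    delay 1; SVD embedding order 3 at delay 1; spectral entropy over 100
    frequency components up to Nyquist; Shannon entropy over a 100-bin
    equal-width amplitude histogram.
    """

    pe_order: int = 3
    pe_delay: int = 1
    apen_m: int = 2
    apen_r: float = 0.15
    apen_tau: int = 1
    saen_m: int = 2
    saen_r: float = 0.2
    saen_tau: int = 1
    svd_order: int = 3
    svd_delay: int = 1
    spe_f: int = 100
    shannon_bins: int = 100

    def __post_init__(self) -> None:
        if min(self.pe_order, self.apen_m, self.saen_m, self.svd_order) < 2:
            raise ValueError("embedding orders must be >= 2")
        if min(self.pe_delay, self.apen_tau, self.saen_tau, self.svd_delay) < 1:
            raise ValueError("delays must be >= 1")
        if self.apen_r <= 0 or self.saen_r <= 0:
            raise ValueError("similarity radii must be > 0")


# ---------------------------------------------------------------------------
# Entropy estimators
# ---------------------------------------------------------------------------


def _embed(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    """Delay-embedding matrix of shape (N−(order−1)·delay, order)."""
    n = x.size - (order - 1) * delay
    if n < 1:
        raise ValueError(
            f"series of length {x.size} too short for order {order}, delay {delay}"
        )
    idx = np.arange(n)[:, None] + np.arange(order)[None, :] * delay
    return x[idx]


def permutation_entropy(x, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Shannon entropy (natural log) of ordinal-pattern frequencies.

    Ties are broken by temporal order (stable ranking).
    """
    x = np.asarray(x, dtype=float)
    m, tau = cfg.pe_order, cfg.pe_delay
    if x.size <= (m - 1) * tau + 1:
        raise ValueError(f"series of length {x.size} too short for order {m}")
    windows = _embed(x, m, tau)
    ranks = np.argsort(windows, axis=1, kind="stable")
    codes = (ranks * (m ** np.arange(m))[None, :]).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def shannon_entropy(x, n_bins: int = 100) -> float:
    """Histogram Shannon entropy in bits over an equal-width amplitude grid."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty series")
    if np.ptp(x) == 0:
        return 0.0  # single occupied bin
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def spectral_entropy(x, rate: float, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Entropy (natural log) of the binned, normalized power spectrum.

    The mean-removed periodogram is folded into ``spe_f`` equal-width
    frequency components between 0 and Nyquist; the DC offset carries no
    oscillatory information and is excluded by the detrending.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * cfg.spe_f:
        raise ValueError(
            f"series of length {x.size} too short for {cfg.spe_f} spectral components"
        )
    freqs, psd = sps.periodogram(x, fs=rate)
    total = psd.sum()
    if total <= 0:
        return 0.0  # silent signal
    edges = np.linspace(0.0, rate / 2.0, cfg.spe_f + 1)
    which = np.clip(np.searchsorted(edges, freqs, side="right") - 1, 0, cfg.spe_f - 1)
    p = np.bincount(which, weights=psd, minlength=cfg.spe_f)
    p = p / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _pairwise_abs(x: np.ndarray) -> np.ndarray:
    """Dense |x_i − x_j| matrix (the m = 1 Chebyshev template distance)."""
    return np.abs(x[:, None] - x[None, :])


def _template_distances(d1: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Chebyshev distances between all length-m delay templates.

    Built as a running maximum over diagonal-shifted copies of the
    pairwise sample-distance matrix ``d1``.
    """
    n = d1.shape[0] - (m - 1) * tau
    out = d1[:n, :n].copy()
    for k in range(1, m):
        off = k * tau
        np.maximum(out, d1[off : off + n, off : off + n], out=out)
    return out


#: Above this length the dense pairwise-distance matrix would be too large;
#: template matching switches to a chunked path.
_DENSE_LIMIT = 6000


def _match_fraction(
    templates: np.ndarray, r: float, exclude_self: bool
) -> np.ndarray:
    """Per-template fraction of templates within Chebyshev distance r.

    Chunked over rows so memory stays bounded for long series; used when
    the shared-distance fast path would not fit in memory.
    """
    n = templates.shape[0]
    counts = np.zeros(n)
    chunk = max(1, int(4e6 // max(n, 1)))
    for start in range(0, n, chunk):
        block = templates[start : start + chunk]
        d = np.max(np.abs(block[:, None, :] - templates[None, :, :]), axis=2)
        counts[start : start + chunk] = (d <= r).sum(axis=1)
    if exclude_self:
        counts -= 1.0
        return counts / (n - 1)
    return counts / n


def approximate_entropy(x, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Pincus approximate entropy, self-matches included, natural log.

    φ^m(r) is the mean log fraction of templates within Chebyshev radius
    r = ``apen_r``·sd of each length-m template; ApEn = φ^m − φ^{m+1}.
    """
    x = np.asarray(x, dtype=float)
    m, tau = cfg.apen_m, cfg.apen_tau
    if x.size <= (m + 1) * tau + 1:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    sd = float(np.std(x))
    if sd == 0:
        return 0.0  # degenerate similarity radius
    r = cfg.apen_r * sd
    d1 = _pairwise_abs(x) if x.size <= _DENSE_LIMIT else None

    def phi(order: int) -> float:
        if d1 is not None:
            d = _template_distances(d1, order, tau)
            c = (d <= r).sum(axis=1) / d.shape[0]
        else:
            c = _match_fraction(_embed(x, order, tau), r, exclude_self=False)
        return float(np.mean(np.log(c)))  # self-match keeps c > 0

    return phi(m) - phi(m + 1)


def sample_entropy(x, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Richman–Moorman sample entropy, self-matches excluded.

    −ln(A/B) with B the m-point and A the (m+1)-point template-match
    probabilities at radius r = ``saen_r``·sd.  Returns NaN when either
    probability is zero (the statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    m, tau = cfg.saen_m, cfg.saen_tau
    if x.size <= m * tau + 1:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    sd = float(np.std(x))
    if sd == 0:
        return math.nan
    r = cfg.saen_r * sd
    # Both template lengths range over the same N − m·tau start points.
    n_templates = x.size - m * tau
    d1 = _pairwise_abs(x) if x.size <= _DENSE_LIMIT else None

    def matches(order: int) -> float:
        if d1 is not None:
            d = _template_distances(d1, order, tau)[:n_templates, :n_templates]
            counts = (d <= r).sum(axis=1).astype(float) - 1.0  # drop self-match
            return float(np.mean(counts / (n_templates - 1)))
        templates = _embed(x, order, tau)[:n_templates]
        return float(np.mean(_match_fraction(templates, r, exclude_self=True)))

    b = matches(m)
    a = matches(m + 1)
    if a <= 0 or b <= 0:
        return math.nan
    return -math.log(a / b)


def svd_entropy(x, cfg: EntropyConfig = EntropyConfig()) -> float:
    """Entropy (bits) of the normalized singular values of the delay embedding."""
    x = np.asarray(x, dtype=float)
    if x.size < (cfg.svd_order - 1) * cfg.svd_delay + 2:
        raise ValueError(f"series of length {x.size} too short for order {cfg.svd_order}")
    if not np.any(x):
        return 0.0
    y = _embed(x, cfg.svd_order, cfg.svd_delay)
    s = np.linalg.svd(y, compute_uv=False)
    sbar = s / s.sum()
    sbar = sbar[sbar > 0]
    return float(-(sbar * np.log2(sbar)).sum())


def entropy_features(
    x, rate: float, cfg: EntropyConfig = EntropyConfig()
) -> dict[str, float]:
    """All six entropy estimators as a name → value mapping (NaN on failure)."""
    x = np.asarray(x, dtype=float)
    out: dict[str, float] = {}
    calls = {
        "permutation_entropy": lambda: permutation_entropy(x, cfg),
        "shannon_entropy": lambda: shannon_entropy(x, cfg.shannon_bins),
        "spectral_entropy": lambda: spectral_entropy(x, rate, cfg),
        "approximate_entropy": lambda: approximate_entropy(x, cfg),
        "sample_entropy": lambda: sample_entropy(x, cfg),
        "svd_entropy": lambda: svd_entropy(x, cfg),
    }
    for name, fn in calls.items():
        try:
            out[name] = float(fn())
        except ValueError:
            out[name] = math.nan
    return out


# ---------------------------------------------------------------------------
# Time / frequency / time-frequency catalogue
# ---------------------------------------------------------------------------


def _autocorrelations(x: np.ndarray, nlags: int) -> np.ndarray:
    import warnings

    from statsmodels.tsa.stattools import acf

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant modes yield NaN acf
        return acf(x, nlags=nlags, fft=True)[1:]


def _partial_autocorrelations(x: np.ndarray, nlags: int) -> np.ndarray:
    """Yule-Walker (MLE) partial autocorrelations at lags 1..nlags.

    Calls yule_walker per lag directly: the pacf convenience wrapper
    re-arms warning filters internally, which floods runs on degenerate
    (constant/zero) decomposition modes.
    """
    import warnings

    from statsmodels.regression.linear_model import yule_walker

    out = np.empty(nlags)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(1, nlags + 1):
            rho, _ = yule_walker(x, order=k, method="mle")
            out[k - 1] = rho[-1]
    return out


def _ar_coefficients(x: np.ndarray, order: int) -> np.ndarray:
    """Least-squares AR(order) coefficients (no intercept term reported)."""
    rows = x.size - order
    design = np.column_stack(
        [np.ones(rows)] + [x[order - k : x.size - k] for k in range(1, order + 1)]
    )
    coef, *_ = np.linalg.lstsq(design, x[order:], rcond=None)
    return coef[1:]


def _change_quantiles(x: np.ndarray, ql: float, qh: float) -> float:
    """Mean |consecutive change| while the series stays inside the
    [quantile(ql), quantile(qh)] amplitude corridor."""
    lo, hi = np.quantile(x, [ql, qh])
    inside = (x >= lo) & (x <= hi)
    both = inside[:-1] & inside[1:]
    if not both.any():
        return 0.0
    return float(np.mean(np.abs(np.diff(x))[both]))


def _number_peaks(x: np.ndarray, support: int) -> int:
    core = x[support:-support]
    ok = np.ones(core.size, dtype=bool)
    for k in range(1, support + 1):
        ok &= core > x[support - k : support - k + core.size]
        ok &= core > x[support + k : support + k + core.size]
    return int(ok.sum())


def _weighted_moments(values: np.ndarray, weights: np.ndarray) -> dict[str, float]:
    total = weights.sum()
    if total <= 0:
        return {"centroid": math.nan, "skew": math.nan, "kurtosis": math.nan}
    p = weights / total
    centroid = float((values * p).sum())
    var = float(((values - centroid) ** 2 * p).sum())
    if var <= 0:
        return {"centroid": centroid, "skew": math.nan, "kurtosis": math.nan}
    sd = math.sqrt(var)
    skew = float((((values - centroid) / sd) ** 3 * p).sum())
    kurt = float((((values - centroid) / sd) ** 4 * p).sum())
    return {"centroid": centroid, "skew": skew, "kurtosis": kurt}


def catalogue_features(
    x, rate: float, strict: bool = True
) -> dict[str, float]:
    """The mandatory time/frequency/time-frequency catalogue.

    With ``strict`` (the default) a series too short for some feature
    raises a ValueError naming it; inside :func:`extract_all` failures are
    reported as NaN instead.
    """
    import warnings

    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError(f"catalogue needs >= 16 samples, got {x.size}")
    out: dict[str, float] = {}

    def put(name: str, fn) -> None:
        try:
            with warnings.catch_warnings():
                # Degenerate series (constant or all-zero modes) produce
                # NaN features by design; the warnings add nothing.
                warnings.simplefilter("ignore")
                out[name] = float(fn())
        except Exception:
            if strict:
                raise ValueError(f"feature {name!r} failed on this series") from None
            out[name] = math.nan

    diffs = np.diff(x)

    # --- time domain -------------------------------------------------------
    put("absolute_energy", lambda: np.sum(x * x))
    total_energy = float(np.sum(x * x))
    for i, chunk in enumerate(np.array_split(x, N_CHUNKS)):
        put(
            f"energy_ratio_by_chunks__{i}",
            lambda c=chunk: np.sum(c * c) / total_energy if total_energy > 0 else math.nan,
        )
    acfs = None
    try:
        acfs = _autocorrelations(x, 10)
    except Exception:
        pass
    for lag in range(1, 11):
        put(
            f"autocorrelation__lag_{lag}",
            lambda v=acfs, k=lag: v[k - 1] if v is not None else math.nan,
        )
    if acfs is not None:
        put("agg_autocorrelation__mean", lambda: np.nanmean(acfs))
        put("agg_autocorrelation__median", lambda: np.nanmedian(acfs))
        put("agg_autocorrelation__var", lambda: np.nanvar(acfs))
    else:
        out["agg_autocorrelation__mean"] = math.nan
        out["agg_autocorrelation__median"] = math.nan
        out["agg_autocorrelation__var"] = math.nan
    pac = None
    try:
        pac = _partial_autocorrelations(x, 5)
    except Exception:
        pass
    for lag in range(1, 6):
        put(
            f"partial_autocorrelation__lag_{lag}",
            lambda v=pac, k=lag: v[k - 1] if v is not None else math.nan,
        )
    ar = None
    try:
        ar = _ar_coefficients(x, 10)
    except Exception:
        pass
    for k in range(1, 11):
        put(f"ar_coefficient__{k}", lambda v=ar, j=k: v[j - 1] if v is not None else math.nan)
    trend = stats.linregress(np.arange(x.size), x)
    put("linear_trend__slope", lambda: trend.slope)
    put("linear_trend__intercept", lambda: trend.intercept)
    put("linear_trend__stderr", lambda: trend.stderr)
    put("linear_trend__rvalue", lambda: trend.rvalue)
    put("mean_abs_change", lambda: np.mean(np.abs(diffs)))
    put("absolute_sum_of_changes", lambda: np.sum(np.abs(diffs)))
    for ql, qh in CHANGE_QUANTILE_CORRIDORS:
        put(
            f"change_quantiles__{ql}_{qh}",
            lambda a=ql, b=qh: _change_quantiles(x, a, b),
        )
    put("maximum", lambda: np.max(x))
    put("minimum", lambda: np.min(x))
    put("mean", lambda: np.mean(x))
    put("median", lambda: np.median(x))
    put("sum_values", lambda: np.sum(x))
    put("standard_deviation", lambda: np.std(x))
    put("variance", lambda: np.var(x))
    put("quantile__0.2", lambda: np.quantile(x, 0.2))
    put("quantile__0.8", lambda: np.quantile(x, 0.8))
    put("number_peaks__support_1", lambda: _number_peaks(x, 1))
    put("number_peaks__support_3", lambda: _number_peaks(x, 3))
    put("number_crossing__level_1", lambda: np.count_nonzero(np.diff(x > 1)))
    put("range_count__m1_1", lambda: np.count_nonzero((x >= -1) & (x < 1)))
    _, counts = np.unique(x, return_counts=True)
    put(
        "percentage_of_reoccurring_datapoints",
        lambda: counts[counts > 1].sum() / x.size,
    )
    put("ratio_value_number_to_length", lambda: counts.size / x.size)
    chunk_maxima = np.array([c.max() for c in np.array_split(x, N_CHUNKS)])
    agg = stats.linregress(np.arange(chunk_maxima.size), chunk_maxima)
    put("agg_linear_trend__max_slope", lambda: agg.slope)
    put("agg_linear_trend__max_intercept", lambda: agg.intercept)
    put("agg_linear_trend__max_stderr", lambda: agg.stderr)
    put("agg_linear_trend__max_rvalue", lambda: agg.rvalue)

    # --- frequency domain --------------------------------------------------
    spectrum = np.fft.rfft(x)
    for k in range(N_FFT_COEFFICIENTS):
        coef = spectrum[k] if k < spectrum.size else math.nan
        put(f"fft_coefficient__{k}_real", lambda c=coef: np.real(c))
        put(f"fft_coefficient__{k}_imag", lambda c=coef: np.imag(c))
        put(f"fft_coefficient__{k}_abs", lambda c=coef: np.abs(c))
    mags = np.abs(spectrum)
    moments = _weighted_moments(np.arange(mags.size, dtype=float), mags)
    put("fft_aggregated__centroid", lambda: moments["centroid"])
    put("fft_aggregated__skew", lambda: moments["skew"])
    put("fft_aggregated__kurtosis", lambda: moments["kurtosis"])

    # --- time-frequency domain ---------------------------------------------
    import pywt

    coeffs, _ = pywt.cwt(x, scales=np.asarray(CWT_WIDTHS, dtype=float), wavelet="mexh")
    for width, row in zip(CWT_WIDTHS, coeffs):
        put(f"cwt_coefficients__width_{width}_mean", lambda r=row: np.mean(r))
        put(f"cwt_coefficients__width_{width}_std", lambda r=row: np.std(r))
        put(f"cwt_coefficients__width_{width}_absmax", lambda r=row: np.max(np.abs(r)))
    put(
        "number_cwt_peaks__max_width_5",
        lambda: len(sps.find_peaks_cwt(x, np.arange(1, 6))),
    )
    return out


# ---------------------------------------------------------------------------
# Registry and provenance
# ---------------------------------------------------------------------------

_DOMAIN_PREFIXES = {
    "time-frequency": ("cwt_coefficients", "number_cwt_peaks"),
    "frequency": ("fft_coefficient", "fft_aggregated"),
    "entropy": (
        "permutation_entropy",
        "shannon_entropy",
        "spectral_entropy",
        "approximate_entropy",
        "sample_entropy",
        "svd_entropy",
    ),
}


def feature_domain(feature: str) -> str:
    """Domain category (time, frequency, time-frequency, entropy) of a feature."""
    for domain, prefixes in _DOMAIN_PREFIXES.items():
        if feature.startswith(prefixes):
            return domain
    return "time"


def parse_feature_name(name: str) -> tuple[str, str]:
    """Split a prefixed feature name back into (component, feature)."""
    component, _, feature = name.partition(COMPONENT_SEPARATOR)
    if not feature:
        raise ValueError(f"feature name {name!r} carries no component prefix")
    return component, feature


def feature_registry(rate: float = 256.0) -> list[dict]:
    """Catalogue description (name, domain, parameters) for documentation."""
    probe = np.sin(np.linspace(0, 40 * np.pi, 1024)) + 1e-3 * np.arange(1024)
    names = list(catalogue_features(probe, rate, strict=False))
    names += list(entropy_features(probe, rate))
    registry = []
    for name in names:
        base, _, params = name.partition(COMPONENT_SEPARATOR)
        registry.append(
            {"name": name, "base": base, "domain": feature_domain(name), "parameters": params}
        )
    return registry


# ---------------------------------------------------------------------------
# Per-segment extraction
# ---------------------------------------------------------------------------


def extract_all(
    decomp: Decomposition,
    raw: Signal | np.ndarray,
    cfg: EntropyConfig = EntropyConfig(),
    rate: float | None = None,
) -> dict[str, float]:
    """Catalogue + entropies on the raw series and every decomposed mode.

    Produces ``(catalogue size + 6) × (M + 2)`` provenance-prefixed
    entries; individual feature failures become NaN, never an abort.
    """
    if isinstance(raw, Signal):
        rate = raw.rate
        raw_vec = flatten_multichannel(raw).channel(0)
    else:
        raw_vec = np.asarray(raw, dtype=float)
        if rate is None:
            raise ValueError("rate is required when raw is a bare vector")
    if decomp.source_n != raw_vec.size:
        raise ValueError(
            f"decomposition of length {decomp.source_n} does not match raw length {raw_vec.size}"
        )
    blocks = {"raw": raw_vec, **decomp.components()}
    out: dict[str, float] = {}
    for component, series in blocks.items():
        feats = catalogue_features(series, rate, strict=False)
        feats.update(entropy_features(series, rate, cfg))
        for name, value in feats.items():
            out[f"{component}{COMPONENT_SEPARATOR}{name}"] = value
    return out


def extract_table(
    segset: SegmentSet,
    decompose_config: DecomposeConfig = DecomposeConfig(),
    entropy_config: EntropyConfig = EntropyConfig(),
    method: str = "ceemd",
    flatten_order: str = "channel-major",
) -> tuple[pd.DataFrame, pd.Series]:
    """Decompose and featurize every segment of a set.

    Multi-channel segments are flattened (``flatten_order``) into one
    series so each segment gets a single decomposition.  Returns the
    rectangular feature table and the aligned label series.
    """
    from .decompose import eemd, emd

    decomposers = {"emd": emd, "eemd": eemd, "ceemd": ceemd}
    if method not in decomposers:
        raise ValueError(f"unknown decomposition method {method!r}")
    rows = []
    for segment in segset.segments:
        flat = flatten_multichannel(segment, flatten_order)
        decomp = decomposers[method](flat.channel(0), decompose_config)
        rows.append(extract_all(decomp, flat, entropy_config))
    table = pd.DataFrame(rows)
    labels = pd.Series(segset.labels, name="label")
    return table, labels
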