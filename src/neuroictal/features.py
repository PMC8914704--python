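"""Per-epoch, per-channel feature extraction.

Each epoch-channel yields up to 23 features:

* ``CD`` — correlation dimension, the Grassberger–Procaccia scaling
  exponent of the correlation sum over delay-embedded points.  Low values
  indicate low-dimensional deterministic dynamics; ictal discharges are
  expected to score lower than stochastic background activity.
* ``SampEn`` — sample entropy, ``-ln(A/B)`` where ``A`` and ``B`` count
  template matches of length ``m+1`` and ``m`` under the Chebyshev metric
  with self-matches excluded (Richman–Moorman counting).  Irregular ictal
  transients are expected to score higher than smooth background.
* 21 sub-band statistics — a six-level discrete wavelet decomposition
  (DWD) splits each channel into detail bands D1..D6 and approximation A6
  (dyadic frequency halving: at 500 Hz, D1 = [125, 250] Hz down to
  A6 = [0, 3.90625] Hz), and each of the 7 sub-signals contributes
  RMS, MA (mean of absolute values) and AM (absolute value of the mean).

Features are optionally quantized to one byte each (affine [min, max] ->
[0, 255] learned on training data) so that a 21-channel pattern fits the
256-byte example budget of neuromorphic prototype memories (12 features
x 21 channels = 252 bytes).

The wavelet transform is an orthogonal Daubechies-4 filter bank
implemented here directly (no wavelet library is bundled with the
runtime).  The transform is periodized: the signal is reflection-padded
to a multiple of ``2**n_levels`` and each level applies circular
convolution, which makes the analysis/synthesis pair exactly orthogonal
and hence perfectly reconstructing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .eeg_data import Epoch

# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

#: Daubechies-4 (8-tap) orthonormal scaling (lowpass decomposition) filter.
DB4_LO = np.array([
    -0.010597401785069032, 0.0328830116668852, 0.030841381835560764,
    -0.18703481171909309, -0.027983769416859854, 0.6308807679298589,
    0.7148465705529157, 0.2303778133088965,
])
#: quadrature-mirror highpass: h[k] = (-1)^k * g[L-1-k]
DB4_HI = DB4_LO[::-1] * np.array([1 if i % 2 == 0 else -1
                                  for i in range(len(DB4_LO))])

BAND_NAMES = ("D1", "D2", "D3", "D4", "D5", "D6", "A6")
STAT_NAMES = ("RMS", "MA", "AM")

#: canonical per-channel feature order: nonlinear first, then the 21 DWD stats
CANONICAL_FEATURES = ("CD", "SampEn") + tuple(
    f"{stat}_{band}" for band in BAND_NAMES for stat in STAT_NAMES
)

NEUROMORPHIC_PATTERN_BYTES = 256  # per-example memory budget


@dataclass
class DWDConfig:
    mother_wavelet: str = "db4"
    n_levels: int = 6
    fs: float = 500.0

    def __post_init__(self):
        if self.mother_wavelet != "db4":
            raise ValueError("only the db4 mother wavelet is built in")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")


@dataclass
class SubbandSet:
    """D1..DL detail + AL approximation coefficient arrays with band ranges."""
    details: list[np.ndarray]          # details[0] = D1 (highest band)
    approximation: np.ndarray
    band_ranges: list[tuple[float, float]]
    band_names: list[str]

    def sub_signals(self):
        """All coefficient arrays in canonical band order D1..DL, AL."""
        return list(self.details) + [self.approximation]


@dataclass
class SampEnParams:
    m: int = 2
    r_mode: str = "relative_sd"        # or "absolute"
    r_value: float = 0.2
    max_samples: int | None = 1250     # desk-scale cap on series length

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("embedding length m must be >= 1")
        if self.r_value <= 0:
            raise ValueError("tolerance must be positive")
        if self.r_mode not in ("relative_sd", "absolute"):
            raise ValueError(f"unknown r_mode {self.r_mode!r}")


@dataclass
class CDParams:
    embed_dim: int = 5
    delay: int | None = None           # None: first acf zero-crossing
    delay_cap: int = 50                # fs/10 samples at 500 Hz
    n_radii: int = 24
    radius_percentiles: tuple[float, float] = (1.0, 50.0)
    fit_window: int = 8
    max_points: int = 400              # desk-scale cap on embedded points
    metric: str = "euclidean"          # or "chebyshev"

    def __post_init__(self):
        if self.embed_dim < 2:
            raise ValueError("embedding dimension must be >= 2")
        if self.delay is not None and self.delay < 1:
            raise ValueError("delay must be >= 1")
        if self.fit_window < 2:
            raise ValueError("fit_window must be >= 2")


@dataclass
class FeatureConfig:
    """Bundle of the per-stage configurations used by extraction."""
    dwd: DWDConfig = field(default_factory=DWDConfig)
    sampen: SampEnParams = field(default_factory=SampEnParams)
    cd: CDParams = field(default_factory=CDParams)
    clean: bool = True


@dataclass
class FeatureVector:
    values: np.ndarray                 # [n_channels x n_features]
    feature_names: list[str]
    channel_names: list[str] = field(default_factory=list)
    label: str = ""
    quantized: np.ndarray | None = None

    def flat(self) -> np.ndarray:
        """Channel-major flattening (channel 0 features, channel 1, ...)."""
        return self.values.reshape(-1)


# ---------------------------------------------------------------------------
# discrete wavelet decomposition (orthogonal db4, periodized)
# ---------------------------------------------------------------------------

def _dwt_step(x: np.ndarray):
    """One circular analysis step: x (even length) -> (approx, detail)."""
    n = x.size
    k = np.arange(n // 2)
    a = np.zeros(n // 2)
    d = np.zeros(n // 2)
    for m, (g, h) in enumerate(zip(DB4_LO, DB4_HI)):
        idx = (2 * k + m) % n
        a += g * x[idx]
        d += h * x[idx]
    return a, d


def _idwt_step(a: np.ndarray, d: np.ndarray):
    """Inverse of :func:`_dwt_step` (transpose of the orthogonal step)."""
    n = 2 * a.size
    x = np.zeros(n)
    k = np.arange(a.size)
    for m, (g, h) in enumerate(zip(DB4_LO, DB4_HI)):
        np.add.at(x, (2 * k + m) % n, g * a + h * d)
    return x


def _pad_to_multiple(x: np.ndarray, block: int):
    """Reflection-pad on the right to a multiple of ``block``."""
    n = x.size
    target = -(-n // block) * block
    if target == n:
        return x, n
    extra = target - n
    if extra > n:
        reps = -(-extra // n)
        tail = np.concatenate([x[::-1] if i % 2 == 0 else x
                               for i in range(reps)])[:extra]
    else:
        tail = x[-2:-extra - 2:-1] if extra > 1 else x[-2:-1]
        if tail.size < extra:          # very short signals
            tail = np.resize(x[::-1], extra)
    return np.concatenate([x, tail]), n


def min_epoch_samples(config: DWDConfig) -> int:
    """Smallest series length decomposable at ``config.n_levels`` levels."""
    return 2 ** config.n_levels


def subband_frequency_ranges(fs: float, n_levels: int):
    """Dyadic band edges: detail level k spans [fs/2^(k+1), fs/2^k]; the
    deepest approximation spans [0, fs/2^(L+1)]."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    ranges = [(fs / 2 ** (k + 1), fs / 2 ** k) for k in range(1, n_levels + 1)]
    ranges.append((0.0, fs / 2 ** (n_levels + 1)))
    return ranges


def dwd_decompose(epoch_channel: np.ndarray, config: DWDConfig | None = None
                  ) -> SubbandSet:
    """Six-level (by default) DWD of one epoch-channel into D1..DL, AL."""
    config = config or DWDConfig()
    x = np.asarray(epoch_channel, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("epoch_channel must be 1-D")
    need = min_epoch_samples(config)
    if x.size < need:
        raise ValueError(
            f"epoch of {x.size} samples too short for {config.n_levels}-level "
            f"decomposition (minimum {need})"
        )
    xp, _ = _pad_to_multiple(x, 2 ** config.n_levels)
    details = []
    a = xp
    for _ in range(config.n_levels):
        a, d = _dwt_step(a)
        details.append(d)
    ranges = subband_frequency_ranges(config.fs, config.n_levels)
    names = [f"D{k}" for k in range(1, config.n_levels + 1)] + [
        f"A{config.n_levels}"]
    return SubbandSet(details=details, approximation=a,
                      band_ranges=ranges, band_names=names)


def dwd_reconstruct(sub: SubbandSet, n_samples: int | None = None) -> np.ndarray:
    """Invert :func:`dwd_decompose`; crops padding when ``n_samples`` given."""
    a = sub.approximation
    for d in reversed(sub.details):
        a = _idwt_step(a, d)
    return a if n_samples is None else a[:n_samples]


def wavelet_artifact_clean(epoch_channel: np.ndarray,
                           config: DWDConfig | None = None) -> np.ndarray:
    """Wavelet-threshold cleaning of one epoch-channel.

    Detail coefficients are soft-thresholded at the universal threshold
    ``sigma * sqrt(2 ln N)`` with ``sigma`` estimated from the median
    absolute deviation of the finest detail band (D1), and the
    low-frequency drift is removed by zeroing the mean of the deepest
    approximation.  The cleaned signal is reconstructed at the original
    length.
    """
    config = config or DWDConfig()
    x = np.asarray(epoch_channel, dtype=np.float64)
    n = x.size
    sub = dwd_decompose(x, config)
    sigma = np.median(np.abs(sub.details[0])) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
    details = [np.sign(d) * np.maximum(np.abs(d) - thr, 0.0)
               for d in sub.details]
    approx = sub.approximation - sub.approximation.mean()
    cleaned = dwd_reconstruct(
        SubbandSet(details, approx, sub.band_ranges, sub.band_names), n)
    return cleaned


def subband_stats(sub: SubbandSet) -> np.ndarray:
    """RMS, MA, AM for each sub-signal, in canonical band order.

    Returns 3 * (n_levels + 1) values (21 for the default six levels);
    ordering matches :data:`CANONICAL_FEATURES`.
    """
    out = []
    for c in sub.sub_signals():
        c = np.asarray(c, dtype=np.float64)
        if c.size == 0:
            raise ValueError("empty coefficient array")
        out.extend([
            float(np.sqrt(np.mean(c ** 2))),   # RMS
            float(np.mean(np.abs(c))),         # MA
            float(abs(np.mean(c))),            # AM
        ])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

class DegenerateSeriesError(ValueError):
    """Tolerance cannot be resolved (e.g. relative r on a constant series)."""


def sample_entropy(series: np.ndarray, params: SampEnParams | None = None
                   ) -> float:
    """SampEn(m, r, n) = -ln(A / B) with Richman–Moorman counting.

    ``B`` counts ordered pairs (i != j) of m-length templates within
    Chebyshev distance r, ``A`` the same for (m+1)-length templates, both
    over the first ``n - m`` template start positions so the conditional-
    probability reading is exact.  ``A == 0`` returns ``+inf`` (maximally
    irregular at length m+1); ``B == 0`` raises (no matches to condition
    on, the statistic is undefined).
    """
    params = params or SampEnParams()
    x = np.asarray(series, dtype=np.float64).ravel()
    if params.max_samples is not None and x.size > params.max_samples:
        x = x[: params.max_samples]
    m = params.m
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series of {n} points too short for m={m}")
    if params.r_mode == "relative_sd":
        sd = float(x.std())
        if sd == 0.0:
            raise DegenerateSeriesError(
                "constant series: relative tolerance r = r_value * SD is "
                "zero; pass an absolute tolerance instead"
            )
        r = params.r_value * sd
    else:
        r = params.r_value

    # Exact ordered-pair counts via KD-trees under the Chebyshev metric;
    # both template lengths use the same n - m start positions.
    nt = n - m
    idx = np.arange(nt)[:, None] + np.arange(m + 1)[None, :]
    templates = x[idx]                  # (m+1)-length templates
    tree_b = cKDTree(templates[:, :m])
    b_count = int(tree_b.count_neighbors(tree_b, r, p=np.inf)) - nt
    tree_a = cKDTree(templates)
    a_count = int(tree_a.count_neighbors(tree_a, r, p=np.inf)) - nt
    if b_count == 0:
        raise ValueError(
            "no m-length template matches (B = 0): SampEn undefined; "
            "increase the tolerance r or the series length"
        )
    if a_count == 0:
        return float("inf")
    return float(-np.log(a_count / b_count))


# ---------------------------------------------------------------------------
# correlation dimension (Grassberger–Procaccia)
# ---------------------------------------------------------------------------

def autocorr_zero_crossing(x: np.ndarray, cap: int = 50) -> int:
    """First lag at which the autocorrelation crosses zero, capped."""
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 1
    cap = max(1, min(cap, x.size - 2))
    for lag in range(1, cap + 1):
        if np.dot(x[:-lag], x[lag:]) / denom <= 0:
            return lag
    return cap


def embed_delay(x: np.ndarray, embed_dim: int, delay: int):
    """Delay embedding: rows are (x[t], x[t+tau], ..., x[t+(E-1)tau])."""
    x = np.asarray(x, dtype=np.float64).ravel()
    span = (embed_dim - 1) * delay
    m = x.size - span
    if m < 2:
        raise ValueError(
            f"series of {x.size} points too short for E={embed_dim}, "
            f"tau={delay}"
        )
    idx = np.arange(m)[:, None] + delay * np.arange(embed_dim)[None, :]
    return x[idx]


def correlation_sum(points: np.ndarray, r: float, times: np.ndarray | None = None,
                    theiler: int = 0, metric: str = "euclidean") -> float:
    """C(r): fraction of distinct embedded-point pairs within distance r.

    Pairs closer in time than the Theiler window (|t_i - t_j| <= theiler)
    are excluded from both numerator and denominator.
    """
    points = np.asarray(points, dtype=np.float64)
    mcount = points.shape[0]
    if times is None:
        times = np.arange(mcount)
    d = pdist(points, metric=metric)
    dt = pdist(times[:, None].astype(np.float64), metric="chebyshev")
    valid = dt > theiler
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("Theiler window excludes every pair")
    return float(np.count_nonzero(d[valid] <= r)) / n_valid


def correlation_dimension(series: np.ndarray, params: CDParams | None = None
                          ) -> float:
    """Correlation dimension estimate CD = d log C(r) / d log r.

    The slope is taken over the sliding window of ``fit_window``
    consecutive radii (log-spaced between two percentiles of the pairwise
    distance distribution) with the best linear-fit quality (R^2),
    restricted to radii with C(r) > 0.
    """
    params = params or CDParams()
    x = np.asarray(series, dtype=np.float64).ravel()
    tau = params.delay or autocorr_zero_crossing(x, params.delay_cap)
    pts = embed_delay(x, params.embed_dim, tau)
    times = np.arange(pts.shape[0], dtype=np.float64)
    if pts.shape[0] > params.max_points:
        # random (fixed-seed) subsample: an even stride would alias
        # periodic orbits into clusters and bias the dimension downward
        sel = np.sort(np.random.default_rng(161803).choice(
            pts.shape[0], size=params.max_points, replace=False))
        pts, times = pts[sel], times[sel]

    d = pdist(pts, metric=params.metric)
    dt = pdist(times[:, None], metric="chebyshev")
    valid = dt > tau
    dv = d[valid]
    if dv.size == 0:
        raise ValueError("Theiler window excludes every pair")
    positive = dv[dv > 0]
    if positive.size == 0:
        raise ValueError("all pairwise distances zero: degenerate series")
    lo, hi = np.percentile(positive, params.radius_percentiles)
    if lo <= 0:
        lo = positive.min()
    if hi <= lo:
        hi = lo * 10.0
    radii = np.geomspace(lo, hi, params.n_radii)

    dv_sorted = np.sort(dv)
    counts = np.searchsorted(dv_sorted, radii, side="right")
    mask = counts > 0
    if not mask.any():
        raise ValueError("all correlation sums zero: radii too small")
    log_r = np.log(radii[mask])
    log_c = np.log(counts[mask] / dv.size)

    w = min(params.fit_window, log_r.size)
    if w < 2:
        raise ValueError("not enough usable radii for a slope fit")
    best_slope, best_r2 = None, -np.inf
    for i in range(log_r.size - w + 1):
        xr, yr = log_r[i:i + w], log_c[i:i + w]
        if np.ptp(xr) == 0 or np.ptp(yr) == 0:
            # saturated C(r) (slope 0) carries no scaling information
            continue
        slope, intercept = np.polyfit(xr, yr, 1)
        resid = yr - (slope * xr + intercept)
        ss_tot = float(np.sum((yr - yr.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
        if r2 > best_r2:
            best_r2, best_slope = r2, slope
    if best_slope is None:
        raise ValueError("no valid fit window over the radius grid")
    return float(max(best_slope, 0.0))


# ---------------------------------------------------------------------------
# per-epoch extraction
# ---------------------------------------------------------------------------

def extract_epoch_features(epoch: Epoch, feature_set=None,
                           config: FeatureConfig | None = None
                           ) -> FeatureVector:
    """Extract the (subset of the) 23 canonical features for every channel.

    Cleaning is applied first; CD and SampEn are computed on the cleaned
    signal and the DWD statistics on its decomposition.
    """
    config = config or FeatureConfig()
    names = list(feature_set) if feature_set is not None else list(
        CANONICAL_FEATURES)
    unknown = set(names) - set(CANONICAL_FEATURES)
    if unknown:
        raise ValueError(f"unknown feature names {sorted(unknown)}")

    dwd_cfg = DWDConfig(config.dwd.mother_wavelet, config.dwd.n_levels,
                        epoch.fs)
    want_cd = "CD" in names
    want_sampen = "SampEn" in names
    want_stats = any(n not in ("CD", "SampEn") for n in names)

    values = np.empty((epoch.n_channels, len(names)))
    col = {nm: j for j, nm in enumerate(names)}
    for ch in range(epoch.n_channels):
        x = epoch.data[ch]
        if config.clean:
            x = wavelet_artifact_clean(x, dwd_cfg)
        if want_cd:
            values[ch, col["CD"]] = correlation_dimension(x, config.cd)
        if want_sampen:
            try:
                values[ch, col["SampEn"]] = sample_entropy(x, config.sampen)
            except DegenerateSeriesError:
                values[ch, col["SampEn"]] = 0.0
        if want_stats:
            stats = subband_stats(dwd_decompose(x, dwd_cfg))
            for nm, v in zip(CANONICAL_FEATURES[2:], stats):
                if nm in col:
                    values[ch, col[nm]] = v
    return FeatureVector(values=values, feature_names=names,
                         label=epoch.label)


def extract_epoch_matrix(epochs, feature_set=None,
                         config: FeatureConfig | None = None):
    """Feature matrix [n_epochs x (n_channels * n_features)] + labels."""
    vecs, labels = [], []
    for ep in epochs:
        fv = extract_epoch_features(ep, feature_set, config)
        vecs.append(fv.flat())
        labels.append(ep.label)
    return np.asarray(vecs), np.asarray(labels)


# ---------------------------------------------------------------------------
# one-byte quantization
# ---------------------------------------------------------------------------

@dataclass
class QuantizationMap:
    """Per-feature affine [min, max] -> [0, 255] map learned on training data."""
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=np.float64)
        self.maxs = np.asarray(self.maxs, dtype=np.float64)
        if np.any(self.maxs < self.mins):
            raise ValueError("quantization map requires max >= min")


def fit_quantizer(training_vectors) -> QuantizationMap:
    X = np.asarray(training_vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training vectors to fit a quantizer")
    X = np.where(np.isfinite(X), X, np.nan)
    mins = np.nanmin(X, axis=0)
    maxs = np.nanmax(X, axis=0)
    mins = np.where(np.isnan(mins), 0.0, mins)
    maxs = np.where(np.isnan(maxs), 0.0, maxs)
    return QuantizationMap(mins=mins, maxs=maxs)


def quantize(vec, qmap: QuantizationMap) -> np.ndarray:
    """Map features to bytes; rounding is half-up, test-time values are
    clipped into the training range, constant features map to 0, and
    non-finite values saturate at 255."""
    v = np.asarray(vec, dtype=np.float64)
    span = qmap.maxs - qmap.mins
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(span > 0, (v - qmap.mins) / span * 255.0, 0.0)
    scaled = np.where(np.isfinite(v), scaled, 255.0)
    q = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5)
    return np.clip(q, 0, 255).astype(np.uint8)


def dequantize(qvec, qmap: QuantizationMap) -> np.ndarray:
    span = qmap.maxs - qmap.mins
    return qmap.mins + np.asarray(qvec, dtype=np.float64) / 255.0 * span
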