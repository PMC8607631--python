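"""Nonlinear-dynamics and information-theoretic voice measures.

These operate on raw sample sequences (numpy arrays), not Waveform objects:
recurrence period density entropy (RPDE), Grassberger-Procaccia correlation
dimension, pitch period entropy (PPE), detrended-fluctuation Hurst exponent,
normalized Lempel-Ziv (LZ76) complexity of the median-binarized signal,
permutation entropy, amplitude-histogram Shannon entropy, first minimum of
the auto mutual information, first zero of the autocorrelation, and the
multifractal spectrum width from multifractal DFA.

All measures are invariant to positive rescaling of the input: neighborhood
radii, histogram ranges and binarization thresholds are defined relative to
the signal's own scale. Measures that cannot be computed return NaN
(flagged missing) rather than raising, except where a precondition is
violated outright.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, rfft

from .errors import InsufficientDataError


@dataclass(frozen=True)
class EmbeddingSpec:
    """Time-delay embedding parameters for state-space measures."""

    dimension: int = 4
    delay: int = 35  # samples, tuned for 22.05 kHz voice
    radius_frac: float = 0.25  # neighborhood radius as a fraction of sd

    def __post_init__(self):
        if self.dimension < 2 or self.delay < 1 or self.radius_frac <= 0:
            raise ValueError("invalid embedding specification")


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = x.size - (m - 1) * tau
    if n < 2:
        raise InsufficientDataError("signal too short for this embedding")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def rpde(
    x: np.ndarray,
    spec: EmbeddingSpec = EmbeddingSpec(),
    max_return_s: float = 0.05,
    rate_hz: int = 22050,
    stride: int = 2,
) -> float:
    """Recurrence period density entropy in [0, 1].

    For each embedded point the time T of first return to its eps-ball
    after leaving it is recorded; RPDE is the normalized entropy of the
    return-time histogram, -sum p ln p / ln(T_max). Near 0 for strictly
    periodic signals (all returns at one period), near 1 for noise.
    """
    x = np.asarray(x, dtype=np.float64)
    sd = x.std()
    if sd == 0:
        return float("nan")
    emb = _embed(x / sd, spec.dimension, spec.delay)
    eps = spec.radius_frac
    n = emb.shape[0]
    horizon = int(round(max_return_s * rate_hz))
    returns = []
    for i in range(0, n - 2, stride):
        seg = emb[i + 1 : min(i + 1 + horizon, n)]
        d2 = np.einsum("ij,ij->i", seg - emb[i], seg - emb[i])
        outside = d2 > eps * eps
        left = np.argmax(outside) if outside.any() else -1
        if left < 0:
            continue
        back = outside[left:]
        ret = np.argmin(back) if (~back).any() else -1
        if ret <= 0:
            continue
        returns.append(left + ret + 1)
    if not returns:
        return float("nan")
    returns = np.asarray(returns)
    t_max = int(returns.max())
    if t_max <= 1:
        return 0.0
    counts = np.bincount(returns)[1:]
    p = counts[counts > 0] / counts.sum()
    if p.size <= 1:
        return 0.0
    h = -np.sum(p * np.log(p)) / np.log(t_max)
    return float(np.clip(h, 0.0, 1.0))


def correlation_dimension(
    x: np.ndarray,
    spec: EmbeddingSpec = EmbeddingSpec(),
    theiler_samples: int | None = None,
    max_points: int = 1200,
) -> float:
    """Grassberger-Procaccia correlation dimension D2.

    Correlation sums C(r) are evaluated on a log-spaced radius grid and D2
    is the least-squares slope of log C vs log r over the small-radius
    scaling region (r between the 2nd and 20th percentile of pairwise
    distances; larger radii saturate and flatten the slope).
    Pairs closer in time than a Theiler window (default: one embedding
    span, or one mean period if supplied) are excluded.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.std() == 0:
        return float("nan")
    emb = _embed(x / x.std(), spec.dimension, spec.delay)
    n = emb.shape[0]
    step = max(1, n // max_points)
    pts = emb[::step]
    idx = np.arange(0, n, step)
    theiler = theiler_samples if theiler_samples is not None else spec.delay * spec.dimension
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    tsep = np.abs(idx[:, None] - idx[None, :])
    mask = np.triu(tsep > theiler, k=1)
    dists = d[mask]
    if dists.size < 100 or np.all(dists == 0):
        return float("nan")
    lo, hi = np.percentile(dists, [2, 20])
    if lo <= 0:
        lo = dists[dists > 0].min()
    r_grid = np.geomspace(lo, hi, 12)
    c = np.array([(dists <= r).mean() for r in r_grid])
    good = c > 0
    if good.sum() < 3:
        return float("nan")
    slope = np.polyfit(np.log(r_grid[good]), np.log(c[good]), 1)[0]
    return float(slope)


def ppe(f0_track_hz: np.ndarray, n_bins: int = 30) -> float:
    """Pitch period entropy of a per-cycle/per-frame f0 sequence.

    The track is mapped to a semitone-like scale p_t = log(f0_t/median f0),
    whitened with an order-2 autoregressive filter fitted by least squares,
    and the normalized entropy of the residual histogram over [-0.5, 0.5]
    (30 bins) is returned. Invariant to transposition (f0 -> c*f0).
    """
    f0 = np.asarray(f0_track_hz, dtype=np.float64)
    if f0.size < 50:
        raise InsufficientDataError("PPE needs at least 50 voiced frames")
    if np.any(f0 <= 0):
        raise ValueError("f0 track must be positive")
    p = np.log(f0 / np.median(f0))
    # least-squares AR(2) whitening
    y = p[2:]
    design = np.column_stack([p[1:-1], p[:-2]])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    counts, _ = np.histogram(resid, bins=n_bins, range=(-0.5, 0.5))
    total = counts.sum()
    if total == 0:
        return float("nan")
    q = counts[counts > 0] / total
    return float(-np.sum(q * np.log(q)) / np.log(n_bins))


def _dfa_fluctuations(
    x: np.ndarray, scales: np.ndarray
) -> np.ndarray:
    """Per-scale arrays of squared window fluctuations, order-1 detrending.

    Windows are taken from both ends of the profile so all data is used.
    Returns a list (per scale) of F^2 values.
    """
    profile = np.cumsum(x - x.mean())
    out = []
    for s in scales:
        s = int(s)
        n_win = profile.size // s
        segs = profile[: n_win * s].reshape(n_win, s)
        segs_rev = profile[profile.size - n_win * s :].reshape(n_win, s)
        both = np.vstack([segs, segs_rev])
        t = np.arange(s, dtype=np.float64)
        design = np.column_stack([t, np.ones(s)])
        coef, *_ = np.linalg.lstsq(design, both.T, rcond=None)
        resid = both.T - design @ coef
        out.append(np.mean(resid**2, axis=0))
    return out


def _dfa_scales(n: int, s_min: int = 16) -> np.ndarray:
    s_max = n // 8
    if s_max <= s_min:
        raise InsufficientDataError("signal too short for DFA")
    scales = np.unique(np.geomspace(s_min, s_max, 12).astype(int))
    return scales


def hurst(x: np.ndarray) -> float:
    """Hurst exponent by order-1 detrended fluctuation analysis.

    White noise gives H ~ 0.5, persistent fractional Gaussian noise with
    Hurst parameter H gives slope ~ H, trend-dominated signals exceed 1.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 1024:
        raise InsufficientDataError("Hurst/DFA needs >= 1024 samples")
    if x.std() == 0:
        return float("nan")
    scales = _dfa_scales(x.size)
    f2 = _dfa_fluctuations(x, scales)
    f = np.array([np.sqrt(np.mean(v)) for v in f2])
    good = f > 0
    if good.sum() < 3:
        return float("nan")
    return float(np.polyfit(np.log(scales[good]), np.log(f[good]), 1)[0])


def mfsw(
    x: np.ndarray, q_values: np.ndarray | None = None, r2_min: float = 0.9
) -> float:
    """Multifractal spectrum width from multifractal DFA.

    Generalized fluctuation functions F_q(s) (order-1 detrending, scales 16
    to n/8, q in {-5..5} with the q->0 logarithmic mean) give generalized
    Hurst exponents h(q); the singularity strengths are alpha(q) =
    d[q h(q)]/dq and the width is max(alpha) - min(alpha). Returns NaN when
    scaling is degenerate (regression R^2 < r2_min for more than half the
    q values).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 4096:
        raise InsufficientDataError("MFDFA needs >= 4096 samples")
    if x.std() == 0:
        return float("nan")
    if q_values is None:
        q_values = np.arange(-5.0, 5.5, 1.0)
    scales = _dfa_scales(x.size)
    f2 = _dfa_fluctuations(x, scales)
    log_s = np.log(scales)
    h = np.empty(q_values.size)
    bad = 0
    for qi, q in enumerate(q_values):
        fq = np.empty(scales.size)
        for si, v in enumerate(f2):
            v = np.maximum(v, 1e-300)
            if abs(q) < 1e-12:
                fq[si] = np.exp(0.5 * np.mean(np.log(v)))
            else:
                fq[si] = np.mean(v ** (q / 2.0)) ** (1.0 / q)
        log_f = np.log(fq)
        slope, intercept = np.polyfit(log_s, log_f, 1)
        pred = slope * log_s + intercept
        ss_res = np.sum((log_f - pred) ** 2)
        ss_tot = np.sum((log_f - log_f.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        if r2 < r2_min:
            bad += 1
        h[qi] = slope
    if bad > q_values.size / 2:
        return float("nan")
    tau = q_values * h
    alpha = np.gradient(tau, q_values)
    return float(max(alpha.max() - alpha.min(), 0.0))


def lz76_word_count(symbols) -> int:
    """LZ76 exhaustive-history word count of a symbol sequence."""
    s = "".join(str(int(b)) for b in symbols)
    n = len(s)
    i, c = 0, 0
    while i < n:
        length = 1
        while i + length <= n and s.find(s[i : i + length], 0, i + length - 1) != -1:
            length += 1
        c += 1
        i += length
    return c


def lz2(x: np.ndarray) -> float:
    """Normalized two-symbol Lempel-Ziv (LZ76) complexity in [0, 1].

    The signal is binarized at its median; the LZ76 word count c(n) is
    normalized as c(n) * log2(n) / n, which approaches 1 for random
    sequences and ~2 log2(n)/n for constant ones.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 64:
        raise InsufficientDataError("LZ-2 needs >= 64 samples")
    bits = (x > np.median(x)).astype(np.uint8)
    c = lz76_word_count(bits)
    return float(np.clip(c * np.log2(n) / n, 0.0, 1.0))


def permutation_entropy(x: np.ndarray, m: int = 3, tau: int = 1) -> float:
    """Normalized permutation entropy of ordinal patterns, in [0, 1].

    Ties are broken by order of occurrence (stable argsort).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size <= m * tau:
        raise InsufficientDataError("signal too short for this pattern length")
    windows = _embed(x, m, tau)
    patterns = np.argsort(windows, axis=1, kind="stable")
    # encode each pattern as an integer
    codes = patterns @ (m ** np.arange(m))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    n_patterns = 1
    for k in range(2, m + 1):
        n_patterns *= k
    return float(np.clip(h / np.log(n_patterns), 0.0, 1.0))


def shannon_entropy(x: np.ndarray, bins: int = 64) -> float:
    """Normalized amplitude-histogram entropy over [-max|x|, max|x|]."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise InsufficientDataError("empty signal")
    peak = np.max(np.abs(x))
    if peak == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(-peak, peak))
    p = counts[counts > 0] / counts.sum()
    return float(np.clip(-np.sum(p * np.log2(p)) / np.log2(bins), 0.0, 1.0))


def ami_first_min(
    x: np.ndarray, rate_hz: int, max_lag_ms: float = 20.0, bins: int = 32
) -> float:
    """Lag (ms) of the first minimum of the auto mutual information,
    histogram-estimated with bins x bins cells.

    The histogram MI of strongly deterministic signals is twitchy across
    lags (bin-occupancy artifacts), so the profile is stabilized by a
    deterministic sub-bin dither and 5-point smoothing, and the first
    minimum is required to be a genuine basin: lower than its predecessor
    and no lower value within the lookahead window. If no such minimum
    exists within range, max_lag_ms is returned. For a sinusoid the first
    minimum sits near a quarter period; iid noise has near-zero MI
    everywhere and yields a minimum within the first milliseconds.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2048:
        raise InsufficientDataError("AMI needs >= 2048 samples")
    sd = x.std()
    if sd > 0:  # fixed-seed dither: deterministic given input and binning
        x = x + np.random.default_rng(12345).uniform(-0.05, 0.05, x.size) * sd
    max_lag = max(2, int(round(max_lag_ms * 1e-3 * rate_hz)))
    mi = np.empty(max_lag)
    for k, lag in enumerate(range(1, max_lag + 1)):
        a, b = x[:-lag], x[lag:]
        joint, _, _ = np.histogram2d(a, b, bins=bins)
        pj = joint / joint.sum()
        px = pj.sum(axis=1, keepdims=True)
        py = pj.sum(axis=0, keepdims=True)
        nz = pj > 0
        mi[k] = np.sum(pj[nz] * np.log(pj[nz] / (px @ py)[nz]))
    width = 5
    sm = np.convolve(mi, np.ones(width) / width, mode="valid")
    offset = (width - 1) // 2 + 1
    look = max(10, max_lag // 30)
    for k in range(1, sm.size - look):
        if sm[k] < sm[k - 1] and sm[k] <= sm[k + 1 : k + 1 + look].min():
            return float((k + offset) / rate_hz * 1e3)
    return float(max_lag_ms)


def acf_first_zero(
    x: np.ndarray, rate_hz: int, max_lag_ms: float = 50.0
) -> float:
    """Lag (ms) of the first zero crossing of the normalized autocorrelation,
    linearly interpolated between samples. NaN if no crossing in range."""
    x = np.asarray(x, dtype=np.float64)
    if x.std() == 0:
        raise ValueError("autocorrelation zero undefined for a constant signal")
    max_lag = int(round(max_lag_ms * 1e-3 * rate_hz))
    xc = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * x.size)))
    spec = rfft(xc, nfft)
    acf = irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    acf = acf / acf[0]
    below = np.flatnonzero(acf[1:] <= 0)
    if below.size == 0:
        return float("nan")
    k = int(below[0]) + 1
    prev, cur = acf[k - 1], acf[k]
    frac = prev / (prev - cur) if prev != cur else 0.0
    return float((k - 1 + frac) / rate_hz * 1e3)
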