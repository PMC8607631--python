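"""Pitch-synchronous, noise, cepstral, glottal and spectral voice features.

All operations take a trimmed one-second voiced :class:`~paravox.io.Waveform`.
Cycle-level measures (jitter, shimmer, glottal quotients) are computed from a
:class:`CycleSeries` produced by :func:`detect_cycles`; spectral measures
(CPP, MFCC) and excitation measures (GNE) work directly on the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, irfft, rfft
from scipy.linalg import solve_toeplitz
from scipy.signal import hilbert, lfilter, resample_poly

from .errors import InsufficientCyclesError, UnvoicedSignalError
from .io import Waveform

F0_MIN_HZ = 50.0
F0_MAX_HZ = 500.0


@dataclass(frozen=True)
class CycleSeries:
    """Per-glottal-cycle periods, peak amplitudes and phase durations.

    ``open_s``/``closed_s`` may be ``None`` until glottal analysis has run,
    or NaN-filled if the inverse-filtering analysis was degenerate.
    """

    onsets: np.ndarray  # sample indices of cycle starts
    periods_s: np.ndarray  # onset differences, seconds
    peak_amps: np.ndarray  # max |sample| within each cycle
    rate_hz: int
    open_s: np.ndarray | None = None
    closed_s: np.ndarray | None = None

    @property
    def n_cycles(self) -> int:
        return self.periods_s.size

    @property
    def mean_f0_hz(self) -> float:
        return float(1.0 / np.mean(self.periods_s))


def _normalized_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased normalized autocorrelation r(0..max_lag) via FFT."""
    x = x - x.mean()
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = rfft(x, nfft)
    acf = irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    if acf[0] <= 0:
        return np.zeros(max_lag + 1)
    return acf / acf[0]


def detect_cycles(
    w: Waveform,
    f0_min_hz: float = F0_MIN_HZ,
    f0_max_hz: float = F0_MAX_HZ,
) -> CycleSeries:
    """Locate glottal cycle onsets by period-constrained peak picking.

    The mean period comes from the global normalized autocorrelation peak in
    the [1/f0_max, 1/f0_min] lag band; cycle onsets are then picked as the
    dominant-polarity waveform peaks, each constrained to lie within +-30%
    of the running period from the previous onset.

    Raises
    ------
    UnvoicedSignalError
        If no autocorrelation peak above 0.3 exists in the search band.
    """
    fs = w.rate_hz
    x = w.samples
    lag_min = int(np.floor(fs / f0_max_hz))
    lag_max = int(np.ceil(fs / f0_min_hz))
    acf = _normalized_acf(x, min(lag_max, x.size - 1))
    band = acf[lag_min : lag_max + 1]
    if band.size == 0 or band.max() < 0.3:
        raise UnvoicedSignalError(
            "no autocorrelation peak above 0.3 in the f0 search band"
        )
    lag = lag_min + int(np.argmax(band))
    # parabolic refinement of the ACF peak
    if 1 <= lag < acf.size - 1:
        y0, y1, y2 = acf[lag - 1 : lag + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            lag = lag + 0.5 * (y0 - y2) / denom
    period = float(lag)

    # dominant polarity: pick the sign whose extreme is larger
    s = x if np.max(x) >= np.max(-x) else -x
    n = s.size

    # anchor on the strongest peak of the first period-and-a-half, then track
    # cycle-to-cycle lags by waveform matching: the lag in [0.7, 1.3] periods
    # maximizing the normalized cross-correlation of successive cycle-length
    # windows, refined to sub-sample precision on the correlation parabola
    first = int(np.argmax(s[: int(np.ceil(period * 1.5))]))
    onsets = [float(first)]
    run_period = period
    pos = first
    while True:
        # template shorter than one cycle: including the next pulse onset
        # would pull the alignment toward an average of adjacent periods
        win = int(round(0.7 * run_period))
        lo = int(np.floor(0.7 * run_period))
        hi = int(np.ceil(1.3 * run_period))
        if pos + hi + win >= n:
            break
        template = s[pos : pos + win]
        t_norm = np.sqrt(np.dot(template, template))
        if t_norm == 0:
            break
        lags = np.arange(lo, hi + 1)
        ncc = np.empty(lags.size)
        for k, lag in enumerate(lags):
            seg = s[pos + lag : pos + lag + win]
            denom = t_norm * np.sqrt(np.dot(seg, seg))
            ncc[k] = np.dot(template, seg) / denom if denom > 0 else 0.0
        k = int(np.argmax(ncc))
        best = float(lags[k])
        if 0 < k < lags.size - 1:  # parabolic refinement
            y0, y1, y2 = ncc[k - 1 : k + 2]
            d = y0 - 2 * y1 + y2
            if d < 0:
                best += 0.5 * (y0 - y2) / d
        onsets.append(onsets[-1] + best)
        run_period = 0.7 * run_period + 0.3 * best
        pos = int(round(onsets[-1]))
    onsets = np.asarray(onsets, dtype=np.float64)
    if onsets.size < 2:
        raise UnvoicedSignalError("fewer than two cycle onsets found")
    periods = np.diff(onsets) / fs
    ints = np.round(onsets).astype(int)
    # per-cycle amplitude from the inverse-filtered glottal flow: the raw
    # waveform peak mixes each pulse with the previous cycle's formant
    # ringing, which systematically shrinks cycle-to-cycle differences
    flow = glottal_flow(w)
    half = int(round(np.median(np.diff(ints)) / 2))
    amps = np.array(
        [
            np.ptp(flow[max(o - half, 0) : min(o + half, n)])
            for o in ints[:-1]
        ]
    )
    if not np.all(amps > 0):  # degenerate inverse filtering: waveform peaks
        amps = np.array(
            [
                np.max(np.abs(x[max(o - half, 0) : min(o + half, n)]))
                for o in ints[:-1]
            ]
        )
    return CycleSeries(
        onsets=onsets[:-1], periods_s=periods, peak_amps=amps, rate_hz=fs
    )


def _relative_mean_abs_diff_pct(v: np.ndarray) -> float:
    if v.size < 2:
        raise InsufficientCyclesError("need at least 2 cycles")
    return float(100.0 * np.mean(np.abs(np.diff(v))) / np.mean(v))


def jitter_local(c: CycleSeries) -> float:
    """Local jitter, percent: 100 * mean|T_{i+1}-T_i| / mean T_i."""
    return _relative_mean_abs_diff_pct(c.periods_s)


def shimmer_local(c: CycleSeries) -> float:
    """Local shimmer, percent: the jitter formula on cycle peak amplitudes."""
    return _relative_mean_abs_diff_pct(c.peak_amps)


def jitter_from_periods(periods_s: np.ndarray) -> float:
    """The local-jitter formula applied to an arbitrary period sequence.

    Exposed so that ground-truth cycle sequences (e.g. from the vowel
    synthesizer) can serve as an oracle for the extractor.
    """
    return _relative_mean_abs_diff_pct(np.asarray(periods_s, dtype=float))


def _frames(x: np.ndarray, frame: int, hop: int):
    starts = np.arange(0, x.size - frame + 1, hop)
    return starts


def hnr_db(w: Waveform, c: CycleSeries) -> float:
    """Harmonics-to-noise ratio in dB, frame-wise normalized autocorrelation.

    Per 40 ms frame (10 ms hop) the normalized ACF is evaluated at the lag
    nearest the local cycle period; with periodic fraction r the frame HNR
    is 10*log10(r/(1-r)), r clipped to [0.001, 0.999]; frames are averaged.
    """
    fs = w.rate_hz
    x = w.samples
    frame = int(round(0.040 * fs))
    hop = int(round(0.010 * fs))
    onsets = c.onsets
    vals = []
    for start in _frames(x, frame, hop):
        center = start + frame // 2
        i = np.searchsorted(onsets, center) - 1
        i = int(np.clip(i, 0, c.periods_s.size - 1))
        lag = int(round(c.periods_s[i] * fs))
        seg = x[start : start + frame]
        if lag <= 0 or lag >= seg.size:
            continue
        a = seg[:-lag] - seg[:-lag].mean()
        b = seg[lag:] - seg[lag:].mean()
        denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
        r = float(np.sum(a * b) / denom) if denom > 0 else 0.0
        r = float(np.clip(r, 0.001, 0.999))
        vals.append(10.0 * np.log10(r / (1.0 - r)))
    return float(np.mean(vals))


def cpp_db(
    w: Waveform,
    quefrency_band_ms: tuple[float, float] = (2.0, 20.0),
    frame_ms: float = 40.0,
    hop_ms: float = 20.0,
) -> float:
    """Cepstral peak prominence in dB.

    Per Hamming frame the real cepstrum of the dB log-magnitude spectrum is
    computed; the peak within the quefrency band (default 2-20 ms, i.e.
    50-500 Hz) is measured against a least-squares regression line fitted
    to the cepstrum over that band; frame values are averaged. A global
    gain change shifts the log spectrum by a constant, which lives entirely
    in quefrency zero, so CPP is gain invariant.
    """
    fs = w.rate_hz
    x = w.samples
    frame = int(round(frame_ms * 1e-3 * fs))
    hop = int(round(hop_ms * 1e-3 * fs))
    nfft = 1 << int(np.ceil(np.log2(2 * frame)))
    win = np.hamming(frame)
    q_lo = int(round(quefrency_band_ms[0] * 1e-3 * fs))
    q_hi = int(round(quefrency_band_ms[1] * 1e-3 * fs))
    q = np.arange(q_lo, q_hi + 1)
    vals = []
    for start in _frames(x, frame, hop):
        seg = x[start : start + frame] * win
        power = np.abs(rfft(seg, nfft)) ** 2
        floor = power.max() * 1e-16
        logspec_db = 10.0 * np.log10(np.maximum(power, max(floor, 1e-300)))
        cep = irfft(logspec_db, nfft)
        # power cepstrum on a dB scale; quefrency zero (overall gain) excluded
        pc = cep[1:] ** 2
        pc_db = 10.0 * np.log10(np.maximum(pc, pc.max() * 1e-12))
        band = pc_db[q_lo - 1 : q_hi]
        peak_i = int(np.argmax(band))
        slope, intercept = np.polyfit(q, band, 1)
        trend = slope * (q_lo + peak_i) + intercept
        vals.append(band[peak_i] - trend)
    return float(np.mean(vals))


def _lpc(x: np.ndarray, order: int) -> np.ndarray:
    """LPC coefficients a (with a[0]=1) by the autocorrelation method."""
    x = x - x.mean()
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = rfft(x * np.hamming(n), nfft)
    r = irfft(spec * np.conj(spec), nfft)[: order + 1]
    r[0] *= 1.0 + 1e-9
    if r[0] <= 0:
        return np.concatenate([[1.0], np.zeros(order)])
    coeffs = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    return np.concatenate([[1.0], -coeffs])


def gne(
    w: Waveform,
    bandwidth_hz: float = 1000.0,
    center_step_hz: float = 500.0,
    lpc_order: int = 13,
    frame_ms: float = 30.0,
) -> float:
    """Glottal-to-noise excitation ratio in [0, 1].

    The signal is downsampled to 10 kHz and inverse filtered by frame-wise
    linear prediction to estimate the excitation. Hilbert envelopes of the
    band-passed excitation (1000 Hz bands centered every 500 Hz from 500 to
    4500 Hz) are cross-correlated at lags within +-0.3 ms between bands
    whose centers differ by more than half a bandwidth; a common glottal
    pulse excitation gives near-identical envelopes (GNE -> 1), turbulent
    noise decorrelates them.
    """
    fs_target = 10000
    g = np.gcd(w.rate_hz, fs_target)
    x = resample_poly(w.samples, fs_target // g, w.rate_hz // g)
    fs = fs_target
    frame = int(round(frame_ms * 1e-3 * fs))
    hop = frame // 2
    centers = np.arange(500.0, 4500.0 + 1, center_step_hz)
    half_bw = bandwidth_hz / 2.0
    max_lag = int(round(0.3e-3 * fs))
    nfft = 1 << int(np.ceil(np.log2(2 * frame)))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    vals = []
    for start in _frames(x, frame, hop):
        seg = x[start : start + frame]
        a = _lpc(seg, lpc_order)
        resid = lfilter(a, [1.0], seg * np.hanning(frame))
        spec = rfft(resid, nfft)
        envelopes = []
        for fc in centers:
            mask = (freqs >= fc - half_bw) & (freqs <= fc + half_bw)
            env = np.abs(hilbert(irfft(spec * mask, nfft)[:frame]))
            env = env - env.mean()
            envelopes.append(env)
        best = 0.0
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if centers[j] - centers[i] <= center_step_hz:
                    continue
                ei, ej = envelopes[i], envelopes[j]
                denom = np.sqrt(np.sum(ei * ei) * np.sum(ej * ej))
                if denom <= 0:
                    continue
                for lag in range(-max_lag, max_lag + 1):
                    if lag >= 0:
                        num = np.sum(ei[lag:] * ej[: ej.size - lag])
                    else:
                        num = np.sum(ej[-lag:] * ei[: ei.size + lag])
                    best = max(best, num / denom)
        vals.append(best)
    return float(np.clip(np.mean(vals), 0.0, 1.0))


def zcr(w: Waveform) -> float:
    """Zero crossings per second; zero samples inherit the preceding sign."""
    x = w.samples
    s = np.sign(x)
    # forward-fill zeros with the previous nonzero sign
    nz = s != 0
    if not nz.any():
        return 0.0
    idx = np.where(nz, np.arange(s.size), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = s[idx]
    filled[: np.argmax(nz)] = filled[np.argmax(nz)]
    crossings = int(np.count_nonzero(filled[1:] != filled[:-1]))
    return crossings / w.duration_s


def glottal_flow(w: Waveform) -> np.ndarray:
    """Glottal flow estimate by two-pass LPC inverse filtering.

    Pass 1 removes a first-order glottal spectral-tilt estimate, pass 2
    estimates the vocal tract (order round(2 + rate/1000)) and inverse
    filters the original signal; a leaky integrator undoes lip radiation.
    """
    fs = w.rate_hz
    x = w.samples
    g1 = _lpc(x, 1)
    y = lfilter(g1, [1.0], x)
    vt = _lpc(y, int(round(2 + fs / 1000.0)))
    resid = lfilter(vt, [1.0], x)
    flow = lfilter([1.0], [1.0, -0.99], resid)
    return flow


def glottal_quotients(
    w: Waveform, c: CycleSeries
) -> tuple[float, float, float]:
    """Glottal-quotient dispersion features (gq_prc5_95, std open, std closed).

    The open phase of each cycle is the longest contiguous run where the
    estimated glottal flow exceeds 50% of its within-cycle range; the
    closed phase is the remainder. All three outputs are normalized by the
    mean period, hence dimensionless:

    - gq_prc5_95: (95th - 5th percentile of periods) / mean period
    - gq_std_cycle_open: sd of open-phase durations / mean period
    - gq_std_cycle_closed: sd of closed-phase durations / mean period

    Returns NaN for the open/closed statistics if the flow analysis is
    degenerate (empty open phase in more than half the cycles).
    """
    if c.n_cycles < 20:
        raise InsufficientCyclesError("glottal quotients need >= 20 cycles")
    fs = w.rate_hz
    flow = glottal_flow(w)
    mean_period = float(np.mean(c.periods_s))
    open_s, closed_s, empty = [], [], 0
    for onset, period in zip(c.onsets, c.periods_s):
        a, b = int(onset), int(onset + round(period * fs))
        seg = flow[a:b]
        if seg.size < 4:
            empty += 1
            continue
        lo, hi = seg.min(), seg.max()
        if hi <= lo:
            empty += 1
            continue
        above = seg > lo + 0.5 * (hi - lo)
        if not above.any():
            empty += 1
            continue
        # longest contiguous run above the half-range threshold
        edges = np.diff(above.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(seg.size)
        run = max(e - s for s, e in zip(starts, ends))
        open_s.append(run / fs)
        closed_s.append(period - run / fs)
    prc = np.percentile(c.periods_s, [5, 95])
    gq_prc5_95 = float((prc[1] - prc[0]) / mean_period)
    if empty > 0.5 * c.n_cycles or len(open_s) < 2:
        return gq_prc5_95, float("nan"), float("nan")
    return (
        gq_prc5_95,
        float(np.std(open_s, ddof=0) / mean_period),
        float(np.std(closed_s, ddof=0) / mean_period),
    )


def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, nfft: int, fs: int) -> np.ndarray:
    edges = _mel_inv(np.linspace(0.0, _mel(fs / 2.0), n_filters + 2))
    bins = np.fft.rfftfreq(nfft, 1.0 / fs)
    fb = np.zeros((n_filters, bins.size))
    for i in range(n_filters):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (bins >= lo) & (bins <= mid)
        down = (bins > mid) & (bins <= hi)
        if mid > lo:
            fb[i, up] = (bins[up] - lo) / (mid - lo)
        if hi > mid:
            fb[i, down] = (hi - bins[down]) / (hi - mid)
    return fb


def mfcc13(
    w: Waveform,
    n_filters: int = 26,
    frame_ms: float = 25.0,
    hop_ms: float = 10.0,
) -> np.ndarray:
    """Mel-frequency cepstral coefficients 1-13, averaged over frames.

    The 0th (energy) coefficient is excluded so a global gain change, which
    adds a constant to every log filterbank energy, leaves all 13 returned
    coefficients unchanged.
    """
    fs = w.rate_hz
    x = w.samples
    frame = int(round(frame_ms * 1e-3 * fs))
    hop = int(round(hop_ms * 1e-3 * fs))
    nfft = 1 << int(np.ceil(np.log2(frame)))
    if nfft < frame:
        nfft *= 2
    win = np.hamming(frame)
    fb = _mel_filterbank(n_filters, nfft, fs)
    starts = _frames(x, frame, hop)
    segs = x[starts[:, None] + np.arange(frame)[None, :]] * win
    power = np.abs(rfft(segs, nfft, axis=1)) ** 2
    energies = power @ fb.T
    # floor relative to the global maximum keeps the log gain-equivariant
    floor = max(energies.max(), 0.0) * 1e-12
    if floor <= 0:
        floor = 1e-300
    log_e = np.log(np.maximum(energies, floor))
    coeffs = dct(log_e, type=2, norm="ortho", axis=1)[:, 1:14]
    return coeffs.mean(axis=0)
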