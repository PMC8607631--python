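"""One-stop extraction of the full 32-feature acoustic/nonlinear vector.

The per-recording feature vector combines 19 acoustic features (jitter,
shimmer, CPP, HNR, GNE, ZCR, 3 glottal quotients, MFCC 1-13 — counting the
MFCCs individually gives 22) with 10 nonlinear measures; with the sex
indicator added at the cohort level this is the 33-feature representation
used for detection.

Nonlinear state-space measures run on a 22.05 kHz downsampled copy of the
voiced second to bound pairwise-distance costs; this halving has negligible
effect on those measures for voice signals band-limited well below 11 kHz.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import resample_poly

from . import acoustic, nonlinear
from .errors import InsufficientDataError, ParavoxError
from .io import Waveform

#: Canonical feature order of the per-recording vector (32 features).
FEATURE_NAMES: tuple[str, ...] = (
    "jitter_pct",
    "shimmer_pct",
    "cpp_db",
    "hnr_db",
    "gne",
    "zcr_per_s",
    "gq_prc5_95",
    "gq_std_cycle_open",
    "gq_std_cycle_closed",
    *[f"mfcc_{i}" for i in range(1, 14)],
    "rpde",
    "d2",
    "ppe",
    "hurst",
    "lz2",
    "perm_entropy",
    "shannon_entropy",
    "ami_first_min_ms",
    "mfsw",
    "acf_first_zero_ms",
)

NONLINEAR_RATE_HZ = 22050


def extract_features(w: Waveform) -> dict[str, float]:
    """Extract the full named feature vector from a trimmed voiced second.

    Features whose analysis fails on a given recording are returned as NaN
    (flagged missing); downstream cohort assembly imputes training-set
    means, so no recording is silently dropped.
    """
    out: dict[str, float] = {name: float("nan") for name in FEATURE_NAMES}

    cycles = acoustic.detect_cycles(w)  # unvoiced input is a hard error
    try:
        out["jitter_pct"] = acoustic.jitter_local(cycles)
        out["shimmer_pct"] = acoustic.shimmer_local(cycles)
    except ParavoxError:
        pass
    out["hnr_db"] = acoustic.hnr_db(w, cycles)
    out["cpp_db"] = acoustic.cpp_db(w)
    out["gne"] = acoustic.gne(w)
    out["zcr_per_s"] = acoustic.zcr(w)
    try:
        gq = acoustic.glottal_quotients(w, cycles)
        out["gq_prc5_95"], out["gq_std_cycle_open"], out["gq_std_cycle_closed"] = gq
    except ParavoxError:
        pass
    for i, v in enumerate(acoustic.mfcc13(w), start=1):
        out[f"mfcc_{i}"] = float(v)

    # nonlinear block at 22.05 kHz
    if w.rate_hz % NONLINEAR_RATE_HZ == 0:
        x = resample_poly(w.samples, 1, w.rate_hz // NONLINEAR_RATE_HZ)
        fs = NONLINEAR_RATE_HZ
    else:
        x = w.samples
        fs = w.rate_hz
    spec = nonlinear.EmbeddingSpec()
    mean_period_samples = int(round(np.mean(cycles.periods_s) * fs))
    out["rpde"] = nonlinear.rpde(x, spec, rate_hz=fs)
    out["d2"] = nonlinear.correlation_dimension(
        x, spec, theiler_samples=mean_period_samples
    )
    try:
        out["ppe"] = nonlinear.ppe(1.0 / cycles.periods_s)
    except InsufficientDataError:
        pass
    out["hurst"] = nonlinear.hurst(x)
    out["lz2"] = nonlinear.lz2(x)
    out["perm_entropy"] = nonlinear.permutation_entropy(x)
    out["shannon_entropy"] = nonlinear.shannon_entropy(x)
    out["ami_first_min_ms"] = nonlinear.ami_first_min(x, fs)
    out["mfsw"] = nonlinear.mfsw(x)
    try:
        out["acf_first_zero_ms"] = nonlinear.acf_first_zero(x, fs)
    except ValueError:
        pass
    return out
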