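"""Reading, validation and silence-trimming of sustained-phonation recordings.

The analysis pipeline operates on exactly one second of voiced signal per
recording: raw files are trimmed so that leading and trailing silence is
discarded and the first full second of the voiced region is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import (
    AudioFormatError,
    EmptyInputError,
    InsufficientVoicingError,
)

REFERENCE_RATE_HZ = 44100


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled mono audio signal.

    Attributes
    ----------
    samples : np.ndarray
        Float samples, dimensionless amplitude nominally in [-1, 1].
    rate_hz : int
        Sampling rate in samples/second.
    source_id : str
        Opaque identifier (file stem, synthesis tag, ...).
    """

    samples: np.ndarray
    rate_hz: int
    source_id: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise EmptyInputError("waveform must hold at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform samples must be finite")
        if int(self.rate_hz) <= 0:
            raise ValueError("rate_hz must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate_hz", int(self.rate_hz))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz


def read_wav(path: str | Path, *, allow_resample: bool = False) -> Waveform:
    """Read a RIFF/WAVE file into a mono :class:`Waveform`.

    Multi-channel input is averaged to mono; integer PCM (16/24/32-bit) is
    rescaled to [-1, 1]. Files whose rate differs from 44.1 kHz are rejected
    unless ``allow_resample`` is set, in which case they are resampled.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises ValueError on malformed headers
        raise AudioFormatError(f"{path}: not a readable WAV file ({exc})") from exc
    if data.size == 0:
        raise EmptyInputError(f"{path}: zero-length audio")
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        offset = 0.0
        if info.min == 0:  # unsigned 8-bit PCM is offset-binary
            offset = (info.max + 1) / 2.0
            scale = offset
        samples = (data.astype(np.float64) - offset) / scale
    else:
        samples = data.astype(np.float64)
    if rate != REFERENCE_RATE_HZ:
        if not allow_resample:
            raise AudioFormatError(
                f"{path}: sample rate {rate} Hz; expected {REFERENCE_RATE_HZ} Hz "
                "(pass allow_resample=True to convert)"
            )
        g = np.gcd(int(rate), REFERENCE_RATE_HZ)
        samples = resample_poly(samples, REFERENCE_RATE_HZ // g, int(rate) // g)
        rate = REFERENCE_RATE_HZ
    return Waveform(samples=samples, rate_hz=int(rate), source_id=path.stem)


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM."""
    scaled = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(str(path), w.rate_hz, (scaled * 32767.0).astype(np.int16))


def _frame_rms_db(
    x: np.ndarray, rate_hz: int, frame_ms: float, hop_ms: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Frame RMS in dB relative to the loudest frame.

    Returns (levels_db, frame_starts, frame_len).
    """
    frame = max(1, int(round(frame_ms * 1e-3 * rate_hz)))
    hop = max(1, int(round(hop_ms * 1e-3 * rate_hz)))
    n = x.size
    starts = np.arange(0, max(n - frame, 0) + 1, hop)
    if starts.size == 0:
        starts = np.array([0])
        frame = n
    elif starts[-1] != n - frame:  # cover the signal tail
        starts = np.append(starts, n - frame)
    idx = starts[:, None] + np.arange(frame)[None, :]
    rms = np.sqrt(np.mean(x[idx] ** 2, axis=1))
    peak = rms.max()
    if peak <= 0:
        levels = np.full(starts.size, -np.inf)
    else:
        with np.errstate(divide="ignore"):
            levels = 20.0 * np.log10(rms / peak)
    return levels, starts, frame


def trim_to_voiced_second(
    w: Waveform,
    energy_threshold_db: float = -40.0,
    frame_ms: float = 25.0,
    hop_ms: float = 10.0,
) -> Waveform:
    """Return exactly one second of signal starting at the first voiced frame.

    Voicing is decided by frame RMS relative to the recording's peak frame
    RMS: frames above ``energy_threshold_db`` (default -40 dB) are voiced.
    The criterion is relative, so the selection is invariant to overall gain.

    Raises
    ------
    InsufficientVoicingError
        If less than one second separates the first and last voiced frame.
    """
    levels, starts, frame = _frame_rms_db(w.samples, w.rate_hz, frame_ms, hop_ms)
    voiced = np.flatnonzero(levels > energy_threshold_db)
    if voiced.size == 0:
        raise InsufficientVoicingError(0.0)
    start = int(starts[voiced[0]])
    end = int(starts[voiced[-1]]) + frame
    voiced_s = (end - start) / w.rate_hz
    if end - start < w.rate_hz:
        raise InsufficientVoicingError(voiced_s)
    seg = w.samples[start : start + w.rate_hz]
    return Waveform(samples=seg, rate_hz=w.rate_hz, source_id=w.source_id)
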