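"""Synthetic sustained vowels and synthetic two-class feature cohorts.

Every downstream stage of the pipeline is testable without clinical
recordings: ``synth_vowel`` produces source-filter /a/ phonations with
known per-cycle ground truth (periods, amplitudes, noise power), and
``synth_cohort`` produces class-conditional Gaussian feature tables with
known informative features, effect sizes and optional covariate shift.

The vowel source is a Rosenberg glottal pulse (open quotient 0.6, speed
quotient 2): its flow derivative excites a cascade of second-order formant
resonators, which gives a realistic spectral tilt so that cepstral and
excitation-based measures behave like they do on real phonations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .errors import SpecError
from .io import Waveform

DEFAULT_FORMANTS_A = ((700.0, 80.0), (1220.0, 120.0), (2600.0, 160.0))
OPEN_QUOTIENT = 0.6
SPEED_QUOTIENT = 2.0


@dataclass(frozen=True)
class SynthesisSpec:
    """Control parameters of a synthetic sustained vowel.

    jitter_pct / shimmer_pct are the standard deviations (percent) of the
    iid Gaussian multiplicative perturbations applied per cycle to the
    period and to the source gain. hnr_db is the harmonics-to-noise ratio
    measured at the formant-filter output; ``np.inf`` means noiseless.
    """

    f0_hz: float = 120.0
    duration_s: float = 2.0
    jitter_pct: float = 0.0
    shimmer_pct: float = 0.0
    hnr_db: float = np.inf
    formants: tuple[tuple[float, float], ...] = DEFAULT_FORMANTS_A
    rate_hz: int = 44100
    seed: int = 0

    def __post_init__(self):
        if not (50.0 <= self.f0_hz <= 500.0):
            raise SpecError(f"f0_hz={self.f0_hz} outside [50, 500]")
        if self.duration_s <= 0:
            raise SpecError("duration_s must be positive")
        if self.rate_hz < 8000:
            raise SpecError("rate_hz must be >= 8000")
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise SpecError("jitter_pct and shimmer_pct must be >= 0")
        # clipped at +-3 sd; guarantee positive periods
        if self.jitter_pct * 3 >= 100.0:
            raise SpecError("jitter_pct too large: cycle periods would vanish")


@dataclass(frozen=True)
class SynthesisTruth:
    """Ground-truth cycle structure of a synthesized vowel."""

    cycle_onsets: np.ndarray  # sample index of each glottal cycle start
    cycle_periods_s: np.ndarray  # per-cycle duration, seconds
    cycle_amps: np.ndarray  # per-cycle source gain (relative amplitude)
    voiced_range: tuple[int, int]
    noise_power: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cycle_onsets": self.cycle_onsets.tolist(),
            "cycle_periods_s": self.cycle_periods_s.tolist(),
            "cycle_amps": self.cycle_amps.tolist(),
            "voiced_range": list(self.voiced_range),
            "noise_power": self.noise_power,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthesisTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            cycle_onsets=np.asarray(d["cycle_onsets"], dtype=np.int64),
            cycle_periods_s=np.asarray(d["cycle_periods_s"], dtype=np.float64),
            cycle_amps=np.asarray(d["cycle_amps"], dtype=np.float64),
            voiced_range=tuple(d["voiced_range"]),
            noise_power=float(d["noise_power"]),
        )


def _rosenberg_pulse(n_open: int, speed_q: float = SPEED_QUOTIENT) -> np.ndarray:
    """One Rosenberg glottal flow pulse spanning the open phase only.

    Rising phase lasts speed_q/(1+speed_q) of the open phase, the closing
    phase the rest; glottal closure (flow back to zero) is the sharp event
    that excites the vocal tract.
    """
    t = np.arange(n_open, dtype=np.float64)
    tp = speed_q / (1.0 + speed_q) * n_open  # end of rising phase
    tn = n_open - tp  # closing duration
    flow = np.zeros(n_open)
    rise = t < tp
    flow[rise] = 0.5 * (1.0 - np.cos(np.pi * t[rise] / tp))
    fall = t >= tp
    flow[fall] = np.cos(np.pi * (t[fall] - tp) / (2.0 * tn))
    return flow


def _formant_filter(x: np.ndarray, formants, rate_hz: int) -> np.ndarray:
    """Cascade of two-pole resonators (center frequency, bandwidth in Hz)."""
    y = x
    for fc, bw in formants:
        r = np.exp(-np.pi * bw / rate_hz)
        theta = 2.0 * np.pi * fc / rate_hz
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        b = [1.0 - r]  # rough unity-ish DC-independent gain; relative scale only
        y = lfilter(b, a, y)
    return y


def synth_vowel(spec: SynthesisSpec) -> tuple[Waveform, SynthesisTruth]:
    """Synthesize a sustained vowel with known cycle-level ground truth.

    Per-cycle periods are T0*(1 + jitter_pct/100 * z_i) and per-cycle source
    gains 1 + shimmer_pct/100 * z'_i with z, z' iid standard normal clipped
    at +-3. White Gaussian noise is passed through the same formant filter
    and scaled so that (periodic power)/(noise power) at the output equals
    ``hnr_db``. The result is peak-normalized to 0.9 and fully determined
    by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.rate_hz
    n_total = int(round(spec.duration_s * fs))
    t0 = 1.0 / spec.f0_hz

    # cycle lengths are quantized to whole samples so the stored truth is
    # exactly what the waveform realizes. The open phase has a fixed
    # duration (open quotient x nominal period): period perturbations live
    # in the closed phase, so every cycle is shape-identical and the
    # excitation landmark sits at a constant offset from the cycle onset.
    n_open = max(4, int(round(OPEN_QUOTIENT * t0 * fs)))
    pulse = _rosenberg_pulse(n_open)
    onsets, periods, gains = [], [], []
    source = np.zeros(n_total)
    pos = 0
    while True:
        z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
        zp = float(np.clip(rng.standard_normal(), -3.0, 3.0))
        period_s = t0 * (1.0 + spec.jitter_pct / 100.0 * z)
        if period_s <= 0:
            raise SpecError("jitter produced a non-positive period")
        n_cycle = max(n_open + 1, int(round(period_s * fs)))
        if pos + n_cycle > n_total:  # drop the final truncated cycle
            break
        gain = 1.0 + spec.shimmer_pct / 100.0 * zp
        source[pos : pos + n_open] = gain * pulse
        onsets.append(pos)
        periods.append(n_cycle / fs)
        gains.append(gain)
        pos += n_cycle
    onsets_a = np.asarray(onsets, dtype=np.int64)
    periods_a = np.asarray(periods, dtype=np.float64)
    gains_a = np.asarray(gains, dtype=np.float64)

    # excite the vocal tract with the flow derivative (radiation included)
    excitation = np.diff(source, prepend=0.0)
    periodic = _formant_filter(excitation, spec.formants, fs)

    p_periodic = float(np.mean(periodic**2))
    if np.isfinite(spec.hnr_db):
        noise = _formant_filter(rng.standard_normal(n_total), spec.formants, fs)
        target_noise_power = p_periodic / (10.0 ** (spec.hnr_db / 10.0))
        noise *= np.sqrt(target_noise_power / np.mean(noise**2))
        signal = periodic + noise
        noise_power = target_noise_power
    else:
        signal = periodic
        noise_power = 0.0

    peak = np.max(np.abs(signal))
    scale = 0.9 / peak if peak > 0 else 1.0
    signal = signal * scale

    truth = SynthesisTruth(
        cycle_onsets=onsets_a,
        cycle_periods_s=periods_a,
        cycle_amps=gains_a,
        voiced_range=(0, n_total),
        noise_power=noise_power * scale**2,
    )
    wav = Waveform(samples=signal, rate_hz=fs,
                   source_id=f"synthetic-a-f0{spec.f0_hz:g}-seed{spec.seed}")
    return wav, truth


# ---------------------------------------------------------------------------
# Synthetic cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Two-class Gaussian feature-table generator settings.

    Emulates a balanced case/control design (default 30 per class):
    class 0 ("healthy") features have mean 0, class 1 ("PD") has mean
    ``effect_sizes[j]`` on each informative feature j (within-class sd
    units), 0 elsewhere; unit variances; optional equicorrelation.
    ``shift_mean``/``shift_scale`` define an affine per-feature covariate
    shift used to generate a "second database" sibling.
    """

    n_per_class: int = 30
    n_features: int = 33
    informative: tuple[int, ...] = ()  # 0-based feature indices
    effect_sizes: tuple[float, ...] = ()
    correlation: float = 0.0
    shift_mean: float | tuple[float, ...] = 0.0
    shift_scale: float | tuple[float, ...] = 1.0
    shift_informative_only: bool = False
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 2:
            raise SpecError("n_per_class must be >= 2")
        if any(j < 0 or j >= self.n_features for j in self.informative):
            raise SpecError("informative indices outside feature range")
        if len(self.effect_sizes) != len(self.informative):
            raise SpecError("effect_sizes must match informative indices")
        if not (0.0 <= self.correlation < 1.0):
            raise SpecError("correlation must be in [0, 1)")
        if not (0.0 <= self.label_noise <= 1.0):
            raise SpecError("label_noise must be a probability")


def _gaussian_block(rng, n, p, correlation):
    """n x p equicorrelated standard Gaussians."""
    z = rng.standard_normal((n, p))
    if correlation > 0:
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(correlation) * shared + np.sqrt(1 - correlation) * z
    return z


def synth_cohort(spec: CohortSpec):
    """Generate a synthetic two-class feature table.

    Returns a :class:`paravox.cohort.FeatureTable`; when ``shift_mean`` or
    ``shift_scale`` deviate from identity a shifted sibling table (the
    "second database") is returned as well, as ``(table, shifted_table)``.
    """
    from .cohort import FeatureTable  # deferred: cohort imports nothing from here

    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    labels = np.repeat(["healthy", "PD"], spec.n_per_class)
    x = _gaussian_block(rng, n, spec.n_features, spec.correlation)
    means = np.zeros(spec.n_features)
    for j, d in zip(spec.informative, spec.effect_sizes):
        means[j] = d
    x[labels == "PD"] += means

    if spec.label_noise > 0:
        flip = rng.random(n) < spec.label_noise
        flipped = labels.copy()
        flipped[flip] = np.where(labels[flip] == "PD", "healthy", "PD")
        labels = flipped

    feature_names = [f"f{j + 1:02d}" for j in range(spec.n_features)]
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    age = rng.integers(51, 88, size=n)

    def build(values):
        import pandas as pd

        df = pd.DataFrame(values, columns=feature_names)
        df.insert(0, "age", age)
        df.insert(0, "sex", sex)
        df.insert(0, "label", labels)
        df.insert(0, "recording_id", "r1")
        df.insert(0, "subject_id", [f"s{i + 1:04d}" for i in range(n)])
        return FeatureTable(df, feature_names=feature_names)

    table = build(x)
    shift_mean = np.broadcast_to(
        np.asarray(spec.shift_mean, dtype=float), (spec.n_features,)
    ).copy()
    shift_scale = np.broadcast_to(
        np.asarray(spec.shift_scale, dtype=float), (spec.n_features,)
    ).copy()
    if spec.shift_informative_only:
        mask = np.zeros(spec.n_features, dtype=bool)
        mask[list(spec.informative)] = True
        shift_mean[~mask] = 0.0
        shift_scale[~mask] = 1.0
    if np.any(shift_mean != 0.0) or np.any(shift_scale != 1.0):
        shifted = build(shift_scale * x + shift_mean)
        return table, shifted
    return table
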