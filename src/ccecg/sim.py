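"""Synthetic CC-ECG simulator.

Real out-of-hospital cardiac-arrest recordings during CPR are not publicly
available, so this module generates labeled 10 s single-lead strips that
reproduce the statistical structure the classifier is trained on:

* coarse ventricular fibrillation (VF) — an irregular narrow-band waveform
  with dominant energy between 3 and 8 Hz and peak-to-peak amplitude above
  200 µV (the shockable class);
* organized rhythm (OR) — a PQRST template train at a configurable heart
  rate with beat-to-beat jitter;
* asystole — low-amplitude baseline noise and drift with peak-to-peak
  amplitude below 100 µV;
* chest-compression (CC) artifacts — quasi-periodic waveforms at 80-160
  compressions per minute with harmonics, cycle-to-cycle amplitude/phase
  jitter, an optional spiky per-compression pulse morphology, and an
  optional 30:2 ventilation pause;
* SNR-controlled mixtures of a clean rhythm and a CC artifact, where SNR is
  10*log10(P_clean / P_corrupted) with power = variance about the mean.

All strips are sampled at 125 Hz (1250 samples), band-limited to 1-30 Hz
with a zero-phase filter, and quantized to the 5 µV/LSB amplitude
resolution of the acquisition chain.  Every generator is deterministic
given its seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .exceptions import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
)
from .metrics import FS_HZ, STRIP_SAMPLES, compute_snr, snr_bin

LSB_UV = 5          # amplitude resolution, µV per least-significant bit
GENERATOR_VERSION = "1.0"

_SOS_BAND = butter(2, [1.0, 30.0], btype="bandpass", fs=FS_HZ, output="sos")


class Rhythm(enum.Enum):
    VF = "VF"
    OR = "OR"
    ASYSTOLE = "ASYSTOLE"


#: Rhythm → shockable flag (only VF is shockable).
SHOCKABLE = {Rhythm.VF: True, Rhythm.OR: False, Rhythm.ASYSTOLE: False}


@dataclass(frozen=True)
class EcgStrip:
    """One labeled 10 s strip: integer µV samples plus provenance."""

    samples: np.ndarray          # int µV, multiples of 5, length 1250
    rhythm: Rhythm
    shockable: bool
    fs: int = FS_HZ
    snr_db: Optional[float] = None       # None for clean strips
    cc_rate_cpm: Optional[float] = None  # None for clean strips
    seed: Optional[int] = None

    def __post_init__(self):
        samples = np.asarray(self.samples)
        if samples.shape != (STRIP_SAMPLES,):
            raise InvalidParameterError(
                f"strip must have {STRIP_SAMPLES} samples, got {samples.shape}"
            )
        if not np.issubdtype(samples.dtype, np.integer):
            raise InvalidParameterError("strip samples must be integer µV")
        if np.any(samples % LSB_UV != 0):
            raise InvalidParameterError("samples must be multiples of 5 µV")
        if self.shockable != SHOCKABLE[self.rhythm]:
            raise InvalidParameterError("shockable flag inconsistent with rhythm")
        object.__setattr__(self, "samples", samples)

    @property
    def peak_to_peak(self) -> int:
        return int(self.samples.max() - self.samples.min())


@dataclass(frozen=True)
class MixSpec:
    """Recipe for one corrupted strip: rhythm + artifact + target SNR."""

    rhythm: Rhythm
    target_snr_db: float
    cc_rate_cpm: float = 110.0
    morphology: str = "mixed"          # sinusoidal | spiky | mixed
    pause_pattern: str = "continuous"  # continuous | 30:2
    heart_rate_bpm: float = 75.0       # used for OR only
    seed: int = 0

    def __post_init__(self):
        if not np.isfinite(self.target_snr_db):
            raise InvalidParameterError("target_snr_db must be finite")
        if self.cc_rate_cpm <= 0:
            raise InvalidParameterError("cc_rate_cpm must be positive")


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def quantize(x: np.ndarray) -> np.ndarray:
    """Round a µV waveform to integer multiples of 5 µV."""
    return (np.round(np.asarray(x, dtype=float) / LSB_UV) * LSB_UV).astype(np.int64)


def bandlimit(x: np.ndarray) -> np.ndarray:
    """Zero-phase 1-30 Hz band-pass (the AED monitoring bandwidth)."""
    return sosfiltfilt(_SOS_BAND, x)


def _check_duration(duration_s: float) -> int:
    if duration_s != 10:
        raise InvalidParameterError("strips are fixed at 10 s duration")
    return STRIP_SAMPLES


def _scale_to_pp(x: np.ndarray, pp_uv: float) -> np.ndarray:
    span = x.max() - x.min()
    if span == 0:
        raise DegenerateInputError("flat waveform cannot be scaled")
    return x * (pp_uv / span)


# ---------------------------------------------------------------------------
# clean rhythm generators
# ---------------------------------------------------------------------------

def gen_vf(duration_s: float = 10, seed: int = 0, amplitude_uv: float = 500.0) -> EcgStrip:
    """Coarse ventricular fibrillation: irregular fibrillatory waves.

    Modeled as an amplitude-modulated oscillator whose instantaneous
    frequency drifts inside 4-7 Hz (dominant VF band), plus a small
    broadband component, band-limited to 1-30 Hz and scaled so the
    peak-to-peak amplitude is ``amplitude_uv`` (> 200 µV by definition of
    coarse VF).
    """
    n = _check_duration(duration_s)
    if amplitude_uv <= 200:
        raise InvalidParameterError("coarse VF requires peak-to-peak > 200 µV")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / FS_HZ
    # instantaneous frequency: smoothed random walk clipped to the VF band
    f_inst = 5.5 + np.cumsum(rng.normal(0.0, 0.05, n))
    f_inst = np.clip(_smooth(f_inst, 31), 4.0, 7.0)
    phase = 2 * np.pi * np.cumsum(f_inst) / FS_HZ + rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.45 * _smooth(rng.normal(0.0, 1.0, n), 63)
    x = envelope * np.sin(phase)
    x += 0.35 * envelope * np.sin(2 * phase + rng.uniform(0, 2 * np.pi))
    x += 0.05 * rng.normal(0.0, 1.0, n)
    x = bandlimit(x)
    x = _scale_to_pp(x, amplitude_uv)
    q = quantize(x)
    # quantization may nibble the extremes; re-scale until the coarse-VF
    # amplitude rule holds (only relevant for amplitudes just above 200 µV)
    while q.max() - q.min() <= 200:
        x = x * 1.05
        q = quantize(x)
    return EcgStrip(samples=q, rhythm=Rhythm.VF, shockable=True, seed=seed)


def _pqrst_template(fs: int) -> np.ndarray:
    """One PQRST complex, unit R-peak amplitude, ~0.55 s support."""
    t = np.arange(int(0.55 * fs)) / fs

    def g(center, width, amp):
        return amp * np.exp(-0.5 * ((t - center) / width) ** 2)

    wave = (
        g(0.10, 0.020, 0.12)    # P
        - g(0.195, 0.010, 0.18)  # Q
        + g(0.215, 0.012, 1.00)  # R
        - g(0.240, 0.012, 0.25)  # S
        + g(0.40, 0.050, 0.22)   # T
    )
    return wave


def gen_or(
    duration_s: float = 10,
    seed: int = 0,
    heart_rate_bpm: float = 75.0,
    qrs_amplitude_uv: float = 1000.0,
) -> EcgStrip:
    """Organized rhythm: a PQRST template train with beat-to-beat jitter."""
    n = _check_duration(duration_s)
    if not 30.0 <= heart_rate_bpm <= 180.0:
        raise InvalidParameterError("heart rate must be within 30-180 bpm")
    rng = np.random.default_rng(seed)
    rr = 60.0 / heart_rate_bpm
    template = _pqrst_template(FS_HZ)
    x = np.zeros(n + len(template))
    t_beat = rng.uniform(0.0, 0.3)
    while t_beat < duration_s:
        i0 = int(round(t_beat * FS_HZ))
        amp = 1.0 + rng.normal(0.0, 0.05)
        x[i0:i0 + len(template)] += amp * template
        t_beat += rr * (1.0 + rng.normal(0.0, 0.03))
    x = x[:n]
    x = x * qrs_amplitude_uv
    x += 8.0 * rng.normal(0.0, 1.0, n)     # baseline noise, µV
    x = bandlimit(x)
    q = quantize(x)
    return EcgStrip(samples=q, rhythm=Rhythm.OR, shockable=False, seed=seed)


def gen_asystole(duration_s: float = 10, seed: int = 0) -> EcgStrip:
    """Asystole: low-amplitude baseline noise and slow drift (< 100 µV p-p)."""
    n = _check_duration(duration_s)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / FS_HZ
    drift = np.sin(2 * np.pi * rng.uniform(0.2, 0.5) * t + rng.uniform(0, 2 * np.pi))
    noise = _smooth(rng.normal(0.0, 1.0, n), 21)  # low-pass noise
    x = 0.5 * drift + noise / max(np.abs(noise).max(), 1e-12)
    x = bandlimit(x)
    x = _scale_to_pp(x, 60.0)
    q = quantize(x)
    return EcgStrip(samples=q, rhythm=Rhythm.ASYSTOLE, shockable=False, seed=seed)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.hanning(width)
    kernel /= kernel.sum()
    return np.convolve(x, kernel, mode="same")


# ---------------------------------------------------------------------------
# chest-compression artifact
# ---------------------------------------------------------------------------

_MORPHOLOGIES = ("sinusoidal", "spiky", "mixed")
_PAUSE_PATTERNS = ("continuous", "30:2")
_HARMONIC_AMPS = (1.0, 0.45, 0.22, 0.10)   # fundamental + 3 harmonics
_PAUSE_LEN_S = 4.0                         # ventilation pause for 30:2


def gen_cc_artifact(
    duration_s: float = 10,
    cc_rate_cpm: float = 110.0,
    morphology: str = "mixed",
    pause_pattern: str = "continuous",
    seed: int = 0,
) -> np.ndarray:
    """Quasi-periodic chest-compression artifact waveform (µV, 125 Hz).

    A harmonic series at the compression fundamental (``cc_rate_cpm``/60 Hz)
    with slow cycle-to-cycle amplitude and phase jitter; the ``spiky`` mode
    adds one narrow pulse per compression (the sharp morphology that can
    mimic QRS or fibrillatory waves).  ``pause_pattern='30:2'`` inserts one
    4 s ventilation gap inside the strip; ``continuous`` keeps compressions
    over the full 10 s, matching the inclusion criterion of at least 10 s
    of CC before the analysis window.
    """
    n = _check_duration(duration_s)
    if not 80.0 <= cc_rate_cpm <= 160.0:
        raise InvalidParameterError("cc_rate_cpm must be within 80-160 /min")
    if morphology not in _MORPHOLOGIES:
        raise InvalidParameterError(f"morphology must be one of {_MORPHOLOGIES}")
    if pause_pattern not in _PAUSE_PATTERNS:
        raise InvalidParameterError(f"pause_pattern must be one of {_PAUSE_PATTERNS}")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / FS_HZ
    f0 = cc_rate_cpm / 60.0

    # slow multiplicative frequency jitter keeps the fundamental sharp
    f_inst = f0 * (1.0 + 0.01 * _smooth(rng.normal(0.0, 1.0, n), 125))
    phase = 2 * np.pi * np.cumsum(f_inst) / FS_HZ + rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.15 * _smooth(rng.normal(0.0, 1.0, n), 63)

    harmonic = np.zeros(n)
    for h, amp in enumerate(_HARMONIC_AMPS, start=1):
        harmonic += amp * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    harmonic *= envelope

    if morphology in ("spiky", "mixed"):
        spikes = np.zeros(n)
        period = 1.0 / f0
        t_c = rng.uniform(0.0, period)
        sigma = 0.045  # pulse width, s
        while t_c < duration_s:
            amp = 1.0 + rng.normal(0.0, 0.15)
            spikes += amp * np.exp(-0.5 * ((t - t_c) / sigma) ** 2)
            t_c += period * (1.0 + rng.normal(0.0, 0.02))
        spikes -= spikes.mean()
        spikes /= max(np.abs(spikes).max(), 1e-12)
        if morphology == "spiky":
            x = spikes
        else:
            x = 0.6 * harmonic / max(np.abs(harmonic).max(), 1e-12) + 0.4 * spikes
    else:
        x = harmonic

    if pause_pattern == "30:2":
        gate = np.ones(n)
        t0 = rng.uniform(1.0, duration_s - _PAUSE_LEN_S - 1.0)
        edge = 0.2  # raised-cosine ramp, s
        tt = (t - t0) / edge
        gate = np.where((t >= t0) & (t <= t0 + _PAUSE_LEN_S), 0.0, 1.0)
        ramp_in = (t >= t0 - edge) & (t < t0)
        gate[ramp_in] = 0.5 * (1 + np.cos(np.pi * (t[ramp_in] - (t0 - edge)) / edge))
        t1 = t0 + _PAUSE_LEN_S
        ramp_out = (t > t1) & (t <= t1 + edge)
        gate[ramp_out] = 0.5 * (1 - np.cos(np.pi * (t[ramp_out] - t1) / edge))
        x = x * gate

    x = bandlimit(x)
    return _scale_to_pp(x, 2000.0)


# ---------------------------------------------------------------------------
# SNR-controlled mixing
# ---------------------------------------------------------------------------

def mix_at_snr(
    clean: EcgStrip,
    artifact: np.ndarray,
    target_snr_db: float,
    cc_rate_cpm: Optional[float] = None,
) -> EcgStrip:
    """Corrupt a clean strip with a CC artifact at a controlled SNR.

    The SNR metric compares the clean strip's power to the corrupted
    strip's power (variance about the mean), so for targets below 0 dB the
    artifact component orthogonal to the clean signal is rescaled to the
    analytic solution  P_art = P_clean * (10^(-SNR/10) - 1).  A target at
    or above 0 dB cannot be met by an additive artifact (the mixture's
    power can never fall below the clean power once the artifact is
    orthogonalized); in that case the artifact power is set relative to
    the clean power as  P_art = P_clean * 10^(-SNR/10)  and the achieved
    metric value is recorded in ``snr_db``.

    The result is re-quantized to 5 µV and carries the achieved SNR.
    """
    if not np.isfinite(target_snr_db):
        raise InvalidParameterError("target_snr_db must be finite")
    a = np.asarray(artifact, dtype=float)
    c = clean.samples.astype(float)
    if a.shape != c.shape:
        raise InvalidParameterError("clean and artifact lengths differ")
    p_clean = float(np.var(c))
    if p_clean == 0.0:
        raise DegenerateInputError("clean strip has zero power")
    if np.all(a == a.flat[0]):
        raise InvalidParameterError("artifact is constant/zero")

    cc = c - c.mean()
    ac = a - a.mean()
    # remove the artifact's projection onto the clean signal so artifact
    # power adds exactly to clean power in the mixture
    ac = ac - (ac @ cc) / (cc @ cc) * cc
    p_art_unit = float(np.mean(ac**2))
    if p_art_unit == 0.0:
        raise InvalidParameterError("artifact is collinear with the clean strip")

    ratio = 10.0 ** (-target_snr_db / 10.0)
    if target_snr_db < 0:
        p_art = p_clean * (ratio - 1.0)
    else:
        p_art = p_clean * ratio
    scale = np.sqrt(p_art / p_art_unit)
    mixed = quantize(c + scale * ac)
    achieved = compute_snr(c, mixed.astype(float)).snr_db
    return EcgStrip(
        samples=mixed,
        rhythm=clean.rhythm,
        shockable=clean.shockable,
        snr_db=achieved,
        cc_rate_cpm=cc_rate_cpm,
        seed=clean.seed,
    )


def gen_mixture(spec: MixSpec) -> EcgStrip:
    """Generate one corrupted strip from a :class:`MixSpec`."""
    rng = np.random.default_rng(spec.seed)
    clean_seed, art_seed = (int(s) for s in rng.integers(0, 2**31, size=2))
    if spec.rhythm is Rhythm.VF:
        clean = gen_vf(10, clean_seed, amplitude_uv=float(rng.uniform(300, 900)))
    elif spec.rhythm is Rhythm.OR:
        clean = gen_or(
            10, clean_seed,
            heart_rate_bpm=spec.heart_rate_bpm,
            qrs_amplitude_uv=float(rng.uniform(600, 1500)),
        )
    else:
        clean = gen_asystole(10, clean_seed)
    artifact = gen_cc_artifact(
        10, spec.cc_rate_cpm, spec.morphology, spec.pause_pattern, art_seed
    )
    strip = mix_at_snr(clean, artifact, spec.target_snr_db, cc_rate_cpm=spec.cc_rate_cpm)
    return replace(strip, seed=spec.seed)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """An ordered collection of strips with id provenance."""

    strips: list = field(default_factory=list)
    ids: list = field(default_factory=list)
    master_seed: Optional[int] = None

    def __post_init__(self):
        if not self.ids:
            self.ids = [f"strip-{i:05d}" for i in range(len(self.strips))]
        if len(self.ids) != len(self.strips):
            raise InvalidInputError("ids and strips length mismatch")

    def __len__(self) -> int:
        return len(self.strips)

    def waveforms(self) -> np.ndarray:
        """(n, 1250) float32 matrix of raw µV samples (no normalization)."""
        return np.stack([s.samples for s in self.strips]).astype(np.float32)

    def labels(self) -> np.ndarray:
        """1 for shockable (VF), 0 for non-shockable."""
        return np.array([int(s.shockable) for s in self.strips], dtype=np.int64)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for sid, s in zip(self.ids, self.strips):
            rows.append(
                {
                    "strip_id": sid,
                    "rhythm": s.rhythm.value,
                    "shockable": bool(s.shockable),
                    "snr_db": None if s.snr_db is None else float(s.snr_db),
                    "cc_rate_cpm": None if s.cc_rate_cpm is None else float(s.cc_rate_cpm),
                    "seed": None if s.seed is None else int(s.seed),
                }
            )
        return pd.DataFrame(rows)

    def subset(self, indices) -> "Dataset":
        return Dataset(
            strips=[self.strips[i] for i in indices],
            ids=[self.ids[i] for i in indices],
            master_seed=self.master_seed,
        )


def _draw(dist, rng) -> float:
    """Draw from a distribution spec: scalar, (lo, hi) range, or sequence."""
    if np.isscalar(dist):
        return float(dist)
    dist = list(dist)
    if len(dist) == 2 and all(np.isscalar(v) for v in dist) and dist[0] < dist[1]:
        return float(rng.uniform(dist[0], dist[1]))
    return float(rng.choice(dist))


def make_dataset(
    class_counts: dict,
    snr_distribution=( -15.0, -1.0),
    cc_rate_distribution=(100.0, 120.0),
    seed: int = 0,
    morphologies: Sequence[str] = _MORPHOLOGIES,
    pause_pattern: str = "continuous",
) -> Dataset:
    """Generate a reproducible labeled dataset of corrupted strips.

    ``class_counts`` maps :class:`Rhythm` (or its string name) to a count.
    ``snr_distribution`` and ``cc_rate_distribution`` are each a scalar, a
    (low, high) uniform range, or a sequence of values sampled uniformly.
    Defaults follow the study conditions: compressions around the 110/min
    metronome rate (100-120/min guideline range) and SNR spanning weak to
    very strong artifacts.
    """
    counts = {}
    for key, cnt in class_counts.items():
        rhythm = key if isinstance(key, Rhythm) else Rhythm(str(key).upper())
        if cnt < 0:
            raise InvalidParameterError("class counts must be non-negative")
        counts[rhythm] = int(cnt)
    rng = np.random.default_rng(seed)
    strips, ids = [], []
    for rhythm in (Rhythm.VF, Rhythm.OR, Rhythm.ASYSTOLE):
        for j in range(counts.get(rhythm, 0)):
            spec = MixSpec(
                rhythm=rhythm,
                target_snr_db=_draw(snr_distribution, rng),
                cc_rate_cpm=_draw(cc_rate_distribution, rng),
                morphology=str(rng.choice(list(morphologies))),
                pause_pattern=pause_pattern,
                heart_rate_bpm=float(rng.uniform(45, 140)),
                seed=int(rng.integers(0, 2**31)),
            )
            strips.append(gen_mixture(spec))
            ids.append(f"{rhythm.value.lower()}-{j:05d}")
    return Dataset(strips=strips, ids=ids, master_seed=seed)


def snr_band_counts(dataset: Dataset) -> pd.DataFrame:
    """Strip counts per rhythm and SNR band (test-composition style table)."""
    man = dataset.manifest()
    man["snr_band"] = [snr_bin(v).value for v in man["snr_db"]]
    return man.pivot_table(
        index="rhythm", columns="snr_band", values="strip_id", aggfunc="count"
    ).fillna(0).astype(int)
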