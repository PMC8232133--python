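"""Corruption and compression-rate metrics for CC-ECG strips.

The signal-to-noise ratio of a chest-compression-corrupted strip is defined
against the clean rhythm as

    SNR = 10 * log10( P(clean) / P(corrupted) )   [dB]

where the power P of a 10 s strip is the variance of its samples about their
mean.  More negative values mean stronger compression artifacts.  Test-set
performance is stratified over four SNR bands and four compression-rate
ranges; the binning rules live here so every report uses the same partition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .exceptions import DegenerateInputError, RateUndetectableError

FS_HZ = 125
STRIP_SAMPLES = 1250

#: Search band for the compression fundamental, in Hz (80-160 per minute).
CC_BAND_HZ = (80.0 / 60.0, 160.0 / 60.0)

#: In-band periodogram peak must exceed this multiple of the broadband
#: median periodogram level to count as a detection.
_PEAK_TO_FLOOR = 10.0


def _as_samples(x) -> np.ndarray:
    """Accept a raw array or anything exposing ``.samples``."""
    samples = getattr(x, "samples", x)
    return np.asarray(samples, dtype=float)


@dataclass(frozen=True)
class SnrResult:
    """SNR of a corrupted strip relative to its clean rhythm."""

    snr_db: float
    p_clean: float      # µV², variance about the mean
    p_corrupted: float  # µV²


def compute_snr(clean, corrupted) -> SnrResult:
    """Signal-to-noise ratio of ``corrupted`` relative to ``clean``.

    Power is the variance of each 10 s strip about its own mean; the two
    strips are compared as-is, with no detrending beyond mean removal.

    Raises
    ------
    DegenerateInputError
        If either strip has zero variance.
    """
    c = _as_samples(clean)
    x = _as_samples(corrupted)
    p_clean = float(np.var(c))
    p_corr = float(np.var(x))
    if p_clean == 0.0 or p_corr == 0.0:
        raise DegenerateInputError("zero-variance input to compute_snr")
    snr = 10.0 * np.log10(p_clean / p_corr)
    return SnrResult(snr_db=float(snr), p_clean=p_clean, p_corrupted=p_corr)


class SnrBand(enum.Enum):
    """Artifact-strength bands: very strong (<= -9 dB), strong (-9, -6],
    moderate (-6, -3], weak (> -3 dB)."""

    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    WEAK = "weak"


def snr_bin(snr_db: float) -> SnrBand:
    """Assign an SNR value to its artifact-strength band.

    Upper bounds of the STRONG and MODERATE intervals are inclusive:
    -9 dB is VERY_STRONG, -6 dB is STRONG, -3 dB is MODERATE.
    """
    if not np.isfinite(snr_db):
        raise DegenerateInputError("snr_bin requires a finite SNR")
    if snr_db <= -9.0:
        return SnrBand.VERY_STRONG
    if snr_db <= -6.0:
        return SnrBand.STRONG
    if snr_db <= -3.0:
        return SnrBand.MODERATE
    return SnrBand.WEAK


def estimate_cc_rate(waveform, fs: int = FS_HZ) -> float:
    """Estimate the chest-compression rate of a corrupted strip.

    The rate is 60 times the frequency of the dominant Hann-windowed
    periodogram peak inside the plausible compression band (80-160 per
    minute).  The peak must exceed ten times the median periodogram level
    over 0.5-10 Hz, otherwise the rate is declared undetectable.

    Returns
    -------
    float
        Compression rate in compressions per minute.

    Raises
    ------
    RateUndetectableError
        If no in-band peak rises above the noise floor.
    """
    x = _as_samples(waveform)
    if np.var(x) == 0.0:
        raise RateUndetectableError("zero-variance waveform")
    freqs, pxx = periodogram(x - x.mean(), fs=fs, window="hann")
    band = (freqs >= CC_BAND_HZ[0]) & (freqs <= CC_BAND_HZ[1])
    wide = (freqs >= 0.5) & (freqs <= 10.0)
    floor = float(np.median(pxx[wide]))
    peak_idx = int(np.argmax(pxx[band]))
    peak_power = float(pxx[band][peak_idx])
    if floor > 0.0 and peak_power < _PEAK_TO_FLOOR * floor:
        raise RateUndetectableError(
            f"in-band peak {peak_power:.3g} below {_PEAK_TO_FLOOR}x floor {floor:.3g}"
        )
    # parabolic interpolation around the peak for sub-bin frequency accuracy
    gi = int(np.flatnonzero(band)[peak_idx])
    f_peak = freqs[gi]
    if 0 < gi < len(freqs) - 1:
        alpha, beta, gamma = pxx[gi - 1], pxx[gi], pxx[gi + 1]
        denom = alpha - 2 * beta + gamma
        if denom != 0:
            delta = 0.5 * (alpha - gamma) / denom
            f_peak = freqs[gi] + np.clip(delta, -0.5, 0.5) * (freqs[1] - freqs[0])
    return float(60.0 * f_peak)


class CcRateBand(enum.Enum):
    """Compression-rate ranges: slow (<100/min), normal-low [100, 110),
    normal-high [110, 120], rapid (>120/min)."""

    SLOW = "slow"
    NORM_LOW = "norm_low"
    NORM_HIGH = "norm_high"
    RAPID = "rapid"


def cc_rate_bin(rate_cpm: float) -> CcRateBand:
    """Assign a compression rate to its range; 110/min goes to NORM_HIGH."""
    if rate_cpm <= 0:
        raise DegenerateInputError("rate must be positive")
    if rate_cpm < 100.0:
        return CcRateBand.SLOW
    if rate_cpm < 110.0:
        return CcRateBand.NORM_LOW
    if rate_cpm <= 120.0:
        return CcRateBand.NORM_HIGH
    return CcRateBand.RAPID
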