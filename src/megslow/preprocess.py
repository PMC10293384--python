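"""Segmentation and band filtering of continuous ROI recordings.

The analysis entry point is a continuous source-space recording (regions x
samples with a sample rate).  This module turns it into the unit every
spectral and connectivity computation consumes: a set of fixed-length,
non-overlapping epochs (default 4096 samples, i.e. 13.11 s at 312.5 Hz),
optionally band-filtered into one of the five canonical frequency bands
delta (0.5-4 Hz), theta (4-8), alpha1 (8-10), alpha2 (10-13) and beta
(13-30).  The five bands tile the full 0.5-30 Hz analysis range, so
relative band powers computed downstream sum to one.

Filtering is exactly zero-phase: each epoch is multiplied in the frequency
domain by a real raised-cosine amplitude mask whose -6 dB points sit on the
band edges (transition width ``min(0.5 * low, 2)`` Hz).  Zero phase matters
because amplitude-envelope connectivity is sensitive to envelope timing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _sig

ANALYSIS_RANGE = (0.5, 30.0)

DEFAULT_EPOCH_LENGTH = 4096
DEFAULT_N_EPOCHS = 10


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, "
                f"got ({self.low}, {self.high})"
            )


CANONICAL_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("delta", 0.5, 4.0),
    FrequencyBand("theta", 4.0, 8.0),
    FrequencyBand("alpha1", 8.0, 10.0),
    FrequencyBand("alpha2", 10.0, 13.0),
    FrequencyBand("beta", 13.0, 30.0),
)

BAND_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


@dataclass
class RoiRecording:
    """Continuous multi-region source time series for one subject visit."""

    subject: str
    visit: str
    sample_rate: float
    data: np.ndarray  # (n_regions, n_samples)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (regions x samples)")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Fixed-length epochs: array (n_epochs, n_regions, epoch_length)."""

    epochs: np.ndarray
    sample_rate: float
    band: FrequencyBand | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x regions x samples)")
        if self.epochs.shape[0] < 1:
            raise ValueError("need at least one epoch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_regions(self) -> int:
        return self.epochs.shape[1]

    @property
    def epoch_length(self) -> int:
        return self.epochs.shape[2]

    @property
    def epoch_duration(self) -> float:
        """Epoch duration in seconds (4096 samples at 312.5 Hz -> 13.11 s)."""
        return self.epoch_length / self.sample_rate

    @property
    def frequency_resolution(self) -> float:
        """Grid spacing of the epoch spectrum, fs / L (0.076 Hz at defaults)."""
        return self.sample_rate / self.epoch_length


def downsample(rec: RoiRecording, factor: int) -> RoiRecording:
    """Anti-alias low-pass filter and decimate a recording by an integer factor.

    The resulting sample rate must stay above 60 Hz (twice the top of the
    0.5-30 Hz analysis range); a factor that violates this is rejected.
    ``factor=1`` returns an identical copy.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    new_rate = rec.sample_rate / factor
    if not new_rate > 2 * ANALYSIS_RANGE[1]:
        raise ValueError(
            f"downsampling by {factor} gives {new_rate:g} Hz, below the "
            f"{2 * ANALYSIS_RANGE[1]:g} Hz needed for the 0.5-30 Hz analysis"
        )
    if factor == 1:
        return replace(rec, data=rec.data.copy())
    out = _sig.decimate(rec.data, factor, ftype="fir", zero_phase=True, axis=-1)
    return RoiRecording(rec.subject, rec.visit, new_rate, out)


def epoch(
    rec: RoiRecording,
    epoch_length: int = DEFAULT_EPOCH_LENGTH,
    n_epochs: int | None = DEFAULT_N_EPOCHS,
) -> EpochSet:
    """Split a recording into consecutive non-overlapping epochs.

    The first ``n_epochs`` windows are taken (the synthetic data carry no
    artifacts, so no visual selection step is needed); the trailing
    remainder is discarded.  With ``n_epochs=None`` all complete windows
    are used.

    Raises
    ------
    ValueError
        If fewer than ``n_epochs`` complete windows are available; the
        message reports the available count.
    """
    if epoch_length < 1:
        raise ValueError("epoch_length must be positive")
    available = rec.n_samples // epoch_length
    if n_epochs is None:
        n_epochs = available
    if available < max(n_epochs, 1):
        raise ValueError(
            f"requested {n_epochs} epochs of {epoch_length} samples but only "
            f"{available} are available ({rec.n_samples} samples)"
        )
    used = rec.data[:, : n_epochs * epoch_length]
    eps = used.reshape(rec.n_regions, n_epochs, epoch_length).transpose(1, 0, 2)
    return EpochSet(eps.copy(), rec.sample_rate)


def _smoothstep_mask(
    freqs: np.ndarray, band: FrequencyBand, transition: float
) -> np.ndarray:
    """Real raised-cosine band-pass amplitude mask, -6 dB at band edges."""
    lo, hi = band.low, band.high
    up = np.clip((freqs - (lo - transition / 2)) / transition, 0.0, 1.0)
    down = np.clip(((hi + transition / 2) - freqs) / transition, 0.0, 1.0)
    # half-cosine ramps: value 0.5 exactly at lo and hi
    rise = 0.5 * (1.0 - np.cos(np.pi * up))
    fall = 0.5 * (1.0 - np.cos(np.pi * down))
    return rise * fall


def band_transition_width(band: FrequencyBand) -> float:
    return min(0.5 * band.low, 2.0)


def bandpass(es: EpochSet, band: FrequencyBand) -> EpochSet:
    """Zero-phase band-pass filter every epoch of every region.

    Applies the frequency-domain raised-cosine mask per epoch.  The epoch
    count and length are preserved, and the output carries the band tag;
    filtering an already band-tagged set is rejected (no double filtering).
    """
    if es.band is not None:
        raise ValueError(
            f"epoch set is already filtered in band {es.band.name!r}"
        )
    nyquist = es.sample_rate / 2
    if band.high > nyquist:
        raise ValueError(
            f"band {band.name!r} upper edge {band.high} Hz exceeds the "
            f"Nyquist frequency {nyquist:g} Hz"
        )
    L = es.epoch_length
    freqs = np.fft.rfftfreq(L, d=1.0 / es.sample_rate)
    mask = _smoothstep_mask(freqs, band, band_transition_width(band))
    spec = np.fft.rfft(es.epochs, axis=-1)
    out = np.fft.irfft(spec * mask, n=L, axis=-1)
    return EpochSet(out, es.sample_rate, band=band)


def bandpass_series(x: np.ndarray, sample_rate: float, band: FrequencyBand) -> np.ndarray:
    """Zero-phase band-pass of a 1-D (or trailing-axis) continuous series."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    mask = _smoothstep_mask(freqs, band, band_transition_width(band))
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * mask, n=n, axis=-1)


def lowpass_series(x: np.ndarray, sample_rate: float, cutoff: float,
                   transition: float | None = None) -> np.ndarray:
    """Zero-phase low-pass (used for the slow envelope modulator)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if transition is None:
        transition = 0.5 * cutoff
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    down = np.clip(((cutoff + transition / 2) - freqs) / transition, 0.0, 1.0)
    mask = 0.5 * (1.0 - np.cos(np.pi * down))
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * mask, n=n, axis=-1)
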