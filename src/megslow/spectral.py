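"""Per-region power spectra, relative band power and dominant-peak frequency.

Spectra are estimated per epoch with a single-taper periodogram on the full
epoch (no sub-windowing), so the frequency grid keeps the native resolution
fs / L -- 0.076 Hz for 4096-sample epochs at 312.5 Hz -- and are averaged
over epochs.  The default taper is a Hann window (leakage control without
changing the grid); a boxcar can be requested where the closed-form
periodogram of a pure tone is wanted.

Relative band power is the fraction of total 0.5-30 Hz power falling into a
band, with band edges treated as half-open intervals [low, high) so the five
canonical bands tile the analysis range exactly and the per-region fractions
sum to one.  Peak frequency is the argmax of the spectrum on the closed
4-13 Hz range, ties broken toward the lower frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .atlas import RegionAtlas
from .preprocess import ANALYSIS_RANGE, CANONICAL_BANDS, EpochSet, FrequencyBand

PEAK_RANGE = (4.0, 13.0)


@dataclass
class SpectrumSet:
    """Epoch-averaged power spectra on the 0.5-30 Hz grid.

    ``power`` has shape (n_regions, n_freqs); ``normalization`` is ``"raw"``
    (periodogram units) or ``"unit-area"`` (each region's spectrum divided by
    its 0.5-30 Hz integral).
    """

    frequencies: np.ndarray
    power: np.ndarray
    frequency_resolution: float
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 2 or self.power.shape[1] != self.frequencies.size:
            raise ValueError("power must be (n_regions, n_freqs)")
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")
        if self.normalization not in ("raw", "unit-area"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def n_regions(self) -> int:
        return self.power.shape[0]

    def integral(self) -> np.ndarray:
        """Riemann integral of each region's spectrum over the stored grid."""
        return self.power.sum(axis=1) * self.frequency_resolution


@dataclass
class BandPowerTable:
    """Relative band powers (n_regions x n_bands) plus per-region peak frequency."""

    relative_power: np.ndarray
    band_names: tuple[str, ...]
    peak_frequency: np.ndarray | None = None

    def band(self, name: str) -> np.ndarray:
        return self.relative_power[:, self.band_names.index(name)]


@dataclass
class RegionSummary:
    """Cortical and subcortical unweighted means of a per-region measure."""

    cortical_mean: np.ndarray | float
    subcortical_mean: np.ndarray | float


def epoch_spectra(es: EpochSet, window: str = "hann") -> SpectrumSet:
    """Epoch-averaged single-window periodogram, restricted to 0.5-30 Hz.

    The input must be broadband (untagged); band-filtered epoch sets are
    rejected because relative power is defined against the broadband
    spectrum.  Power is a one-sided density (power per Hz), so the integral
    over the full grid approximates the time-domain variance.
    """
    if es.band is not None:
        raise ValueError(
            "epoch_spectra expects a broadband epoch set, got band "
            f"{es.band.name!r}"
        )
    freqs, pxx = _sig.periodogram(
        es.epochs,
        fs=es.sample_rate,
        window=window,
        nfft=es.epoch_length,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    mean_power = pxx.mean(axis=0)  # average over epochs -> (regions, freqs)
    sel = (freqs >= ANALYSIS_RANGE[0]) & (freqs <= ANALYSIS_RANGE[1])
    return SpectrumSet(
        freqs[sel], mean_power[:, sel], es.frequency_resolution, "raw"
    )


def normalize_spectrum(ss: SpectrumSet) -> SpectrumSet:
    """Divide each region's spectrum by its 0.5-30 Hz area (unit-area tag)."""
    if ss.normalization != "raw":
        raise ValueError("spectrum is already normalized")
    area = ss.integral()
    if np.any(area <= 0):
        bad = np.flatnonzero(area <= 0)
        raise ValueError(f"zero total power in regions {bad.tolist()}")
    return SpectrumSet(
        ss.frequencies.copy(),
        ss.power / area[:, None],
        ss.frequency_resolution,
        "unit-area",
    )


def relative_band_power(
    ss: SpectrumSet, bands: tuple[FrequencyBand, ...] = CANONICAL_BANDS
) -> BandPowerTable:
    """Per-region fraction of 0.5-30 Hz power in each band.

    Bins are assigned to a band when ``low <= f < high``; the denominator is
    the power summed over ``0.5 <= f < 30``.  Because the ratio is scale
    free the result is identical for raw and unit-area input.  A band table
    that does not tile the analysis range triggers a warning (the fractions
    then need not sum to one).
    """
    f = ss.frequencies
    denom_mask = (f >= ANALYSIS_RANGE[0]) & (f < ANALYSIS_RANGE[1])
    denom = ss.power[:, denom_mask].sum(axis=1)
    if np.any(denom <= 0):
        raise ValueError("zero total power; cannot form relative band power")
    covered = np.zeros_like(f, dtype=bool)
    rel = np.empty((ss.n_regions, len(bands)))
    for k, band in enumerate(bands):
        m = (f >= band.low) & (f < band.high)
        covered |= m
        rel[:, k] = ss.power[:, m].sum(axis=1) / denom
    if not np.array_equal(covered & denom_mask, denom_mask):
        warnings.warn(
            "bands do not tile the 0.5-30 Hz analysis range; relative powers "
            "will not sum to one",
            stacklevel=2,
        )
    return BandPowerTable(
        rel, tuple(b.name for b in bands), peak_frequency=peak_frequency(ss)
    )


def peak_frequency(
    ss: SpectrumSet, frange: tuple[float, float] = PEAK_RANGE
) -> np.ndarray:
    """Frequency of the maximum-power bin within the closed 4-13 Hz range.

    Ties are broken toward the lower frequency (argmax returns the first
    maximum on an ascending grid).  Raw and unit-area spectra give the same
    answer per region.
    """
    f = ss.frequencies
    m = (f >= frange[0]) & (f <= frange[1])
    if not np.any(m):
        raise ValueError(f"spectra do not cover the range {frange}")
    sub = ss.power[:, m]
    return f[m][np.argmax(sub, axis=1)]


def summarize_regions(
    values: np.ndarray, atlas: RegionAtlas
) -> RegionSummary:
    """Unweighted cortical (78-region) and subcortical (12-region) means.

    ``values`` is (n_regions,) or (n_regions, k); the region dimension must
    match the atlas.  Means are taken after any epoch averaging upstream.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != atlas.n_regions:
        raise ValueError(
            f"measure has {values.shape[0]} regions, atlas has "
            f"{atlas.n_regions}"
        )
    cort, sub = atlas.cortical_indices, atlas.subcortical_indices
    cm = np.nanmean(values[cort], axis=0)
    sm = np.nanmean(values[sub], axis=0)
    if values.ndim == 1:
        return RegionSummary(float(cm), float(sm))
    return RegionSummary(cm, sm)
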