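"""Synthetic resting-state cohorts with known ground truth.

No public recordings exist for the kind of longitudinal patient cohort this
pipeline analyzes, so every downstream stage is exercised on simulated data
whose generating parameters are known exactly.  The generator emulates the
statistical structure the analysis assumes:

* per-region signals with a 1/f-type background spectrum plus an
  oscillatory alpha-range bump whose center frequency drifts downward
  across visits (spectral slowing),
* optional band-limited envelope coupling between designated region pairs
  (a shared slow amplitude modulator, the mechanism amplitude-envelope
  connectivity measures),
* a three-visit longitudinal cohort (healthy controls at baseline only;
  de novo and treated patient groups at all visits) with monotone dropout,
* clinical scores (CAMCOG, UPDRS-III) generated as noisy linear functions
  of the spectral state (the true peak frequency) plus a subject-level
  random intercept.

Signals are produced by spectral shaping of white noise (a frequency-domain
amplitude mask), which gives direct, analyzable control of the expected
spectrum; the true band powers and true peak frequency of every generated
signal are therefore available in closed form and returned as ground truth.
Everything is reproducible bit-for-bit from the design seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import hilbert

from .preprocess import (
    ANALYSIS_RANGE,
    BAND_BY_NAME,
    CANONICAL_BANDS,
    FrequencyBand,
    RoiRecording,
    bandpass_series,
    lowpass_series,
)

N_REGIONS = 90

DEFAULT_PEAK_WIDTH = 0.6  # Hz, Gaussian sigma of the oscillatory bump


# ---------------------------------------------------------------------------
# signal-level specification and simulation


@dataclass(frozen=True)
class SignalSpec:
    """Spectral shape of one region's signal.

    ``peak_power_ratio`` is the ratio of oscillatory-bump power to
    background power, both integrated over the 0.5-30 Hz analysis range.
    ``band_power_tilts`` optionally multiplies the model spectrum inside
    named canonical bands.
    """

    one_over_f_exponent: float = 1.0
    peak_frequency: float = 10.0
    peak_power_ratio: float = 1.0
    peak_width: float = DEFAULT_PEAK_WIDTH
    band_power_tilts: Mapping[str, float] | None = None
    sample_rate: float = 312.5
    duration: float = 131.072  # ten 4096-sample epochs at 312.5 Hz

    def __post_init__(self) -> None:
        vals = [
            self.one_over_f_exponent,
            self.peak_frequency,
            self.peak_power_ratio,
            self.peak_width,
            self.sample_rate,
            self.duration,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("signal spec contains non-finite values")
        if self.sample_rate <= 2 * ANALYSIS_RANGE[1]:
            raise ValueError("sample_rate must exceed 60 Hz (2 x 30 Hz)")
        if not (4.0 <= self.peak_frequency <= 13.0):
            raise ValueError("peak_frequency must lie in [4, 13] Hz")
        if self.peak_power_ratio < 0 or self.peak_width <= 0:
            raise ValueError("power quantities must be non-negative")
        if self.band_power_tilts:
            for name, mult in self.band_power_tilts.items():
                if name not in BAND_BY_NAME:
                    raise ValueError(f"unknown band {name!r} in tilts")
                if not (np.isfinite(mult) and mult >= 0):
                    raise ValueError("band tilts must be non-negative finite")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


def model_psd(spec: SignalSpec, freqs: np.ndarray) -> np.ndarray:
    """Model power spectral density (arbitrary units) on a frequency grid.

    Background f^(-exponent) (flattened below 0.5 Hz to avoid the pole)
    plus a Gaussian oscillatory bump scaled so that its 0.5-30 Hz power is
    ``peak_power_ratio`` times the background's; per-band multiplicative
    tilts applied last.
    """
    freqs = np.asarray(freqs, dtype=float)
    lo, hi = ANALYSIS_RANGE
    bg = np.clip(freqs, lo, None) ** (-spec.one_over_f_exponent)
    bg = np.where(freqs == 0.0, 0.0, bg)
    bump = np.exp(
        -0.5 * ((freqs - spec.peak_frequency) / spec.peak_width) ** 2
    )
    in_range = (freqs >= lo) & (freqs < hi)
    bg_power = bg[in_range].sum()
    bump_power = bump[in_range].sum()
    if bump_power > 0 and spec.peak_power_ratio > 0:
        bump = bump * (spec.peak_power_ratio * bg_power / bump_power)
    else:
        bump = np.zeros_like(bump)
    psd = bg + bump
    if spec.band_power_tilts:
        for name, mult in spec.band_power_tilts.items():
            band = BAND_BY_NAME[name]
            psd = np.where(
                (freqs >= band.low) & (freqs < band.high), psd * mult, psd
            )
    return psd


def true_band_powers(
    spec: SignalSpec,
    bands: tuple[FrequencyBand, ...] = CANONICAL_BANDS,
    df: float = 0.005,
) -> dict[str, float]:
    """Relative band powers implied by the model spectrum (fine-grid integral)."""
    freqs = np.arange(ANALYSIS_RANGE[0], ANALYSIS_RANGE[1], df)
    psd = model_psd(spec, freqs)
    total = psd.sum()
    return {
        b.name: float(psd[(freqs >= b.low) & (freqs < b.high)].sum() / total)
        for b in bands
    }


def _shaped_noise(
    spec: SignalSpec, rng: np.random.Generator, n_series: int
) -> np.ndarray:
    """(n_series, n_samples) independent realizations of the model spectrum."""
    n = spec.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sample_rate)
    amp = np.sqrt(model_psd(spec, freqs))
    white = rng.standard_normal((n_series, n))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * amp, n=n, axis=-1)
    # unit-RMS convention; absolute scale is irrelevant to every measure
    rms = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return shaped / rms


def simulate_roi_signal(
    spec: SignalSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """One region's time series by spectral shaping of white noise.

    The expected periodogram of the output is proportional to
    ``model_psd(spec)``.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    return _shaped_noise(spec, rng, 1)[0]


# ---------------------------------------------------------------------------
# envelope coupling


@dataclass(frozen=True)
class CouplingSpec:
    """Planted band-limited envelope coupling between one region pair."""

    region_pair: tuple[int, int]
    band: FrequencyBand
    strength: float  # target leakage-free envelope correlation

    def __post_init__(self) -> None:
        i, j = self.region_pair
        if i == j:
            raise ValueError("region_pair must name two distinct regions")
        if not (0.0 <= self.strength < 1.0):
            raise ValueError("coupling strength must lie in [0, 1)")


MODULATOR_CUTOFF = 1.0  # Hz; shared amplitude modulator is slower than this

_CALIBRATION_GAIN_GRID = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0)
_CALIBRATION_SEED = 987654321
_calibration_cache: dict[tuple, tuple[PchipInterpolator, float]] = {}


def _modulated_pair_envelopes(
    band: FrequencyBand, fs: float, n: int, gain: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Envelopes of two independent carriers sharing one log-normal modulator."""
    m = lowpass_series(rng.standard_normal(n), fs, MODULATOR_CUTOFF)
    sd = m.std()
    if sd > 0:
        m = m / sd
    g = np.exp(gain * m)
    # modulation sidebands are clipped back to the band's filter support,
    # exactly as `plant_envelope_coupling` does
    e1 = np.abs(hilbert(bandpass_series(
        bandpass_series(rng.standard_normal(n), fs, band) * g, fs, band)))
    e2 = np.abs(hilbert(bandpass_series(
        bandpass_series(rng.standard_normal(n), fs, band) * g, fs, band)))
    return e1, e2


def _coupling_curve(
    band: FrequencyBand, fs: float
) -> tuple[PchipInterpolator, float]:
    """Monotone map: target envelope correlation -> modulator gain.

    The forward gain->correlation curve is estimated once per (band, sample
    rate) by Monte Carlo on long realizations with a fixed internal seed,
    then inverted and cached.  Returns (inverse curve, maximum achievable
    correlation).
    """
    key = (band.name, round(band.low, 6), round(band.high, 6), round(fs, 6))
    if key in _calibration_cache:
        return _calibration_cache[key]
    key_hash = zlib.crc32(repr(key).encode())
    n = int(round(fs * 120.0))  # 2 minutes per realization
    rho = []
    for gain in _CALIBRATION_GAIN_GRID:
        rs = []
        rng = np.random.default_rng(
            np.random.SeedSequence([_CALIBRATION_SEED, key_hash])
        )
        for _ in range(4):
            e1, e2 = _modulated_pair_envelopes(band, fs, n, gain, rng)
            rs.append(np.corrcoef(e1, e2)[0, 1])
        rho.append(float(np.mean(rs)))
    rho = np.maximum.accumulate(np.asarray(rho))  # enforce monotonicity
    rho[0] = 0.0
    # strictly increasing support for the inverse interpolator
    rho_u, idx = np.unique(rho, return_index=True)
    gains_u = np.asarray(_CALIBRATION_GAIN_GRID)[idx]
    curve = PchipInterpolator(rho_u, gains_u, extrapolate=False)
    result = (curve, float(rho_u[-1]))
    _calibration_cache[key] = result
    return result


def plant_envelope_coupling(
    x: np.ndarray,
    y: np.ndarray,
    spec: CouplingSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
    sample_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Impose a shared slow amplitude modulator on the band components of a pair.

    The band-limited component of each signal is multiplied by the same
    log-normal slow gain ``exp(a * m)`` (m a shared < 1 Hz unit-variance
    modulator), with ``a`` calibrated numerically so that the ideal
    leakage-free envelope correlation approaches ``spec.strength``.
    Out-of-band content and the band RMS are unchanged.  ``strength=0``
    returns the pair untouched.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if spec.band.high > sample_rate / 2:
        raise ValueError(
            f"band {spec.band.name!r} exceeds the Nyquist frequency "
            f"{sample_rate / 2:g} Hz"
        )
    if spec.strength == 0.0:
        return x.copy(), y.copy()
    curve, max_s = _coupling_curve(spec.band, sample_rate)
    if spec.strength > max_s:
        raise ValueError(
            f"coupling strength {spec.strength} exceeds the maximum "
            f"~{max_s:.2f} achievable by the shared-modulator mechanism"
        )
    gain = float(curve(spec.strength))
    rng = np.random.default_rng(seed)
    n = x.size
    m = lowpass_series(rng.standard_normal(n), sample_rate, MODULATOR_CUTOFF)
    sd = m.std()
    if sd > 0:
        m = m / sd
    g = np.exp(gain * m)
    out = []
    for sig in (x, y):
        b = bandpass_series(sig, sample_rate, spec.band)
        rest = sig - b
        # re-filter the modulated component so the slow-gain sidebands stay
        # inside the band's filter support (out-of-band content unchanged)
        b2 = bandpass_series(b * g, sample_rate, spec.band)
        rms_old = np.sqrt(np.mean(b**2))
        rms_new = np.sqrt(np.mean(b2**2))
        if rms_new > 0:
            b2 *= rms_old / rms_new
        out.append(rest + b2)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# cohort-level design


@dataclass(frozen=True)
class ClinicalModel:
    """Noisy linear map from the spectral state to clinical scores.

    CAMCOG (global cognition, higher = better) rises with peak frequency;
    UPDRS-III (motor impairment, higher = worse) falls with it.  Each score
    also carries a subject-level random intercept and observation noise.
    """

    camcog_intercept: float = 60.0
    camcog_peak_slope: float = 4.0
    camcog_subject_sd: float = 2.0
    camcog_noise_sd: float = 3.0
    updrs_intercept: float = 70.0
    updrs_peak_slope: float = -6.0
    updrs_subject_sd: float = 2.0
    updrs_noise_sd: float = 4.0


_DEFAULT_COVARIATES: dict[str, dict[str, float]] = {
    # per-group baseline demographics; age/duration in years, LEDD in mg
    "HC": {
        "age_mean": 58.9, "age_sd": 6.6, "p_male": 0.62, "p_isced_high": 0.69,
        "duration_mean": 0.0, "duration_sd": 0.0,
        "ledd_mean": 0.0, "ledd_sd": 0.0,
    },
    "de_novo": {
        "age_mean": 60.6, "age_sd": 7.9, "p_male": 0.71, "p_isced_high": 0.71,
        "duration_mean": 0.94, "duration_sd": 0.42,
        "ledd_mean": 0.0, "ledd_sd": 0.0,
    },
    "treated": {
        "age_mean": 64.1, "age_sd": 6.8, "p_male": 0.48, "p_isced_high": 0.52,
        "duration_mean": 7.1, "duration_sd": 3.0,
        "ledd_mean": 524.0, "ledd_sd": 394.0,
    },
}

_DEFAULT_PEAK_MEANS = {"HC": 10.0, "de_novo": 9.5, "treated": 9.0}
_PEAK_BETWEEN_SUBJECT_SD = 0.8
_LEDD_VISIT_INCREMENT = (370.0, 100.0)  # mean, sd per visit transition


def _default_couplings() -> tuple[CouplingSpec, ...]:
    return (
        CouplingSpec((4, 11), BAND_BY_NAME["alpha2"], 0.4),
        CouplingSpec((30, 40), BAND_BY_NAME["beta"], 0.3),
    )


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic longitudinal cohort.

    Defaults reproduce the structure of the study population the pipeline
    is meant for: 16 healthy controls (baseline only), 17 early-stage
    drug-naive (de novo) and 44 treated patients, three visits, a 0.5 Hz
    per-visit downward drift of the oscillatory peak in the patient groups,
    mild per-visit band-power tilts in the slowing direction, and
    missing-at-random dropout between visits.
    """

    n_controls: int = 16
    n_de_novo: int = 17
    n_treated: int = 44
    visits: tuple[str, ...] = ("BL", "FU1", "FU2")
    slowing_per_visit: float = 0.5  # Hz decrease of peak frequency per visit
    band_shift_per_visit: Mapping[str, float] = field(
        default_factory=lambda: {
            "delta": 0.04, "theta": 0.04, "alpha2": -0.04, "beta": -0.04,
        }
    )
    dropout_probability: float = 0.2
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    couplings: tuple[CouplingSpec, ...] = field(
        default_factory=_default_couplings
    )
    covariate_distributions: Mapping[str, Mapping[str, float]] | None = None
    # recording geometry (shrink for quick simulations)
    sample_rate: float = 312.5
    epoch_length: int = 4096
    n_epochs: int = 10
    # spectral state
    one_over_f_exponent: float = 1.0
    peak_power_ratio: float = 1.0
    peak_group_means: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PEAK_MEANS)
    )
    peak_between_subject_sd: float = _PEAK_BETWEEN_SUBJECT_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_controls, self.n_de_novo, self.n_treated) < 0:
            raise ValueError("group counts must be non-negative")
        if not (0.0 <= self.dropout_probability <= 1.0):
            raise ValueError("dropout_probability must lie in [0, 1]")
        if len(self.visits) < 1:
            raise ValueError("need at least one visit")

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_length / self.sample_rate


@dataclass
class GroundTruth:
    """True generating state per subject-visit, plus the planted couplings."""

    table: pd.DataFrame  # subject, group, visit, peak_frequency, rel powers
    couplings: tuple[CouplingSpec, ...]
    clinical_model: ClinicalModel


COHORT_COLUMNS = (
    "subject", "group", "visit", "age", "sex", "ISCED",
    "disease_duration", "LEDD", "UPDRS_III", "CAMCOG",
)


def _visit_tilts(design: CohortDesign, v: int) -> dict[str, float]:
    return {
        name: (1.0 + shift) ** v
        for name, shift in design.band_shift_per_visit.items()
    }


def simulate_cohort(
    design: CohortDesign,
) -> tuple[list[RoiRecording], pd.DataFrame, GroundTruth]:
    """Generate recordings, a cohort table and ground truth for one cohort.

    Healthy controls contribute a baseline visit only; patients are followed
    over all visits with monotone missing-at-random dropout (once dropped,
    absent thereafter).  Every surviving subject-visit gets a 90-region
    recording built from `simulate_roi_signal` with the planted couplings
    applied, and clinical scores drawn from the clinical model.  Fully
    reproducible from ``design.seed``.
    """
    root = np.random.SeedSequence(design.seed)
    ss_demo, ss_drop, ss_clin, ss_sig = root.spawn(4)
    rng_demo = np.random.default_rng(ss_demo)
    rng_drop = np.random.default_rng(ss_drop)
    rng_clin = np.random.default_rng(ss_clin)

    cov = dict(_DEFAULT_COVARIATES)
    if design.covariate_distributions:
        for g, d in design.covariate_distributions.items():
            cov[g] = {**cov.get(g, {}), **d}

    subjects: list[dict] = []
    for group, count, prefix in (
        ("HC", design.n_controls, "HC"),
        ("de_novo", design.n_de_novo, "DN"),
        ("treated", design.n_treated, "TR"),
    ):
        c = cov[group]
        for k in range(count):
            base_peak = float(
                np.clip(
                    rng_demo.normal(
                        design.peak_group_means[group],
                        design.peak_between_subject_sd,
                    ),
                    5.0, 12.0,
                )
            )
            subjects.append(
                {
                    "subject": f"{prefix}{k + 1:03d}",
                    "group": group,
                    "age": float(rng_demo.normal(c["age_mean"], c["age_sd"])),
                    "sex": "M" if rng_demo.random() < c["p_male"] else "F",
                    "ISCED": int(rng_demo.random() < c["p_isced_high"]),
                    "disease_duration": float(
                        max(
                            rng_demo.normal(
                                c["duration_mean"], c["duration_sd"]
                            ),
                            0.0,
                        )
                    ),
                    "ledd_bl": float(
                        max(rng_demo.normal(c["ledd_mean"], c["ledd_sd"]), 0.0)
                    ),
                    "base_peak": base_peak,
                    "b_camcog": rng_clin.normal(
                        0.0, design.clinical_model.camcog_subject_sd
                    ),
                    "b_updrs": rng_clin.normal(
                        0.0, design.clinical_model.updrs_subject_sd
                    ),
                }
            )

    recordings: list[RoiRecording] = []
    rows: list[dict] = []
    truth_rows: list[dict] = []
    clin = design.clinical_model

    for subj in subjects:
        is_patient = subj["group"] != "HC"
        present = True
        ledd = subj["ledd_bl"]
        for v, visit in enumerate(design.visits):
            if not is_patient and v > 0:
                break  # controls are studied at baseline only
            if v > 0:
                inc_mean, inc_sd = _LEDD_VISIT_INCREMENT
                ledd = max(ledd + rng_clin.normal(inc_mean, inc_sd), 0.0)
                if rng_drop.random() < design.dropout_probability:
                    present = False
            if not present:
                continue  # dropped out; absent at this and later visits

            drift = design.slowing_per_visit * v if is_patient else 0.0
            true_peak = float(np.clip(subj["base_peak"] - drift, 4.2, 12.8))
            spec = SignalSpec(
                one_over_f_exponent=design.one_over_f_exponent,
                peak_frequency=true_peak,
                peak_power_ratio=design.peak_power_ratio,
                band_power_tilts=_visit_tilts(design, v) if is_patient else None,
                sample_rate=design.sample_rate,
                duration=design.duration,
            )
            sv_seed = ss_sig.spawn(1)[0]
            seeds = sv_seed.spawn(1 + len(design.couplings))
            data = _shaped_noise(
                spec, np.random.default_rng(seeds[0]), N_REGIONS
            )
            for ci, cspec in enumerate(design.couplings):
                i, j = cspec.region_pair
                data[i], data[j] = plant_envelope_coupling(
                    data[i], data[j], cspec,
                    seeds[1 + ci], design.sample_rate,
                )
            recordings.append(
                RoiRecording(subj["subject"], visit, design.sample_rate, data)
            )

            camcog = (
                clin.camcog_intercept
                + clin.camcog_peak_slope * true_peak
                + subj["b_camcog"]
                + rng_clin.normal(0.0, clin.camcog_noise_sd)
            )
            if is_patient:
                updrs = (
                    clin.updrs_intercept
                    + clin.updrs_peak_slope * true_peak
                    + subj["b_updrs"]
                    + rng_clin.normal(0.0, clin.updrs_noise_sd)
                )
            else:
                updrs = np.nan  # motor scale not administered to controls
            rows.append(
                {
                    "subject": subj["subject"],
                    "group": subj["group"],
                    "visit": visit,
                    "age": subj["age"],
                    "sex": subj["sex"],
                    "ISCED": subj["ISCED"],
                    "disease_duration": subj["disease_duration"],
                    "LEDD": ledd if is_patient else 0.0,
                    "UPDRS_III": updrs,
                    "CAMCOG": camcog,
                }
            )
            truth_rows.append(
                {
                    "subject": subj["subject"],
                    "group": subj["group"],
                    "visit": visit,
                    "peak_frequency": true_peak,
                    **{
                        f"rel_power_{k}": pv
                        for k, pv in true_band_powers(spec).items()
                    },
                }
            )

    table = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    truth = GroundTruth(
        pd.DataFrame(truth_rows), design.couplings, design.clinical_model
    )
    return recordings, table, truth
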