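"""Synthetic-data generation: ground-truth chest/wrist displacement traces,
raw complex IF frame cubes for a point target at short range, and whole
synthetic cohorts with known blood-pressure / transit-time links.

The cohort generator encodes the causal chain the measurement method relies
on: blood pressure sets the pulse transit time through the inverse BP-PTT
relation, PWV = arm_length / PTT, and the systolic peak narrows as PWV rises
(faster wave -> sharper skin response), which is what makes the
area-under-curve sharpness feature informative downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import DisplacementTrace, IFFrameCube, RadarConfig
from .physio import BPModelParams, SubjectProfile, bp_params_for_dbp_range, ptt_from_bp

__all__ = [
    "PulseWaveformModel",
    "NoiseSpec",
    "SyntheticCohort",
    "default_subjects",
    "generate_displacement",
    "synthesize_if_cube",
    "generate_cohort",
    "waveform_models_for_reading",
    "DEFAULT_TARGET_RANGE_M",
    "CHEST_PULSE_AMPLITUDE_MM",
    "WRIST_PULSE_AMPLITUDE_MM",
]

# measurement geometry default: radar-to-skin distance
DEFAULT_TARGET_RANGE_M = 0.5
# the wrist pulse is much weaker than the chest pulse; both configurable
CHEST_PULSE_AMPLITUDE_MM = 0.3
WRIST_PULSE_AMPLITUDE_MM = 0.08
# systolic peak width: narrows as the wave speeds up and as the systolic
# drive (pulse pressure) grows; see _pulse_width
PULSE_WIDTH_SCALE_M = 0.5
PP_REF_MMHG = 42.0
PP_WIDTH_EXPONENT = 0.4

_CONDITIONS = ("morning", "rest", "evening", "post_exercise")
# each condition confines the DBP draw to a band of the subject's range
_CONDITION_DBP_BANDS = {
    "morning": (0.00, 0.35),
    "rest": (0.15, 0.50),
    "evening": (0.30, 0.65),
    "post_exercise": (0.60, 1.00),
}
_CONDITION_HEART_RATE_HZ = {
    "morning": 1.00,
    "rest": 1.10,
    "evening": 1.15,
    "post_exercise": 1.55,
}


@dataclass(frozen=True)
class PulseWaveformModel:
    """Parametric model of one site's skin-displacement waveform.

    The pulse train is a sequence of raised-cosine systolic peaks (smooth
    single peaks, no dicrotic notch) riding on an optional respiration
    sinusoid (chest only). ``ptt_delay_s`` shifts the whole train in time
    (wrist lags chest by the transit time).
    """

    heart_rate_hz: float
    pulse_amplitude_mm: float
    pulse_width_s: float
    respiration_amplitude_mm: float = 0.0
    respiration_rate_hz: float = 0.25
    ptt_delay_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.heart_rate_hz > 0:
            raise ValueError("heart_rate_hz must be positive")
        if self.pulse_amplitude_mm != 0.0 and not (0.01 <= self.pulse_amplitude_mm <= 1.0):
            raise ValueError(
                f"pulse_amplitude_mm must be 0 or in [0.01, 1] mm, got {self.pulse_amplitude_mm}"
            )
        if not self.pulse_width_s > 0:
            raise ValueError("pulse_width_s must be positive")
        if self.pulse_width_s >= 1.0 / self.heart_rate_hz:
            raise ValueError(
                f"pulse_width_s={self.pulse_width_s} must be shorter than the beat "
                f"interval {1.0 / self.heart_rate_hz:.3f} s"
            )
        if self.respiration_amplitude_mm < 0 or self.ptt_delay_s < 0:
            raise ValueError("respiration_amplitude_mm and ptt_delay_s must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic perturbations applied per cohort reading.

    All-zero gives a fully deterministic cohort that follows the BP-PTT link
    exactly.
    """

    ptt_jitter_s: float = 0.004
    pulse_width_jitter_s: float = 0.004
    pp_jitter_mmhg: float = 3.0
    heart_rate_jitter_hz: float = 0.05

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class SyntheticCohort:
    """A set of subjects and their per-reading ground-truth table.

    ``readings`` columns: subject_id, condition, sbp_mmhg, dbp_mmhg, pp_mmhg,
    ptt_s, pulse_width_s, heart_rate_hz.
    """

    subjects: list[SubjectProfile]
    readings: pd.DataFrame
    rng_seed: Optional[int]

    def __post_init__(self) -> None:
        if (self.readings["pp_mmhg"] <= 0).any():
            raise ValueError("every reading must satisfy PP = SBP - DBP > 0")

    def subject(self, subject_id: str) -> SubjectProfile:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


# the BP-PTT constants of all subjects are mild perturbations of one shared
# relation (the vasculature physics is common; the constants are
# subject-dependent only through geometry and wall properties)
_GLOBAL_DBP_SPAN = (58.0, 103.0)
_GLOBAL_PTT_SPAN = (0.14, 0.32)


def default_subjects() -> list[SubjectProfile]:
    """Five default subjects spanning ages 20-76 and arm lengths 0.64-0.74 m.

    Subject 3 is the outlier case: a wide, low-anchored DBP range, large
    pulse pressure and the largest deviation from the shared BP-PTT
    relation, emulating a medicated hypertensive participant.
    """
    base = bp_params_for_dbp_range(_GLOBAL_DBP_SPAN, _GLOBAL_PTT_SPAN)
    rows = [
        # id, age, arm length, DBP range, PP base, k1 scale, k2 shift
        ("s1", 20, 0.725, (65.0, 85.0), 40.0, 0.98, -0.5),
        ("s2", 57, 0.732, (80.0, 100.0), 46.0, 1.03, 1.0),
        ("s3", 76, 0.643, (58.0, 103.0), 55.0, 0.88, -4.0),
        ("s4", 49, 0.685, (70.0, 90.0), 43.0, 1.00, 0.0),
        ("s5", 24, 0.737, (63.0, 83.0), 41.0, 1.01, 0.5),
    ]
    subjects = []
    for sid, age, arm, dbp_range, pp_base, k1_scale, k2_shift in rows:
        params = BPModelParams(
            a=base.a, b=base.b, k1=base.k1 * k1_scale, k2=base.k2 + k2_shift
        )
        sbp_range = (dbp_range[0] + pp_base - 8.0, dbp_range[1] + pp_base + 8.0)
        subjects.append(
            SubjectProfile(
                subject_id=sid,
                age=age,
                arm_length=arm,
                bp_params=params,
                baseline_sbp_range=sbp_range,
                baseline_dbp_range=dbp_range,
            )
        )
    return subjects


_SUBJECT_PP_BASE = {"s1": 40.0, "s2": 46.0, "s3": 55.0, "s4": 43.0, "s5": 41.0}


def generate_displacement(
    model: PulseWaveformModel, config: RadarConfig
) -> DisplacementTrace:
    """Sample the waveform model at the radar frame period.

    Raised-cosine peaks of full width ``pulse_width_s`` are centered at
    ``ptt_delay_s + (k + 1/2) / heart_rate_hz``; the half-beat offset keeps
    the first peak fully inside the record.
    """
    t = config.frame_times_s()
    values = np.zeros_like(t)
    if model.pulse_amplitude_mm != 0.0:
        beat = 1.0 / model.heart_rate_hz
        half_width = model.pulse_width_s / 2.0
        duration = config.duration_s
        k = 0
        while True:
            center = model.ptt_delay_s + (k + 0.5) * beat
            if center - half_width > duration:
                break
            mask = np.abs(t - center) <= half_width
            values[mask] += (
                model.pulse_amplitude_mm
                * 0.5
                * (1.0 + np.cos(2.0 * np.pi * (t[mask] - center) / model.pulse_width_s))
            )
            k += 1
    if model.respiration_amplitude_mm > 0.0:
        values += model.respiration_amplitude_mm * np.sin(
            2.0 * np.pi * model.respiration_rate_hz * t
        )
    return DisplacementTrace(values_mm=values, sample_period_s=config.frame_period_s)


def synthesize_if_cube(
    trace: DisplacementTrace,
    config: RadarConfig,
    target_range_m: float = DEFAULT_TARGET_RANGE_M,
    dc_offset: complex = 0j,
    snr_db: float = math.inf,
    seed: Optional[int] = None,
    amplitude: float = 1.0,
) -> IFFrameCube:
    """Synthesize the complex IF cube for a single point target.

    Per frame ``n`` the fast-time signal is a tone at the beat frequency of
    the instantaneous range ``R + d[n]`` with starting phase
    ``4*pi*(R + d[n]) / wavelength``, plus the DC offset and, if ``snr_db``
    is finite, complex white Gaussian noise at that SNR relative to the tone
    power.
    """
    if len(trace) != config.n_frames:
        raise ValueError(
            f"trace length {len(trace)} does not match config n_frames {config.n_frames}"
        )
    if not 0 < target_range_m < config.max_unambiguous_range_m:
        raise ValueError(
            f"target_range_m={target_range_m} outside the unambiguous range "
            f"(0, {config.max_unambiguous_range_m:.2f}) m"
        )
    d_m = trace.values_mm * 1e-3
    ranges = target_range_m + d_m  # (n_frames,)
    fast_t = np.arange(config.adc_samples_per_chirp) / config.adc_sample_rate_hz
    beat_hz = 2.0 * config.chirp_slope_hz_per_s * ranges / 299_792_458.0
    phase0 = 4.0 * np.pi * ranges / config.wavelength_m
    arg = 2.0 * np.pi * beat_hz[:, None] * fast_t[None, :] + phase0[:, None]
    samples = amplitude * np.exp(1j * arg)
    if math.isfinite(snr_db):
        rng = np.random.default_rng(seed)
        noise_power = amplitude**2 * 10.0 ** (-snr_db / 10.0)
        sigma = math.sqrt(noise_power / 2.0)
        samples = samples + sigma * (
            rng.standard_normal(samples.shape) + 1j * rng.standard_normal(samples.shape)
        )
    samples = samples + dc_offset
    return IFFrameCube(samples=samples, config=config, dc_offset=dc_offset, noise_snr_db=snr_db)


def _pulse_width(pwv_mps: float, pp_mmhg: float) -> float:
    """Systolic peak width (s): strictly decreasing in PWV and, mildly, in
    pulse pressure. The PWV term is the sharper-peak-at-higher-speed
    mechanism; the pulse-pressure term makes the peak shape carry systolic
    information beyond what the transit time already encodes."""
    return (PULSE_WIDTH_SCALE_M / pwv_mps) * (PP_REF_MMHG / pp_mmhg) ** PP_WIDTH_EXPONENT


def _draw_reading(
    subject: SubjectProfile,
    pp_base: float,
    condition: str,
    noise: NoiseSpec,
    rng: np.random.Generator,
    max_resample: int = 50,
) -> dict:
    dlo, dhi = subject.baseline_dbp_range
    band_lo, band_hi = _CONDITION_DBP_BANDS[condition]
    u = rng.uniform(band_lo, band_hi)
    dbp = dlo + u * (dhi - dlo)
    # pulse pressure rises mildly with DBP (shared cardiovascular drive)
    pp = pp_base + 0.3 * (dbp - 0.5 * (dlo + dhi)) + noise.pp_jitter_mmhg * rng.standard_normal()
    pp = max(pp, 10.0)
    sbp = dbp + pp

    params = subject.bp_params
    for _ in range(max_resample):
        if dbp > params.k2:
            break
        u = rng.uniform(band_lo, band_hi)
        dbp = dlo + u * (dhi - dlo)
    else:
        raise RuntimeError(
            f"could not draw DBP > k2={params.k2} for subject {subject.subject_id}"
        )

    ptt = float(ptt_from_bp(dbp, params))
    ptt_meas = ptt + noise.ptt_jitter_s * rng.standard_normal()
    ptt_meas = max(ptt_meas, 0.02)
    pwv = subject.arm_length / ptt
    width = _pulse_width(pwv, pp)
    width_meas = width + noise.pulse_width_jitter_s * rng.standard_normal()
    width_meas = max(width_meas, 0.02)
    hr = _CONDITION_HEART_RATE_HZ[condition] + noise.heart_rate_jitter_hz * rng.standard_normal()
    hr = min(max(hr, 0.7), 3.0)
    return {
        "subject_id": subject.subject_id,
        "condition": condition,
        "sbp_mmhg": sbp,
        "dbp_mmhg": dbp,
        "pp_mmhg": pp,
        "ptt_s": ptt_meas,
        "pulse_width_s": width_meas,
        "heart_rate_hz": hr,
    }


def generate_cohort(
    n_subjects: int = 5,
    readings_per_subject: int = 50,
    noise: Optional[NoiseSpec] = None,
    seed: Optional[int] = None,
    subjects: Optional[Sequence[SubjectProfile]] = None,
) -> SyntheticCohort:
    """Generate a synthetic cohort table (default 5 subjects x 50 readings).

    Each reading draws an activity condition, a condition-dependent DBP and
    pulse pressure, derives SBP = DBP + PP, maps DBP to the true transit
    time through the subject's BP-PTT constants, and sets the systolic peak
    width as a decreasing function of PWV = arm_length / PTT. Measurement
    jitter from ``noise`` lands on PTT, peak width, PP and heart rate.
    Deterministic under ``seed``.
    """
    if n_subjects < 1 or readings_per_subject < 1:
        raise ValueError("subject and reading counts must be positive")
    noise = NoiseSpec() if noise is None else noise
    if subjects is None:
        subjects = default_subjects()
        if n_subjects > len(subjects):
            raise ValueError(
                f"only {len(subjects)} default subjects available; pass `subjects` "
                f"explicitly for n_subjects={n_subjects}"
            )
        subjects = subjects[:n_subjects]
    else:
        subjects = list(subjects)
        if len(subjects) != n_subjects:
            raise ValueError("len(subjects) must equal n_subjects")

    rng = np.random.default_rng(seed)
    rows = []
    for subject in subjects:
        pp_base = _SUBJECT_PP_BASE.get(subject.subject_id, 42.0)
        for i in range(readings_per_subject):
            # deterministic round-robin keeps conditions balanced per subject
            condition = _CONDITIONS[i % len(_CONDITIONS)]
            rows.append(_draw_reading(subject, pp_base, condition, noise, rng))
    readings = pd.DataFrame(rows)
    return SyntheticCohort(subjects=list(subjects), readings=readings, rng_seed=seed)


def waveform_models_for_reading(
    reading: dict | pd.Series,
    chest_pulse_amplitude_mm: float = CHEST_PULSE_AMPLITUDE_MM,
    wrist_pulse_amplitude_mm: float = WRIST_PULSE_AMPLITUDE_MM,
    respiration_amplitude_mm: float = 1.0,
    respiration_rate_hz: float = 0.25,
) -> tuple[PulseWaveformModel, PulseWaveformModel]:
    """Chest and wrist waveform models for one cohort reading.

    The chest model carries the respiration component; the wrist model is
    delayed by the reading's transit time and carries the weaker pulse.
    """
    chest = PulseWaveformModel(
        heart_rate_hz=float(reading["heart_rate_hz"]),
        pulse_amplitude_mm=chest_pulse_amplitude_mm,
        pulse_width_s=float(reading["pulse_width_s"]),
        respiration_amplitude_mm=respiration_amplitude_mm,
        respiration_rate_hz=respiration_rate_hz,
    )
    wrist = replace(
        chest,
        pulse_amplitude_mm=wrist_pulse_amplitude_mm,
        respiration_amplitude_mm=0.0,
        ptt_delay_s=float(reading["ptt_s"]),
    )
    return chest, wrist
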