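"""Core data containers shared across the simulation and processing stages:
radar chirp/frame configuration, complex IF data cubes, and skin-displacement
time series.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

SPEED_OF_LIGHT = 299_792_458.0  # m/s

__all__ = ["SPEED_OF_LIGHT", "RadarConfig", "IFFrameCube", "DisplacementTrace"]


@dataclass(frozen=True)
class RadarConfig:
    """FMCW chirp and frame parameters.

    Defaults correspond to a 77 GHz automotive-band evaluation radar:
    29.99 MHz/us chirp slope, 2.5 MHz ADC rate, 128 fast-time samples,
    0.5 ms frame period and a 10 s (20,000-frame) record.
    """

    carrier_frequency_ghz: float = 77.0
    chirp_slope_mhz_per_us: float = 29.99
    adc_sample_rate_mhz: float = 2.5
    adc_samples_per_chirp: int = 128
    frame_period_ms: float = 0.5
    n_frames: int = 20_000
    pulse_duration_us: float = 57.0

    def __post_init__(self) -> None:
        for name in (
            "carrier_frequency_ghz",
            "chirp_slope_mhz_per_us",
            "adc_sample_rate_mhz",
            "frame_period_ms",
            "pulse_duration_us",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"RadarConfig.{name} must be positive")
        if self.adc_samples_per_chirp < 1 or self.n_frames < 1:
            raise ValueError("sample and frame counts must be positive integers")
        adc_window_us = self.adc_samples_per_chirp / self.adc_sample_rate_mhz
        if adc_window_us > self.pulse_duration_us * (1 + 1e-12):
            raise ValueError(
                f"ADC acquisition window ({adc_window_us:.2f} us) exceeds the "
                f"chirp duration ({self.pulse_duration_us:.2f} us)"
            )

    @property
    def wavelength_m(self) -> float:
        """Carrier wavelength in meters (~3.9 mm at 77 GHz)."""
        return SPEED_OF_LIGHT / (self.carrier_frequency_ghz * 1e9)

    @property
    def frame_period_s(self) -> float:
        return self.frame_period_ms * 1e-3

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_period_s

    @property
    def adc_sample_rate_hz(self) -> float:
        return self.adc_sample_rate_mhz * 1e6

    @property
    def chirp_slope_hz_per_s(self) -> float:
        return self.chirp_slope_mhz_per_us * 1e12

    def range_bin_spacing_m(self, n_fft: Optional[int] = None) -> float:
        """Range increment per FFT bin for an ``n_fft``-point fast-time FFT."""
        if n_fft is None:
            n_fft = self.adc_samples_per_chirp
        return SPEED_OF_LIGHT * self.adc_sample_rate_hz / (2.0 * self.chirp_slope_hz_per_s * n_fft)

    @property
    def max_unambiguous_range_m(self) -> float:
        # complex baseband sampling: the full FFT span is usable
        return self.range_bin_spacing_m() * self.adc_samples_per_chirp

    def beat_frequency_hz(self, target_range_m: float) -> float:
        """De-chirped tone frequency for a point target at the given range."""
        return 2.0 * self.chirp_slope_hz_per_s * target_range_m / SPEED_OF_LIGHT

    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period_s

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RadarConfig":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RadarConfig":
        return cls.from_dict(json.loads(text))


@dataclass
class IFFrameCube:
    """Complex de-chirped (IF) samples, shape (n_frames, adc_samples_per_chirp)."""

    samples: np.ndarray
    config: RadarConfig
    dc_offset: complex = 0j
    noise_snr_db: float = math.inf

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        expected = (self.config.n_frames, self.config.adc_samples_per_chirp)
        if self.samples.shape != expected:
            raise ValueError(
                f"cube shape {self.samples.shape} does not match config {expected}"
            )
        if not np.all(np.isfinite(self.samples.view(float))):
            raise ValueError("cube contains non-finite samples")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]


@dataclass
class DisplacementTrace:
    """Uniformly sampled skin-displacement time series, in millimeters."""

    values_mm: np.ndarray
    sample_period_s: float
    origin_bin: Optional[int] = None
    radar_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.values_mm = np.asarray(self.values_mm, dtype=float).ravel()
        if not self.sample_period_s > 0:
            raise ValueError("sample_period_s must be positive")
        if not np.all(np.isfinite(self.values_mm)):
            raise ValueError("displacement trace contains non-finite values")

    def __len__(self) -> int:
        return self.values_mm.size

    @property
    def duration_s(self) -> float:
        return len(self) * self.sample_period_s

    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) * self.sample_period_s

    def demeaned(self) -> "DisplacementTrace":
        return dataclasses.replace(self, values_mm=self.values_mm - self.values_mm.mean())
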