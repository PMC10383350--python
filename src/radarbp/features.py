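"""Feature extraction from skin-displacement traces.

Three measurements drive the blood-pressure models: the pulse transit time
(PTT) between the chest and wrist waveforms, the pulse wave velocity
PWV = arm_length / PTT, and a peak-sharpness feature: the area between the
unit-normalized pulse peak and the horizontal line at half amplitude (AUC),
averaged over the highest peaks of the record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import DisplacementTrace
from .sim import SyntheticCohort

__all__ = [
    "PeakSet",
    "UnreliablePTTError",
    "detect_pulse_peaks",
    "estimate_ptt",
    "compute_pwv",
    "compute_auc",
    "features_from_cohort",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ["subject_id", "ptt_s", "pwv_mps", "auc_s", "sbp_mmhg", "dbp_mmhg", "pp_mmhg"]


class UnreliablePTTError(RuntimeError):
    """Raised when the cross-correlation peak is too weak to trust."""


@dataclass
class PeakSet:
    """Detected systolic peaks of one trace, in time order."""

    peak_indices: np.ndarray
    peak_amplitudes_mm: np.ndarray
    local_baselines_mm: np.ndarray
    incomplete: bool = False  # fewer peaks found than requested

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.peak_amplitudes_mm = np.asarray(self.peak_amplitudes_mm, dtype=float)
        self.local_baselines_mm = np.asarray(self.local_baselines_mm, dtype=float)
        if np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if np.any(self.peak_amplitudes_mm <= self.local_baselines_mm):
            raise ValueError("peak amplitudes must exceed their local baselines")

    def __len__(self) -> int:
        return self.peak_indices.size


def detect_pulse_peaks(
    trace: DisplacementTrace,
    min_separation_s: float = 0.4,
    k_peaks: int = 3,
) -> PeakSet:
    """Find the ``k_peaks`` most prominent pulse peaks, returned in time order.

    Prominence (not raw height) ranks the candidates so baseline drift does
    not promote peaks riding on a swell. If fewer than ``k_peaks`` local
    maxima exist the available ones are returned with ``incomplete=True`` and
    a warning.
    """
    if trace.duration_s < 2.0:
        raise ValueError("need at least 2 s of data for peak detection")
    x = trace.values_mm
    distance = max(1, int(round(min_separation_s / trace.sample_period_s)))
    indices, props = sps.find_peaks(x, distance=distance, prominence=0.0)
    if indices.size == 0:
        warnings.warn("no pulse peaks found in trace", stacklevel=2)
        return PeakSet(
            peak_indices=np.array([], dtype=int),
            peak_amplitudes_mm=np.array([]),
            local_baselines_mm=np.array([]),
            incomplete=True,
        )
    order = np.argsort(props["prominences"])[::-1]
    top = np.sort(indices[order[:k_peaks]])
    incomplete = indices.size < k_peaks
    if incomplete:
        warnings.warn(
            f"only {indices.size} peaks found, {k_peaks} requested", stacklevel=2
        )
    baselines = np.array([_segment_bounds(x, i)[2] for i in top])
    return PeakSet(
        peak_indices=top,
        peak_amplitudes_mm=x[top],
        local_baselines_mm=baselines,
        incomplete=incomplete,
    )


def _segment_bounds(x: np.ndarray, peak: int) -> tuple[int, int, float]:
    """Bounds of the peak's beat segment: the adjacent local minima
    (inclusive), plus the segment minimum used as the local baseline."""
    left = peak
    while left > 0 and x[left - 1] <= x[left]:
        left -= 1
    right = peak
    n = x.size
    while right < n - 1 and x[right + 1] <= x[right]:
        right += 1
    baseline = float(min(x[left], x[right]))
    return left, right, baseline


def estimate_ptt(
    chest: DisplacementTrace,
    wrist: DisplacementTrace,
    search_window_s: tuple[float, float] = (0.05, 0.5),
    min_correlation: float = 0.3,
) -> float:
    """Chest-to-wrist pulse delay via normalized cross-correlation.

    Returns the lag (seconds, positive = wrist lags chest) that maximizes the
    normalized cross-correlation within ``search_window_s``. Resolution is
    one frame period. The two traces must be synchronized and share the same
    sample period.

    Raises
    ------
    UnreliablePTTError
        If the best correlation within the window falls below
        ``min_correlation``.
    """
    if not np.isclose(chest.sample_period_s, wrist.sample_period_s):
        raise ValueError("chest and wrist traces must share the same sample period")
    dt = chest.sample_period_s
    lo, hi = search_window_s
    if not 0 <= lo < hi:
        raise ValueError("search window must satisfy 0 <= low < high")
    a = chest.values_mm - chest.values_mm.mean()
    b = wrist.values_mm - wrist.values_mm.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise UnreliablePTTError("flat trace: cross-correlation undefined")
    # full linear cross-correlation; lag k>0 means the wrist copy is delayed
    corr = sps.correlate(b, a, mode="full", method="auto") / denom
    lags = sps.correlation_lags(b.size, a.size, mode="full")
    lag_lo = int(np.ceil(lo / dt - 1e-9))
    lag_hi = int(np.floor(hi / dt + 1e-9))
    in_window = (lags >= lag_lo) & (lags <= lag_hi)
    if not in_window.any():
        raise ValueError("search window contains no whole-frame lag")
    window_corr = corr[in_window]
    window_lags = lags[in_window]
    best = int(np.argmax(window_corr))
    peak_corr = float(window_corr[best])
    if peak_corr < min_correlation:
        raise UnreliablePTTError(
            f"peak normalized correlation {peak_corr:.3f} < {min_correlation} "
            "within the search window"
        )
    lag = int(window_lags[best])
    if lag in (lag_lo, lag_hi):
        warnings.warn(
            f"PTT estimate {lag * dt:.4f} s hit the search-window boundary "
            f"[{lo}, {hi}] s; the true delay may lie outside",
            stacklevel=2,
        )
    return lag * dt


def compute_pwv(ptt_s: float, arm_length_m: float) -> float:
    """Pulse wave velocity: arterial path length over transit time (m/s)."""
    if not ptt_s > 0:
        raise ValueError(f"ptt must be positive, got {ptt_s!r}")
    if not arm_length_m > 0:
        raise ValueError(f"arm_length must be positive, got {arm_length_m!r}")
    return arm_length_m / ptt_s


def _peak_auc(x: np.ndarray, dt: float, peak: int) -> float:
    """Half-amplitude area of one peak, in seconds.

    The beat segment between the adjacent local minima is baseline-subtracted
    and scaled so the peak is 1; the integral of (x - 0.5) is taken over the
    contiguous super-threshold region around the peak, with the 0.5 crossings
    located by linear interpolation.
    """
    left, right, baseline = _segment_bounds(x, peak)
    seg = x[left : right + 1] - baseline
    peak_val = seg[peak - left]
    if peak_val <= 0:
        return 0.0
    seg = seg / peak_val
    p = peak - left
    above = seg - 0.5

    i = p
    while i > 0 and above[i - 1] >= 0:
        i -= 1
    j = p
    m = seg.size
    while j < m - 1 and above[j + 1] >= 0:
        j += 1

    # trapezoid over samples [i, j] of the super-threshold region
    area = float(np.trapezoid(above[i : j + 1], dx=dt))
    # fractional extensions to the interpolated 0.5 crossings
    if i > 0:
        frac = above[i] / (above[i] - above[i - 1])  # in (0, 1]
        area += 0.5 * above[i] * frac * dt
    else:
        warnings.warn("peak segment never crosses half amplitude on the left", stacklevel=3)
    if j < m - 1:
        frac = above[j] / (above[j] - above[j + 1])
        area += 0.5 * above[j] * frac * dt
    else:
        warnings.warn("peak segment never crosses half amplitude on the right", stacklevel=3)
    return area


def compute_auc(trace: DisplacementTrace, peaks: PeakSet) -> float:
    """Mean half-amplitude area (seconds) over the peaks of ``peaks``.

    Each peak is normalized to unit amplitude above its local baseline, so
    the result is invariant to gain and offset of the trace; sharper peaks
    give smaller areas.
    """
    if len(peaks) < 1:
        raise ValueError("need at least one peak to compute AUC")
    x = trace.values_mm
    dt = trace.sample_period_s
    areas = [_peak_auc(x, dt, int(p)) for p in peaks.peak_indices]
    return float(np.mean(areas))


def features_from_cohort(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-reading feature table from a synthetic cohort's ground-truth links.

    PWV is derived from the recorded (possibly jittered) transit time and the
    subject's arm length; AUC uses the closed-form half-amplitude area of a
    raised-cosine peak, width / (2*pi). Columns follow ``FEATURE_COLUMNS``.
    """
    arm = {s.subject_id: s.arm_length for s in cohort.subjects}
    df = cohort.readings
    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "ptt_s": df["ptt_s"],
            "pwv_mps": df["subject_id"].map(arm).astype(float) / df["ptt_s"],
            "auc_s": df["pulse_width_s"] / (2.0 * np.pi),
            "sbp_mmhg": df["sbp_mmhg"],
            "dbp_mmhg": df["dbp_mmhg"],
            "pp_mmhg": df["pp_mmhg"],
        }
    )
    return out
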