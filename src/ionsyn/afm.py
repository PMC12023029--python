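"""AFM fibril morphometry: height, twist periodicity, polymorph classification.

Works on baseline-subtracted centerline height profiles h(s).  Height is the
median of local-maximum (crest) heights after a light median filter — robust
to single-pixel tip artifacts; on flat rods every plateau point is a
(non-strict) local maximum, so the estimate reduces to the profile median.
Periodicity is the lag of the first peak of the normalized autocorrelation
of the detrended profile, refined by parabolic interpolation; profiles whose
best peak falls below a threshold are nonperiodic.  Classification assigns
(h, p) pairs to the polymorph class table by standardized distance, with
nonperiodic fibrils labelled p1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import median_filter, uniform_filter1d

from .presets import POLYMORPH_PRESETS, PolymorphPreset

AUTOCORR_THRESHOLD = 0.3
UNCLASSIFIED_DISTANCE = 3.0


@dataclass
class FibrilProfile:
    """Centerline height profile: uniform arclength grid (nm) x height (nm)."""

    s: np.ndarray
    h: np.ndarray
    fibril_id: str = "f0"
    condition: str = ""

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.s.shape != self.h.shape or self.s.ndim != 1:
            raise ValueError("s and h must be matching 1-D arrays")
        if self.s.size < 50:
            raise ValueError("profile needs at least 50 samples")
        steps = np.diff(self.s)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("arclength must be uniform and increasing")

    @property
    def dx(self) -> float:
        return float(self.s[1] - self.s[0])


@dataclass
class FibrilMeasurement:
    fibril_id: str
    condition: str
    h: float
    p: float | None  # None = nonperiodic
    peak_strength: float
    label: str = ""
    distance: float = math.nan


def measure_height(
    profile: FibrilProfile,
    smooth_window: int = 7,
    period_hint: float | None = None,
    detect_period: bool = True,
) -> float:
    """Fibril height (nm): median of crest heights of the filtered profile.

    A light median filter suppresses single-pixel tip artifacts.  For
    periodic fibrils (period detected internally, or passed as
    ``period_hint``) the crests are the one-per-period local maxima and the
    height is their median; for nonperiodic flat-topped rods every plateau
    point is a crest, so the estimate reduces to the profile median.
    """
    h = profile.h
    if np.all(h == 0):
        raise ValueError("all-zero profile")
    period = period_hint
    if period is None and detect_period:
        period, _, _ = measure_periodicity(profile)
    if period is not None:
        # widen the filter with the period so crest values are read from a
        # noise-suppressed profile without eroding the crests themselves
        smooth_window = max(smooth_window, int(period / (10.0 * profile.dx)) | 1)
    if smooth_window > 1:
        h = median_filter(h, size=smooth_window, mode="nearest")
    if period is not None:
        min_distance = max(int(round(0.7 * period / profile.dx)), 1)
        peaks, _ = signal.find_peaks(h, distance=min_distance)
        if peaks.size:
            return float(np.median(h[peaks]))
    return float(np.median(h))


def measure_periodicity(
    profile: FibrilProfile,
    threshold: float = AUTOCORR_THRESHOLD,
    min_lag_nm: float | None = None,
) -> tuple[float | None, float, bool]:
    """Twist periodicity (nm) from the autocorrelation of the detrended profile.

    Returns ``(p, peak_strength, low_confidence)``; ``p`` is None when the
    first autocorrelation peak is below ``threshold`` (nonperiodic).
    ``low_confidence`` marks profiles shorter than two candidate periods.
    """
    x = signal.detrend(profile.h, type="linear")
    n = x.size
    acf = np.correlate(x, x, mode="full")[n - 1 :]
    if acf[0] <= 0:
        return None, 0.0, True
    acf = acf / acf[0]
    max_lag = n // 2
    segment = uniform_filter1d(acf[: max_lag + 1], size=5, mode="nearest")
    # skip the smeared zero-lag noise spike; twist periods below ~10 nm are
    # outside the morphological range of amyloid fibrils anyway
    min_lag_nm = 10.0 if min_lag_nm is None else min_lag_nm
    min_lag = max(4, int(round(min_lag_nm / profile.dx)))
    peaks, _ = signal.find_peaks(segment[min_lag:])
    peaks = peaks + min_lag
    candidates = [p for p in peaks if segment[p] >= threshold]
    if not candidates:
        strongest = float(segment[peaks].max()) if len(peaks) else 0.0
        return None, strongest, n < 100
    lag = int(candidates[0])
    strength = float(segment[lag])
    # parabolic refinement on the unsmoothed autocorrelation
    if 1 <= lag < max_lag:
        a, b, c = acf[lag - 1], acf[lag], acf[lag + 1]
        denom = a - 2 * b + c
        offset = 0.5 * (a - c) / denom if denom != 0 else 0.0
        lag_refined = lag + float(np.clip(offset, -0.5, 0.5))
    else:
        lag_refined = float(lag)
    low_confidence = n < 2 * lag
    return lag_refined * profile.dx, strength, low_confidence


def classify_polymorph(
    h: float,
    p: float | None,
    presets: dict[str, PolymorphPreset] | None = None,
    max_distance: float = UNCLASSIFIED_DISTANCE,
) -> tuple[str, float]:
    """Polymorph label and standardized distance for one (h, p) measurement.

    Nonperiodic fibrils are p1 by definition; periodic fibrils go to the
    nearest periodic class in (h, p) standardized by the class SDs, or to
    ``unclassified`` beyond ``max_distance``.
    """
    presets = presets or POLYMORPH_PRESETS
    if not presets:
        raise ValueError("empty preset table")
    if p is None:
        ref = presets.get("p1")
        dist = abs(h - ref.mean_height) / ref.sd_height if ref else math.nan
        return "p1", float(dist)
    best_label, best_dist = "unclassified", math.inf
    for label, preset in presets.items():
        if not preset.periodic:
            continue
        d = math.hypot(
            (h - preset.mean_height) / preset.sd_height,
            (p - preset.mean_period) / preset.sd_period,
        )
        if d < best_dist:
            best_label, best_dist = label, d
    if best_dist > max_distance:
        return "unclassified", float(best_dist)
    return best_label, float(best_dist)


def measure_fibril(
    profile: FibrilProfile,
    presets: dict[str, PolymorphPreset] | None = None,
    threshold: float = AUTOCORR_THRESHOLD,
) -> FibrilMeasurement:
    p, strength, _ = measure_periodicity(profile, threshold=threshold)
    h = measure_height(profile, period_hint=p, detect_period=False)
    label, dist = classify_polymorph(h, p, presets)
    return FibrilMeasurement(profile.fibril_id, profile.condition, h, p, strength, label, dist)


def population_summary(measurements: list[FibrilMeasurement]) -> pd.DataFrame:
    """Relative abundance per polymorph per condition (fractions sum to 1).

    ``unclassified`` fibrils are reported separately and excluded from the
    abundance denominator.
    """
    if not measurements:
        raise ValueError("no measurements")
    frame = pd.DataFrame(
        {
            "condition": [m.condition for m in measurements],
            "label": [m.label for m in measurements],
        }
    )
    rows = []
    for condition, grp in frame.groupby("condition", sort=False):
        classified = grp[grp["label"] != "unclassified"]
        counts = classified["label"].value_counts()
        total = int(counts.sum())
        for label, count in counts.items():
            rows.append(
                {
                    "condition": condition,
                    "label": label,
                    "count": int(count),
                    "abundance": count / total if total else math.nan,
                }
            )
        n_uncl = int((grp["label"] == "unclassified").sum())
        if n_uncl:
            rows.append(
                {"condition": condition, "label": "unclassified", "count": n_uncl, "abundance": math.nan}
            )
    return pd.DataFrame(rows)
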