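"""ThT aggregation kinetics: plate normalization and empirical sigmoid fits.

Fibril formation monitored by thioflavin-T fluorescence follows a sigmoidal
time course.  Each trace is fitted with the Boltzmann sigmoid

    F(t) = F_max / (1 + exp(-k * (t - t50)))

where ``F_max`` is the plateau (percent of plate maximum), ``k`` (1/h) the
slope of the exponential phase and ``t50`` (h) its midpoint, i.e. the time at
which F = F_max / 2.  The nucleation lag time is derived from the fitted
parameters as ``t_lag = t50 - 2/k`` (intersection of the steepest tangent
with the baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import stats


@dataclass
class KineticTrace:
    """One well's fluorescence time course (time strictly increasing, hours)."""

    time: np.ndarray
    fluorescence: np.ndarray
    well_id: str = "A1"
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape or self.time.ndim != 1:
            raise ValueError("time and fluorescence must be matching 1-D arrays")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class KineticFit:
    well_id: str
    condition: str
    converged: bool
    f_max: float = math.nan
    k: float = math.nan
    t50: float = math.nan
    rss: float = math.nan

    @property
    def t_lag(self) -> float:
        if not self.converged:
            return math.nan
        return self.t50 - 2.0 / self.k


def sigmoid(t, f_max, k, t50):
    """Boltzmann sigmoid, numerically safe for large |k*(t - t50)|."""
    arg = np.clip(-k * (np.asarray(t, dtype=float) - t50), -500.0, 500.0)
    return f_max / (1.0 + np.exp(arg))


def normalize_plate(traces: list[KineticTrace]) -> list[KineticTrace]:
    """Scale all traces so the plate-wide maximum maps to 100 (%).

    Mirrors the plate-reader convention of normalizing to the well with the
    highest raw fluorescence; relative ordering between wells is preserved.
    """
    if not traces:
        raise ValueError("empty plate")
    plate_max = max(float(np.max(t.fluorescence)) for t in traces)
    if plate_max <= 0:
        raise ValueError("degenerate plate: no positive fluorescence")
    scale = 100.0 / plate_max
    return [
        KineticTrace(t.time.copy(), t.fluorescence * scale, t.well_id, t.condition)
        for t in traces
    ]


def fit_sigmoid(
    trace: KineticTrace,
    min_amplitude: float = 5.0,
    plateau_fraction: float = 0.9,
) -> KineticFit:
    """Least-squares Boltzmann fit of a normalized trace.

    ``converged`` is False (parameters NaN) for flat / non-aggregating wells
    (dynamic range below ``min_amplitude``) and for traces whose final 10% of
    points have not reached ``plateau_fraction`` of the fitted plateau, so
    extrapolated plateaus are never reported.
    """
    t, f = trace.time, trace.fluorescence
    if t.size < 4:
        raise ValueError("at least 4 points are required to fit a sigmoid")
    f_range = float(np.max(f) - np.min(f))
    if f_range < min_amplitude:
        return KineticFit(trace.well_id, trace.condition, converged=False)

    # Initialization: midpoint from the half-range crossing, slope from the
    # steepest finite-difference segment.
    half = np.min(f) + 0.5 * f_range
    above = np.nonzero(f >= half)[0]
    t50_0 = float(t[above[0]]) if above.size else float(t[t.size // 2])
    slopes = np.diff(f) / np.diff(t)
    k0 = max(4.0 * float(np.nanmax(slopes)) / f_range, 1e-3)

    model = Model(sigmoid)
    params = model.make_params(
        f_max=dict(value=float(np.max(f)), min=0.0),
        k=dict(value=k0, min=1e-6),
        t50=dict(value=t50_0, min=float(t[0]) - (t[-1] - t[0]), max=2.0 * float(t[-1])),
    )
    try:
        result = model.fit(f, params, t=t)
    except Exception:
        return KineticFit(trace.well_id, trace.condition, converged=False)
    if not result.success:
        return KineticFit(trace.well_id, trace.condition, converged=False)

    f_max = float(result.params["f_max"].value)
    k = float(result.params["k"].value)
    t50 = float(result.params["t50"].value)
    n_tail = max(1, t.size // 10)
    plateau_reached = float(np.mean(f[-n_tail:])) >= plateau_fraction * f_max
    if k <= 0 or not plateau_reached:
        return KineticFit(trace.well_id, trace.condition, converged=False)
    rss = float(np.sum(result.residual**2))
    return KineticFit(trace.well_id, trace.condition, True, f_max, k, t50, rss)


def fits_to_frame(fits: list[KineticFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "well_id": [f.well_id for f in fits],
            "condition": [f.condition for f in fits],
            "converged": [f.converged for f in fits],
            "f_max": [f.f_max for f in fits],
            "k": [f.k for f in fits],
            "t50": [f.t50 for f in fits],
            "t_lag": [f.t_lag for f in fits],
            "rss": [f.rss for f in fits],
        }
    )


def summarize_conditions(fits: list[KineticFit]) -> tuple[pd.DataFrame, pd.Series]:
    """Per-condition mean +/- SD of (t_lag, t50, k) and one-way ANOVA p-values.

    Conditions with no converged fit appear with NaN statistics; a condition
    with a single converged fit reports NaN SD.  The ANOVA (one per parameter)
    runs across all conditions with >= 2 converged fits.
    """
    frame = fits_to_frame(fits)
    conv = frame[frame["converged"]]
    rows = []
    for condition, grp in frame.groupby("condition", sort=False):
        g = grp[grp["converged"]]
        row = {"condition": condition, "n": int(len(g))}
        for par in ("t_lag", "t50", "k"):
            row[f"{par}_mean"] = float(g[par].mean()) if len(g) else math.nan
            row[f"{par}_sd"] = float(g[par].std(ddof=1)) if len(g) > 1 else math.nan
        rows.append(row)
    summary = pd.DataFrame(rows)

    pvals = {}
    groups = {c: g for c, g in conv.groupby("condition") if len(g) >= 2}
    for par in ("t_lag", "t50", "k"):
        if len(groups) >= 2:
            samples = [g[par].to_numpy() for g in groups.values()]
            pvals[par] = float(stats.f_oneway(*samples).pvalue)
        else:
            pvals[par] = math.nan
    return summary, pd.Series(pvals, name="anova_p")
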