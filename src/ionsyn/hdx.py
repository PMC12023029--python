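"""HDX-MS uptake kinetics with empirical chemical-exchange normalization.

Deuterium uptake of a peptide or ETD fragment is modelled as a one-phase
stretched exponential

    D(t) = N * (1 - exp(-(k_obs * t) ** beta))

with ``N`` the number of exchangeable backbone amides, ``k_obs`` (1/s) the
observed rate and ``beta`` in (0, 1.5] absorbing rate heterogeneity within
the peptide.  Because the chemical exchange rate depends on the buffer
(ionic strength, pH) and not only on structure, curves measured in different
ionic conditions are normalized via the fully unstructured reference peptide
bradykinin: the per-condition (k_obs, beta) of bradykinin defines a 2-D
multiplicative scaling onto the reference condition, which is then applied
to every protein fit in that condition, leaving only conformational
protection differences.

Residue-level consolidation combines peptides and ETD fragments by
inverse-span-length weighting, and differential maps are masked with the
hybrid criterion (Welch's t-test AND a global magnitude threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import stats

from .sequences import validate_sequence

#: Default labeling times (s), spanning sub-second chemical-exchange probes
#: to the slow structured-protein regime.
DEFAULT_TIMEPOINTS = (0.05, 0.5, 5.0, 30.0, 180.0, 900.0, 1800.0)


def count_exchangeable(sequence: str) -> int:
    """Number of exchange-competent backbone amides.

    The N-terminal residue (fast back-exchanging free amine) and all
    prolines (no amide proton) are excluded.
    """
    seq = validate_sequence(sequence)
    return sum(1 for aa in seq[1:] if aa != "P")


def stretched_exponential(t, n, k_obs, beta):
    t = np.asarray(t, dtype=float)
    return n * (1.0 - np.exp(-np.power(np.clip(k_obs * t, 0.0, None), beta)))


@dataclass
class HDXFit:
    converged: bool
    k_obs: float = math.nan
    beta: float = math.nan
    n: float = math.nan
    rss: float = math.nan


@dataclass(frozen=True)
class ScalingFactors:
    """Multiplicative (k_obs, beta) correction onto the reference condition."""

    s_k: float
    s_beta: float
    condition: str = ""
    reference: str = ""

    def __post_init__(self) -> None:
        if self.s_k <= 0 or self.s_beta <= 0:
            raise ValueError("scaling factors must be positive")

    @classmethod
    def identity(cls, condition: str = "", reference: str = "") -> "ScalingFactors":
        return cls(1.0, 1.0, condition, reference)


def fit_uptake(
    times: np.ndarray,
    uptake: np.ndarray,
    n_exchangeable: float,
    fix_n: bool = True,
) -> HDXFit:
    """Stretched-exponential fit of one uptake curve.

    ``N`` is fixed to the theoretical maximum by default (``fix_n=False``
    frees it); ``beta`` is bounded to (0, 1.5].  Returns an unconverged fit
    (parameters NaN) for degenerate data, e.g. all-zero uptake.
    """
    times = np.asarray(times, dtype=float)
    uptake = np.asarray(uptake, dtype=float)
    if np.unique(times).size < 4:
        raise ValueError("need at least 4 distinct labeling times")
    if np.all(uptake < 1e-3 * max(n_exchangeable, 1.0)):
        return HDXFit(converged=False)

    # k init: inverse of the time where uptake crosses N*(1 - 1/e).
    target = n_exchangeable * (1.0 - math.exp(-1.0))
    above = np.nonzero(uptake >= target)[0]
    t_cross = float(times[above[0]]) if above.size else float(times[-1])
    k0 = 1.0 / max(t_cross, 1e-9)

    model = Model(stretched_exponential)
    params = model.make_params(
        n=dict(value=float(n_exchangeable), vary=not fix_n, min=1e-6),
        k_obs=dict(value=k0, min=1e-9, max=1e6),
        beta=dict(value=1.0, min=0.05, max=1.5),
    )
    try:
        result = model.fit(uptake, params, t=times)
    except Exception:
        return HDXFit(converged=False)
    if not result.success:
        return HDXFit(converged=False)
    return HDXFit(
        converged=True,
        k_obs=float(result.params["k_obs"].value),
        beta=float(result.params["beta"].value),
        n=float(result.params["n"].value),
        rss=float(np.sum(result.residual**2)),
    )


def correct_back_exchange(uptake: np.ndarray, be_fraction: float) -> np.ndarray:
    """Scale raw uptake by 1/(1 - be_fraction) to undo back-exchange losses."""
    if not 0.0 <= be_fraction < 1.0:
        raise ValueError("back-exchange fraction must lie in [0, 1)")
    return np.asarray(uptake, dtype=float) / (1.0 - be_fraction)


def derive_scaling(
    fit_condition: HDXFit,
    fit_reference: HDXFit,
    condition: str = "",
    reference: str = "",
) -> ScalingFactors:
    """2-D empirical factor from per-condition bradykinin fits."""
    if not (fit_condition.converged and fit_reference.converged):
        raise ValueError("both bradykinin fits must be converged")
    return ScalingFactors(
        s_k=fit_reference.k_obs / fit_condition.k_obs,
        s_beta=fit_reference.beta / fit_condition.beta,
        condition=condition,
        reference=reference,
    )


def apply_scaling(fit: HDXFit, factors: ScalingFactors) -> HDXFit:
    if not fit.converged:
        raise ValueError("cannot scale an unconverged fit")
    return HDXFit(True, fit.k_obs * factors.s_k, fit.beta * factors.s_beta, fit.n, fit.rss)


def normalize_condition(
    table: pd.DataFrame,
    factors: ScalingFactors,
    fix_n: bool = True,
) -> pd.DataFrame:
    """Regenerate a condition's uptake table with chemical exchange normalized.

    Each (peptide, replicate) curve in ``table`` (columns ``id``,
    ``start_res``, ``end_res``, ``n_exchangeable``, ``time_s``, ``uptake_Da``,
    ``replicate``) is fitted, its parameters are multiplied by ``factors``,
    and the parametric correction is applied additively,

        D'(t) = D(t) + [model(t; scaled params) - model(t; fitted params)],

    so replicate residuals survive the correction and downstream Welch
    testing sees the real measurement scatter.  Curves whose fit does not
    converge are passed through unchanged (column ``normalized`` records
    which).
    """
    out = table.copy()
    out["normalized"] = False
    for (_pid, _rep), idx in table.groupby(["id", "replicate"]).groups.items():
        sub = table.loc[idx]
        n_ex = float(sub["n_exchangeable"].iloc[0])
        fit = fit_uptake(sub["time_s"].to_numpy(), sub["uptake_Da"].to_numpy(), n_ex, fix_n=fix_n)
        if not fit.converged:
            continue
        scaled = apply_scaling(fit, factors)
        t = sub["time_s"].to_numpy()
        shift = stretched_exponential(t, scaled.n, scaled.k_obs, scaled.beta) - \
            stretched_exponential(t, fit.n, fit.k_obs, fit.beta)
        out.loc[idx, "uptake_Da"] = sub["uptake_Da"].to_numpy() + shift
        out.loc[idx, "normalized"] = True
    return out


def consolidate_residues(
    spans: list[tuple[int, int]],
    uptakes: list[float],
    n_residues: int,
) -> np.ndarray:
    """Combine overlapping peptide/fragment uptake to per-residue values.

    Each span contributes its mean per-residue uptake (uptake / span length)
    to every residue it covers, weighted by 1/span length so that shorter
    (higher-resolution) ETD fragments dominate.  Residues with no coverage
    are NaN.
    """
    if len(spans) != len(uptakes):
        raise ValueError("spans and uptakes must have equal length")
    if not spans:
        raise ValueError("no coverage at all")
    num = np.zeros(n_residues)
    den = np.zeros(n_residues)
    for (start, end), uptake in zip(spans, uptakes):
        if not 1 <= start <= end <= n_residues:
            raise ValueError(f"span ({start}, {end}) outside 1..{n_residues}")
        length = end - start + 1
        weight = 1.0 / length
        num[start - 1 : end] += weight * (uptake / length)
        den[start - 1 : end] += weight
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def residue_uptake_matrix(
    table: pd.DataFrame, n_residues: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Residue x time x replicate uptake array from a long uptake table.

    Returns ``(matrix, times, replicates)``; cells without coverage are NaN.
    """
    times = np.sort(table["time_s"].unique())
    reps = np.sort(table["replicate"].unique())
    matrix = np.full((n_residues, times.size, reps.size), np.nan)
    for (t, r), sub in table.groupby(["time_s", "replicate"]):
        ti = int(np.searchsorted(times, t))
        ri = int(np.searchsorted(reps, r))
        spans = list(zip(sub["start_res"].astype(int), sub["end_res"].astype(int)))
        matrix[:, ti, ri] = consolidate_residues(spans, sub["uptake_Da"].tolist(), n_residues)
    return matrix, times, reps


@dataclass
class DifferentialMap:
    """Residue x time differential uptake with a hybrid significance mask."""

    delta: np.ndarray  # mean(B) - mean(A), Da
    pvalues: np.ndarray
    mask: np.ndarray  # True = significant
    times: np.ndarray
    global_threshold: float
    convention: str = "stateB - stateA; positive = more uptake (deprotection) in stateB"

    def to_frame(self, masked: bool = True) -> pd.DataFrame:
        data = np.where(self.mask, self.delta, np.nan) if masked else self.delta
        return pd.DataFrame(
            data,
            index=pd.RangeIndex(1, self.delta.shape[0] + 1, name="residue"),
            columns=pd.Index(self.times, name="time_s"),
        )


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t-statistic and two-sided p over the last axis."""
    na, nb = a.shape[-1], b.shape[-1]
    ma, mb = np.nanmean(a, axis=-1), np.nanmean(b, axis=-1)
    va, vb = np.nanvar(a, axis=-1, ddof=1), np.nanvar(b, axis=-1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = (mb - ma) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return tstat, p


def differential_map(
    state_a: np.ndarray,
    state_b: np.ndarray,
    times: np.ndarray,
    alpha: float = 0.05,
) -> DifferentialMap:
    """Hybrid-significance differential uptake map between two states.

    ``state_a``/``state_b`` are residue x time x replicate arrays (>= 2,
    normally >= 3 replicates).  A cell is significant iff its Welch p-value
    is below ``alpha`` AND |delta| exceeds the global threshold
    t_crit(alpha, pooled df) * pooled SEM computed over all covered cells.
    """
    state_a = np.asarray(state_a, dtype=float)
    state_b = np.asarray(state_b, dtype=float)
    if state_a.shape != state_b.shape:
        raise ValueError("state arrays must have the same shape")
    na, nb = state_a.shape[-1], state_b.shape[-1]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 replicates per state")

    delta = np.nanmean(state_b, axis=-1) - np.nanmean(state_a, axis=-1)
    _, p = _welch(state_a, state_b)

    covered = ~np.isnan(delta)
    va = np.nanvar(state_a, axis=-1, ddof=1)[covered]
    vb = np.nanvar(state_b, axis=-1, ddof=1)[covered]
    mean_va, mean_vb = float(np.mean(va)), float(np.mean(vb))
    se2 = mean_va / na + mean_vb / nb
    if se2 > 0:
        df = se2**2 / ((mean_va / na) ** 2 / (na - 1) + (mean_vb / nb) ** 2 / (nb - 1))
        threshold = float(stats.t.ppf(1.0 - alpha / 2.0, df) * math.sqrt(se2))
    else:
        threshold = 0.0
    mask = covered & (p < alpha) & (np.abs(delta) > threshold)
    return DifferentialMap(delta, p, mask, np.asarray(times), threshold)
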