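"""Weighted 1H-15N chemical-shift perturbations between two states.

The combined amide CSP of residue i between two HSQC peak lists is

    dd_w = sqrt(ddH^2 + (alpha * ddN)^2)          (optionally / sqrt(2))

with ``alpha`` the 15N down-weighting (default 0.14, the field standard for
backbone amides).  Residues assigned in only one state are reported absent.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

DEFAULT_ALPHA = 0.14


def compute_csp(
    state1: pd.DataFrame,
    state2: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    sqrt2_norm: bool = False,
) -> pd.DataFrame:
    """Per-residue weighted CSPs between two peak lists.

    Parameters
    ----------
    state1, state2
        Peak lists with columns ``residue``, ``dH_ppm``, ``dN_ppm``;
        residue indices must be unique within each list.
    alpha
        Nitrogen weight in the combination rule.
    sqrt2_norm
        Apply an additional 1/sqrt(2) prefactor to the combined shift.

    Returns
    -------
    DataFrame with columns ``residue``, ``ddH``, ``ddN``, ``dd_weighted``
    for residues present in both states, sorted by residue.
    """
    for df in (state1, state2):
        if df["residue"].duplicated().any():
            raise ValueError("residue indices must be unique within a peak list")
    merged = state1.merge(state2, on="residue", suffixes=("_1", "_2"))
    if merged.empty:
        raise ValueError("the two states share no residues")
    ddh = merged["dH_ppm_2"].to_numpy() - merged["dH_ppm_1"].to_numpy()
    ddn = merged["dN_ppm_2"].to_numpy() - merged["dN_ppm_1"].to_numpy()
    dd = np.sqrt(ddh**2 + (alpha * ddn) ** 2)
    if sqrt2_norm:
        dd = dd / math.sqrt(2.0)
    out = pd.DataFrame(
        {"residue": merged["residue"], "ddH": ddh, "ddN": ddn, "dd_weighted": dd}
    )
    return out.sort_values("residue", ignore_index=True)


def flag_perturbed(
    csps: pd.DataFrame,
    method: str = "mean_sd",
    cutoff: float | None = None,
    n_sd: float = 1.0,
    trim_sd: float = 3.0,
) -> pd.DataFrame:
    """Flag significantly perturbed residues.

    ``mean_sd`` (default): outliers above ``trim_sd`` standard deviations are
    removed iteratively, then residues with dd_weighted > mean + ``n_sd``*SD
    of the trimmed set are flagged.  ``fixed``: flag dd_weighted > ``cutoff``.
    """
    if len(csps) < 5:
        raise ValueError("need at least 5 residues to flag perturbations")
    values = csps["dd_weighted"].to_numpy(dtype=float)
    if method == "fixed":
        if cutoff is None:
            raise ValueError("fixed method requires a cutoff")
        threshold = cutoff
    elif method == "mean_sd":
        keep = np.ones(values.size, dtype=bool)
        while True:
            mean = values[keep].mean()
            sd = values[keep].std(ddof=0)
            new_keep = keep & (values <= mean + trim_sd * sd)
            if new_keep.sum() == keep.sum() or new_keep.sum() < 3:
                break
            keep = new_keep
        threshold = values[keep].mean() + n_sd * values[keep].std(ddof=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    out = csps.copy()
    out["flagged"] = out["dd_weighted"].to_numpy() > threshold
    out.attrs["threshold"] = float(threshold)
    return out
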