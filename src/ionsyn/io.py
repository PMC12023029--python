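"""CSV / .dat readers and writers for the pipeline's tabular interfaces."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .afm import FibrilProfile
from .kinetics import KineticTrace
from .sans import ScatteringCurve


# ThT plates: long format (plate, well, condition, time_h, fluorescence)

def write_plate_csv(traces: list[KineticTrace], path: str, plate: str = "plate1") -> None:
    rows = []
    for t in traces:
        for time, f in zip(t.time, t.fluorescence):
            rows.append(
                {"plate": plate, "well": t.well_id, "condition": t.condition,
                 "time_h": time, "fluorescence": f}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate_csv(path: str) -> list[KineticTrace]:
    frame = pd.read_csv(path)
    traces = []
    for (well, condition), grp in frame.groupby(["well", "condition"], sort=False):
        grp = grp.sort_values("time_h")
        traces.append(
            KineticTrace(grp["time_h"].to_numpy(), grp["fluorescence"].to_numpy(),
                         well_id=str(well), condition=str(condition))
        )
    return traces


# NMR peak lists: residue, dH_ppm, dN_ppm

def read_peaklist_csv(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"residue", "dH_ppm", "dN_ppm"}
    if not required <= set(frame.columns):
        raise ValueError(f"peak list must have columns {sorted(required)}")
    return frame


# HDX uptake tables: id, start_res, end_res, n_exchangeable, time_s,
# uptake_Da, replicate, condition

def read_uptake_csv(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"id", "start_res", "end_res", "time_s", "uptake_Da", "replicate"}
    if not required <= set(frame.columns):
        raise ValueError(f"uptake table must have columns {sorted(required)}")
    return frame


# Scattering curves: 3-column whitespace-delimited (q, I, sigma)

def write_dat(curve: ScatteringCurve, path: str) -> None:
    np.savetxt(
        path,
        np.column_stack([curve.q, curve.i, curve.sigma]),
        header="q_invA I sigma",
        fmt="%.8e",
    )


def read_dat(path: str) -> ScatteringCurve:
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("scattering file must have 3 columns (q, I, sigma)")
    return ScatteringCurve(q=data[:, 0], i=data[:, 1], sigma=data[:, 2])


# AFM centerline profiles: fibril_id, s_nm, h_nm, condition

def write_profiles_csv(profiles: list[FibrilProfile], path: str) -> None:
    rows = []
    for p in profiles:
        for s, h in zip(p.s, p.h):
            rows.append({"fibril_id": p.fibril_id, "s_nm": s, "h_nm": h, "condition": p.condition})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles_csv(path: str) -> list[FibrilProfile]:
    frame = pd.read_csv(path)
    out = []
    for fid, grp in frame.groupby("fibril_id", sort=False):
        grp = grp.sort_values("s_nm")
        condition = str(grp["condition"].iloc[0]) if "condition" in grp else ""
        out.append(
            FibrilProfile(grp["s_nm"].to_numpy(), grp["h_nm"].to_numpy(),
                          fibril_id=str(fid), condition=condition)
        )
    return out
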