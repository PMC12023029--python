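"""Trajectory-derived observables for the aSyn monomer.

Implements the analysis metrics applied to the simulations: per-residue ion
proximity frequencies and residence times, hydration-shell water persistence,
inter-region center-of-mass distances, radius of gyration, and windowed
globularity (shape isotropy of the positional-fluctuation covariance).

Distances are in Angstrom, times in ps, residue indices 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory import ION, PROTEIN, WATER, Trajectory

#: First-hydration-shell convention: water O / ion to protein heavy atom.
DEFAULT_SHELL_CUTOFF = 3.5
DEFAULT_ION_CUTOFF = 3.5

#: Default aSyn region scheme and the finer early/late splits.
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "n_term": (1, 60),
    "nac": (61, 95),
    "c_term": (96, 140),
}
FINE_REGIONS: dict[str, tuple[int, int]] = {
    "n_term_early": (1, 30),
    "n_term_late": (31, 60),
    "nac_early": (61, 78),
    "nac_late": (79, 95),
    "c_term_early": (96, 118),
    "c_term_late": (119, 140),
}


@dataclass(frozen=True)
class RegionPartition:
    """Named, non-overlapping, 1-based inclusive residue ranges."""

    ranges: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, (start, end) in self.ranges.items():
            if start < 1 or end < start:
                raise ValueError(f"bad range for region {name!r}")
            span = set(range(start, end + 1))
            if span & seen:
                raise ValueError(f"region {name!r} overlaps another region")
            seen |= span

    def residues(self, name: str) -> np.ndarray:
        if name not in self.ranges:
            raise KeyError(f"unknown region {name!r}")
        start, end = self.ranges[name]
        return np.arange(start, end + 1)

    @classmethod
    def default(cls) -> "RegionPartition":
        return cls(dict(DEFAULT_REGIONS))

    @classmethod
    def fine(cls) -> "RegionPartition":
        return cls(dict(FINE_REGIONS))


def _contact_matrix(traj: Trajectory, probe_idx: np.ndarray, cutoff: float) -> np.ndarray:
    """(n_frames, n_probes) bool: probe within ``cutoff`` of any protein atom."""
    prot = traj.protein_index
    if prot.size == 0:
        raise ValueError("trajectory contains no protein particles")
    out = np.zeros((traj.n_frames, probe_idx.size), dtype=bool)
    if cutoff <= 0:
        return out
    for f in range(traj.n_frames):
        tree = cKDTree(traj.coords[f, prot])
        d, _ = tree.query(traj.coords[f, probe_idx], k=1)
        out[f] = d <= cutoff
    return out


def _run_lengths(mask_1d: np.ndarray) -> list[int]:
    """Lengths (frames) of maximal consecutive True runs."""
    runs, count = [], 0
    for v in mask_1d:
        if v:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def ion_proximity_frequency(
    traj: Trajectory,
    ion_species: str,
    cutoff: float = DEFAULT_ION_CUTOFF,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-residue ion contact frequency and per-ion residence statistics.

    Frequency of residue r is the fraction of frames in which at least one
    ion of ``ion_species`` lies within ``cutoff`` of any atom of r.
    Residence of an ion is the mean length of its maximal consecutive-frame
    protein-contact runs times the frame interval (ps); ions that never
    touch the protein have NaN residence.
    """
    ions = traj.select(ION, ion_species)
    if ions.size == 0:
        raise ValueError(f"no ions of species {ion_species!r} in trajectory")
    prot = traj.protein_index
    residues = np.unique(traj.residue[prot])
    freq = pd.Series(0.0, index=pd.Index(residues, name="residue"), name="frequency")
    if cutoff > 0:
        hit = np.zeros((traj.n_frames, residues.size), dtype=bool)
        res_of_col = {r: j for j, r in enumerate(residues)}
        for f in range(traj.n_frames):
            tree = cKDTree(traj.coords[f, ions])
            pairs = tree.query_ball_point(traj.coords[f, prot], cutoff)
            for atom_pos, neighbours in enumerate(pairs):
                if neighbours:
                    hit[f, res_of_col[traj.residue[prot[atom_pos]]]] = True
        freq[:] = hit.mean(axis=0)

    contact = _contact_matrix(traj, ions, cutoff)
    rows = []
    for j, ion in enumerate(ions):
        runs = _run_lengths(contact[:, j])
        rows.append(
            {
                "ion_index": int(ion),
                "species": ion_species,
                "n_runs": len(runs),
                "mean_residence_ps": float(np.mean(runs)) * traj.frame_dt_ps if runs else math.nan,
                "max_residence_ps": float(np.max(runs)) * traj.frame_dt_ps if runs else math.nan,
                "contact_fraction": float(contact[:, j].mean()),
            }
        )
    return freq, pd.DataFrame(rows)


@dataclass
class WaterPersistence:
    durations_ps: np.ndarray  # one entry per maximal shell-residence run
    mean_persistence_ps: float
    escape_rate_per_frame: float  # 1 / mean run length (frames)
    displacements: np.ndarray  # (n_frames - 1, n_waters) per-step |dr|


def water_persistence(
    traj: Trajectory,
    shell_cutoff: float = DEFAULT_SHELL_CUTOFF,
) -> WaterPersistence:
    """Continuous hydration-shell residence durations of every water.

    A run of k consecutive in-shell frames spans (k - 1) * dt ps, so a water
    that never leaves a window of f frames has persistence (f - 1) * dt.
    For a memoryless escape process the run lengths are geometric and the
    per-frame escape rate is recovered as 1 / mean(run length).
    Waters that never enter the shell are excluded from the distribution.
    """
    if traj.n_frames < 2:
        raise ValueError("persistence needs at least 2 frames")
    waters = traj.select(WATER)
    if waters.size == 0:
        raise ValueError("trajectory contains no waters")
    in_shell = _contact_matrix(traj, waters, shell_cutoff)
    runs: list[int] = []
    for j in range(waters.size):
        runs.extend(_run_lengths(in_shell[:, j]))
    runs_arr = np.array(runs, dtype=float)
    durations = (runs_arr - 1.0) * traj.frame_dt_ps
    disp = np.linalg.norm(np.diff(traj.coords[:, waters, :], axis=0), axis=2)
    mean_run = float(runs_arr.mean()) if runs_arr.size else math.nan
    return WaterPersistence(
        durations_ps=durations,
        mean_persistence_ps=float(durations.mean()) if durations.size else math.nan,
        escape_rate_per_frame=1.0 / mean_run if runs_arr.size else math.nan,
        displacements=disp,
    )


def _region_atoms(traj: Trajectory, partition: RegionPartition, region: str) -> np.ndarray:
    start, end = partition.ranges[region] if region in partition.ranges else (None, None)
    if start is None:
        raise KeyError(f"unknown region {region!r}")
    prot = traj.protein_index
    sel = prot[(traj.residue[prot] >= start) & (traj.residue[prot] <= end)]
    if sel.size == 0:
        raise ValueError(f"region {region!r} selects no atoms")
    return sel


def region_com_distance(
    traj: Trajectory,
    partition: RegionPartition,
    pair: tuple[str, str],
    bins: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame distance between mass-weighted region centers of mass.

    Returns ``(series, hist, bin_edges)`` with the series in Angstrom.
    """
    a = _region_atoms(traj, partition, pair[0])
    b = _region_atoms(traj, partition, pair[1])
    wa = traj.masses[a] / traj.masses[a].sum()
    wb = traj.masses[b] / traj.masses[b].sum()
    com_a = np.einsum("fij,i->fj", traj.coords[:, a, :], wa)
    com_b = np.einsum("fij,i->fj", traj.coords[:, b, :], wb)
    series = np.linalg.norm(com_a - com_b, axis=1)
    hist, edges = np.histogram(series, bins=bins)
    return series, hist, edges


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration of one frame selection (Angstrom)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("empty selection")
    if masses is None:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    w = masses / masses.sum()
    com = w @ coords
    return float(np.sqrt(np.sum(w * np.sum((coords - com) ** 2, axis=1))))


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation superposing centred ``mobile`` onto centred ``reference``."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


@dataclass
class ShapeMetrics:
    window: tuple[int, int]
    rg: float
    globularity: float  # lambda_min / lambda_max, in (0, 1]; NaN if singular
    eig_ratio: float  # lambda_max / lambda_min as reported by PCA tools
    valid: bool


def _window_shape(coords: np.ndarray, masses: np.ndarray, align: bool) -> tuple[float, float]:
    """(globularity, eig_ratio) of a (frames, atoms, 3) coordinate block."""
    x = coords - coords.mean(axis=1, keepdims=True)  # centre each frame
    mean = x.mean(axis=0)
    if align and coords.shape[1] >= 3:
        for _ in range(2):
            aligned = np.empty_like(x)
            for f in range(x.shape[0]):
                aligned[f] = x[f] @ _kabsch(x[f], mean)
            x = aligned
            mean = x.mean(axis=0)
    fluct = (x - mean).reshape(-1, 3)
    cov = np.cov(fluct.T)
    eig = np.sort(np.linalg.eigvalsh(cov))
    if eig[-1] <= 0:
        return math.nan, math.nan
    if eig[0] <= 0:
        return 0.0, math.inf
    return float(eig[0] / eig[-1]), float(eig[-1] / eig[0])


def globularity(
    traj: Trajectory,
    window: int = 6,
    stride: int = 1,
    align: bool = True,
    full_chain: bool = True,
) -> list[ShapeMetrics]:
    """Windowed shape isotropy of positional fluctuations.

    For each sliding residue window (and optionally the full chain) the 3x3
    covariance of atomic positional fluctuations about the mean structure
    (after optional Kabsch superposition) is diagonalized.  Reported
    globularity is lambda_min / lambda_max in (0, 1] — 1 for isotropic
    fluctuations, small for fluctuations confined to one axis — with the
    raw lambda_max / lambda_min ratio also emitted.
    """
    if traj.n_frames < 2:
        raise ValueError("globularity needs at least 2 frames")
    if window < 3:
        raise ValueError("window must span at least 3 residues")
    prot = traj.protein_index
    residues = np.unique(traj.residue[prot])
    out: list[ShapeMetrics] = []

    def one(first: int, last: int) -> ShapeMetrics:
        sel = prot[(traj.residue[prot] >= first) & (traj.residue[prot] <= last)]
        block = traj.coords[:, sel, :]
        g, ratio = _window_shape(block, traj.masses[sel], align)
        rg = float(
            np.mean([radius_of_gyration(block[f], traj.masses[sel]) for f in range(block.shape[0])])
        )
        return ShapeMetrics((first, last), rg, g, ratio, valid=not math.isnan(g))

    for start in range(int(residues[0]), int(residues[-1]) - window + 2, stride):
        out.append(one(start, start + window - 1))
    if full_chain:
        out.append(one(int(residues[0]), int(residues[-1])))
    return out
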