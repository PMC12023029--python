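"""Toy-trajectory container and multi-model PDB round trip.

The in-memory representation is deliberately minimal: coordinates in
Angstrom for every frame, plus a flat particle table (kind, species,
residue index, mass).  Coarse protein beads sit on Calpha positions; waters
are single O sites (resname HOH) and ions are monatomic HETATM records
(resnames NA/CA/CL/K).  Reading goes through MDAnalysis so externally
produced multi-model PDBs are accepted too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sequences import ASYN_SEQUENCE, MEAN_RESIDUE_MASS

PROTEIN = "protein"
WATER = "water"
ION = "ion"

ION_MASSES = {"NA": 22.99, "CA": 40.08, "CL": 35.45, "K": 39.10}
WATER_MASS = 18.02

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
_AA3_SET = set(_AA3.values())


@dataclass
class Trajectory:
    """Frames of typed particles at a fixed interval.

    coords: (n_frames, n_particles, 3) Angstrom.
    kind: per-particle {"protein", "water", "ion"}.
    species: ion species label (NA/CA/CL/K) or "" for non-ions.
    residue: 1-based residue index for protein particles, -1 otherwise.
    """

    coords: np.ndarray
    kind: np.ndarray
    species: np.ndarray
    residue: np.ndarray
    masses: np.ndarray
    frame_dt_ps: float
    sequence: str = ASYN_SEQUENCE
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, particles, 3)")
        if self.frame_dt_ps <= 0:
            raise ValueError("frame interval must be positive")
        n = self.coords.shape[1]
        for arr in (self.kind, self.species, self.residue, self.masses):
            if len(arr) != n:
                raise ValueError("particle table length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def select(self, kind: str, species: str | None = None) -> np.ndarray:
        sel = self.kind == kind
        if species is not None:
            sel &= self.species == species
        return np.nonzero(sel)[0]

    @property
    def protein_index(self) -> np.ndarray:
        return self.select(PROTEIN)


def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, element, hetatm):
    record = "HETATM" if hetatm else "ATOM  "
    return (
        f"{record}{serial % 100000:5d} {name:<4s}{resname:>4s} {chain}"
        f"{resseq % 10000:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


def write_pdb(traj: Trajectory, path: str) -> None:
    """Write a deterministic multi-model PDB (MODEL/ENDMDL per frame)."""
    seq = traj.sequence
    with open(path, "w") as fh:
        fh.write(f"REMARK   6 FRAME_DT_PS {traj.frame_dt_ps:.3f}\n")
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            serial = 1
            water_res = 1
            ion_res = 1
            for i in range(traj.coords.shape[1]):
                xyz = traj.coords[m, i]
                if traj.kind[i] == PROTEIN:
                    resi = int(traj.residue[i])
                    resname = _AA3.get(seq[resi - 1], "ALA") if resi <= len(seq) else "ALA"
                    fh.write(_pdb_atom_line(serial, "CA", resname, "A", resi, xyz, "C", False))
                elif traj.kind[i] == WATER:
                    fh.write(_pdb_atom_line(serial, "O", "HOH", "W", water_res, xyz, "O", True))
                    water_res += 1
                else:
                    sp = str(traj.species[i])
                    fh.write(_pdb_atom_line(serial, sp, sp, "I", ion_res, xyz, sp[0], True))
                    ion_res += 1
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb(path: str, frame_dt_ps: float | None = None) -> Trajectory:
    """Load a multi-model PDB via MDAnalysis into a :class:`Trajectory`.

    Particle typing is inferred from residue names (HOH -> water,
    NA/CA/CL/K -> ion, amino acids -> protein); the frame interval is taken
    from the REMARK header when present, else from ``frame_dt_ps``.
    """
    import MDAnalysis as mda

    dt = frame_dt_ps
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK   6 FRAME_DT_PS"):
                dt = float(line.split()[-1])
                break
            if line.startswith(("MODEL", "ATOM", "HETATM")):
                break
    if dt is None:
        raise ValueError("frame interval not recorded in file; pass frame_dt_ps")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)

    resnames = [str(r).upper() for r in u.atoms.resnames]
    kind, species, residue, masses = [], [], [], []
    for i, resname in enumerate(resnames):
        if resname in ("HOH", "WAT", "TIP3", "SOL"):
            kind.append(WATER); species.append(""); residue.append(-1); masses.append(WATER_MASS)
        elif resname in ION_MASSES:
            kind.append(ION); species.append(resname); residue.append(-1)
            masses.append(ION_MASSES[resname])
        elif resname in _AA3_SET:
            kind.append(PROTEIN); species.append("")
            residue.append(int(u.atoms.resids[i])); masses.append(MEAN_RESIDUE_MASS)
        else:
            raise ValueError(f"unrecognized residue name {resname!r}")
    return Trajectory(
        coords=coords,
        kind=np.array(kind),
        species=np.array(species),
        residue=np.array(residue, dtype=int),
        masses=np.array(masses, dtype=float),
        frame_dt_ps=float(dt),
    )
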