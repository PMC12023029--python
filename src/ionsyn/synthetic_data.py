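"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of its arguments and seed (identical calls
are byte-identical), emulates the statistical structure the corresponding
analysis assumes, and returns the generating parameters so downstream tests
can do parameter recovery.  Noiseless outputs satisfy the analysis models
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinetics as _kinetics
from . import sans as _sans
from .afm import FibrilProfile
from .hdx import count_exchangeable, stretched_exponential
from .presets import (
    POLYMORPH_PRESETS,
    IonSpec,
    PolymorphPreset,
    SyntheticConditionPreset,
)
from .sequences import ASYN_SEQUENCE, BRADYKININ_SEQUENCE, acidic_residues
from .trajectory import ION, ION_MASSES, PROTEIN, WATER, WATER_MASS, Trajectory, write_pdb
from .sequences import MEAN_RESIDUE_MASS

#: Default per-residue intrinsic exchange rate (1/s) for the protein; a
#: single constant rather than sequence-dependent tables, since the
#: normalization stage only needs a multiplicative condition confound.
DEFAULT_K_INT = 0.1
#: Bradykinin exchanges fast (unstructured, short peptide).
BRADYKININ_K_INT = 1.0

#: Dense sub-second-to-30 s schedule used for the fast-exchanging reference
#: peptide, so both k_obs and beta are well constrained.
BRADYKININ_TIMEPOINTS = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 30.0)


# --------------------------------------------------------------------------
# ThT kinetics


def make_tht_trace(
    preset: SyntheticConditionPreset,
    n_timepoints: int = 250,
    dt: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    well_id: str = "A1",
) -> tuple[_kinetics.KineticTrace, dict]:
    """One sigmoidal ThT trace (time in hours) plus generating parameters."""
    if n_timepoints < 10:
        raise ValueError("need at least 10 timepoints")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    kp = preset.kinetics_params
    time = np.arange(n_timepoints) * dt
    clean = _kinetics.sigmoid(time, kp.f_max, kp.k, kp.t50)
    rng = np.random.default_rng(seed)
    values = clean + rng.normal(0.0, noise_sd, size=time.size) if noise_sd > 0 else clean
    trace = _kinetics.KineticTrace(time, values, well_id=well_id, condition=preset.name)
    truth = {"f_max": kp.f_max, "k": kp.k, "t50": kp.t50, "t_lag": kp.t_lag}
    return trace, truth


def make_tht_plate(
    presets: dict[str, SyntheticConditionPreset],
    n_wells: int = 6,
    n_timepoints: int = 250,
    dt: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[list[_kinetics.KineticTrace], dict]:
    """Replicate wells for every condition on one plate."""
    traces, truths = [], {}
    ss = np.random.SeedSequence(seed)
    children = ss.generate_state(len(presets) * n_wells) % (2**31)
    w = 0
    for name, preset in presets.items():
        truths[name] = None
        for rep in range(n_wells):
            trace, truth = make_tht_trace(
                preset, n_timepoints, dt, noise_sd, seed=int(children[w]),
                well_id=f"{name}_{rep}",
            )
            truths[name] = truth
            traces.append(trace)
            w += 1
    return traces, truths


# --------------------------------------------------------------------------
# HDX


def default_peptides(n_residues: int = 140, length: int = 10) -> list[tuple[int, int]]:
    """Non-overlapping tiling peptides covering the sequence."""
    return [(s, min(s + length - 1, n_residues)) for s in range(1, n_residues + 1, length)]


@dataclass
class HDXDataset:
    protein: pd.DataFrame
    bradykinin: pd.DataFrame
    truth: dict


def _peptide_beta(seed: int, index: int) -> float:
    """Per-peptide stretching exponent, condition-independent by construction."""
    rng = np.random.default_rng([seed, 7, index % (2**31)])
    return float(np.clip(rng.normal(0.9, 0.03), 0.7, 1.1))


def make_hdx_dataset(
    sequence: str,
    peptides: list[tuple[int, int]],
    preset: SyntheticConditionPreset,
    timepoints: tuple[float, ...] | None = None,
    n_replicates: int = 3,
    noise_sd: float = 0.15,
    seed: int = 0,
    k_int: float = DEFAULT_K_INT,
) -> HDXDataset:
    """Uptake tables for the protein AND bradykinin under one condition.

    Per-peptide observed rate: k_obs = chem_rate_scale * k_int * <1/PF> over
    the exchangeable residues of the span; bradykinin has protection = 1, so
    its curves carry only the chemical-rate confound.  Uptake follows the
    one-phase stretched exponential with additive replicate noise (sd in Da,
    clipped at zero).  The stretching exponent of a peptide depends on the
    seed and peptide index but not on the condition, so protection-null
    condition pairs differ only through chem_rate_scale.
    """
    from .hdx import DEFAULT_TIMEPOINTS

    times = np.asarray(timepoints if timepoints is not None else DEFAULT_TIMEPOINTS, float)
    if np.any(times < 0.05) or np.any(times > 1800.0):
        raise ValueError("timepoints must lie within [0.05, 1800] s")
    n_res = len(sequence)
    profile = preset.protection_profile
    if profile.size < n_res:
        raise ValueError("protection profile shorter than sequence")
    rng = np.random.default_rng([seed, abs(hash(preset.name)) % (2**31)])

    truth: dict = {"condition": preset.name, "peptides": {}}
    rows = []
    for idx, (start, end) in enumerate(peptides):
        if not 1 <= start <= end <= n_res:
            raise ValueError(f"peptide span ({start}, {end}) outside sequence")
        pep_seq = sequence[start - 1 : end]
        n_ex = count_exchangeable(pep_seq)
        if n_ex == 0:
            continue
        exchangeable = [
            start + off
            for off in range(1, len(pep_seq))
            if pep_seq[off] != "P"
        ]
        inv_pf = np.mean([1.0 / profile[r - 1] for r in exchangeable])
        k_obs = preset.chem_rate_scale * k_int * float(inv_pf)
        beta = _peptide_beta(seed, idx)
        clean = stretched_exponential(times, n_ex, k_obs, beta)
        pid = f"pep_{start:03d}_{end:03d}"
        truth["peptides"][pid] = {
            "span": (start, end), "n_exchangeable": n_ex, "k_obs": k_obs, "beta": beta,
        }
        for rep in range(n_replicates):
            noisy = clean + rng.normal(0.0, noise_sd, size=times.size) if noise_sd > 0 else clean
            noisy = np.clip(noisy, 0.0, None)
            for t, d in zip(times, noisy):
                rows.append(
                    {
                        "id": pid, "start_res": start, "end_res": end,
                        "n_exchangeable": n_ex, "time_s": t, "uptake_Da": d,
                        "replicate": rep, "condition": preset.name,
                    }
                )
    protein = pd.DataFrame(rows)

    # bradykinin: protection = 1, fast intrinsic exchange, dense early times
    bk_times = np.asarray(BRADYKININ_TIMEPOINTS, dtype=float)
    bk_n = count_exchangeable(BRADYKININ_SEQUENCE)
    bk_k = preset.chem_rate_scale * BRADYKININ_K_INT
    bk_beta = _peptide_beta(seed, -1)
    bk_clean = stretched_exponential(bk_times, bk_n, bk_k, bk_beta)
    bk_rows = []
    for rep in range(n_replicates):
        noisy = bk_clean + rng.normal(0.0, noise_sd, size=bk_times.size) if noise_sd > 0 else bk_clean
        noisy = np.clip(noisy, 0.0, None)
        for t, d in zip(bk_times, noisy):
            bk_rows.append(
                {
                    "id": "bradykinin", "start_res": 1, "end_res": len(BRADYKININ_SEQUENCE),
                    "n_exchangeable": bk_n, "time_s": t, "uptake_Da": d,
                    "replicate": rep, "condition": preset.name,
                }
            )
    truth["bradykinin"] = {"n_exchangeable": bk_n, "k_obs": bk_k, "beta": bk_beta}
    return HDXDataset(protein=protein, bradykinin=pd.DataFrame(bk_rows), truth=truth)


# --------------------------------------------------------------------------
# Toy trajectory


def make_toy_trajectory(
    preset: SyntheticConditionPreset,
    n_residues: int = 140,
    n_frames: int = 601,
    frame_dt: float = 5.0,
    n_waters: int = 200,
    sequence: str = ASYN_SEQUENCE,
    jitter_sd: float = 0.25,
    seed: int = 0,
    path: str | None = None,
) -> tuple[Trajectory, dict]:
    """Calpha-bead protein + point waters/ions with stochastic hop dynamics.

    The protein scaffold is a static self-avoiding chain with small thermal
    jitter.  Divalent ions bind acidic C-terminal beads and stay bound with
    per-frame probability ``divalent_stickiness`` (long residence);
    monovalent ions hop on and off any bead with their own (lower)
    stickiness.  Each shell water escapes with per-frame probability
    ``water_exchange_rate`` and does not return, so shell-residence runs are
    geometric with exactly that escape rate.  If ``path`` is given the
    trajectory is also written as a multi-model PDB.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if n_residues < 2 or n_residues > len(sequence):
        raise ValueError("n_residues must lie in [2, len(sequence)]")
    spec: IonSpec = preset.ion_spec
    rng = np.random.default_rng(seed)

    scaffold = None
    while scaffold is None:
        scaffold = _sans._grow_chain(n_residues, rng, stiffness=1.0, compaction=0.0)
    scaffold = scaffold - scaffold.mean(axis=0)

    acidic_ct = [r for r in acidic_residues(sequence[:n_residues]) if r >= max(1, n_residues - 44)]
    if not acidic_ct:
        acidic_ct = list(range(max(1, n_residues - 10), n_residues + 1))
    any_sites = list(range(1, n_residues + 1))

    def far_position() -> np.ndarray:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        return scaffold[rng.integers(n_residues)] + direction * rng.uniform(25.0, 45.0)

    def bound_position(site: int) -> np.ndarray:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        return scaffold[site - 1] + direction * 2.5

    ion_defs = []  # (species, stickiness, sites)
    for _ in range(spec.n_divalent):
        sites = acidic_ct if spec.divalent_targets == "acidic_cterm" else any_sites
        ion_defs.append(("CA", spec.divalent_stickiness, sites))
    mono_species = "K" if preset.name == "k" else "NA"
    for _ in range(spec.n_monovalent):
        sites = acidic_ct if spec.monovalent_targets == "acidic_cterm" else any_sites
        ion_defs.append((mono_species, spec.monovalent_stickiness, sites))

    n_ions = len(ion_defs)
    n_particles = n_residues + n_waters + n_ions
    coords = np.empty((n_frames, n_particles, 3))

    # protein
    coords[:, :n_residues, :] = scaffold[None, :, :] + rng.normal(
        0.0, jitter_sd, size=(n_frames, n_residues, 3)
    )

    # waters: start in shell (2.8 A from a random bead), escape irreversibly
    water_slice = slice(n_residues, n_residues + n_waters)
    escape_frame = np.full(n_waters, n_frames, dtype=int)
    if preset.water_exchange_rate > 0:
        geom = rng.geometric(preset.water_exchange_rate, size=n_waters)
        escape_frame = np.minimum(geom, n_frames)
    for w in range(n_waters):
        bead = int(rng.integers(n_residues))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        # 2.4 A from the bead: deep enough inside the 3.5 A shell that
        # thermal jitter cannot fake an escape
        home = scaffold[bead] + direction * 2.4
        out = far_position()
        for f in range(n_frames):
            base = home if f < escape_frame[w] else out
            coords[f, n_residues + w] = base + rng.normal(0.0, 0.05, size=3)

    # ions: two-state Markov chain (bound to a site / free)
    ion_truth = {"CA": [], "NA": [], "K": []}
    for j, (species, stickiness, sites) in enumerate(ion_defs):
        col = n_residues + n_waters + j
        bound = rng.random() < 0.5
        site = int(rng.choice(sites))
        bound_frames = 0
        for f in range(n_frames):
            if bound:
                coords[f, col] = bound_position(site)
                bound_frames += 1
                if rng.random() >= stickiness:
                    bound = False
            else:
                coords[f, col] = far_position()
                if rng.random() < spec.bind_prob:
                    bound = True
                    site = int(rng.choice(sites))
        ion_truth[species].append(bound_frames / n_frames)

    kind = np.array(
        [PROTEIN] * n_residues + [WATER] * n_waters + [d[0] for d in ion_defs], dtype=object
    )
    kind[n_residues + n_waters :] = ION
    species = np.array([""] * (n_residues + n_waters) + [d[0] for d in ion_defs], dtype=object)
    residue = np.array(
        list(range(1, n_residues + 1)) + [-1] * (n_waters + n_ions), dtype=int
    )
    masses = np.array(
        [MEAN_RESIDUE_MASS] * n_residues
        + [WATER_MASS] * n_waters
        + [ION_MASSES[d[0]] for d in ion_defs]
    )
    truth = {
        "water_exchange_rate": preset.water_exchange_rate,
        "expected_divalent_residence_frames": (
            1.0 / (1.0 - spec.divalent_stickiness) if spec.n_divalent else None
        ),
        "expected_monovalent_residence_frames": (
            1.0 / (1.0 - spec.monovalent_stickiness) if spec.n_monovalent else None
        ),
        "acidic_cterm_sites": acidic_ct,
        "bound_fraction": {k: v for k, v in ion_truth.items() if v},
    }
    traj = Trajectory(
        coords=coords, kind=kind.astype(str), species=species.astype(str),
        residue=residue, masses=masses, frame_dt_ps=frame_dt,
        sequence=sequence[:n_residues], ground_truth=truth,
    )
    if path is not None:
        write_pdb(traj, path)
    return traj, truth


# --------------------------------------------------------------------------
# Scattering


def make_scattering(
    pool: _sans.ConformerPool,
    true_subset: list[int],
    weights: list[float] | None = None,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> _sans.ScatteringCurve:
    """Experimental-style curve mixed from a known pool subset.

    I_exp(q) = sum_i w_i I_i(q) plus Gaussian noise with sigma =
    noise_fraction * I; the recorded sigma column uses a small floor when
    noise_fraction is zero so chi^2 stays defined.
    """
    if len(true_subset) == 0:
        raise ValueError("true_subset must be non-empty")
    idx = np.asarray(true_subset, dtype=int)
    if np.any(idx < 0) or np.any(idx >= len(pool)):
        raise ValueError("subset indices outside pool")
    if weights is None:
        w = np.full(idx.size, 1.0 / idx.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != idx.size or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must match subset and sum to 1")
    clean = w @ pool.intensities[idx]
    sigma = np.maximum(noise_fraction, 1e-4) * clean
    rng = np.random.default_rng(seed)
    values = clean + rng.normal(0.0, sigma) if noise_fraction > 0 else clean
    return _sans.ScatteringCurve(q=pool.q.copy(), i=values, sigma=sigma)


# --------------------------------------------------------------------------
# AFM profiles


def _profile_length(preset: PolymorphPreset) -> float:
    if preset.periodic:
        return 8.0 * preset.mean_period
    return 1200.0


def make_afm_profiles(
    mixture: dict[str, float],
    n_fibrils: int = 100,
    dx: float = 2.0,
    pixel_noise: float = 0.1,
    jitter_scale: float = 1.0,
    seed: int = 0,
    presets: dict[str, PolymorphPreset] | None = None,
    condition: str = "",
) -> tuple[list[FibrilProfile], list[str]]:
    """Synthetic centerline profiles drawn from a polymorph mixture.

    Periodic classes are raised cosines whose crest equals the per-fibril
    height draw (modulation depth 1/3 of the crest); p1 rods are flat-topped.
    ``pixel_noise`` is the additive noise SD as a fraction of the class mean
    height; ``jitter_scale`` multiplies the class SDs (0 = exact class
    means).  Returns the profiles and their ground-truth labels.
    """
    presets = presets or POLYMORPH_PRESETS
    labels = list(mixture)
    fractions = np.array([mixture[k] for k in labels], dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("mixture fractions must sum to 1")
    for label in labels:
        if label not in presets:
            raise ValueError(f"unknown polymorph label {label!r}")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_fibrils, fractions)

    profiles: list[FibrilProfile] = []
    truth: list[str] = []
    fid = 0
    for label, count in zip(labels, counts):
        preset = presets[label]
        for _ in range(count):
            h_i = max(preset.mean_height + jitter_scale * preset.sd_height * rng.standard_normal(), 0.5)
            length = _profile_length(preset)
            n = max(int(round(length / dx)), 50)
            s = np.arange(n) * dx
            if preset.periodic:
                p_i = max(
                    preset.mean_period + jitter_scale * preset.sd_period * rng.standard_normal(),
                    4.0 * dx,
                )
                phase = rng.uniform(0.0, 2.0 * np.pi)
                profile = h_i * (1.0 + 0.5 * np.cos(2.0 * np.pi * s / p_i + phase)) / 1.5
            else:
                profile = np.full(n, h_i)
            if pixel_noise > 0:
                profile = profile + rng.normal(0.0, pixel_noise * preset.mean_height, size=n)
            profiles.append(FibrilProfile(s, profile, fibril_id=f"fib_{fid:04d}", condition=condition))
            truth.append(label)
            fid += 1
    return profiles, truth
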