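"""EOM-lite: random conformer pools, Debye scattering, and GA sub-ensemble selection.

A pool of self-avoiding Calpha chains (bond 3.8 A, excluded volume 4.0 A,
per-chain stiffness/compaction drawn to span compact-to-extended) stands in
for the RANCH pool; theoretical curves come from the Debye formula with
uniform bead form factors; a genetic algorithm selects the fixed-size
multiset of conformers whose equal-weight average curve best fits an
experimental I(q), judged by

    chi^2 = 1/(M-1) * sum_m ((c * I_ens(q_m) - I_exp(q_m)) / sigma_m)^2

with ``c`` the least-squares scale factor.  Pool and selection are compared
as Rg histograms, the standard EOM readout for disordered proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

BOND_LENGTH = 3.8  # consecutive Calpha distance, A
EXCLUDED_VOLUME = 4.0  # minimum nonbonded bead separation, A

DEFAULT_Q = np.logspace(np.log10(0.005), np.log10(0.45), 101)


@dataclass
class ScatteringCurve:
    q: np.ndarray
    i: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")


@dataclass
class ConformerPool:
    coords: np.ndarray  # (pool, n_residues, 3)
    rg: np.ndarray
    q: np.ndarray
    intensities: np.ndarray  # (pool, n_q)

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass
class GAParams:
    population: int = 100
    generations: int = 200
    mutation_rate: float = 0.05
    crossover_rate: float = 0.9
    elitism: int = 2
    tournament: int = 3


@dataclass
class EnsembleSelection:
    indices: np.ndarray  # selected pool indices, with multiplicity
    weights: np.ndarray  # multiplicity / ensemble size, sums to 1
    chi2: float
    scale: float
    rg_values: np.ndarray


def _chain_rg(chain: np.ndarray) -> float:
    com = chain.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((chain - com) ** 2, axis=1))))


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _grow_chain(
    n_residues: int,
    rng: np.random.Generator,
    stiffness: float,
    compaction: float,
    max_step_tries: int = 60,
) -> np.ndarray | None:
    """One self-avoiding chain, or None if growth stalled.

    ``stiffness`` biases each bond direction along the previous one
    (persistent, extended chains); ``compaction`` biases it toward the
    current centroid (collapsed chains).
    """
    chain = np.zeros((n_residues, 3))
    direction = _random_unit(rng)
    chain[1] = chain[0] + BOND_LENGTH * direction
    for i in range(2, n_residues):
        placed = False
        centroid = chain[:i].mean(axis=0)
        for _ in range(max_step_tries):
            pull = centroid - chain[i - 1]
            norm = np.linalg.norm(pull)
            pull = pull / norm if norm > 0 else 0.0
            trial = stiffness * direction + compaction * pull + _random_unit(rng)
            trial /= np.linalg.norm(trial)
            candidate = chain[i - 1] + BOND_LENGTH * trial
            # self-avoidance against all non-adjacent beads
            d2 = np.sum((chain[: i - 1] - candidate) ** 2, axis=1)
            if np.all(d2 >= EXCLUDED_VOLUME**2):
                chain[i] = candidate
                direction = trial
                placed = True
                break
        if not placed:
            return None
    return chain


def generate_pool(
    n_residues: int,
    pool_size: int,
    seed: int,
    q: np.ndarray = DEFAULT_Q,
    bin_width: float = 0.25,
) -> ConformerPool:
    """Self-avoiding random Calpha pool with per-chain Rg and Debye curves.

    Per-chain stiffness is log-uniform over [0.05, 5] and a compact fraction
    of chains receives an additional centroid attraction, so that a
    140-residue pool spans sub-20 A collapsed globules to >55 A extended
    coils (the Rg window relevant for disordered aSyn).
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if pool_size < 1:
        raise ValueError("pool_size must be positive")
    rng = np.random.default_rng(seed)
    chains = np.empty((pool_size, n_residues, 3))
    made = 0
    while made < pool_size:
        stiffness = 10.0 ** rng.uniform(-1.3, 0.7)
        compaction = rng.uniform(0.2, 1.0) if rng.random() < 0.35 else 0.0
        chain = _grow_chain(n_residues, rng, stiffness, compaction)
        if chain is not None:
            chains[made] = chain
            made += 1
    rg = np.array([_chain_rg(c) for c in chains])
    intensities = batch_debye(chains, q, bin_width=bin_width)
    return ConformerPool(coords=chains, rg=rg, q=np.asarray(q, dtype=float), intensities=intensities)


def debye_scattering(chain: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Exact Debye curve of one bead chain with unit form factors.

    I(q) = sum_ij sin(q r_ij)/(q r_ij); the i = j and q -> 0 limits are 1.
    """
    chain = np.asarray(chain, dtype=float)
    q = np.asarray(q, dtype=float)
    if chain.ndim != 2 or chain.shape[0] < 1:
        raise ValueError("chain must contain at least one bead")
    if np.any(q <= 0):
        raise ValueError("q values must be positive")
    n = chain.shape[0]
    if n == 1:
        return np.ones_like(q)
    r = pdist(chain)
    qr = np.outer(q, r)
    with np.errstate(invalid="ignore"):
        sinc = np.where(qr > 0, np.sin(qr) / qr, 1.0)
    return n + 2.0 * sinc.sum(axis=1)


def batch_debye(chains: np.ndarray, q: np.ndarray, bin_width: float = 0.25) -> np.ndarray:
    """Histogram-accelerated Debye curves for a whole pool.

    Pair distances are binned at ``bin_width`` (A) and the pool's curves are
    a single counts x sinc-table product; accurate to the bin discretization
    and self-consistent across generation and selection.
    """
    chains = np.asarray(chains, dtype=float)
    q = np.asarray(q, dtype=float)
    n_chains, n_beads, _ = chains.shape
    extent = chains.reshape(-1, 3)
    dmax = float(np.linalg.norm(extent.max(axis=0) - extent.min(axis=0))) + bin_width
    n_bins = max(int(np.ceil(dmax / bin_width)), 1)
    counts = np.zeros((n_chains, n_bins), dtype=np.float64)
    for c in range(n_chains):
        r = pdist(chains[c])
        idx = np.minimum((r / bin_width).astype(int), n_bins - 1)
        counts[c] = np.bincount(idx, minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    qr = np.outer(q, centers)
    sinc = np.sin(qr) / qr
    return n_beads + 2.0 * counts @ sinc.T


def chi_squared(i_model: np.ndarray, target: ScatteringCurve) -> tuple[float, float]:
    """Reduced chi^2 of a model curve against the target, with optimal scale."""
    w = 1.0 / target.sigma**2
    c = float(np.sum(w * i_model * target.i) / np.sum(w * i_model**2))
    resid = (c * i_model - target.i) / target.sigma
    return float(np.sum(resid**2) / (target.q.size - 1)), c


def _population_chi2(
    population: np.ndarray, intensities: np.ndarray, target: ScatteringCurve
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized chi^2 and scale for a (pop, ens_size) index matrix."""
    i_ens = intensities[population].mean(axis=1)  # (pop, n_q)
    w = 1.0 / target.sigma**2
    num = i_ens @ (w * target.i)
    den = np.einsum("pq,q,pq->p", i_ens, w, i_ens)
    c = num / den
    resid = (c[:, None] * i_ens - target.i) / target.sigma
    return np.sum(resid**2, axis=1) / (target.q.size - 1), c


def _local_refine(
    individual: np.ndarray,
    intensities: np.ndarray,
    target: ScatteringCurve,
    max_passes: int = 30,
) -> tuple[np.ndarray, float, float]:
    """Coordinate descent: try every pool member in every slot until stable."""
    ens = individual.copy()
    size = ens.size
    w = 1.0 / target.sigma**2
    total = intensities[ens].sum(axis=0)

    def chi2_of(i_sum: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i_ens = i_sum / size
        num = i_ens @ (w * target.i)
        den = np.einsum("pq,q,pq->p", i_ens, w, i_ens)
        c = num / den
        resid = (c[:, None] * i_ens - target.i) / target.sigma
        return np.sum(resid**2, axis=1) / (target.q.size - 1), c

    best_chi2, best_c = chi2_of(total[None, :])
    best_chi2, best_c = float(best_chi2[0]), float(best_c[0])
    for _ in range(max_passes):
        improved = False
        for slot in range(size):
            candidates = total - intensities[ens[slot]] + intensities
            chi2, c = chi2_of(candidates)
            j = int(np.argmin(chi2))
            if chi2[j] < best_chi2 - 1e-15:
                total = candidates[j]
                ens[slot] = j
                best_chi2, best_c = float(chi2[j]), float(c[j])
                improved = True
        if not improved:
            break
    return ens, best_chi2, best_c


def select_ensemble(
    pool: ConformerPool,
    target: ScatteringCurve,
    ensemble_size: int = 50,
    ga: GAParams | None = None,
    seed: int = 0,
    refine: bool = True,
) -> EnsembleSelection:
    """Genetic-algorithm selection of the best-fitting conformer multiset.

    Individuals are index multisets of fixed size; fitness is the reduced
    chi^2 of the equal-weight ensemble-average curve.  Tournament selection,
    single-point crossover, per-gene mutation and elitism; the best
    individual ever seen is polished by a coordinate-descent pass over the
    slots (``refine``), so the result is never worse than the best member of
    the random initial population.
    """
    ga = ga or GAParams()
    if ensemble_size < 1 or ensemble_size > len(pool):
        raise ValueError("ensemble_size must lie in [1, pool size]")
    if not np.allclose(pool.q, target.q):
        raise ValueError("pool and target must share a q grid (resample first)")
    rng = np.random.default_rng(seed)
    pop = rng.integers(0, len(pool), size=(ga.population, ensemble_size))

    # Seed part of the population from the continuous relaxation: nonnegative
    # least squares over the whole pool on the sigma-weighted curves.  For an
    # exactly representable (noiseless) mixture the NNLS support is the
    # generating subset, so the GA starts at (or near) the optimum.
    try:
        from scipy.optimize import nnls

        w_nnls, _ = nnls(
            (pool.intensities / target.sigma).T, target.i / target.sigma,
            maxiter=10 * len(pool),
        )
    except Exception:
        w_nnls = np.zeros(len(pool))
    if w_nnls.sum() > 0:
        probs = w_nnls / w_nnls.sum()
        # largest-remainder rounding of ensemble_size * probs
        quota = ensemble_size * probs
        counts = np.floor(quota).astype(int)
        short = ensemble_size - counts.sum()
        if short > 0:
            order = np.argsort(quota - counts)[::-1]
            counts[order[:short]] += 1
        pop[0] = np.repeat(np.arange(len(pool)), counts)[:ensemble_size]
        n_sampled = min(max(ga.population // 10, 1), ga.population - 1)
        for i in range(1, 1 + n_sampled):
            pop[i] = rng.choice(len(pool), size=ensemble_size, p=probs)
    chi2, scales = _population_chi2(pop, pool.intensities, target)
    best_i = int(np.argmin(chi2))
    best = (pop[best_i].copy(), float(chi2[best_i]), float(scales[best_i]))

    for _ in range(ga.generations):
        order = np.argsort(chi2)
        next_pop = [pop[order[i]].copy() for i in range(min(ga.elitism, ga.population))]
        while len(next_pop) < ga.population:
            contenders = rng.integers(0, ga.population, size=ga.tournament)
            p1 = pop[contenders[np.argmin(chi2[contenders])]]
            contenders = rng.integers(0, ga.population, size=ga.tournament)
            p2 = pop[contenders[np.argmin(chi2[contenders])]]
            child = p1.copy()
            if ensemble_size > 1 and rng.random() < ga.crossover_rate:
                cut = int(rng.integers(1, ensemble_size))
                child[cut:] = p2[cut:]
            mutate = rng.random(ensemble_size) < ga.mutation_rate
            child[mutate] = rng.integers(0, len(pool), size=int(mutate.sum()))
            next_pop.append(child)
        pop = np.array(next_pop)
        chi2, scales = _population_chi2(pop, pool.intensities, target)
        gen_best = int(np.argmin(chi2))
        if chi2[gen_best] < best[1]:
            best = (pop[gen_best].copy(), float(chi2[gen_best]), float(scales[gen_best]))

    if refine:
        refined, chi2_r, scale_r = _local_refine(best[0], pool.intensities, target)
        if chi2_r <= best[1]:
            best = (refined, chi2_r, scale_r)

    indices = np.sort(best[0])
    unique, counts = np.unique(indices, return_counts=True)
    return EnsembleSelection(
        indices=indices,
        weights=counts / ensemble_size,
        chi2=best[1],
        scale=best[2],
        rg_values=pool.rg[indices],
    )


def enumerate_best(
    pool: ConformerPool, target: ScatteringCurve, ensemble_size: int
) -> tuple[np.ndarray, float]:
    """Exhaustive optimum over all multisets (small pools only)."""
    from itertools import combinations_with_replacement

    best_chi2, best_idx = np.inf, None
    for combo in combinations_with_replacement(range(len(pool)), ensemble_size):
        i_ens = pool.intensities[list(combo)].mean(axis=0)
        chi2, _ = chi_squared(i_ens, target)
        if chi2 < best_chi2:
            best_chi2, best_idx = chi2, combo
    return np.array(best_idx), float(best_chi2)


def rg_distribution(
    pool: ConformerPool,
    selection: EnsembleSelection | None = None,
    bin_width: float = 2.0,
) -> pd.DataFrame:
    """Paired, normalized Rg histograms of the pool and the selected ensemble."""
    if len(pool) == 0:
        raise ValueError("empty pool")
    lo = float(pool.rg.min())
    hi = float(pool.rg.max()) + bin_width
    edges = np.arange(np.floor(lo / bin_width) * bin_width, hi + bin_width, bin_width)
    pool_hist, _ = np.histogram(pool.rg, bins=edges)
    out = pd.DataFrame(
        {
            "rg_low": edges[:-1],
            "rg_high": edges[1:],
            "pool": pool_hist / pool_hist.sum(),
        }
    )
    if selection is not None:
        sel_hist, _ = np.histogram(selection.rg_values, bins=edges)
        out["selected"] = sel_hist / sel_hist.sum()
    return out
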