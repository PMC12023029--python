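# Methods

This note documents the models implemented in `ionsyn`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices that affect results.

## Aggregation kinetics (ThT)

Traces are normalized so the well with the highest raw fluorescence on a
plate maps to 100%. Each normalized trace is fitted by nonlinear least
squares (lmfit/Levenberg–Marquardt) with the Boltzmann sigmoid

    F(t) = F_max / (1 + exp(−k (t − t50))),

the standard empirical description of nucleation-limited amyloid growth:
`F_max` is the plateau, `t50` the midpoint (F = F_max/2 by construction),
`k` (h⁻¹) the exponential-phase slope. The lag time is derived, not fitted:
`t_lag = t50 − 2/k`, the intersection of the steepest tangent with the
baseline. Initialization uses the half-range crossing for `t50`, four times
the maximum finite-difference slope over the range for `k`, and the trace
maximum for `F_max`; this is robust for any sigmoidal trace. A fit is
reported `converged` only if the optimizer succeeded, the dynamic range
exceeds 5 (percent-of-plate units, so flat non-aggregating wells are
excluded rather than mis-fit) and the mean of the final 10% of points
reaches 90% of the fitted plateau — plateaus are never extrapolated.
Condition summaries report mean ± SD over converged fits and one-way ANOVA
(scipy `f_oneway`) per parameter.

## Chemical-shift perturbations

For residues assigned in both states,

    Δδ = sqrt(ΔδH² + (α ΔδN)²),

with the field-standard amide nitrogen weight α = 0.14 (configurable, with
an optional 1/√2 prefactor, so alternative weightings can be substituted
exactly). Perturbed residues are flagged above mean + 1 SD, where mean and
SD are computed after iteratively removing values above 3 SD — large
binding-site shifts therefore do not inflate their own threshold. A fixed
cutoff rule is available. Matching is by residue index; assignment transfer
is upstream of this package.

## HDX kinetics and the bradykinin normalization

Uptake of a peptide or ETD fragment is modelled as the one-phase stretched
exponential

    D(t) = N (1 − exp(−(k_obs t)^β)),

the unique two-parameter one-phase form in (k_obs, β); β ∈ (0, 1.5] absorbs
within-peptide rate heterogeneity. `N` is fixed to the theoretical number of
exchangeable amides by default (first residue and prolines excluded); a
free-N mode exists because instrument-calibrated plateaus sometimes fall
short of theory. Back-exchange is corrected multiplicatively,
`D ← D/(1 − be)`.

Chemical exchange depends on the buffer (ionic strength), not only on
structure. The fully unstructured peptide bradykinin (RPPGFSPFR, 5
exchangeable amides) is measured under every condition; its fitted
(k_obs, β) define per-condition multiplicative factors
`s_k = k_ref/k_cond`, `s_β = β_ref/β_cond` mapping each condition onto the
reference. The correction is applied to protein curves **additively through
the fitted model** — `D′(t) = D(t) + [model(scaled) − model(fitted)]` — so
that replicate scatter survives normalization and downstream significance
testing sees the true measurement variance. (Regenerating curves purely from
scaled parameters would smooth away replicate noise and inflate Welch
t-statistics; this choice keeps the type-I error of the protection-null test
below 5%.)

Residue consolidation combines overlapping peptides and fragments: each span
contributes its mean per-residue uptake weighted by 1/length, so short
(near-residue-resolution) ETD fragments dominate where available. A
strict-subtraction scheme was considered and rejected as unstable for noisy
short fragments.

Differential maps use the hybrid criterion: a residue × time cell is
significant iff Welch's t-test gives p < α (default 0.05) AND |ΔD| exceeds
the global threshold t_crit(α, pooled df) × pooled SEM computed over all
covered cells. Sign convention: ΔD = state2 − state1, positive = more uptake
(deprotection) in state2; the convention string is carried in the output.

## Trajectory metrics

Coordinates are Å, times ps, residue indexing 1-based inclusive. Region
scheme: N-terminus 1–60, NAC 61–95, C-terminus 96–140, with early/late
splits (1–30/31–60, 61–78/79–95, 96–118/119–140).

* **Ion proximity frequency** — fraction of frames with ≥ 1 ion of the
  species within the contact cutoff of any atom of the residue. Cutoff
  3.5 Å (first-shell convention; configurable). Residence is the mean
  length of maximal consecutive-frame contact runs × frame interval, gap
  tolerance zero.
* **Water persistence** — maximal consecutive-frame runs within 3.5 Å of
  any protein heavy atom; a run of k frames spans (k−1)·dt ps. For a
  memoryless escape process run lengths are geometric, and the per-frame
  escape rate is recovered as 1/mean(run frames).
* **Region COM distances** — mass-weighted centers of mass, all protein
  atoms by default (Cα-only behind the same selection machinery).
* **Radius of gyration** — mass-weighted RMS distance from the COM.
* **Globularity** — the 3×3 covariance of atomic positional fluctuations
  about the mean structure (after optional Kabsch superposition, two
  refinement passes) is diagonalized per six-residue sliding window and for
  the full chain. Reported globularity is λ_min/λ_max ∈ (0, 1] so that
  *lower = less globular*; the raw λ_max/λ_min is emitted alongside, since
  both orientations of the ratio appear in the literature. Rigid windows
  (singular covariance) are flagged invalid rather than guessed.

Contact searches use a cKDTree; an all-pairs brute-force oracle in the test
suite confirms exact agreement on small systems.

## EOM-lite scattering ensembles

The conformer pool is built from self-avoiding Cα chains: bond length
3.8 Å (exact), excluded volume 4.0 Å between non-adjacent beads. Per-chain
stiffness is log-uniform on [0.05, 5] (direction persistence) and ~35% of
chains receive a centroid attraction (compaction 0.2–1.0), so a 140-residue
pool spans collapsed globules (R_g < 20 Å) through extended coils
(> 55 Å) — covering the R_g window relevant for disordered aSyn. Theoretical
curves use the Debye formula with uniform bead form factors (no hydration
layer — this is a deliberately simplified EOM, not a reimplementation of
ATSAS); pool curves are computed via pair-distance histograms (bin 0.25 Å),
which agree with the exact pair sum to well under the noise level and are
self-consistent between generation and selection. Default q grid:
0.005–0.45 Å⁻¹, 101 log-spaced points.

Selection minimizes the reduced χ² of the equal-weight ensemble average
with an analytic least-squares scale factor. The optimizer is a genetic
algorithm over fixed-size index multisets (population 100, generations 200,
single-point crossover 0.9, per-gene mutation 0.05, tournament 3, elitism
2 — all configurable), seeded in part from the nonnegative-least-squares
relaxation over the whole pool (for an exactly representable mixture the
NNLS support *is* the generating subset) and polished by coordinate descent
over slots. The best individual ever seen is returned, so the result is
never worse than the best random start; on pools small enough to enumerate,
the optimum is reached exactly. Multiplicity (repeated conformers) is
allowed, matching GAJOE behaviour.

## AFM morphometry

Inputs are baseline-subtracted centerline height profiles h(s) on a uniform
arclength grid (tracing from raw images is out of scope). Periodicity is the
lag of the first peak ≥ 0.3 (configurable) of the normalized autocorrelation
of the linearly detrended profile, parabolic-refined; lags below 10 nm are
excluded (they sit inside the smeared zero-lag noise spike, and fibril twist
periods are far larger). Height is the median of crest heights of a
median-filtered profile, with crests found one-per-period when a period is
known and the filter width scaled to the period; for nonperiodic rods every
plateau point is a crest and the estimate reduces to the profile median,
making it robust to single-pixel tip artifacts. Whether published heights
are peak or mean crest heights is ambiguous; median-of-crests was adopted
and documented.

Classification: nonperiodic → p1; otherwise the nearest periodic class by
the SD-standardized distance in (h, p), with measurements beyond 3
standardized units left unclassified. The class table ships with the
measured polymorph parameters — p1 (7.5 ± 1.7 nm, nonperiodic),
p2a (8.6 ± 1.4, 422 ± 18), p2b (13.8 ± 1.4, 413 ± 33),
p3a (8.7 ± 0.7, 96 ± 15), p3b (13.5 ± 0.5, 111 ± 5) — and is
user-replaceable.

## Synthetic-data generators

Each generator is a pure function of (arguments, seed); identical calls are
byte-identical, and noiseless outputs satisfy the corresponding analysis
model exactly. The condition presets encode the study's qualitative
structure as ground truth: Ca²⁺ aggregates fastest and no-salt slowest
(t50 24 h vs 100 h, Na/K halving the no-salt lag); HDX deprotection after
normalization ranks Na > Na+Ca > Ca > no salt, concentrated at NAC residues
60–90 and C-terminal 120–135; divalent ions bind acidic C-terminal sites
with 0.98/frame stay probability (mean residence 50 frames) while
monovalent ions hop transiently; shell-water escape probabilities per 5 ps
frame are 0.02 (Ca) to 0.05 (no salt). Ion counts mirror the simulated
systems: 34 Ca²⁺ in the CaCl₂-containing boxes, 150 monovalent ions for
150 mM NaCl/KCl, 10 Na⁺ for the minimally neutralized box.

Deliberate simplifications:

* Intrinsic HDX rates are a per-residue constant (0.1 s⁻¹ protein,
  1 s⁻¹ bradykinin), not sequence-dependent reference tables — the
  normalization logic only requires a multiplicative condition confound.
  Bradykinin is sampled on a dense 0.05–30 s schedule so both k_obs and β
  are well constrained; replicate noise (default 0.15 Da, free parameter)
  is additive Gaussian clipped at zero.
* The toy trajectory is a static jittered Cα scaffold with point waters and
  ions following two-state Markov rules, not physical dynamics: shell
  waters sit 2.4 Å from a bead (safely inside the 3.5 Å cutoff against
  thermal jitter) and escape irreversibly with the preset per-frame
  probability, making residence runs exactly geometric. Metrics recover
  prescribed statistics; nothing here tests force fields, solvent
  thermodynamics or conformational exchange.
* AFM profiles are raised cosines (crest = the per-fibril height draw,
  modulation depth 1/3) or flat tops for p1, plus additive pixel noise
  (default 10% of the class mean height); real fibril curvature, crossings
  and tip convolution are not modelled.

Passing tests therefore demonstrate that the estimators are correct and
unbiased under the stated statistical structure — not that they are robust
to every artifact of real instrument data.

## Problem sizes and determinism

The demo and verification runs use reduced sizes chosen to keep the full
pipeline at a few minutes on one core: 4–6 wells × 250 hourly timepoints per
condition; 14 tiling peptides × 7 labeling times × 3 replicates; 140-residue
/ 301–601-frame / 150–200-water toy trajectories; pools of 300–10,000
conformers; 100–200 fibrils per condition. Every stochastic stage derives
its stream from an explicit seed (stage-hashed from the run seed), outputs
carry the config hash, seed and package version, and repeated runs are
byte-identical.

## Known limitations

* The empirical sigmoid has no mechanistic content (no nucleation-elongation
  rate constants); that is by design.
* The hybrid-significance "data flattening" refinement used by some HDX
  packages is not implemented; the mask is the two-criterion rule only.
* Residue consolidation resolution is bounded by peptide length: a
  deprotected residue inside an otherwise unaffected span smears across the
  span (visible as boundary false positives in the power tests).
* The mean + 1 SD CSP flag marks the upper tail of whatever distribution
  remains after trimming; with continuous measurement noise at every
  residue it will always flag a percentage of unperturbed residues — a
  fixed cutoff is provided for that regime.
* EOM-lite ensembles, like EOM itself, are not unique: distinct multisets
  can fit one curve equally well; only R_g distributions should be
  interpreted.
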