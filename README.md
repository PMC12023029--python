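# ionsyn

**How the ionic milieu shapes α-synuclein aggregation — a desk-scale analysis
pipeline.**

α-Synuclein (aSyn) is a 140-residue intrinsically disordered protein whose
amyloid aggregation underlies Parkinson's disease. Physiological ions —
Ca²⁺, Na⁺, K⁺ — change the monomer's conformational ensemble, its hydration
shell, its aggregation kinetics, and ultimately which fibril polymorph grows.
`ionsyn` implements the complete computational analysis chain used to
quantify these effects, together with synthetic-data generators that emulate
every input with known ground truth, so each stage is verifiable end to end
on a laptop.

## What it computes

| Stage | Model / statistic |
|---|---|
| `kinetics` | ThT traces normalized to the plate maximum and fitted with the Boltzmann sigmoid `F(t) = F_max / (1 + e^{−k(t−t50)})`; lag time `t_lag = t50 − 2/k`; one-way ANOVA across conditions |
| `csp` | Weighted amide chemical-shift perturbations `Δδ = √(ΔδH² + (α·ΔδN)²)`, α = 0.14, with iterative mean + SD outlier flagging |
| `hdx` | One-phase stretched-exponential uptake `D(t) = N(1 − e^{−(k_obs·t)^β})`; condition-dependent chemical-exchange rates removed via the 2-D (k_obs, β) bradykinin scaling; peptide/ETD-fragment consolidation to residues (inverse-span-length weights); differential maps masked by Welch's t-test AND a global pooled-SEM threshold |
| `md_metrics` | Ion proximity frequency and residence times, hydration-shell water persistence, inter-region center-of-mass distances (N-term 1–60, NAC 61–95, C-term 96–140), radius of gyration, windowed globularity `λ_min/λ_max` |
| `sans` | EOM-lite: 10,000 self-avoiding Cα chains, Debye scattering, genetic-algorithm selection of the 50-member sub-ensemble minimizing reduced χ², pool-vs-selected R_g distributions |
| `afm` | Fibril height and twist periodicity from centerline profiles (autocorrelation), classification into the polymorph classes p1 (7.5 ± 1.7 nm, nonperiodic), p2a/p2b (~420 nm period), p3a/p3b (~100 nm period), and per-condition abundances |
| `synthetic_data` | Generators for all of the above with ground truth returned |

## Worked example

```python
from ionsyn.presets import CONDITION_PRESETS, CONDITION_AFM_MIXTURES
from ionsyn.synthetic_data import make_tht_trace, make_afm_profiles
from ionsyn.kinetics import fit_sigmoid
from ionsyn.afm import measure_fibril, population_summary

trace, truth = make_tht_trace(CONDITION_PRESETS["ca"], noise_sd=1.0, seed=42)
fit = fit_sigmoid(trace)
print(f"condition={trace.condition}  t_lag={fit.t_lag:.1f} h  "
      f"t50={fit.t50:.1f} h  k={fit.k:.3f} /h")

profiles, _ = make_afm_profiles(CONDITION_AFM_MIXTURES["ca"],
                                n_fibrils=200, seed=42, condition="ca")
print(population_summary([measure_fibril(p) for p in profiles]).to_string(index=False))
```

prints

```
condition=ca  t_lag=16.0 h  t50=24.0 h  k=0.252 /h
condition        label  count  abundance
       ca          p3a    138   0.696970
       ca           p1     47   0.237374
       ca          p3b     13   0.065657
       ca unclassified      2        NaN
```

The fitted lag (16 h) and midpoint (24 h) match the Ca²⁺ preset's generating
parameters, and the classified fibril population is dominated by the
short-period twisted polymorph p3a, as expected for a calcium-grown sample.

The same stages are scriptable from the shell:

```bash
ionsyn demo --seed 1 --out-dir demo_out     # full pipeline + ordering report
ionsyn synth afm --condition ca --out profiles.csv
ionsyn afm --profiles profiles.csv
```

`ionsyn demo` runs every stage on synthetic data for all five conditions
(no salt, Ca²⁺, Na⁺, Na⁺+Ca²⁺, K⁺) and asserts the built-in orderings:
no-salt aggregates slowest and Ca²⁺ fastest; post-normalization HDX
deprotection ranks Na > Na+Ca > Ca > no salt; water persists longer around
the protein in Ca²⁺ than Na⁺; Ca²⁺ fibril populations are dominated by
short-period polymorphs.

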