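"""Condition and polymorph presets: the ground truth behind every generator.

The five ionic conditions (no salt, Ca2+, Na+, Na+ + Ca2+, K+) encode the
study's qualitative findings as quantitative generator parameters:

* aggregation kinetics — all ions accelerate aggregation, Ca2+ most strongly,
  Na+/K+ roughly halving the lag and midpoint times of the salt-free buffer;
* HDX — conditions differ both in intrinsic (chemical) exchange rate, which
  the bradykinin normalization must remove, and in conformational protection
  (deprotection ordering Na > Na+Ca > Ca > no salt at the NAC and C-terminus);
* hydration/ions — divalent cations bind acidic C-terminal sites with long
  residence, monovalent cations make transient contacts, and shell-water
  escape is slowest in the Ca2+ condition;
* fibril populations — Ca2+-containing conditions are dominated by the
  short-period twisted polymorphs (p3a/p3b), salt-free and Na+/K+ conditions
  by the long-period p2 pair plus nonperiodic p1 rods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .sequences import ASYN_SEQUENCE

CONDITION_NAMES = ("no_salt", "ca", "na", "na_ca", "k")


@dataclass(frozen=True)
class KineticsParams:
    """Empirical sigmoid parameters of one aggregation condition (hours)."""

    t50: float
    k: float  # 1/h, slope of the exponential phase
    f_max: float = 100.0  # percent of plate maximum

    def __post_init__(self) -> None:
        if self.t50 <= 0 or self.k <= 0 or self.f_max <= 0:
            raise ValueError("t50, k and f_max must be positive")

    @property
    def t_lag(self) -> float:
        return self.t50 - 2.0 / self.k


@dataclass(frozen=True)
class IonSpec:
    """Toy-trajectory ion content and binding behaviour.

    Stickiness is the per-frame probability that a bound ion stays bound;
    mean bound residence is therefore 1/(1 - stickiness) frames.
    """

    n_divalent: int = 0
    n_monovalent: int = 0
    divalent_stickiness: float = 0.0
    monovalent_stickiness: float = 0.0
    divalent_targets: str = "acidic_cterm"  # or "any"
    monovalent_targets: str = "any"
    bind_prob: float = 0.1

    def __post_init__(self) -> None:
        for s in (self.divalent_stickiness, self.monovalent_stickiness):
            if not 0.0 <= s < 1.0:
                raise ValueError("stickiness must lie in [0, 1)")
        if not 0.0 <= self.bind_prob <= 1.0:
            raise ValueError("bind_prob must lie in [0, 1]")
        for t in (self.divalent_targets, self.monovalent_targets):
            if t not in ("acidic_cterm", "any"):
                raise ValueError(f"unknown target selector {t!r}")


@dataclass(frozen=True)
class SyntheticConditionPreset:
    name: str
    chem_rate_scale: float
    protection_profile: np.ndarray = field(repr=False)
    ion_spec: IonSpec
    water_exchange_rate: float  # per-frame shell escape probability
    kinetics_params: KineticsParams

    def __post_init__(self) -> None:
        if self.chem_rate_scale <= 0:
            raise ValueError("chem_rate_scale must be positive")
        profile = np.asarray(self.protection_profile, dtype=float)
        if profile.ndim != 1 or profile.size == 0:
            raise ValueError("protection_profile must be a 1-D array")
        if np.any(profile < 1.0):
            raise ValueError("protection factors must be >= 1")
        if not 0.0 <= self.water_exchange_rate <= 1.0:
            raise ValueError("water_exchange_rate must lie in [0, 1]")
        if self.kinetics_params.t_lag >= self.kinetics_params.t50:
            raise ValueError("t_lag must be smaller than t50")
        object.__setattr__(self, "protection_profile", profile)


def default_protection_profile(condition: str, n_residues: int = 140) -> np.ndarray:
    """Per-residue protection factors (>= 1) for one condition.

    The salt-free baseline protects the NAC core most strongly and the
    C-terminal tail least; ionic conditions deprotect the NAC (61-95,
    strongest at 60-90) and the late C-terminus (120-135) by a
    condition-dependent factor encoding the deprotection ordering
    Na > Na+Ca > Ca > no salt.
    """
    base = np.ones(n_residues)
    base[:60] = 8.0          # N-terminal lipid-binding repeats
    base[60:95] = 40.0       # NAC hydrophobic core
    base[95:] = 3.0          # acidic C-terminal tail
    deprotect = {"no_salt": 1.0, "ca": 2.0, "na_ca": 3.0, "na": 4.0, "k": 2.5}
    factor = deprotect.get(condition)
    if factor is None:
        raise ValueError(f"unknown condition {condition!r}")
    profile = base.copy()
    affected = np.zeros(n_residues, dtype=bool)
    affected[59:90] = True           # residues 60-90
    affected[119:135] = True         # residues 120-135
    profile[affected] = np.maximum(base[affected] / factor, 1.0)
    return profile


def _make_condition_presets() -> dict[str, SyntheticConditionPreset]:
    # Ion counts follow the simulated systems: 34 Ca2+ in the CaCl2-containing
    # boxes, 150 mM NaCl / KCl emulated as 150 monovalent ions, and a
    # minimally neutralized salt-free box (10 Na+).
    ion_specs = {
        "no_salt": IonSpec(n_monovalent=10, monovalent_stickiness=0.5),
        "ca": IonSpec(n_divalent=34, divalent_stickiness=0.98),
        "na": IonSpec(n_monovalent=150, monovalent_stickiness=0.5),
        "na_ca": IonSpec(n_divalent=34, n_monovalent=150,
                         divalent_stickiness=0.98, monovalent_stickiness=0.5),
        "k": IonSpec(n_monovalent=150, monovalent_stickiness=0.5),
    }
    kinetics = {
        "no_salt": KineticsParams(t50=100.0, k=2.0 / 30.0),  # t_lag 70 h
        "ca": KineticsParams(t50=24.0, k=0.25),              # t_lag 16 h
        "na": KineticsParams(t50=50.0, k=0.10),              # t_lag 30 h
        "na_ca": KineticsParams(t50=48.0, k=2.0 / 19.0),     # t_lag 29 h
        "k": KineticsParams(t50=52.0, k=2.0 / 21.0),         # t_lag 31 h
    }
    chem_scale = {"no_salt": 1.0, "ca": 1.15, "na": 1.5, "na_ca": 1.6, "k": 1.45}
    water_escape = {"no_salt": 0.05, "ca": 0.02, "na": 0.04, "na_ca": 0.03, "k": 0.045}
    presets = {}
    for name in CONDITION_NAMES:
        presets[name] = SyntheticConditionPreset(
            name=name,
            chem_rate_scale=chem_scale[name],
            protection_profile=default_protection_profile(name, len(ASYN_SEQUENCE)),
            ion_spec=ion_specs[name],
            water_exchange_rate=water_escape[name],
            kinetics_params=kinetics[name],
        )
    return presets


CONDITION_PRESETS: dict[str, SyntheticConditionPreset] = _make_condition_presets()


@dataclass(frozen=True)
class PolymorphPreset:
    """One AFM fibril polymorph class: height and twist periodicity (nm)."""

    label: str
    mean_height: float
    sd_height: float
    mean_period: float | None  # None = nonperiodic rods
    sd_period: float | None

    def __post_init__(self) -> None:
        if self.mean_height <= 0 or self.sd_height < 0:
            raise ValueError("heights must be positive")
        if self.mean_period is not None and (self.sd_period is None or self.sd_period <= 0):
            raise ValueError("periodic classes need sd_period > 0")

    @property
    def periodic(self) -> bool:
        return self.mean_period is not None


POLYMORPH_PRESETS: dict[str, PolymorphPreset] = {
    "p1": PolymorphPreset("p1", 7.5, 1.7, None, None),
    "p2a": PolymorphPreset("p2a", 8.6, 1.4, 422.0, 18.0),
    "p2b": PolymorphPreset("p2b", 13.8, 1.4, 413.0, 33.0),
    "p3a": PolymorphPreset("p3a", 8.7, 0.7, 96.0, 15.0),
    "p3b": PolymorphPreset("p3b", 13.5, 0.5, 111.0, 5.0),
}

# Per-condition fibril population mixtures. The Ca2+ condition is dominated
# by p3a at 75% relative abundance; Na+Ca carries ~70% p3a+p3b vs ~30% p1;
# salt-free and monovalent-only conditions favour the p2 pair.
CONDITION_AFM_MIXTURES: dict[str, dict[str, float]] = {
    "no_salt": {"p1": 0.30, "p2a": 0.45, "p2b": 0.25},
    "ca": {"p1": 0.20, "p3a": 0.75, "p3b": 0.05},
    "na": {"p1": 0.25, "p2a": 0.30, "p2b": 0.20, "p3a": 0.25},
    "na_ca": {"p1": 0.30, "p3a": 0.50, "p3b": 0.20},
    "k": {"p1": 0.30, "p2a": 0.45, "p2b": 0.25},
}


def null_condition_presets() -> dict[str, SyntheticConditionPreset]:
    """All five condition names sharing one parameter set (for null checks)."""
    ref = CONDITION_PRESETS["no_salt"]
    return {name: replace(ref, name=name) for name in CONDITION_NAMES}
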