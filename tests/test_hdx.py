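"""HDX uptake fitting, bradykinin normalization, consolidation and mapping."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from ionsyn.hdx import (
    ScalingFactors,
    apply_scaling,
    consolidate_residues,
    correct_back_exchange,
    count_exchangeable,
    derive_scaling,
    differential_map,
    fit_uptake,
    normalize_condition,
    residue_uptake_matrix,
    stretched_exponential,
)
from ionsyn.presets import CONDITION_PRESETS
from ionsyn.sequences import ASYN_SEQUENCE
from ionsyn.synthetic_data import default_peptides, make_hdx_dataset


@pytest.mark.parametrize(
    "sequence,expected",
    [
        ("RPPGFSPFR", 5),  # bradykinin: 8 non-first residues minus 3 prolines
        ("AAAA", 3),
        ("P", 0),
        ("AP", 0),
        (ASYN_SEQUENCE, 139 - ASYN_SEQUENCE[1:].count("P")),
    ],
)
def test_count_exchangeable(sequence, expected):
    assert count_exchangeable(sequence) == expected


def test_count_exchangeable_rejects_bad_letters():
    with pytest.raises(ValueError):
        count_exchangeable("AXA")


class TestFitUptake:
    times = np.array([0.05, 0.2, 1.0, 5.0, 30.0, 180.0, 900.0])

    def test_noiseless_parameter_recovery(self):
        d = stretched_exponential(self.times, 5.0, 1.0, 0.8)
        fit = fit_uptake(self.times, d, 5.0)
        assert fit.converged
        assert fit.k_obs == pytest.approx(1.0, rel=1e-4)
        assert fit.beta == pytest.approx(0.8, rel=1e-4)

    def test_single_exponential_limit(self):
        d = stretched_exponential(self.times, 5.0, 0.5, 1.0)
        fit = fit_uptake(self.times, d, 5.0)
        assert abs(fit.beta - 1.0) < 0.02

    def test_all_zero_uptake_unconverged(self):
        fit = fit_uptake(self.times, np.zeros_like(self.times), 5.0)
        assert not fit.converged and np.isnan(fit.k_obs)

    def test_too_few_times_rejected(self):
        with pytest.raises(ValueError):
            fit_uptake(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]), 5.0)

    def test_free_n_mode_recovers_plateau(self):
        d = stretched_exponential(self.times, 4.2, 1.0, 0.9)
        fit = fit_uptake(self.times, d, 5.0, fix_n=False)
        assert fit.n == pytest.approx(4.2, rel=1e-3)

    def test_grid_search_oracle_matches_solver_rss(self):
        """Dense (k_obs, beta) grid agrees with the bounded solver within 1%."""
        rng = np.random.default_rng(8)
        d = stretched_exponential(self.times, 5.0, 0.7, 0.85) + 0.1 * rng.standard_normal(7)
        fit = fit_uptake(self.times, d, 5.0)
        best = np.inf
        for k, b in itertools.product(np.geomspace(0.05, 5, 120), np.linspace(0.5, 1.2, 90)):
            rss = float(np.sum((stretched_exponential(self.times, 5.0, k, b) - d) ** 2))
            best = min(best, rss)
        assert fit.rss <= best * 1.01


class TestBackExchange:
    def test_zero_fraction_is_identity(self):
        u = np.array([1.0, 2.0])
        np.testing.assert_allclose(correct_back_exchange(u, 0.0), u)

    def test_arithmetic(self):
        assert correct_back_exchange(np.array([2.0]), 0.2)[0] == pytest.approx(2.5)

    def test_round_trip(self):
        u = np.array([0.5, 1.5, 3.0])
        back = correct_back_exchange(u, 0.3) * (1 - 0.3)
        np.testing.assert_allclose(back, u)

    def test_full_back_exchange_rejected(self):
        with pytest.raises(ValueError):
            correct_back_exchange(np.array([1.0]), 1.0)


class TestScaling:
    def _fit(self, k, b):
        t = np.geomspace(0.05, 900, 9)
        return fit_uptake(t, stretched_exponential(t, 5.0, k, b), 5.0)

    def test_identical_fits_give_identity(self):
        f = self._fit(1.0, 0.9)
        s = derive_scaling(f, f)
        assert s.s_k == pytest.approx(1.0) and s.s_beta == pytest.approx(1.0)

    def test_doubled_rate_gives_half_factor(self):
        s = derive_scaling(self._fit(2.0, 0.9), self._fit(1.0, 0.9))
        assert s.s_k == pytest.approx(0.5, rel=1e-3)

    def test_apply_then_inverse_restores_fit(self):
        f = self._fit(1.5, 0.8)
        s = ScalingFactors(0.4, 1.1)
        inv = ScalingFactors(1 / 0.4, 1 / 1.1)
        back = apply_scaling(apply_scaling(f, s), inv)
        assert back.k_obs == pytest.approx(f.k_obs) and back.beta == pytest.approx(f.beta)

    def test_unconverged_input_rejected(self):
        from ionsyn.hdx import HDXFit

        with pytest.raises(ValueError):
            derive_scaling(HDXFit(converged=False), self._fit(1.0, 0.9))

    def test_chem_rate_confound_removed_end_to_end(self):
        """Scaling by bradykinin factors reproduces reference uptake curves."""
        base = CONDITION_PRESETS["no_salt"]
        flat = np.ones(140)
        ref = replace(base, name="ref", protection_profile=flat, chem_rate_scale=1.0)
        alt = replace(base, name="alt", protection_profile=flat, chem_rate_scale=2.0)
        ds_ref = make_hdx_dataset(ASYN_SEQUENCE, [(1, 10)], ref, noise_sd=0.0, seed=4, n_replicates=1)
        ds_alt = make_hdx_dataset(ASYN_SEQUENCE, [(1, 10)], alt, noise_sd=0.0, seed=4, n_replicates=1)

        def bk_fit(ds):
            bk = ds.bradykinin
            return fit_uptake(bk["time_s"].to_numpy(), bk["uptake_Da"].to_numpy(), 5.0)

        factors = derive_scaling(bk_fit(ds_alt), bk_fit(ds_ref))
        corrected = normalize_condition(ds_alt.protein, factors)
        np.testing.assert_allclose(
            corrected["uptake_Da"].to_numpy(),
            ds_ref.protein["uptake_Da"].to_numpy(),
            atol=0.05,
        )


class TestConsolidation:
    def test_uniform_partition_of_single_peptide(self):
        out = consolidate_residues([(1, 10)], [5.0], 10)
        np.testing.assert_allclose(out, 0.5)

    def test_short_fragment_dominates_weighting(self):
        """Peptide (1-10, 5 Da) + fragment (1-2, 2 Da): residues 1-2 near 1 Da."""
        out = consolidate_residues([(1, 10), (1, 2)], [5.0, 2.0], 10)
        expected12 = (0.1 * 0.5 + 0.5 * 1.0) / 0.6
        assert out[0] == pytest.approx(expected12)
        assert out[1] == pytest.approx(expected12)
        assert out[5] == pytest.approx(0.5)

    def test_disjoint_spans_leave_gap_unassigned(self):
        out = consolidate_residues([(1, 3), (8, 10)], [1.5, 3.0], 10)
        assert np.isnan(out[4])
        np.testing.assert_allclose(out[:3], 0.5)
        np.testing.assert_allclose(out[7:], 1.0)

    def test_no_coverage_rejected(self):
        with pytest.raises(ValueError):
            consolidate_residues([], [], 10)

    def test_span_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            consolidate_residues([(5, 12)], [1.0], 10)


class TestDifferentialMap:
    def _matrix(self, preset, seed, peptides=None):
        ds = make_hdx_dataset(
            ASYN_SEQUENCE, peptides or default_peptides(), preset, noise_sd=0.15, seed=seed
        )
        return residue_uptake_matrix(ds.protein, 140)

    def test_identical_states_give_empty_mask(self):
        preset = CONDITION_PRESETS["no_salt"]
        a, times, _ = self._matrix(preset, seed=1)
        b, _, _ = self._matrix(preset, seed=2)
        dm = differential_map(a, b, times)
        assert dm.mask.mean() < 0.05

    def test_injected_deprotection_recovered_with_positive_sign(self):
        """Protection halved at residues 60-90 -> positive delta, recall >= 0.8."""
        base = CONDITION_PRESETS["no_salt"]
        prof_a = np.full(140, 20.0)
        prof_b = prof_a.copy()
        prof_b[59:90] = 10.0
        a, times, _ = self._matrix(replace(base, name="A", protection_profile=prof_a), seed=5)
        b, _, _ = self._matrix(replace(base, name="B", protection_profile=prof_b), seed=6)
        dm = differential_map(a, b, times)
        affected = np.zeros(140, bool)
        affected[59:90] = True
        recall = dm.mask.any(axis=1)[affected].mean()
        assert recall >= 0.8
        assert np.nanmean(dm.delta[affected]) > 0

    def test_too_few_replicates_rejected(self):
        a = np.zeros((10, 3, 1))
        with pytest.raises(ValueError):
            differential_map(a, a, np.arange(3))

    def test_type_i_control_after_normalization(self):
        """Protection-null condition pairs: < 5% significant cells post-scaling."""
        base = CONDITION_PRESETS["no_salt"]
        flat = np.ones(140)
        rates = []
        for seed, scale in ((11, 2.0), (23, 1.5), (47, 3.0)):
            a = replace(base, name="condA", protection_profile=flat, chem_rate_scale=1.0)
            b = replace(base, name="condB", protection_profile=flat, chem_rate_scale=scale)
            ds_a = make_hdx_dataset(ASYN_SEQUENCE, default_peptides(), a, noise_sd=0.15, seed=seed)
            ds_b = make_hdx_dataset(ASYN_SEQUENCE, default_peptides(), b, noise_sd=0.15, seed=seed)

            def bk_fit(ds):
                bk = ds.bradykinin
                return fit_uptake(bk["time_s"].to_numpy(), bk["uptake_Da"].to_numpy(), 5.0)

            factors = derive_scaling(bk_fit(ds_b), bk_fit(ds_a))
            corrected = normalize_condition(ds_b.protein, factors)
            ma, times, _ = residue_uptake_matrix(ds_a.protein, 140)
            mb, _, _ = residue_uptake_matrix(corrected, 140)
            rates.append(differential_map(ma, mb, times).mask.mean())
        assert np.mean(rates) < 0.05

    def test_power_against_protection_ratio_two(self):
        """PF ratio 2 at 30% of residues, 3 replicates: > 70% detected."""
        base = CONDITION_PRESETS["no_salt"]
        prof_a = np.full(140, 20.0)
        prof_b = prof_a.copy()
        affected = np.zeros(140, bool)
        affected[40:82] = True
        prof_b[affected] = 10.0
        a, times, _ = self._matrix(replace(base, name="A", protection_profile=prof_a), seed=15)
        b, _, _ = self._matrix(replace(base, name="B", protection_profile=prof_b), seed=16)
        dm = differential_map(a, b, times)
        assert dm.mask.any(axis=1)[affected].mean() > 0.7
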