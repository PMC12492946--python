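"""Generator invariants: pedigree, genotypes, calendar, phenotypes, traits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resilience_rnam import synthetic_data as sd
from resilience_rnam.relationships import MISSING, pedigree_A


class TestSimulatePedigree:
    def test_founders_only_when_no_generations(self):
        ped = sd.simulate_pedigree(8, 0, seed=1)
        assert len(ped) == 8
        assert (ped["sire_id"] == 0).all() and (ped["dam_id"] == 0).all()

    def test_seed_determinism(self):
        a = sd.simulate_pedigree(10, 3, 2, seed=1)
        b = sd.simulate_pedigree(10, 3, 2, seed=1)
        pd.testing.assert_frame_equal(a, b)
        c = sd.simulate_pedigree(10, 3, 2, seed=2)
        assert not a.equals(c)

    def test_parents_precede_offspring_and_exist(self):
        ped = sd.simulate_pedigree(10, 2, 3, seed=5)
        pos = {a: i for i, a in enumerate(ped["animal_id"])}
        for _, row in ped.iterrows():
            for parent in (row.sire_id, row.dam_id):
                if parent != 0:
                    assert pos[parent] < pos[row.animal_id]

    def test_fullsib_relationship_half(self):
        """Mean additive relationship among full sibs is 0.5 (non-inbred parents)."""
        ped = sd.simulate_pedigree(40, 1, 6, seed=8)
        A = pedigree_A(ped)
        off = ped[ped["generation"] == 1]
        sib_vals = []
        for (_, _), grp in off.groupby(["sire_id", "dam_id"]):
            idx = grp.index.to_numpy()
            for i in range(len(idx)):
                for j in range(i + 1, len(idx)):
                    sib_vals.append(A[idx[i], idx[j]])
        assert np.mean(sib_vals) == pytest.approx(0.5, abs=1e-12)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            sd.simulate_pedigree(1, 1)
        with pytest.raises(ValueError):
            sd.simulate_pedigree(10, -1)


class TestSimulateGenotypes:
    def test_no_missing_when_rate_zero(self):
        ped = sd.simulate_pedigree(6, 1, 2, seed=1)
        g = sd.simulate_genotypes(ped, 50, missing_rate=0.0, seed=2)
        assert not (g.calls == MISSING).any()

    def test_forced_heterozygote(self):
        ped = pd.DataFrame(
            {"animal_id": [1, 2, 3], "sire_id": [0, 0, 1], "dam_id": [0, 0, 2],
             "generation": [0, 0, 1], "sex": ["M", "F", "M"]}
        )
        # search seeds until the parents are 0 and 2 at some SNP, then the
        # offspring must be heterozygous at that SNP in every case
        found = 0
        for seed in range(30):
            g = sd.simulate_genotypes(ped, 200, maf_low=0.4, maf_high=0.5, seed=seed)
            opp = (g.calls[0] == 0) & (g.calls[1] == 2) | (g.calls[0] == 2) & (g.calls[1] == 0)
            if opp.any():
                found += opp.sum()
                assert (g.calls[2][opp] == 1).all()
        assert found > 10

    def test_empty_pedigree_raises(self):
        with pytest.raises(ValueError):
            sd.simulate_genotypes(pd.DataFrame({"animal_id": [], "sire_id": [], "dam_id": []}), 10)


class TestSimulateEnvironment:
    def test_zero_prevalence_all_low(self, default_params):
        params = sd.TrueParameters(challenge_prevalence=0.0)
        cal = sd.simulate_environment(5, 20, params, seed=3)
        assert (cal["challenge_state"] == 0).all()

    def test_prevalence_within_binomial_error(self, default_params):
        cal = sd.simulate_environment(100, 100, default_params, seed=4)
        frac = cal["challenge_state"].mean()
        se = np.sqrt(0.3 * 0.7 / len(cal))
        assert abs(frac - 0.3) < 3 * se

    def test_midpoint_posterior_half(self):
        mix = sd.MixtureSpec(weights=(0.5, 0.5), means=(-1.5, -0.5), sds=(0.2, 0.2))
        assert mix.posterior_high(np.array([-1.0]))[0] == pytest.approx(0.5)

    def test_equal_means_rejected(self):
        with pytest.raises(ValueError):
            sd.MixtureSpec(means=(-1.0, -1.0))


class TestSimulatePhenotypes:
    def test_zero_variances_give_exact_fixed_sums(self):
        params = sd.TrueParameters(K=np.zeros((3, 3)), T=np.zeros((3, 3)), Q=(0.0, 0.0),
                                   batch_sd_dfi=0.0, batch_sd_trait2=0.0)
        ped = sd.simulate_pedigree(6, 1, 2, seed=1)
        cal = sd.simulate_environment(2, 5, params, seed=2)
        sim = sd.simulate_phenotypes(ped, cal, params, sd.assign_batches(ped, 2), seed=3)
        assert np.allclose(sim.dfi["dfi"], params.mu_dfi)
        assert np.allclose(sim.traits["value"], params.mu_trait2)

    def test_breeding_value_covariance_matches_K(self, default_params):
        """Across unrelated founders the empirical covariance of
        (a10, a11, a2) converges to K (3 Monte-Carlo SEs)."""
        n = 4000
        ped = sd.simulate_pedigree(n, 0, seed=5)
        cal = sd.simulate_environment(1, 2, default_params, seed=6)
        assignment = {int(a): 1 for a in ped["animal_id"][:10]}
        sim = sd.simulate_phenotypes(ped, cal, default_params, assignment, seed=7)
        a = sim.truth["a"]
        emp = np.cov(a.T)
        K = default_params.K
        for i in range(3):
            for j in range(3):
                # MC SE of a covariance estimate
                se = np.sqrt((K[i, i] * K[j, j] + K[i, j] ** 2) / n)
                assert abs(emp[i, j] - K[i, j]) < 3 * se, (i, j)

    def test_intercept_variance_within_five_percent(self, default_params):
        ped = sd.simulate_pedigree(2000, 0, seed=15)
        cal = sd.simulate_environment(1, 2, default_params, seed=6)
        assignment = {int(a): 1 for a in ped["animal_id"][:10]}
        sim = sd.simulate_phenotypes(ped, cal, default_params, assignment, seed=16)
        assert np.var(sim.truth["a"][:, 0], ddof=1) == pytest.approx(0.036, rel=0.05)

    def test_overall_mean_dfi_near_default(self, small_dataset, default_params):
        assert small_dataset["dfi"]["dfi"].mean() == pytest.approx(
            default_params.mu_dfi, abs=0.15
        )

    def test_seed_determinism(self, default_params):
        ped = sd.simulate_pedigree(8, 1, 2, seed=1)
        cal = sd.simulate_environment(2, 4, default_params, seed=2)
        asg = sd.assign_batches(ped, 2)
        a = sd.simulate_phenotypes(ped, cal, default_params, asg, seed=9)
        b = sd.simulate_phenotypes(ped, cal, default_params, asg, seed=9)
        pd.testing.assert_frame_equal(a.dfi, b.dfi)
        pd.testing.assert_frame_equal(a.traits, b.traits)

    def test_unassigned_animal_rejected(self, default_params):
        ped = sd.simulate_pedigree(4, 0, seed=1)
        cal = sd.simulate_environment(1, 3, default_params, seed=2)
        with pytest.raises(ValueError):
            sd.simulate_phenotypes(ped, cal, default_params, {99: 1}, seed=3)

    def test_non_psd_K_rejected(self):
        K = np.array([[0.01, 0.5, 0.0], [0.5, 0.01, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError):
            sd.TrueParameters(K=K)

    def test_calibrated_log_cv_is_bimodal(self, default_params):
        """With well-separated mixture components the realized within-day
        log CV of DFI reproduces the two-component structure."""
        from resilience_rnam import challenge_descriptor as cd

        ped = sd.simulate_pedigree(60, 1, 10, seed=31)
        cal = sd.simulate_environment(10, 40, default_params, seed=32)
        sim = sd.simulate_phenotypes(ped, cal, default_params,
                                     sd.assign_batches(ped, 10), seed=33,
                                     day_cv_calibration=True)
        res = cd.daily_log_cv(sim.dfi)
        x = res.day_cv["log_cv"].to_numpy()
        fit = cd.fit_gaussian_mixture(x, seed=1)
        # recovered components straddle the generating means and both carry weight
        assert fit.means[0] == pytest.approx(-1.5, abs=0.2)
        assert fit.means[1] == pytest.approx(-0.5, abs=0.25)
        assert 0.15 < fit.weights[1] < 0.45


class TestDeriveProductionTraits:
    @pytest.mark.parametrize(
        "kwargs, field, expected",
        [
            (dict(age_initial=70, W_initial=30, W_final=100, age_final=140), "adg", 1.0),
            (dict(age_initial=70, W_initial=30, W_final=98, age_final=138), "age", 72.0),
            (dict(G3=0, G4=0, M3=0, M4=0), "lmp", 60.12),
            (dict(BFT_test=8.0, beta_BFT=0.1, W_final=90, W_initial=30), "bft", 9.0),
        ],
    )
    def test_printed_formula_values(self, kwargs, field, expected):
        base = dict(age_initial=70, W_initial=30, W_final=100, age_final=140,
                    BFT_test=8, LMT_test=60, beta_BFT=0.1, beta_LMT=0.5,
                    G3=10, G4=12, M3=50, M4=55)
        base.update(kwargs)
        out = sd.derive_production_traits(**base)
        assert getattr(out, field) == pytest.approx(expected)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(1, 50), st.floats(1, 50), st.floats(1, 80), st.floats(1, 80), st.floats(0, 2))
    def test_lmp_linear_in_measurements(self, g3, g4, m3, m4, scale):
        """LMP is exactly linear: doubling a depth shifts LMP by its coefficient."""
        base = dict(age_initial=70, W_initial=30, W_final=100, age_final=140,
                    BFT_test=8, LMT_test=60, beta_BFT=0.1, beta_LMT=0.5)
        a = sd.derive_production_traits(**base, G3=g3, G4=g4, M3=m3, M4=m4)
        b = sd.derive_production_traits(**base, G3=g3 + scale, G4=g4, M3=m3, M4=m4)
        assert b.lmp - a.lmp == pytest.approx(-0.487 * scale, abs=1e-9)

    def test_invalid_weights_raise(self):
        with pytest.raises(ValueError):
            sd.derive_production_traits(70, 100, 30, 140, 8, 60, 0.1, 0.5, 0, 0, 0, 0)


def test_dataset_roundtrip(tmp_path, small_dataset, default_params):
    sd.write_dataset(tmp_path, small_dataset["pedigree"], small_dataset["dfi"],
                     small_dataset["traits"], small_dataset["calendar"],
                     default_params, seed=21)
    back = sd.load_parameters(tmp_path / "parameters.yaml")
    assert np.allclose(back.K, default_params.K)
    assert back.mixture.means == default_params.mixture.means
    dfi = pd.read_csv(tmp_path / "dfi.csv")
    assert len(dfi) == len(small_dataset["dfi"])
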