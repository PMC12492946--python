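"""Model-frame assembly, MME-based restricted likelihood (against a dense
oracle), EM/AI-REML behaviour and the boundary-mixture ratio test."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import chi2 as chi2_dist

from conftest import dense_restricted_loglik
from resilience_rnam import rnam_reml as rr
from resilience_rnam import synthetic_data as sd
from resilience_rnam.relationships import pedigree_A


@pytest.fixture(scope="module")
def toy_vc(default_params):
    return (
        default_params.K * 1.2,
        default_params.T * 0.9,
        np.array([0.2, 10.0]),
    )


class TestBuildModelFrame:
    def test_shape_contract(self, small_frame, small_dataset):
        n = len(small_dataset["dfi"])
        m = len(small_dataset["traits"])
        assert small_frame.n == n + m
        dm = small_frame.design_matrices("rnam")
        assert dm["Z10"].shape == (n, small_frame.n_ped)
        assert dm["Z2"].shape == (m, small_frame.n_ped)

    def test_slope_columns_zero_when_descriptor_zero(self, small_dataset):
        desc = small_dataset["descriptor"].copy()
        desc["p"] = 0.0
        frame = rr.build_model_frame(small_dataset["dfi"], small_dataset["traits"], desc)
        assert not frame.design_matrices("rnam")["Z11"].any()

    def test_hand_built_incidence(self):
        dfi = pd.DataFrame(
            {
                "animal_id": [1, 1, 2, 3],
                "batch_id": [1, 1, 1, 1],
                "day_index": [1, 2, 1, 2],
                "dfi": [2.0, 2.2, 2.4, 2.1],
            }
        )
        traits = pd.DataFrame({"animal_id": [1, 3], "trait": "AGE",
                               "value": [130.0, 140.0], "batch_id": [1, 1]})
        desc = pd.DataFrame({"batch_id": [1, 1], "day_index": [1, 2], "p": [0.2, 0.8]})
        frame = rr.build_model_frame(dfi, traits, desc, animal_order=[1, 2, 3])
        dm = frame.design_matrices("rnam")
        assert np.array_equal(dm["Z10"], [[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        assert np.allclose(dm["Z11"], [[0.2, 0, 0], [0.8, 0, 0], [0, 0.2, 0], [0, 0, 0.8]])
        assert np.array_equal(dm["Z2"], [[1, 0, 0], [0, 0, 1]])
        assert np.allclose(dm["W11"], dm["W10"] * frame.p_cov[:, None])

    def test_records_without_descriptor_dropped(self, small_dataset):
        desc = small_dataset["descriptor"].iloc[:-2]
        frame = rr.build_model_frame(small_dataset["dfi"], small_dataset["traits"], desc)
        assert frame.n_dropped_missing_descriptor > 0

    def test_missing_trait_records_error(self, small_dataset):
        empty = small_dataset["traits"].iloc[0:0]
        with pytest.raises(ValueError, match="zero records"):
            rr.build_model_frame(small_dataset["dfi"], empty, small_dataset["descriptor"],
                                 trait_name="AGE")

    def test_unknown_fixed_effect_error(self, small_dataset):
        with pytest.raises(ValueError, match="unknown fixed effect"):
            rr.build_model_frame(small_dataset["dfi"], small_dataset["traits"],
                                 small_dataset["descriptor"],
                                 fixed_config={"DFI": ["herd_year_season"]})


class TestRestrictedLoglik:
    def test_matches_dense_oracle_rnam(self, small_frame, small_dataset, toy_vc):
        K, T, Q = toy_vc
        mme = rr.restricted_loglik(small_frame, K, T, Q, small_dataset["A_inv"])
        dense = dense_restricted_loglik(small_frame, K, T, Q, small_dataset["A"])
        assert mme == pytest.approx(dense, abs=1e-6)

    def test_matches_dense_oracle_am(self, small_frame, small_dataset, toy_vc):
        K, T, Q = toy_vc
        K2 = K[np.ix_([0, 2], [0, 2])]
        T2 = T[np.ix_([0, 2], [0, 2])]
        mme = rr.restricted_loglik(small_frame, K2, T2, Q, small_dataset["A_inv"], model="am")
        dense = dense_restricted_loglik(small_frame, K2, T2, Q, small_dataset["A"], model="am")
        assert mme == pytest.approx(dense, abs=1e-6)

    def test_matches_dense_oracle_without_pe(self, small_frame, small_dataset, toy_vc):
        K, T, Q = toy_vc
        mme = rr.restricted_loglik(small_frame, K, None, Q, small_dataset["A_inv"],
                                   include_pe=False)
        dense = dense_restricted_loglik(small_frame, K, None, Q, small_dataset["A"],
                                        include_pe=False)
        assert mme == pytest.approx(dense, abs=1e-6)

    def test_scaling_change_of_variables(self, small_frame, small_dataset, toy_vc):
        """Scaling y by c and all variance components by c^2 shifts the
        restricted log-likelihood by -(n - p) log c."""
        K, T, Q = toy_vc
        c = 2.0
        base = rr.restricted_loglik(small_frame, K, T, Q, small_dataset["A_inv"])
        import dataclasses

        scaled = dataclasses.replace(small_frame, y1=c * small_frame.y1, y2=c * small_frame.y2)
        up = rr.restricted_loglik(scaled, c**2 * K, c**2 * T, c**2 * Q, small_dataset["A_inv"])
        n_p = small_frame.n - (small_frame.X1.shape[1] + small_frame.X2.shape[1])
        assert up - base == pytest.approx(-n_p * np.log(c), abs=1e-6)

    def test_duplicated_data_doubles_loglik_difference(self, small_dataset, toy_vc):
        """An independent copy of the dataset doubles the log-likelihood
        difference between two parameter points (independence additivity)."""
        K, T, Q = toy_vc
        ped = small_dataset["pedigree"]
        n = len(ped)
        dfi2 = small_dataset["dfi"].copy()
        dfi2["animal_id"] += n
        dfi2["batch_id"] += 10  # distinct fixed-effect levels keep copies independent
        tr2 = small_dataset["traits"].copy()
        tr2["animal_id"] += n
        tr2["batch_id"] += 10
        desc2 = small_dataset["descriptor"].copy()
        desc2["batch_id"] += 10
        ped2 = ped.copy()
        ped2["animal_id"] += n
        ped2.loc[ped2["sire_id"] > 0, "sire_id"] += n
        ped2.loc[ped2["dam_id"] > 0, "dam_id"] += n
        both_ped = pd.concat([ped, ped2], ignore_index=True)
        # interleave parent generations first to keep parents before offspring
        both_ped = both_ped.sort_values(["generation", "animal_id"]).reset_index(drop=True)
        frame1 = rr.build_model_frame(small_dataset["dfi"], small_dataset["traits"],
                                      small_dataset["descriptor"],
                                      animal_order=ped["animal_id"].to_numpy())
        both = rr.build_model_frame(
            pd.concat([small_dataset["dfi"], dfi2], ignore_index=True),
            pd.concat([small_dataset["traits"], tr2], ignore_index=True),
            pd.concat([small_dataset["descriptor"], desc2], ignore_index=True),
            animal_order=both_ped["animal_id"].to_numpy(),
        )
        A2 = pedigree_A(both_ped)
        d1 = rr.restricted_loglik(frame1, K, T, Q, small_dataset["A_inv"]) - \
            rr.restricted_loglik(frame1, 0.8 * K, T, Q, small_dataset["A_inv"])
        d2 = rr.restricted_loglik(both, K, T, Q, np.linalg.inv(A2)) - \
            rr.restricted_loglik(both, 0.8 * K, T, Q, np.linalg.inv(A2))
        assert d2 == pytest.approx(2 * d1, rel=1e-6)

    def test_non_psd_inputs_rejected(self, small_frame, small_dataset):
        K = np.array([[0.1, 0.9, 0], [0.9, 0.1, 0], [0, 0, 1.0]])
        with pytest.raises(ValueError):
            rr.restricted_loglik(small_frame, K, np.eye(3), [0.1, 1.0], small_dataset["A_inv"])


class TestRemlFit:
    def test_em_iterations_never_decrease_loglik(self, small_frame, small_dataset):
        fit = rr.reml_fit(small_frame, small_dataset["A_inv"],
                          relationship=small_dataset["A"], algorithm="em",
                          max_iter=15, tol=0, loglik_tol=0)
        # re-evaluate the likelihood path: run again capturing each step
        K, T, Q = rr._default_init(rr._Assembly(small_frame, "rnam", True))
        asm = rr._Assembly(small_frame, "rnam", True)
        sign, ld = np.linalg.slogdet(small_dataset["A_inv"])
        lls = []
        st = rr._evaluate(asm, K, T, Q, small_dataset["A_inv"], -ld)
        for _ in range(15):
            lls.append(st.loglik)
            K, T, Q = rr._em_update(asm, st, small_dataset["A_inv"], Q)
            st = rr._evaluate(asm, K, T, Q, small_dataset["A_inv"], -ld)
        lls.append(st.loglik)
        assert np.all(np.diff(lls) > -1e-7)

    def test_fitted_loglik_at_least_truth(self, small_frame, small_dataset, default_params):
        fit = rr.reml_fit(small_frame, small_dataset["A_inv"],
                          relationship=small_dataset["A"], tol=1e-5, max_iter=40,
                          loglik_tol=1e-4)
        at_truth = rr.restricted_loglik(small_frame, default_params.K, default_params.T,
                                        np.array(default_params.Q), small_dataset["A_inv"])
        assert fit.loglik >= at_truth - 1e-6

    def test_estimated_K_psd(self, small_frame, small_dataset):
        fit = rr.reml_fit(small_frame, small_dataset["A_inv"],
                          relationship=small_dataset["A"], tol=1e-5, max_iter=30)
        assert np.linalg.eigvalsh(fit.K).min() >= -1e-9

    def test_closed_form_balanced_one_way(self):
        """Univariate, no permanent environment, identity kernel, balanced
        design: REML equals the ANOVA estimators sigma_e^2 = MSW and
        sigma_a^2 = (MSB - MSW) / r."""
        rng = np.random.default_rng(42)
        n_animals, r = 25, 6
        a = rng.normal(0, np.sqrt(0.4), n_animals)
        y = 10 + a[:, None] + rng.normal(0, np.sqrt(0.8), (n_animals, r))
        dfi = pd.DataFrame(
            {
                "animal_id": np.repeat(np.arange(1, n_animals + 1), r),
                "batch_id": 1,
                "day_index": np.tile(np.arange(1, r + 1), n_animals),
                "dfi": y.ravel(),
            }
        )
        desc = pd.DataFrame({"batch_id": 1, "day_index": np.arange(1, r + 1), "p": 0.0})
        frame = rr.build_model_frame(dfi, None, desc)
        fit = rr.reml_fit(frame, np.eye(n_animals), relationship=np.eye(n_animals),
                          model="am", include_pe=False, tol=1e-10, max_iter=200,
                          loglik_tol=0.0)
        ybar = y.mean(axis=1)
        msb = r * np.sum((ybar - ybar.mean()) ** 2) / (n_animals - 1)
        msw = np.sum((y - ybar[:, None]) ** 2) / (n_animals * (r - 1))
        assert fit.Q[0] == pytest.approx(msw, rel=1e-4)
        assert fit.K[0, 0] == pytest.approx((msb - msw) / r, rel=1e-4)

    def test_am_nested_in_rnam(self, small_frame, small_dataset):
        am = rr.fit_animal_model(small_frame, small_dataset["A_inv"],
                                 relationship=small_dataset["A"], tol=1e-5, max_iter=40)
        rnam = rr.reml_fit(small_frame, small_dataset["A_inv"],
                           relationship=small_dataset["A"], tol=1e-5, max_iter=40)
        assert rnam.loglik >= am.loglik - 0.2

    def test_all_p_zero_leaves_slope_unidentified(self, small_dataset):
        """With p = 0 everywhere the slope never enters the likelihood, so
        the reaction-norm and animal models agree on the intercept block."""
        desc = small_dataset["descriptor"].copy()
        desc["p"] = 0.0
        frame = rr.build_model_frame(
            small_dataset["dfi"], small_dataset["traits"], desc,
            animal_order=small_dataset["pedigree"]["animal_id"].to_numpy(),
        )
        Ai, A = small_dataset["A_inv"], small_dataset["A"]
        am = rr.fit_animal_model(frame, Ai, relationship=A, tol=1e-6, max_iter=50,
                                 loglik_tol=1e-5)
        init_K = np.zeros((3, 3))
        init_K[np.ix_([0, 2], [0, 2])] = am.K
        init_K[1, 1] = 0.05
        init_T = np.zeros((3, 3))
        init_T[np.ix_([0, 2], [0, 2])] = am.T
        init_T[1, 1] = 0.05
        rnam = rr.reml_fit(frame, Ai, relationship=A, tol=1e-6, max_iter=50,
                           init=(init_K, init_T, am.Q), loglik_tol=1e-5)
        assert rnam.loglik == pytest.approx(am.loglik, abs=0.05)
        assert rnam.K[0, 0] == pytest.approx(am.K[0, 0], rel=0.05, abs=5e-3)

    def test_convergence_flag_false_at_max_iter(self, small_frame, small_dataset):
        fit = rr.reml_fit(small_frame, small_dataset["A_inv"],
                          relationship=small_dataset["A"], max_iter=1, tol=0,
                          loglik_tol=0)
        assert not fit.converged
        assert fit.n_iter == 1


class TestRemlrt:
    def test_printed_likelihood_arithmetic(self):
        assert 881941.77 - 868811.53 == pytest.approx(13130.24)

    def test_equal_likelihoods_give_zero_and_p_one(self, small_frame):
        a = _fake_fit("rnam", -1000.0, small_frame)
        b = _fake_fit("am", -1000.0, small_frame)
        res = rr.remlrt(a, b)
        assert res.chi2 == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_mixture_pvalue_matches_quadrature(self):
        """p-value for chi2 = 20 equals numerical integration of the
        0.5 chi2_5 + 0.5 chi2_7 mixture density."""
        x = 20.0
        dens = lambda t: 0.5 * chi2_dist.pdf(t, 5) + 0.5 * chi2_dist.pdf(t, 7)
        num, _ = integrate.quad(dens, x, np.inf)
        assert rr.mixture_chi2_sf(x) == pytest.approx(num, abs=1e-10)

    def test_different_frames_rejected(self, small_frame, small_dataset):
        other = rr.build_model_frame(small_dataset["dfi"].iloc[:-5],
                                     small_dataset["traits"], small_dataset["descriptor"])
        a = _fake_fit("rnam", -1000.0, small_frame)
        b = _fake_fit("am", -1001.0, other)
        with pytest.raises(ValueError, match="different model frames"):
            rr.remlrt(a, b)

    def test_df_pair_follows_boundary_convention(self, small_frame):
        res = rr.remlrt(_fake_fit("rnam", -10.0, small_frame),
                        _fake_fit("am", -15.0, small_frame))
        assert res.df_pair == (5, 7)
        assert res.weights == (0.5, 0.5)


def _fake_fit(model, loglik, frame):
    return rr.FitResult(
        model=model, K=np.eye(3 if model == "rnam" else 2),
        T=np.eye(3 if model == "rnam" else 2), Q=np.array([0.1, 1.0]),
        gen_labels=("a10", "a11", "a2") if model == "rnam" else ("a10", "a2"),
        loglik=loglik, n_iter=1, converged=True, boundary={}, solutions={},
        frame_signature=frame.signature(), include_pe=True, trait_name="AGE",
    )
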