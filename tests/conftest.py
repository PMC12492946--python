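import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from resilience_rnam import rnam_reml as rr

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from resilience_rnam import synthetic_data as sd
from resilience_rnam.relationships import pedigree_A


@pytest.fixture(scope="session")
def default_params():
    return sd.TrueParameters()


@pytest.fixture(scope="session")
def small_dataset(default_params):
    """A compact simulated population shared by several test modules:
    16 founders, 24 recorded offspring in 3 batches of 8, 12 days each."""
    ped = sd.simulate_pedigree(16, 1, 3, seed=21)
    cal = sd.simulate_environment(3, 12, default_params, seed=22)
    assignment = sd.assign_batches(ped, 3)
    sim = sd.simulate_phenotypes(ped, cal, default_params, assignment, seed=23,
                                 day_cv_calibration=False)
    desc = cal.rename(columns={"true_p": "p"})[["batch_id", "day_index", "p"]]
    A = pedigree_A(ped)
    return {
        "pedigree": ped,
        "calendar": cal,
        "assignment": assignment,
        "dfi": sim.dfi,
        "traits": sim.traits,
        "truth": sim.truth,
        "descriptor": desc,
        "A": A,
        "A_inv": np.linalg.inv(A),
    }


@pytest.fixture(scope="session")
def small_frame(small_dataset):
    return rr.build_model_frame(
        small_dataset["dfi"],
        small_dataset["traits"],
        small_dataset["descriptor"],
        animal_order=small_dataset["pedigree"]["animal_id"].to_numpy(),
    )


def dense_restricted_loglik(frame, K, T, Q, A, model="rnam", include_pe=True):
    """Independent dense-covariance REML log-likelihood oracle.

    Builds V = Z (K x A) Z' + W (T x I) W' + R explicitly and evaluates
    -2 l = (n-p) ln 2pi + ln|V| + ln|X' V^-1 X| + y' P y
    without any mixed-model-equation identity.
    """
    dm = frame.design_matrices(model)
    n1, n2, na, npe = frame.n1, frame.n2, frame.n_ped, frame.n_pe
    n = n1 + n2
    X = np.zeros((n, dm["X1"].shape[1] + dm["X2"].shape[1]))
    X[:n1, : dm["X1"].shape[1]] = dm["X1"]
    if n2:
        X[n1:, dm["X1"].shape[1]:] = dm["X2"]
    k = 3 if model == "rnam" else 2
    Zg = np.zeros((n, k * na))
    cols = [dm["Z10"]] + ([dm["Z11"]] if model == "rnam" else [])
    for i, Z in enumerate(cols):
        Zg[:n1, i * na : (i + 1) * na] = Z
    if n2:
        Zg[n1:, (k - 1) * na :] = dm["Z2"]
    V = Zg @ np.kron(np.asarray(K), A) @ Zg.T
    if include_pe:
        Zp = np.zeros((n, k * npe))
        colsW = [dm["W10"]] + ([dm["W11"]] if model == "rnam" else [])
        for i, W in enumerate(colsW):
            Zp[:n1, i * npe : (i + 1) * npe] = W
        if n2:
            Zp[n1:, (k - 1) * npe :] = dm["W2"]
        V += Zp @ np.kron(np.asarray(T), np.eye(npe)) @ Zp.T
    q = np.atleast_1d(np.asarray(Q, dtype=float))
    rdiag = np.r_[np.full(n1, q[0]), np.full(n2, q[1]) if n2 else []]
    V[np.diag_indices(n)] += rdiag
    y = np.r_[frame.y1, frame.y2]
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    m2l = (
        (n - X.shape[1]) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + float(y @ P @ y)
    )
    return -0.5 * m2l
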