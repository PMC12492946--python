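"""Bivariate reaction-norm animal model fitted by REML.

The model couples daily feed intake (DFI, trait 1, one record per animal
per day) with a production trait measured once per animal (trait 2):

    [y1]   [X1  0 ] [b1]   [Z10 Z11  0 ] [a10]   [W10 W11  0 ] [pe10]   [e1]
    [y2] = [0   X2] [b2] + [ 0   0  Z2 ] [a11] + [ 0   0  W2 ] [pe11] + [e2]
                                         [a2 ]                 [pe2 ]

Each DFI record carries the day's challenge probability p; the slope
incidence Z11 (and W11) equals the intercept incidence scaled by p, so an
animal's genetic effect on DFI at gradient p is a10 + p*a11. Random
effects: (a10, a11, a2) ~ N(0, K (x) H) with H a pedigree/genomic
relationship matrix, permanent-environmental triples ~ N(0, T (x) I),
residuals diagonal with trait-specific variances Q = diag(ve1, ve2) (the
residual covariance is not estimable because the two traits are never
observed simultaneously). The plain animal model (AM) drops the slope
terms, collapsing K and T to 2x2.

REML maximization uses average-information (AI) updates on the
(co)variance entries with EM-REML fallback whenever an AI step leaves the
positive-semidefinite cone or decreases the restricted likelihood. All
likelihood quantities are computed through the mixed-model equations
(MME), never a dense phenotypic covariance, so cost scales with the
number of animals rather than records:

    -2 l_R = (n - p) ln 2pi + ln|R| + ln|G| + ln|C| + y'Py

with C the MME coefficient matrix and y'Py = y'R^-1 y - rhs' sol.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_solve, cholesky
from scipy.linalg.lapack import dpotri
from scipy.stats import chi2 as chi2_dist

from .gradient_correlations import GeneticCovK

__all__ = [
    "ModelFrame",
    "FitResult",
    "REMLRTResult",
    "TRAIT_FIXED_EFFECTS",
    "CONTINUOUS_COVARIATES",
    "build_model_frame",
    "restricted_loglik",
    "reml_fit",
    "fit_animal_model",
    "remlrt",
    "mixture_chi2_sf",
]

# Fixed effects per trait in the reference evaluation's configuration;
# effect names must match columns of the record tables.
TRAIT_FIXED_EFFECTS = {
    "DFI": ["pen", "batch", "farm"],
    "AGE": ["sex", "batch", "farm"],
    "BFT": ["sex", "batch", "farm", "weight_control"],
    "LMT": ["sex", "batch", "farm", "weight_control"],
    "FCR": ["pen", "batch", "farm", "weight_control"],
    "LMP": ["sex", "batch", "farm", "hot_carcass_weight"],
    "PH24": ["sex", "batch", "farm", "hot_carcass_weight", "slaughter_date"],
    "DLP": ["sex", "batch", "farm", "weight_control", "slaughter_date", "sample_weight"],
    "BHW": ["sex", "batch", "farm", "weight_control"],
}
# Covariates fitted as continuous regressions; everything else is a factor
# with first-level-reference coding.
CONTINUOUS_COVARIATES = {"weight_control", "hot_carcass_weight", "sample_weight"}

_EIG_FLOOR = 1e-10


@dataclass
class ModelFrame:
    """Assembled responses, designs and index maps for one DFI-trait pair."""

    y1: np.ndarray
    X1: np.ndarray
    p_cov: np.ndarray  # challenge probability per DFI record
    gen_idx1: np.ndarray  # DFI record -> position in animal_order
    pe_idx1: np.ndarray  # DFI record -> position in pe_animal_order
    animal_order: np.ndarray  # ordering shared with the relationship matrix
    pe_animal_order: np.ndarray  # animals carrying permanent-env. effects
    trait_name: Optional[str] = None
    y2: np.ndarray = field(default_factory=lambda: np.empty(0))
    X2: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    gen_idx2: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    pe_idx2: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    fixed_names1: tuple = ()
    fixed_names2: tuple = ()
    n_dropped_missing_descriptor: int = 0

    def __post_init__(self):
        if len(self.y1) == 0:
            raise ValueError("no DFI records in frame")
        if np.any((self.p_cov < 0) | (self.p_cov > 1)):
            raise ValueError("descriptor p must lie in [0, 1]")

    @property
    def n1(self) -> int:
        return len(self.y1)

    @property
    def n2(self) -> int:
        return len(self.y2)

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    @property
    def bivariate(self) -> bool:
        return self.n2 > 0

    @property
    def n_ped(self) -> int:
        return len(self.animal_order)

    @property
    def n_pe(self) -> int:
        return len(self.pe_animal_order)

    def signature(self) -> str:
        h = hashlib.sha256()
        for arr in (self.y1, self.y2, self.p_cov, self.gen_idx1, self.gen_idx2):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def design_matrices(self, model: str = "rnam") -> dict:
        """Dense incidence matrices for inspection and small-scale oracles."""
        n1, n2, na, npe = self.n1, self.n2, self.n_ped, self.n_pe
        out = {"X1": self.X1, "X2": self.X2}
        Z10 = np.zeros((n1, na))
        Z10[np.arange(n1), self.gen_idx1] = 1.0
        W10 = np.zeros((n1, npe))
        W10[np.arange(n1), self.pe_idx1] = 1.0
        Z2 = np.zeros((n2, na))
        W2 = np.zeros((n2, npe))
        if n2:
            Z2[np.arange(n2), self.gen_idx2] = 1.0
            W2[np.arange(n2), self.pe_idx2] = 1.0
        out.update(Z10=Z10, Z2=Z2, W10=W10, W2=W2)
        if model == "rnam":
            out["Z11"] = Z10 * self.p_cov[:, None]
            out["W11"] = W10 * self.p_cov[:, None]
        return out


def _design_for_trait(df: pd.DataFrame, effects: Sequence[str]) -> tuple[np.ndarray, tuple]:
    """Intercept + reference-coded factors / continuous covariates, pruned
    to full column rank by pivoted QR."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for eff in effects:
        if eff not in df.columns:
            raise ValueError(f"unknown fixed effect {eff!r}: no such column in the records")
        if eff in CONTINUOUS_COVARIATES:
            cols.append(df[eff].to_numpy(dtype=float))
            names.append(eff)
        else:
            d = pd.get_dummies(df[eff].astype("category"), prefix=eff, drop_first=True)
            for c in d.columns:
                cols.append(d[c].to_numpy(dtype=float))
                names.append(str(c))
    X = np.column_stack(cols)
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    keep = sorted(piv[: int(np.sum(diag > 1e-8 * max(diag[0], 1.0)))])
    return X[:, keep], tuple(names[i] for i in keep)


def build_model_frame(
    dfi: pd.DataFrame,
    traits: Optional[pd.DataFrame],
    descriptor: pd.DataFrame,
    fixed_config: Optional[dict] = None,
    trait_name: Optional[str] = None,
    animal_order: Optional[Sequence] = None,
) -> ModelFrame:
    """Merge records with the environmental descriptor and build designs.

    ``fixed_config`` maps trait name (or "DFI") to the list of fixed-effect
    columns; defaults to batch only, which is what the synthetic generator
    produces. DFI records whose batch-day has no descriptor value are
    dropped (counted in ``n_dropped_missing_descriptor``). ``animal_order``
    fixes the animal ordering and must match the relationship matrix used
    at fit time; it defaults to the sorted union of record animals.
    """
    fixed_config = fixed_config or {}
    merged = dfi.merge(descriptor, on=["batch_id", "day_index"], how="left")
    n_dropped = int(merged["p"].isna().sum())
    merged = merged.dropna(subset=["p"]).reset_index(drop=True)
    if len(merged) == 0:
        raise ValueError("no DFI record has a descriptor value")

    if traits is not None:
        if trait_name is None:
            unique = traits["trait"].unique()
            if len(unique) != 1:
                raise ValueError(f"trait_name required; records contain {list(unique)}")
            trait_name = str(unique[0])
        tr = traits.loc[traits["trait"] == trait_name].reset_index(drop=True)
        if len(tr) == 0:
            raise ValueError(f"trait {trait_name!r} has zero records")
        if tr["animal_id"].duplicated().any():
            raise ValueError(f"trait {trait_name!r} has repeated records for an animal")
    else:
        tr = None

    rec_animals = [merged["animal_id"].to_numpy()]
    if tr is not None:
        rec_animals.append(tr["animal_id"].to_numpy())
    pe_order = np.unique(np.concatenate(rec_animals))
    if animal_order is None:
        order = pe_order
    else:
        order = np.asarray(animal_order)
    pos = {a: i for i, a in enumerate(order)}
    missing = set(pe_order) - set(pos)
    if missing:
        raise ValueError(f"record animals missing from animal_order: {sorted(missing)[:5]}")
    pe_pos = {a: i for i, a in enumerate(pe_order)}

    X1, names1 = _design_for_trait(merged, fixed_config.get("DFI", ["batch_id"]))
    frame_kwargs = dict(
        y1=merged["dfi"].to_numpy(dtype=float),
        X1=X1,
        p_cov=merged["p"].to_numpy(dtype=float),
        gen_idx1=np.array([pos[a] for a in merged["animal_id"]], dtype=np.int64),
        pe_idx1=np.array([pe_pos[a] for a in merged["animal_id"]], dtype=np.int64),
        animal_order=order,
        pe_animal_order=pe_order,
        fixed_names1=names1,
        n_dropped_missing_descriptor=n_dropped,
        trait_name=trait_name,
    )
    if tr is not None:
        X2, names2 = _design_for_trait(tr, fixed_config.get(trait_name, ["batch_id"]))
        frame_kwargs.update(
            y2=tr["value"].to_numpy(dtype=float),
            X2=X2,
            gen_idx2=np.array([pos[a] for a in tr["animal_id"]], dtype=np.int64),
            pe_idx2=np.array([pe_pos[a] for a in tr["animal_id"]], dtype=np.int64),
            fixed_names2=names2,
        )
    return ModelFrame(**frame_kwargs)


# -- internal assembly -------------------------------------------------------


class _Assembly:
    """Model-specific sparse design and its fixed cross-products.

    Column layout: [fixed | genetic comp 0..k-1 by animal | pe comp 0..k-1].
    The data cross-products W'W (per trait) never change across REML
    iterations; only the variance structure added to them does.
    """

    def __init__(self, frame: ModelFrame, model: str, include_pe: bool):
        if model not in ("rnam", "am"):
            raise ValueError(f"unknown model {model!r}")
        self.frame = frame
        self.model = model
        self.include_pe = include_pe
        n1, n2 = frame.n1, frame.n2
        n = n1 + n2
        self.n1, self.n2, self.n = n1, n2, n

        # genetic component coefficients per stacked record
        p = frame.p_cov
        one1 = np.ones(n1)
        zero2 = np.zeros(n2)
        if model == "rnam":
            comps = [("a10", np.concatenate([one1, zero2]))]
            comps.append(("a11", np.concatenate([p, zero2])))
        else:
            comps = [("a10", np.concatenate([one1, zero2]))]
        if frame.bivariate:
            comps.append(("a2", np.concatenate([np.zeros(n1), np.ones(n2)])))
        self.gen_labels = tuple(lbl for lbl, _ in comps)
        self.gen_coefs = np.array([c for _, c in comps])  # (k_g, n)
        self.k_g = len(comps)
        self.k_pe = self.k_g if include_pe else 0

        self.gidx = np.concatenate([frame.gen_idx1, frame.gen_idx2]).astype(np.int64)
        self.pidx = np.concatenate([frame.pe_idx1, frame.pe_idx2]).astype(np.int64)
        self.n_ped, self.n_pe = frame.n_ped, frame.n_pe

        p1 = frame.X1.shape[1]
        p2 = frame.X2.shape[1] if frame.bivariate else 0
        self.p_fixed = p1 + p2
        X = np.zeros((n, self.p_fixed))
        X[:n1, :p1] = frame.X1
        if frame.bivariate:
            X[n1:, p1:] = frame.X2
        self.gs = self.p_fixed
        self.ps = self.gs + self.k_g * self.n_ped
        self.dim = self.ps + self.k_pe * self.n_pe

        rows, cols, vals = [], [], []
        r_idx, c_idx = np.nonzero(X)
        rows.append(r_idx)
        cols.append(c_idx)
        vals.append(X[r_idx, c_idx])
        recs = np.arange(n)
        for c in range(self.k_g):
            rows.append(recs)
            cols.append(self.gs + c * self.n_ped + self.gidx)
            vals.append(self.gen_coefs[c])
        for c in range(self.k_pe):
            rows.append(recs)
            cols.append(self.ps + c * self.n_pe + self.pidx)
            vals.append(self.gen_coefs[c])
        W = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, self.dim),
        ).tocsr()
        W.sum_duplicates()
        self.W = W

        y = np.concatenate([frame.y1, frame.y2])
        self.y = y
        self.trait_rows = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])
        W1, W2 = W[:n1], W[n1:]
        self.C1 = (W1.T @ W1).toarray()
        self.C2 = (W2.T @ W2).toarray() if n2 else np.zeros((self.dim, self.dim))
        self.Wty1 = W1.T @ y[:n1]
        self.Wty2 = W2.T @ y[n1:] if n2 else np.zeros(self.dim)
        self.yty1 = float(y[:n1] @ y[:n1])
        self.yty2 = float(y[n1:] @ y[n1:]) if n2 else 0.0

        # padded per-record nonzero structure for diag(W Ci W')
        nnz = np.diff(W.indptr)
        m = int(nnz.max())
        J = np.zeros((n, m), dtype=np.int64)
        V = np.zeros((n, m))
        for r in range(n):
            a, b = W.indptr[r], W.indptr[r + 1]
            J[r, : b - a] = W.indices[a:b]
            V[r, : b - a] = W.data[a:b]
        self.padJ, self.padV = J, V

        self.n_traits = 2 if frame.bivariate else 1
        self.n_counts = (n1, n2) if frame.bivariate else (n1,)

    def q_row(self, Q) -> np.ndarray:
        q = np.asarray(Q, dtype=float)
        return q[self.trait_rows] if self.n_traits == 2 else np.full(self.n, q[0])


def _sym_inv_logdet(M: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a small symmetric PD matrix, with an
    eigenvalue floor so boundary estimates stay usable."""
    w, V = np.linalg.eigh(M)
    floor = max(_EIG_FLOOR, 1e-8 * w.max())
    w = np.maximum(w, floor)
    return (V / w) @ V.T, float(np.sum(np.log(w)))


def _floor_psd(M: np.ndarray, floor_frac: float = 1e-8) -> np.ndarray:
    w, V = np.linalg.eigh(M)
    floor = floor_frac * max(w.max(), 1e-12)
    if w.min() >= floor:
        return M
    w = np.maximum(w, floor)
    return (V * w) @ V.T


@dataclass
class _State:
    loglik: float
    chol: np.ndarray
    Ci: Optional[np.ndarray]
    sol: np.ndarray
    Py: np.ndarray
    resid: np.ndarray
    d_diag: Optional[np.ndarray]
    N_g: Optional[np.ndarray]
    N_pe: Optional[np.ndarray]


def _evaluate(asm: _Assembly, K, T, Q, Hinv, logdetH, derivatives: bool = True) -> _State:
    n1, n2 = asm.n1, asm.n2
    q = np.asarray(Q, dtype=float)
    Kinv, logdetK = _sym_inv_logdet(K)
    C = asm.C1 / q[0]
    if asm.n_traits == 2:
        C = C + asm.C2 / q[1]
    gs, ps = asm.gs, asm.ps
    ge = gs + asm.k_g * asm.n_ped
    C[gs:ge, gs:ge] += np.kron(Kinv, Hinv)
    logdetT = 0.0
    if asm.k_pe:
        Tinv, logdetT = _sym_inv_logdet(T)
        ar = np.arange(asm.n_pe)
        for a in range(asm.k_pe):
            for b in range(asm.k_pe):
                C[ps + a * asm.n_pe + ar, ps + b * asm.n_pe + ar] += Tinv[a, b]

    L = cholesky(C, lower=True, overwrite_a=True, check_finite=False)
    logdetC = 2.0 * float(np.sum(np.log(np.diag(L))))
    rhs = asm.Wty1 / q[0] + (asm.Wty2 / q[1] if asm.n_traits == 2 else 0.0)
    sol = cho_solve((L, True), rhs, check_finite=False)
    yry = asm.yty1 / q[0] + (asm.yty2 / q[1] if asm.n_traits == 2 else 0.0)
    yPy = yry - float(rhs @ sol)

    logR = n1 * np.log(q[0]) + (n2 * np.log(q[1]) if asm.n_traits == 2 else 0.0)
    logG = asm.n_ped * logdetK + asm.k_g * logdetH
    if asm.k_pe:
        logG += asm.n_pe * logdetT
    m2l = (asm.n - asm.p_fixed) * np.log(2 * np.pi) + logR + logG + logdetC + yPy
    loglik = -0.5 * m2l

    resid = asm.y - asm.W @ sol
    Py = resid / asm.q_row(q)

    st = _State(loglik, L, None, sol, Py, resid, None, None, None)
    if derivatives:
        _add_derivatives(asm, st, Hinv)
    return st


def _add_derivatives(asm: _Assembly, st: _State, Hinv) -> None:
    """Fill the MME-inverse-based quantities (C^-1 blocks, traces, diag of
    W C^-1 W') needed by the EM update and the AI scores."""
    if st.Ci is not None:
        return
    gs, ps = asm.gs, asm.ps
    ge = gs + asm.k_g * asm.n_ped
    Ci, _ = dpotri(st.chol, lower=1)
    Ci = np.tril(Ci) + np.tril(Ci, -1).T
    st.Ci = Ci
    Gblk = Ci[gs:ge, gs:ge].reshape(asm.k_g, asm.n_ped, asm.k_g, asm.n_ped)
    N_g = np.empty((asm.k_g, asm.k_g))
    for a in range(asm.k_g):
        for b in range(a, asm.k_g):
            # tr(Hinv @ B) with symmetric Hinv
            N_g[a, b] = N_g[b, a] = float(np.sum(Hinv * Gblk[a, :, b, :].T))
    st.N_g = N_g
    if asm.k_pe:
        N_pe = np.empty((asm.k_pe, asm.k_pe))
        for a in range(asm.k_pe):
            for b in range(a, asm.k_pe):
                sa = slice(ps + a * asm.n_pe, ps + (a + 1) * asm.n_pe)
                sb = slice(ps + b * asm.n_pe, ps + (b + 1) * asm.n_pe)
                N_pe[a, b] = N_pe[b, a] = float(np.trace(Ci[sa, sb]))
        st.N_pe = N_pe
    # diag(W Ci W') per record via the padded nonzero structure
    g = Ci[asm.padJ[:, :, None], asm.padJ[:, None, :]]
    st.d_diag = np.einsum("ni,nj,nij->n", asm.padV, asm.padV, g)


def _param_list(asm: _Assembly):
    params = []
    for a in range(asm.k_g):
        for b in range(a + 1):
            params.append(("K", a, b))
    for a in range(asm.k_pe):
        for b in range(a + 1):
            params.append(("T", a, b))
    for t in range(asm.n_traits):
        params.append(("Q", t, t))
    return params


def _pack(asm, K, T, Q):
    th = []
    for blk, a, b in _param_list(asm):
        th.append({"K": K, "T": T}[blk][a, b] if blk != "Q" else Q[a])
    return np.array(th)


def _unpack(asm, theta):
    params = _param_list(asm)
    K = np.zeros((asm.k_g, asm.k_g))
    T = np.zeros((asm.k_pe, asm.k_pe)) if asm.k_pe else None
    Q = np.zeros(asm.n_traits)
    for val, (blk, a, b) in zip(theta, params):
        if blk == "K":
            K[a, b] = K[b, a] = val
        elif blk == "T":
            T[a, b] = T[b, a] = val
        else:
            Q[a] = val
    return K, T, Q


def _scores_and_ai(asm: _Assembly, st: _State, K, T, Q, H):
    """Gradient of the restricted log-likelihood and the AI matrix."""
    params = _param_list(asm)
    q = np.asarray(Q, dtype=float)
    Kinv, _ = _sym_inv_logdet(K)
    WtPy = asm.W.T @ st.Py
    gs, ps = asm.gs, asm.ps
    t_g = WtPy[gs : gs + asm.k_g * asm.n_ped].reshape(asm.k_g, asm.n_ped)
    Ht = t_g @ H  # H symmetric: rows are H @ t_c
    MK = Kinv @ st.N_g @ Kinv
    if asm.k_pe:
        Tinv, _ = _sym_inv_logdet(T)
        t_pe = WtPy[ps : ps + asm.k_pe * asm.n_pe].reshape(asm.k_pe, asm.n_pe)
        MT = Tinv @ st.N_pe @ Tinv

    n_par = len(params)
    scores = np.empty(n_par)
    F = np.empty((asm.n, n_par))
    row_q = asm.q_row(q)
    for i, (blk, a, b) in enumerate(params):
        if blk == "K":
            mult = 1.0 if a == b else 2.0
            trPV = asm.n_ped * (Kinv[a, b] * mult) - (MK[a, b] * mult)
            yPVPy = mult * float(t_g[a] @ Ht[b])
            v = np.zeros((asm.k_g, asm.n_ped))
            v[a] += Ht[b]
            if a != b:
                v[b] += Ht[a]
            F[:, i] = np.einsum("cn,cn->n", asm.gen_coefs, v[:, asm.gidx])
        elif blk == "T":
            mult = 1.0 if a == b else 2.0
            trPV = asm.n_pe * (Tinv[a, b] * mult) - (MT[a, b] * mult)
            yPVPy = mult * float(t_pe[a] @ t_pe[b])
            v = np.zeros((asm.k_pe, asm.n_pe))
            v[a] += t_pe[b]
            if a != b:
                v[b] += t_pe[a]
            F[:, i] = np.einsum("cn,cn->n", asm.gen_coefs[: asm.k_pe], v[:, asm.pidx])
        else:  # residual variance of trait a
            mask = asm.trait_rows == a
            n_t = int(mask.sum())
            trPV = n_t / q[a] - float(st.d_diag[mask].sum()) / q[a] ** 2
            yPVPy = float(np.sum(st.Py[mask] ** 2))
            f = np.zeros(asm.n)
            f[mask] = st.Py[mask]
            F[:, i] = f
        scores[i] = -0.5 * (trPV - yPVPy)

    U = asm.W.T @ (F / row_q[:, None])
    Zm = cho_solve((st.chol, True), U, check_finite=False)
    PF = (F - asm.W @ Zm) / row_q[:, None]
    AI = 0.5 * (F.T @ PF)
    return scores, 0.5 * (AI + AI.T)


def _em_update(asm: _Assembly, st: _State, Hinv, Q):
    q = np.asarray(Q, dtype=float)
    gs, ps = asm.gs, asm.ps
    Ug = st.sol[gs : gs + asm.k_g * asm.n_ped].reshape(asm.k_g, asm.n_ped).T
    K_new = (Ug.T @ Hinv @ Ug + st.N_g) / asm.n_ped
    T_new = None
    if asm.k_pe:
        Upe = st.sol[ps : ps + asm.k_pe * asm.n_pe].reshape(asm.k_pe, asm.n_pe).T
        T_new = (Upe.T @ Upe + st.N_pe) / asm.n_pe
    Q_new = np.empty(asm.n_traits)
    for t in range(asm.n_traits):
        mask = asm.trait_rows == t
        Q_new[t] = (float(np.sum(st.resid[mask] ** 2)) + float(st.d_diag[mask].sum())) / int(
            mask.sum()
        )
    return 0.5 * (K_new + K_new.T), T_new if T_new is None else 0.5 * (T_new + T_new.T), Q_new


@dataclass
class FitResult:
    """REML estimates, restricted log-likelihood and BLUE/BLUP solutions."""

    model: str
    K: np.ndarray
    T: Optional[np.ndarray]
    Q: np.ndarray
    gen_labels: tuple
    loglik: float
    n_iter: int
    converged: bool
    boundary: dict
    solutions: dict
    frame_signature: str
    include_pe: bool
    trait_name: Optional[str]
    pe2_profile_flatness: Optional[float] = None

    @property
    def minus2loglik(self) -> float:
        return -2.0 * self.loglik

    def genetic_cov(self) -> GeneticCovK:
        if self.K.shape != (3, 3):
            raise ValueError("genetic_cov requires the full 3x3 reaction-norm K")
        return GeneticCovK.from_matrix(self.K)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "model": self.model,
                    "trait": self.trait_name,
                    "K": self.K.tolist(),
                    "T": None if self.T is None else self.T.tolist(),
                    "Q": self.Q.tolist(),
                    "gen_labels": list(self.gen_labels),
                    "loglik": self.loglik,
                    "minus2loglik": self.minus2loglik,
                    "n_iter": self.n_iter,
                    "converged": self.converged,
                    "boundary": self.boundary,
                    "pe2_profile_flatness": self.pe2_profile_flatness,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    def solutions_frame(self) -> pd.DataFrame:
        gen = self.solutions["genetic"]
        pe = self.solutions["pe"]
        df = gen.copy()
        if pe is not None:
            df = df.merge(pe, on="animal_id", how="left")
        return df


def restricted_loglik(
    frame: ModelFrame,
    K,
    T,
    Q,
    relationship_inv: np.ndarray,
    model: str = "rnam",
    include_pe: bool = True,
) -> float:
    """Restricted log-likelihood at fixed (K, T, Q) via the MME identities."""
    K = np.asarray(K, dtype=float)
    if np.linalg.eigvalsh(K).min() < -1e-8 * max(1.0, abs(K).max()):
        raise ValueError("K must be positive semidefinite")
    if include_pe:
        T = np.asarray(T, dtype=float)
        if np.linalg.eigvalsh(T).min() < -1e-8 * max(1.0, abs(T).max()):
            raise ValueError("T must be positive semidefinite")
    if np.min(np.asarray(Q, dtype=float)) <= 0:
        raise ValueError("residual variances must be positive")
    asm = _Assembly(frame, model, include_pe)
    _check_dims(asm, K, T, Q, relationship_inv)
    sign, logdetHinv = np.linalg.slogdet(relationship_inv)
    if sign <= 0:
        raise ValueError("relationship inverse must be positive definite")
    st = _evaluate(asm, K, T if include_pe else None, Q, relationship_inv, -logdetHinv, derivatives=False)
    return st.loglik


def _check_dims(asm: _Assembly, K, T, Q, Hinv):
    if np.asarray(K).shape != (asm.k_g, asm.k_g):
        raise ValueError(f"K must be {asm.k_g}x{asm.k_g} for model {asm.model!r}")
    if asm.k_pe and np.asarray(T).shape != (asm.k_pe, asm.k_pe):
        raise ValueError(f"T must be {asm.k_pe}x{asm.k_pe}")
    if len(np.atleast_1d(Q)) != asm.n_traits:
        raise ValueError(f"Q must have {asm.n_traits} entries")
    if Hinv.shape != (asm.n_ped, asm.n_ped):
        raise ValueError("relationship inverse does not match the frame's animal_order")


def _default_init(asm: _Assembly):
    v1 = float(np.var(asm.frame.y1))
    K = np.eye(asm.k_g)
    T = np.eye(asm.k_pe) if asm.k_pe else None
    scale = [0.15 * v1, 0.1 * v1]
    if asm.frame.bivariate:
        v2 = float(np.var(asm.frame.y2))
        scale.append(0.3 * v2)
    if asm.model == "am":
        scale = [scale[0]] + scale[2:] if asm.frame.bivariate else [scale[0]]
    for i, s in enumerate(scale):
        K[i, i] = max(s, 1e-6)
        if T is not None:
            T[i, i] = max(0.5 * s, 1e-6)
    Q = np.array([0.5 * v1] + ([0.4 * float(np.var(asm.frame.y2))] if asm.frame.bivariate else []))
    return K, T, Q


def reml_fit(
    frame: ModelFrame,
    relationship_inv: np.ndarray,
    init=None,
    tol: float = 1e-8,
    max_iter: int = 500,
    model: str = "rnam",
    include_pe: bool = True,
    relationship: Optional[np.ndarray] = None,
    algorithm: str = "ai-em",
    loglik_tol: float = 1e-3,
    verbose: bool = False,
) -> FitResult:
    """Fit the reaction-norm (or plain) animal model by AI-REML.

    AI steps are taken on the (co)variance entries; whenever a step leaves
    the PSD cone (after an eigenvalue-floor projection attempt) or lowers
    the restricted likelihood, the iteration falls back to an EM-REML
    update, which never decreases it. Convergence is declared when the
    largest relative parameter change drops below ``tol``. ``relationship``
    (dense H) is only needed for AI steps and is obtained by inverting
    ``relationship_inv`` when not supplied. ``algorithm`` is "ai-em"
    (default) or "em" (pure EM, used mostly for diagnostics).

    Two stopping rules apply: the primary one on the largest relative
    parameter change (``tol``), and a likelihood-stall rule (three
    consecutive iterations improving the restricted log-likelihood by less
    than ``loglik_tol``) that ends the slow crawl along flat ridges — the
    pe2/e2 split of a single-record trait, or a variance pinned at the
    zero boundary — where parameters drift while the likelihood is done.
    """
    asm = _Assembly(frame, model, include_pe)
    if init is None:
        K, T, Q = _default_init(asm)
    else:
        K, T, Q = init
        K = np.asarray(K, dtype=float).copy()
        T = None if (T is None or not include_pe) else np.asarray(T, dtype=float).copy()
        Q = np.atleast_1d(np.asarray(Q, dtype=float)).copy()
    _check_dims(asm, K, T, Q, relationship_inv)
    sign, logdetHinv = np.linalg.slogdet(relationship_inv)
    if sign <= 0:
        raise ValueError("relationship inverse must be positive definite")
    logdetH = -logdetHinv
    H = None
    if algorithm == "ai-em":
        H = relationship if relationship is not None else np.linalg.inv(relationship_inv)

    # per-trait residual floors: keep the MME conditioned even when a
    # residual runs to its boundary along the pe/e ridge of a
    # single-record trait
    q_floor = 1e-6 * np.array(
        [float(np.var(asm.frame.y1))]
        + ([float(np.var(asm.frame.y2))] if asm.n_traits == 2 else [])
    )
    q_floor = np.maximum(q_floor, 1e-12)
    # characteristic scale per parameter (geometric mean of the initial
    # block variances), so relative change is well defined for covariances
    # that start or pass through zero
    scale_ref = np.empty(len(_param_list(asm)))
    for i, (blk, a, b) in enumerate(_param_list(asm)):
        if blk == "K":
            scale_ref[i] = np.sqrt(max(K[a, a] * K[b, b], 1e-16))
        elif blk == "T":
            scale_ref[i] = np.sqrt(max(T[a, a] * T[b, b], 1e-16))
        else:
            scale_ref[i] = max(Q[a], 1e-16)

    def valid(Kn, Tn, Qn):
        if np.any(Qn < q_floor):
            return False
        if np.linalg.eigvalsh(Kn).min() < -1e-9 * max(1.0, np.abs(Kn).max()):
            return False
        if asm.k_pe and np.linalg.eigvalsh(Tn).min() < -1e-9 * max(1.0, np.abs(Tn).max()):
            return False
        return True

    st = _evaluate(asm, K, T, Q, relationship_inv, logdetH)
    converged = False
    n_iter = 0
    stall = 0
    n_em_warmup = 2 if algorithm == "ai-em" else max_iter
    damp_ladder = (0.0, 0.1, 1.0, 10.0, 100.0, 1000.0)
    last_damp = 0  # index into damp_ladder that last produced an uphill step
    ai_cooldown = 0  # skip AI for a few iterations after a total rejection
    for it in range(1, max_iter + 1):
        n_iter = it
        theta = _pack(asm, K, T, Q)
        step_kind = "EM"
        Kn = Tn = Qn = st_new = None
        if algorithm == "ai-em" and it > n_em_warmup and ai_cooldown == 0:
            try:
                scores, AI = _scores_and_ai(asm, st, K, T, Q, H)
                # the AI matrix is near-singular along weakly identified
                # directions (e.g. the pe2/e2 ridge); escalate
                # Levenberg-Marquardt damping until the step improves the
                # restricted likelihood, resuming at the damping that
                # worked last to avoid wasted trial factorizations
                D = np.diag(np.maximum(np.diag(AI), 1e-12 * max(AI.max(), 1.0)))
                eps = 1e-10 * max(AI.max(), 1.0) * np.eye(len(AI))
                start = 0 if last_damp == 0 else max(last_damp - 1, 0)
                for idamp in range(start, len(damp_ladder)):
                    damp = damp_ladder[idamp]
                    try:
                        delta = np.linalg.solve(AI + damp * D + eps, scores)
                    except np.linalg.LinAlgError:
                        continue
                    Kc, Tc, Qc = _unpack(asm, theta + delta)
                    Kc = _floor_psd(Kc)
                    Tc = _floor_psd(Tc) if asm.k_pe else None
                    Qc = np.maximum(Qc, q_floor)
                    if not valid(Kc, Tc, Qc):
                        continue
                    try:
                        st_c = _evaluate(asm, Kc, Tc, Qc, relationship_inv, logdetH, derivatives=False)
                    except np.linalg.LinAlgError:
                        continue
                    if st_c.loglik >= st.loglik - 1e-9 * (1 + abs(st.loglik)):
                        Kn, Tn, Qn, st_new = Kc, Tc, Qc, st_c
                        step_kind = "AI" if damp == 0.0 else f"AI~{damp}"
                        last_damp = idamp
                        break
                if Kn is None:
                    ai_cooldown = 2
                    last_damp = len(damp_ladder) - 1
            except np.linalg.LinAlgError:
                ai_cooldown = 2
        elif ai_cooldown:
            ai_cooldown -= 1
        if Kn is None:  # EM-REML fallback: monotone in the restricted likelihood
            Kn, Tn, Qn = _em_update(asm, st, relationship_inv, Q)
            Qn = np.maximum(Qn, q_floor)
            st_new = _evaluate(asm, Kn, Tn, Qn, relationship_inv, logdetH, derivatives=False)
            # over-relaxation: EM crawls geometrically along boundaries and
            # flat ridges, so try lengthening the step while it keeps paying
            delta_em = _pack(asm, Kn, Tn, Qn) - theta
            Kx, Tx, Qx = _unpack(asm, theta + 4.0 * delta_em)
            Kx = _floor_psd(Kx)
            Tx = _floor_psd(Tx) if asm.k_pe else None
            Qx = np.maximum(Qx, q_floor)
            if valid(Kx, Tx, Qx):
                try:
                    st_x = _evaluate(asm, Kx, Tx, Qx, relationship_inv, logdetH, derivatives=False)
                    if st_x.loglik > st_new.loglik:
                        Kn, Tn, Qn, st_new = Kx, Tx, Qx, st_x
                        step_kind = "EMx4"
                except np.linalg.LinAlgError:
                    pass
        _add_derivatives(asm, st_new, relationship_inv)
        theta_new = _pack(asm, Kn, Tn, Qn)
        rel_change = float(np.max(np.abs(theta_new - theta) / (np.abs(theta) + 1e-2 * scale_ref)))
        if verbose:
            print(f"iter {it:3d} [{step_kind:3s}] loglik={st_new.loglik:.6f} max-rel-change={rel_change:.2e}")
        gain = st_new.loglik - st.loglik
        K, T, Q, st = Kn, Tn, Qn, st_new
        if rel_change < tol:
            converged = True
            break
        stall = stall + 1 if abs(gain) < loglik_tol else 0
        if stall >= 2:
            converged = True
            break

    boundary = {}
    for lbl, i in zip(asm.gen_labels, range(asm.k_g)):
        boundary[f"var_{lbl}"] = bool(K[i, i] < 1e-6 * max(np.trace(K) / asm.k_g, 1e-12))
    gs, ps = asm.gs, asm.ps
    beta = dict(zip(list(frame.fixed_names1) + [f"{frame.trait_name}:{x}" for x in frame.fixed_names2], st.sol[: asm.p_fixed]))
    gen = pd.DataFrame({"animal_id": frame.animal_order})
    Ug = st.sol[gs : gs + asm.k_g * asm.n_ped].reshape(asm.k_g, asm.n_ped)
    for c, lbl in enumerate(asm.gen_labels):
        gen[lbl] = Ug[c]
    pe = None
    if asm.k_pe:
        pe = pd.DataFrame({"animal_id": frame.pe_animal_order})
        Upe = st.sol[ps : ps + asm.k_pe * asm.n_pe].reshape(asm.k_pe, asm.n_pe)
        for c, lbl in enumerate(asm.gen_labels):
            pe[f"pe_{lbl}"] = Upe[c]

    flat = None
    if include_pe and frame.bivariate:
        # profile flatness of the pe2/e2 split: shift 5% of var_e2 into
        # var_pe2 and record the log-likelihood drop (near-zero = flat ridge)
        shift = 0.05 * Q[-1]
        T_alt = T.copy()
        T_alt[-1, -1] += shift
        Q_alt = Q.copy()
        Q_alt[-1] -= shift
        if Q_alt[-1] > q_floor[-1]:
            st_alt = _evaluate(asm, K, T_alt, Q_alt, relationship_inv, logdetH, derivatives=False)
            flat = float(st.loglik - st_alt.loglik)

    return FitResult(
        model=model,
        K=K,
        T=T,
        Q=Q,
        gen_labels=asm.gen_labels,
        loglik=float(st.loglik),
        n_iter=n_iter,
        converged=converged,
        boundary=boundary,
        solutions={"beta": beta, "genetic": gen, "pe": pe},
        frame_signature=frame.signature(),
        include_pe=include_pe,
        trait_name=frame.trait_name,
        pe2_profile_flatness=flat,
    )


def fit_animal_model(frame: ModelFrame, relationship_inv: np.ndarray, **kwargs) -> FitResult:
    """Plain animal model: the reaction-norm slope terms removed (2x2 K, T)."""
    kwargs.pop("model", None)
    return reml_fit(frame, relationship_inv, model="am", **kwargs)


@dataclass(frozen=True)
class REMLRTResult:
    chi2: float
    p_value: float
    df_pair: tuple = (5, 7)
    weights: tuple = (0.5, 0.5)


def mixture_chi2_sf(x: float, df_pair=(5, 7), weights=(0.5, 0.5)) -> float:
    """Survival function of the boundary-null chi-square mixture."""
    return float(sum(w * chi2_dist.sf(x, df) for w, df in zip(weights, df_pair)))


def remlrt(fit_rnam: FitResult, fit_am: FitResult) -> REMLRTResult:
    """REML ratio test of the reaction-norm model against the plain animal
    model: chi2 = (-2 loglik AM) - (-2 loglik RNAM), referred to the
    boundary mixture 0.5 chi2_5 + 0.5 chi2_7."""
    if fit_rnam.frame_signature != fit_am.frame_signature:
        raise ValueError("fits come from different model frames")
    if fit_rnam.model != "rnam" or fit_am.model != "am":
        raise ValueError("pass the reaction-norm fit first and the animal-model fit second")
    chi2 = fit_am.minus2loglik - fit_rnam.minus2loglik
    if chi2 < 0:
        # small negatives arise when the nested fits stop at slightly
        # different points of a flat ridge; anything larger means one fit
        # is genuinely unconverged
        if chi2 < -0.5:
            raise ValueError(f"nested-model likelihoods inconsistent (chi2 = {chi2})")
        chi2 = 0.0
    return REMLRTResult(chi2=float(chi2), p_value=mixture_chi2_sf(chi2))
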