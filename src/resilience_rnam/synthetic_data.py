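"""Synthetic pedigreed populations with daily feed intake and production traits.

The generator emulates the data structure of a nucleus pig-breeding test
station: batches of contemporaneous growing pigs on automatic feeders, a
daily feed intake (DFI) record per animal per day, a single record per
animal for a production trait, a multi-generation pedigree and SNP
genotypes. Day-to-day environmental challenges are latent binary states
whose signature is the within-batch-day coefficient of variation (CV) of
DFI: on "high CV" (challenge) days the log CV comes from the upper
component of a two-component Gaussian mixture.

Phenotypes follow the bivariate reaction-norm animal model exactly:

    dfi_{id} = mu1 + batch effect + a10_i + p_d a11_i + pe10_i + p_d pe11_i + e_{id}
    trait2_i = mu2 + batch effect + a2_i + pe2_i + e2_i

with (a10, a11, a2) ~ N(0, K x A) over the pedigree (A is the numerator
relationship matrix), permanent-environmental triples iid N(0, T), and
Gaussian residuals. ``day_cv_calibration`` controls whether the day's
residual variance is additionally scaled so the realized within-day CV
tracks the day's mixture draw (emulating real data, where challenge days
genuinely inflate within-day variation) or left homoscedastic (generating
exactly from the fitted model, as parameter-recovery studies require).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
import yaml

from .relationships import MISSING, GenotypeMatrix, pedigree_A

__all__ = [
    "MixtureSpec",
    "TrueParameters",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_environment",
    "simulate_phenotypes",
    "simulate_additional_trait",
    "derive_production_traits",
    "assign_batches",
    "write_dataset",
    "load_parameters",
]

# Default magnitudes: the DFI-AGE pair of the reference Piétrain evaluation
# (see reference_estimates); DFI mean 2.36 kg/day as in that population.
_DEFAULT_K = np.array(
    [
        [0.036, -0.021, -0.918],
        [-0.021, 0.087, 0.254],
        [-0.918, 0.254, 34.773],
    ]
)
_DEFAULT_T = np.array(
    [
        [0.030, -0.004, -0.836],
        [-0.004, 0.122, -0.776],
        [-0.836, -0.776, 30.422],
    ]
)


@dataclass(frozen=True)
class MixtureSpec:
    """Two-component Gaussian mixture of the log CV of DFI across days."""

    weights: tuple[float, float] = (0.7, 0.3)
    means: tuple[float, float] = (-1.5, -0.5)  # low CV days, high CV days
    sds: tuple[float, float] = (0.2, 0.25)

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.means[0] >= self.means[1]:
            raise ValueError("mixture component means must be distinct and ascending")
        if min(self.sds) <= 0:
            raise ValueError("mixture sds must be positive")

    def posterior_high(self, x) -> np.ndarray:
        """Posterior probability that log CV value(s) x belong to the
        higher-mean ('high CV day') component."""
        from scipy.stats import norm

        x = np.asarray(x, dtype=float)
        d0 = self.weights[0] * norm.pdf(x, self.means[0], self.sds[0])
        d1 = self.weights[1] * norm.pdf(x, self.means[1], self.sds[1])
        return d1 / (d0 + d1)


@dataclass
class TrueParameters:
    """Generating values of the reaction-norm model and the day mixture."""

    K: np.ndarray = field(default_factory=lambda: _DEFAULT_K.copy())
    T: np.ndarray = field(default_factory=lambda: _DEFAULT_T.copy())
    Q: tuple[float, float] = (0.175, 12.420)  # residual variances (DFI, trait2)
    mixture: MixtureSpec = field(default_factory=MixtureSpec)
    challenge_prevalence: float = 0.3
    mu_dfi: float = 2.36  # kg/day
    trait2_name: str = "AGE"
    mu_trait2: float = 135.10  # days at 100 kg for the default trait
    batch_sd_dfi: float = 0.10
    batch_sd_trait2: float = 2.0

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        for name, M in (("K", self.K), ("T", self.T)):
            if M.shape != (3, 3) or not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} must be a symmetric 3x3 matrix")
            if np.linalg.eigvalsh(M).min() < -1e-8 * max(1.0, abs(M).max()):
                raise ValueError(f"{name} must be positive semidefinite")
        if min(self.Q) < 0:
            raise ValueError("residual variances must be non-negative")
        if not 0.0 <= self.challenge_prevalence <= 1.0:
            raise ValueError("challenge_prevalence must be a probability")


def simulate_pedigree(
    n_founders: int, n_generations: int, offspring_per_mating: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Random-mating pedigree: columns animal_id, sire_id, dam_id, generation, sex.

    Founders (generation 0) have unknown parents (coded 0). Each later
    generation pairs the previous generation's males and females at random
    (no selfing possible since sexes differ) and each pair leaves
    ``offspring_per_mating`` offspring of random sex.
    """
    if n_founders < 2:
        raise ValueError("need at least two founders")
    if n_generations < 0 or offspring_per_mating < 1:
        raise ValueError("invalid counts")
    rng = np.random.default_rng(seed)
    rows = []
    next_id = 1
    males, females = [], []
    for f in range(n_founders):
        sex = "M" if f % 2 == 0 else "F"
        rows.append((next_id, 0, 0, 0, sex))
        (males if sex == "M" else females).append(next_id)
        next_id += 1
    for gen in range(1, n_generations + 1):
        if not males or not females:
            raise ValueError("a generation ran out of one sex; add founders")
        n_mat = min(len(males), len(females))
        sires = rng.permutation(np.array(males))[:n_mat]
        dams = rng.permutation(np.array(females))[:n_mat]
        males, females = [], []
        for s, d in zip(sires, dams):
            for _ in range(offspring_per_mating):
                sex = "M" if rng.random() < 0.5 else "F"
                rows.append((next_id, int(s), int(d), gen, sex))
                (males if sex == "M" else females).append(next_id)
                next_id += 1
    return pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id", "generation", "sex"])


def simulate_genotypes(
    pedigree: pd.DataFrame,
    n_snps: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-dropped biallelic genotypes: founders from Hardy-Weinberg at
    uniform allele frequencies in [maf_low, maf_high], descendants by
    Mendelian transmission of one allele per parent per SNP."""
    if len(pedigree) == 0:
        raise ValueError("empty pedigree")
    if not 0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng(seed)
    freq = rng.uniform(maf_low, maf_high, size=n_snps)
    ids = pedigree["animal_id"].to_numpy()
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    # track the two allele copies separately so transmission is Mendelian
    alleles = np.zeros((n, 2, n_snps), dtype=np.int8)
    for i in range(n):
        s, d = pedigree["sire_id"].iat[i], pedigree["dam_id"].iat[i]
        for k, parent in enumerate((s, d)):
            if parent in (0, None) or (isinstance(parent, float) and np.isnan(parent)):
                alleles[i, k] = rng.random(n_snps) < freq
            else:
                pg = alleles[pos[parent]]
                pick = (rng.random(n_snps) < 0.5).astype(np.int8)
                alleles[i, k] = pg[pick, np.arange(n_snps)]
    calls = alleles.sum(axis=1).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = MISSING
    return GenotypeMatrix(ids, np.array([f"snp{j + 1}" for j in range(n_snps)]), calls)


def simulate_environment(
    n_batches: int, days_per_batch: int, params: TrueParameters, seed: int = 0
) -> pd.DataFrame:
    """Latent challenge calendar: one row per batch-day with the binary
    challenge state, the day's log-CV draw from the corresponding mixture
    component, and ``true_p``, the Bayes posterior of the high-CV component
    at that draw (the quantity the descriptor stage estimates)."""
    mix = params.mixture
    rng = np.random.default_rng(seed)
    batch = np.repeat(np.arange(1, n_batches + 1), days_per_batch)
    day = np.tile(np.arange(1, days_per_batch + 1), n_batches)
    state = (rng.random(len(batch)) < params.challenge_prevalence).astype(int)
    mu = np.where(state == 1, mix.means[1], mix.means[0])
    sd = np.where(state == 1, mix.sds[1], mix.sds[0])
    log_cv = rng.normal(mu, sd)
    true_p = mix.posterior_high(log_cv)
    return pd.DataFrame(
        {
            "batch_id": batch,
            "day_index": day,
            "challenge_state": state,
            "log_cv_target": log_cv,
            "true_p": true_p,
        }
    )


def assign_batches(pedigree: pd.DataFrame, n_batches: int, generation: Optional[int] = None) -> dict:
    """Assign the (last) generation's animals to batches in id order."""
    gen = pedigree["generation"].max() if generation is None else generation
    animals = pedigree.loc[pedigree["generation"] == gen, "animal_id"].to_numpy()
    return {int(a): int(b) for a, b in zip(animals, np.arange(len(animals)) % n_batches + 1)}


class SimulatedPhenotypes(NamedTuple):
    dfi: pd.DataFrame
    traits: pd.DataFrame
    truth: dict  # sampled breeding values, pe effects and batch effects


def simulate_phenotypes(
    pedigree: pd.DataFrame,
    calendar: pd.DataFrame,
    params: TrueParameters,
    assignment: dict,
    seed: int = 0,
    day_cv_calibration: bool = True,
    A: Optional[np.ndarray] = None,
) -> SimulatedPhenotypes:
    """Draw breeding values, permanent-environmental effects and records.

    ``assignment`` maps animal_id -> batch_id for every recorded animal.
    With ``day_cv_calibration`` the day's residual standard deviation is
    scaled so the expected within-day CV matches the calendar's log-CV
    draw; without it residuals are homoscedastic at var_e1 (the fitted
    model's own assumption). Pass a precomputed ``A`` to skip rebuilding
    the numerator relationship matrix.
    """
    if not assignment:
        raise ValueError("assignment is empty")
    ids = pedigree["animal_id"].to_numpy()
    pos = {int(a): i for i, a in enumerate(ids)}
    missing = [a for a in assignment if int(a) not in pos]
    if missing:
        raise ValueError(f"assigned animals not in pedigree: {missing[:5]}")
    cal_batches = set(calendar["batch_id"].tolist())
    bad = {b for b in assignment.values() if b not in cal_batches}
    if bad:
        raise ValueError(f"animals assigned to batches without calendar days: {sorted(bad)[:5]}")

    rng = np.random.default_rng(seed)
    n = len(ids)
    if A is None:
        A = pedigree_A(pedigree)
    # (a10, a11, a2) ~ N(0, K (x) A): chol(A) Z chol(K)'
    LA = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    LK = _psd_cholesky(params.K)
    a = LA @ rng.standard_normal((n, 3)) @ LK.T

    rec_animals = np.array(sorted(int(x) for x in assignment))
    m = len(rec_animals)
    LT = _psd_cholesky(params.T)
    pe = rng.standard_normal((m, 3)) @ LT.T

    batches = sorted(cal_batches)
    b_dfi = dict(zip(batches, rng.normal(0.0, params.batch_sd_dfi, len(batches))))
    b_tr2 = dict(zip(batches, rng.normal(0.0, params.batch_sd_trait2, len(batches))))

    ve1, ve2 = params.Q
    cal = calendar.sort_values(["batch_id", "day_index"])
    by_batch = {int(b): g for b, g in cal.groupby("batch_id")}
    animal_batch = {int(a): int(assignment[a]) for a in rec_animals}
    rows_animal, rows_batch, rows_day, rows_dfi = [], [], [], []

    for b in batches:
        members = [a for a in rec_animals if animal_batch[a] == b]
        if not members:
            continue
        gidx = np.array([pos[a] for a in members])
        ridx = np.searchsorted(rec_animals, members)
        days = by_batch[int(b)]
        for day, p_d, log_cv in zip(
            days["day_index"].to_numpy(), days["true_p"].to_numpy(), days["log_cv_target"].to_numpy()
        ):
            u = a[gidx, 0] + p_d * a[gidx, 1] + pe[ridx, 0] + p_d * pe[ridx, 1]
            day_mean = params.mu_dfi + b_dfi[b]
            if day_cv_calibration and ve1 > 0:
                target_var = (np.exp(log_cv) * day_mean) ** 2
                v_between = u.var(ddof=1) if len(u) > 1 else 0.0
                lam = max((target_var - v_between) / ve1, 0.05)
            else:
                lam = 1.0
            e = rng.normal(0.0, np.sqrt(ve1 * lam), len(members)) if ve1 > 0 else 0.0
            y = day_mean + u + e
            rows_animal.extend(members)
            rows_batch.extend([b] * len(members))
            rows_day.extend([day] * len(members))
            rows_dfi.extend(np.atleast_1d(y))

    dfi = pd.DataFrame(
        {
            "animal_id": rows_animal,
            "batch_id": rows_batch,
            "day_index": rows_day,
            "dfi": rows_dfi,
        }
    )

    ridx_all = np.arange(m)
    gidx_all = np.array([pos[a] for a in rec_animals])
    e2 = rng.normal(0.0, np.sqrt(ve2), m) if ve2 > 0 else np.zeros(m)
    y2 = (
        params.mu_trait2
        + np.array([b_tr2[animal_batch[a]] for a in rec_animals])
        + a[gidx_all, 2]
        + pe[ridx_all, 2]
        + e2
    )
    traits = pd.DataFrame(
        {
            "animal_id": rec_animals,
            "trait": params.trait2_name,
            "value": y2,
            "batch_id": [animal_batch[a] for a in rec_animals],
        }
    )
    truth = {
        "animal_ids": ids,
        "a": a,
        "pe_animal_ids": rec_animals,
        "pe": pe,
        "batch_effects_dfi": b_dfi,
        "batch_effects_trait2": b_tr2,
        "seed": seed,
    }
    return SimulatedPhenotypes(dfi=dfi, traits=traits, truth=truth)


def _psd_cholesky(M: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerant of zero (boundary) variances."""
    M = np.asarray(M, dtype=float)
    if np.allclose(M, 0):
        return np.zeros_like(M)
    w, V = np.linalg.eigh(M)
    w = np.clip(w, 0.0, None)
    return V @ np.diag(np.sqrt(w))


def simulate_additional_trait(
    pedigree: pd.DataFrame,
    truth: dict,
    trait_name: str,
    K_pair: np.ndarray,
    T_pair: np.ndarray,
    var_e2: float,
    mu2: float,
    batch_sd: float,
    assignment: dict,
    seed: int = 0,
    A: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Single-record trait consistent with already-drawn DFI effects.

    Given the intercept/slope breeding values and permanent-environmental
    effects in ``truth`` (from :func:`simulate_phenotypes`), draws the
    trait's genetic and permanent-environmental effects from their exact
    conditional distribution under the pair's 3x3 covariances: with
    a ~ N(0, K (x) A), a2 | (a10, a11) has mean w'(a10_i, a11_i) with
    w = K_11^-1 k_12 and residual covariance (k22 - k12' K_11^-1 k12) A.
    This lets one simulated population serve several DFI-trait analyses.
    """
    K_pair = np.asarray(K_pair, dtype=float)
    T_pair = np.asarray(T_pair, dtype=float)
    rng = np.random.default_rng(seed)
    ids = pedigree["animal_id"].to_numpy()
    if A is None:
        A = pedigree_A(pedigree)
    n = len(ids)
    LA = np.linalg.cholesky(A + 1e-10 * np.eye(n))

    def conditional(effects2, S):
        w = np.linalg.solve(S[:2, :2], S[:2, 2])
        s2 = max(S[2, 2] - S[:2, 2] @ w, 0.0)
        return effects2 @ w, s2

    mean_a, s2_a = conditional(truth["a"][:, :2], K_pair)
    a2 = mean_a + np.sqrt(s2_a) * (LA @ rng.standard_normal(n))
    mean_pe, s2_pe = conditional(truth["pe"][:, :2], T_pair)
    pe2 = mean_pe + rng.normal(0.0, np.sqrt(s2_pe), len(mean_pe))

    rec_animals = truth["pe_animal_ids"]
    pos = {int(a): i for i, a in enumerate(ids)}
    gidx = np.array([pos[int(a)] for a in rec_animals])
    batches = sorted(set(assignment.values()))
    b_eff = dict(zip(batches, rng.normal(0.0, batch_sd, len(batches))))
    e2 = rng.normal(0.0, np.sqrt(var_e2), len(rec_animals)) if var_e2 > 0 else 0.0
    y2 = mu2 + np.array([b_eff[assignment[int(a)]] for a in rec_animals]) + a2[gidx] + pe2 + e2
    return pd.DataFrame(
        {
            "animal_id": rec_animals,
            "trait": trait_name,
            "value": y2,
            "batch_id": [assignment[int(a)] for a in rec_animals],
        }
    )


class ProductionTraits(NamedTuple):
    adg: float
    age: float
    bft: float
    lmt: float
    lmp: float


def derive_production_traits(
    age_initial: float,
    W_initial: float,
    W_final: float,
    age_final: float,
    BFT_test: float,
    LMT_test: float,
    beta_BFT: float,
    beta_LMT: float,
    G3: float,
    G4: float,
    M3: float,
    M4: float,
) -> ProductionTraits:
    """Standard growth-test trait derivations.

    ADG = (W_final - W_initial) / (age_final - age_initial)  [kg/day]
    AGE = age_initial + (100 - W_final) / ADG                [days at 100 kg]
    BFT = BFT_test + beta_BFT * (100 - W_final)              [mm at 100 kg]
    LMT = LMT_test + beta_LMT * (100 - W_final)              [mm at 100 kg]
    LMP = 60.12 - 0.487 G3 - 0.133 G4 + 0.111 M3 + 0.036 M4  [%]

    where G3/G4 are fat depths and M3/M4 muscle depths (mm) at the standard
    lumbar measurement sites.
    """
    if age_final <= age_initial:
        raise ValueError("age_final must exceed age_initial")
    if W_final <= W_initial:
        raise ValueError("W_final must exceed W_initial")
    adg = (W_final - W_initial) / (age_final - age_initial)
    if adg == 0:
        raise ZeroDivisionError("zero average daily gain; AGE undefined")
    age = age_initial + (100.0 - W_final) / adg
    bft = BFT_test + beta_BFT * (100.0 - W_final)
    lmt = LMT_test + beta_LMT * (100.0 - W_final)
    lmp = 60.12 - 0.487 * G3 - 0.133 * G4 + 0.111 * M3 + 0.036 * M4
    return ProductionTraits(adg=adg, age=age, bft=bft, lmt=lmt, lmp=lmp)


# -- IO ----------------------------------------------------------------------

def write_dataset(outdir, pedigree, dfi, traits, calendar, params: TrueParameters, seed: int) -> None:
    """Tidy CSV outputs plus YAML parameters and a JSON manifest with the seed."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pedigree[["animal_id", "sire_id", "dam_id"]].to_csv(outdir / "pedigree.csv", index=False)
    dfi.to_csv(outdir / "dfi.csv", index=False)
    traits.to_csv(outdir / "traits.csv", index=False)
    calendar.to_csv(outdir / "calendar.csv", index=False)
    with open(outdir / "parameters.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "K": params.K.tolist(),
                "T": params.T.tolist(),
                "Q": list(params.Q),
                "mixture": {
                    "weights": list(params.mixture.weights),
                    "means": list(params.mixture.means),
                    "sds": list(params.mixture.sds),
                },
                "challenge_prevalence": params.challenge_prevalence,
                "mu_dfi": params.mu_dfi,
                "trait2_name": params.trait2_name,
                "mu_trait2": params.mu_trait2,
                "batch_sd_dfi": params.batch_sd_dfi,
                "batch_sd_trait2": params.batch_sd_trait2,
            },
            fh,
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"seed": seed, "n_dfi_records": len(dfi), "n_trait_records": len(traits)}, fh)


def load_parameters(path) -> TrueParameters:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    mix = d.pop("mixture")
    return TrueParameters(
        K=np.array(d["K"]),
        T=np.array(d["T"]),
        Q=tuple(d["Q"]),
        mixture=MixtureSpec(
            weights=tuple(mix["weights"]), means=tuple(mix["means"]), sds=tuple(mix["sds"])
        ),
        challenge_prevalence=d["challenge_prevalence"],
        mu_dfi=d["mu_dfi"],
        trait2_name=d["trait2_name"],
        mu_trait2=d["mu_trait2"],
        batch_sd_dfi=d["batch_sd_dfi"],
        batch_sd_trait2=d["batch_sd_trait2"],
    )
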