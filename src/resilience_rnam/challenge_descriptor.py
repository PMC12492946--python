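"""Per batch-day probability of an unrecorded environmental challenge.

Within-batch, within-day variability of daily feed intake (DFI) across
animals is summarized by its coefficient of variation (CV); the natural
log of the CV across all batch-days is modelled as a two-component
Gaussian mixture fitted by EM. Days are then scored by the posterior
probability ``p`` of the higher-mean ("high CV", challenge) component,
which downstream serves as the continuous environmental descriptor of the
reaction-norm model. A parametric bootstrap of the likelihood-ratio
statistic checks that two components are really needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "DayCVResult",
    "MixtureFit",
    "daily_log_cv",
    "fit_gaussian_mixture",
    "posterior_challenge_probability",
    "bootstrap_component_test",
    "plot_mixture",
]

SD_FLOOR = 1e-4  # on the log CV scale; prevents component collapse


@dataclass
class DayCVResult:
    """Retained batch-day CVs plus a tally of excluded days by reason."""

    day_cv: pd.DataFrame  # batch_id, day_index, n_animals, cv, log_cv
    n_excluded_few_animals: int
    n_excluded_nonpositive_mean: int
    n_excluded_zero_cv: int


@dataclass
class MixtureFit:
    weights: np.ndarray  # (2,), sums to 1
    means: np.ndarray  # ascending; component 2 is the "high CV" one
    sds: np.ndarray
    responsibilities: np.ndarray  # (n, 2), rows sum to 1
    loglik: float
    n_iter: int
    converged: bool

    def posterior_high(self, x) -> np.ndarray:
        """Posterior probability of the higher-mean component at value(s) x."""
        x = np.asarray(x, dtype=float)
        lo = np.log(self.weights)[:, None] + norm.logpdf(x[None, :], self.means[:, None], self.sds[:, None])
        return np.exp(lo[1] - logsumexp(lo, axis=0))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "weights": self.weights.tolist(),
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "loglik": self.loglik,
                    "n_iter": self.n_iter,
                    "converged": self.converged,
                },
                fh,
                indent=2,
            )


def daily_log_cv(records: pd.DataFrame, min_animals: int = 5) -> DayCVResult:
    """CV of DFI across animals per batch-day and its natural log.

    The CV uses the sample standard deviation (n-1 denominator) over the
    day's mean. Days with fewer than ``min_animals`` records, a
    non-positive mean, or zero dispersion (log CV undefined) are excluded
    and counted. ``min_animals`` defaults to 5 because the CV of fewer
    observations is too unstable to classify a day.
    """
    if min_animals < 2:
        raise ValueError("min_animals must be at least 2")
    g = records.groupby(["batch_id", "day_index"])["dfi"]
    stats = g.agg(n_animals="count", mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()
    few = stats["n_animals"] < min_animals
    nonpos = ~few & (stats["mean"] <= 0)
    zero = ~few & ~nonpos & (stats["sd"] <= 0)
    keep = ~(few | nonpos | zero)
    if not keep.any():
        raise ValueError("every batch-day was excluded; nothing to fit")
    out = stats.loc[keep, ["batch_id", "day_index", "n_animals"]].copy()
    out["cv"] = (stats.loc[keep, "sd"] / stats.loc[keep, "mean"]).to_numpy()
    out["log_cv"] = np.log(out["cv"].to_numpy())
    return DayCVResult(
        day_cv=out.reset_index(drop=True),
        n_excluded_few_animals=int(few.sum()),
        n_excluded_nonpositive_mean=int(nonpos.sum()),
        n_excluded_zero_cv=int(zero.sum()),
    )


def _em(x, w, mu, sd, tol, max_iter, sd_floor):
    """EM iterations for a univariate 2-component Gaussian mixture.

    Returns (w, mu, sd, resp, loglik, n_iter, converged) or None if a
    component's variance collapsed.
    """
    n = len(x)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        logp = np.log(w)[:, None] + norm.logpdf(x[None, :], mu[:, None], sd[:, None])
        ll_terms = logsumexp(logp, axis=0)
        ll = float(ll_terms.sum())
        resp = np.exp(logp - ll_terms)  # (2, n)
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-10):
            return None
        w = nk / n
        mu = (resp @ x) / nk
        sd = np.sqrt((resp @ x**2) / nk - mu**2)
        if np.any(sd < sd_floor):
            return None
        if ll - ll_old < tol and it > 1:
            return w, mu, sd, resp.T, ll, it, True
        ll_old = ll
    # report the loglik consistent with the returned parameters
    logp = np.log(w)[:, None] + norm.logpdf(x[None, :], mu[:, None], sd[:, None])
    ll_terms = logsumexp(logp, axis=0)
    resp = np.exp(logp - ll_terms)
    return w, mu, sd, resp.T, float(ll_terms.sum()), max_iter, False


def fit_gaussian_mixture(
    values,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_starts: int = 10,
    seed: int | None = None,
    sd_floor: float = SD_FLOOR,
    force_equal_components: bool = False,
) -> MixtureFit:
    """Best-of-``n_starts`` EM fit of a 2-component Gaussian mixture.

    The first start splits the data at its median (low half -> component 1,
    high half -> component 2); further starts perturb that split randomly.
    Components are stored with means ascending so component 2 is always
    the high-CV one. With ``force_equal_components`` both components are
    pinned to a common mean and sd, which reduces the fit to the pooled
    single-Gaussian maximum likelihood (useful as a degenerate reference).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 observations to fit the mixture")
    if force_equal_components:
        mu, sd = x.mean(), x.std(ddof=0)
        w = np.array([0.5, 0.5])
        means, sds = np.array([mu, mu]), np.array([sd, sd])
        ll = float(norm.logpdf(x, mu, sd).sum())
        resp = np.full((len(x), 2), 0.5)
        return MixtureFit(w, means, sds, resp, ll, 0, True)

    rng = np.random.default_rng(seed)
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if len(hi) == 0:  # all values tied at the median
        lo, hi = x[: len(x) // 2], x[len(x) // 2 :]
    base = (
        np.array([0.5, 0.5]),
        np.array([lo.mean(), hi.mean()]),
        np.maximum(np.array([lo.std() or x.std() or 1.0, hi.std() or x.std() or 1.0]), sd_floor),
    )
    best = None
    for start in range(n_starts):
        if start == 0:
            w0, mu0, sd0 = (a.copy() for a in base)
        else:
            w0 = np.array([0.5, 0.5])
            mu0 = np.sort(base[1] + rng.normal(0, x.std() or 1.0, 2))
            sd0 = np.maximum(base[2] * rng.uniform(0.5, 2.0, 2), sd_floor)
        res = _em(x, w0, mu0, sd0, tol, max_iter, sd_floor)
        if res is None:
            continue
        if best is None or res[4] > best[4]:
            best = res
    if best is None:
        raise RuntimeError("all EM restarts collapsed to a degenerate fit")
    w, mu, sd, resp, ll, it, conv = best
    order = np.argsort(mu)
    return MixtureFit(w[order], mu[order], sd[order], resp[:, order], ll, it, conv)


def posterior_challenge_probability(fit: MixtureFit, day_cv: pd.DataFrame) -> pd.DataFrame:
    """Environmental descriptor: p = posterior of the high-CV component per day."""
    if not fit.converged:
        raise ValueError("mixture fit did not converge; refuse to score days")
    out = day_cv[["batch_id", "day_index"]].copy()
    out["p"] = fit.posterior_high(day_cv["log_cv"].to_numpy())
    return out


def _normal_mle_loglik(x) -> tuple[float, float, float]:
    mu, sd = x.mean(), x.std(ddof=0)
    return mu, sd, float(norm.logpdf(x, mu, sd).sum())


def bootstrap_component_test(
    values,
    n_bootstrap: int = 199,
    seed: int | None = None,
    n_starts: int = 4,
    max_retries: int = 3,
    em_tol: float = 1e-7,
    em_max_iter: int = 200,
) -> tuple[float, float]:
    """Parametric-bootstrap likelihood-ratio test of 2 vs 1 components.

    The observed statistic is 2*(loglik of the 2-component EM fit minus the
    single-Gaussian MLE loglik). Its null distribution is built by refitting
    both models on datasets simulated from the single-Gaussian MLE;
    p = (1 + #{bootstrap >= observed}) / (n_bootstrap + 1).
    """
    if n_bootstrap < 99:
        raise ValueError("use at least 99 bootstrap replicates")
    x = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)

    def lrt_stat(data, em_seed):
        # the same EM settings are used for the observed data and every
        # null replicate, so the comparison stays calibrated
        mu, sd, ll1 = _normal_mle_loglik(data)
        fit2 = fit_gaussian_mixture(data, n_starts=n_starts, seed=em_seed,
                                    tol=em_tol, max_iter=em_max_iter)
        return max(2.0 * (fit2.loglik - ll1), 0.0), mu, sd

    observed, mu0, sd0 = lrt_stat(x, rng.integers(2**31))
    null = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        for attempt in range(max_retries + 1):
            sim = rng.normal(mu0, sd0, len(x))
            try:
                null[b], _, _ = lrt_stat(sim, rng.integers(2**31))
                break
            except RuntimeError:
                if attempt == max_retries:
                    raise
    p_value = (1.0 + np.sum(null >= observed)) / (n_bootstrap + 1.0)
    return float(observed), float(p_value)


def plot_mixture(fit: MixtureFit, values, path) -> None:
    """Histogram of log CV with the fitted component and mixture densities."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(values, dtype=float)
    grid = np.linspace(x.min() - 0.5, x.max() + 0.5, 400)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(x, bins=40, density=True, alpha=0.4, color="grey")
    total = np.zeros_like(grid)
    for k in range(2):
        d = fit.weights[k] * norm.pdf(grid, fit.means[k], fit.sds[k])
        total += d
        ax.plot(grid, d, "--", label=f"component {k + 1}")
    ax.plot(grid, total, "k-", label="mixture")
    ax.set_xlabel("log CV of DFI")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
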