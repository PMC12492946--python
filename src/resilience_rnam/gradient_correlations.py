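"""Gradient-dependent genetic parameters of a linear reaction norm.

With breeding values decomposed into an intercept ``a10`` (merit at the
non-challenging reference, p = 0), a slope ``a11`` (environmental
sensitivity) and a correlated second trait ``a2``, the total breeding value
of daily feed intake at gradient value ``p`` is ``a1 = a10 + p * a11``.
Every quantity here is closed-form arithmetic on the 3x3 genetic
(co)variance matrix K over (a10, a11, a2):

* Var(a1)(p)   = s2_a10 + p^2 s2_a11 + 2 p cov(a10, a11)
* r(a1, a2)(p) = (cov(a10,a2) + p cov(a11,a2)) / sqrt(Var(a1)(p) s2_a2)
* r(a11, a2)   = cov(a11,a2) / sqrt(s2_a11 s2_a2)
* r(a1, a11)(p)= (cov(a10,a11) + p s2_a11) / sqrt(Var(a1)(p) s2_a11)
* p* = -cov(a10,a11) / s2_a11, the environmental-insensitivity point where
  intercept and slope are uncorrelated and Var(a1) is minimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "GeneticCovK",
    "Trajectory",
    "InsensitivityPoint",
    "total_genetic_variance",
    "correlation_dfi_trait",
    "correlation_slope_trait",
    "correlation_total_slope",
    "insensitivity_point",
    "default_p_grid",
    "write_trajectories",
    "plot_trajectories",
]

_PSD_TOL = 1e-8


@dataclass(frozen=True)
class GeneticCovK:
    """Genetic (co)variances over (intercept a10, slope a11, trait2 a2)."""

    var_a10: float
    var_a11: float
    var_a2: float
    cov_a10_a11: float
    cov_a10_a2: float
    cov_a11_a2: float

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.var_a10, self.cov_a10_a11, self.cov_a10_a2],
                [self.cov_a10_a11, self.var_a11, self.cov_a11_a2],
                [self.cov_a10_a2, self.cov_a11_a2, self.var_a2],
            ]
        )

    @classmethod
    def from_matrix(cls, K: np.ndarray) -> "GeneticCovK":
        K = np.asarray(K, dtype=float)
        if K.shape != (3, 3):
            raise ValueError(f"K must be 3x3, got {K.shape}")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("K must be symmetric")
        return cls(K[0, 0], K[1, 1], K[2, 2], K[0, 1], K[0, 2], K[1, 2])

    def validate_psd(self, tol: float = _PSD_TOL) -> None:
        w = np.linalg.eigvalsh(self.matrix)
        if w.min() < -tol * max(1.0, w.max()):
            raise ValueError(f"K is not positive semidefinite (eigenvalues {w})")


@dataclass(frozen=True)
class Trajectory:
    """One scalar quantity evaluated on an ordered grid of gradient values."""

    p_grid: np.ndarray
    values: np.ndarray
    quantity_name: str

    def __post_init__(self):
        p = np.asarray(self.p_grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if p.ndim != 1 or p.shape != v.shape:
            raise ValueError("p_grid and values must be 1-D with equal length")
        if np.any(np.diff(p) <= 0):
            raise ValueError("p_grid must be strictly increasing")
        object.__setattr__(self, "p_grid", p)
        object.__setattr__(self, "values", v)


class InsensitivityPoint(NamedTuple):
    p: float
    in_range: bool  # whether p falls inside [0, 1]


def default_p_grid(n: int = 101) -> np.ndarray:
    """Uniform grid on [0, 1]; 101 points resolve the curves to 0.01 in p."""
    return np.linspace(0.0, 1.0, n)


def _as_cov(K) -> GeneticCovK:
    if isinstance(K, GeneticCovK):
        return K
    return GeneticCovK.from_matrix(np.asarray(K))


def total_genetic_variance(K, p_grid=None) -> Trajectory:
    """Total additive genetic variance of DFI, Var(a10 + p a11), along p."""
    K = _as_cov(K)
    K.validate_psd()
    p = default_p_grid() if p_grid is None else np.asarray(p_grid, dtype=float)
    v = K.var_a10 + p**2 * K.var_a11 + 2.0 * p * K.cov_a10_a11
    return Trajectory(p, v, "total_genetic_variance_dfi")


def correlation_dfi_trait(K, p_grid=None) -> Trajectory:
    """Genetic correlation of the DFI total breeding value with trait 2 along p."""
    K = _as_cov(K)
    K.validate_psd()
    if K.var_a10 <= 0 or K.var_a11 <= 0 or K.var_a2 <= 0:
        raise ValueError("all three genetic variances must be positive")
    p = default_p_grid() if p_grid is None else np.asarray(p_grid, dtype=float)
    var_a1 = K.var_a10 + p**2 * K.var_a11 + 2.0 * p * K.cov_a10_a11
    r = (K.cov_a10_a2 + p * K.cov_a11_a2) / np.sqrt(var_a1 * K.var_a2)
    return Trajectory(p, r, "correlation_dfi_trait2")


def correlation_slope_trait(K) -> float:
    """Genetic correlation of the DFI slope (sensitivity) with trait 2."""
    K = _as_cov(K)
    if K.var_a11 <= 0 or K.var_a2 <= 0:
        raise ValueError("slope and trait variances must be positive")
    return K.cov_a11_a2 / np.sqrt(K.var_a11 * K.var_a2)


def correlation_total_slope(K, p_grid=None) -> Trajectory:
    """Genetic correlation of the DFI total breeding value with its slope along p."""
    K = _as_cov(K)
    K.validate_psd()
    if K.var_a10 <= 0 or K.var_a11 <= 0:
        raise ValueError("intercept and slope variances must be positive")
    p = default_p_grid() if p_grid is None else np.asarray(p_grid, dtype=float)
    var_a1 = K.var_a10 + p**2 * K.var_a11 + 2.0 * p * K.cov_a10_a11
    r = (K.cov_a10_a11 + p * K.var_a11) / np.sqrt(var_a1 * K.var_a11)
    return Trajectory(p, r, "correlation_dfi_slope")


def insensitivity_point(K) -> InsensitivityPoint:
    """Gradient value p* = -cov(a10,a11)/var(a11) where r(a10+p a11, a11) = 0.

    At p* the intercept is uncorrelated with the sensitivity slope and the
    total genetic variance is at its quadratic minimum. The value is
    returned unclipped; ``in_range`` flags whether it lies in [0, 1].
    """
    K = _as_cov(K)
    if K.var_a11 <= 0:
        raise ValueError("slope variance must be positive")
    p = -K.cov_a10_a11 / K.var_a11
    return InsensitivityPoint(float(p), bool(0.0 <= p <= 1.0))


def write_trajectories(path, trajectories) -> None:
    """Write trajectories sharing one grid as tidy CSV (p, one column each)."""
    import pandas as pd

    trajectories = list(trajectories)
    p = trajectories[0].p_grid
    data = {"p": p}
    for t in trajectories:
        if not np.array_equal(t.p_grid, p):
            raise ValueError("trajectories must share the same p grid")
        data[t.quantity_name] = np.round(t.values, 3)
    pd.DataFrame(data).to_csv(path, index=False)


def plot_trajectories(path, trajectories) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    trajectories = list(trajectories)
    fig, axes = plt.subplots(1, len(trajectories), figsize=(4 * len(trajectories), 3.2))
    if len(trajectories) == 1:
        axes = [axes]
    for ax, t in zip(axes, trajectories):
        ax.plot(t.p_grid, t.values)
        ax.set_xlabel("p (probability of a challenge)")
        ax.set_ylabel(t.quantity_name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
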