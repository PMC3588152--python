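"""Closed-form theory of the diversity-stability relationship.

Under two empirically supported scaling assumptions —

* Taylor's power law, ``v = a * m**b``, linking each species' temporal
  variance to its mean abundance, and
* overyielding, ``m_n(i) = m1(i) / n**x``, linking a species' mean in an
  ``n``-species mixture to its monoculture mean ``m1(i)`` —

the weighted mean species CV factorises into a diversity-independent
"average single-species variability" term and a *mean-abundance effect*
``n**(x*(2-b)/2)``, giving the community CV prediction

    CV_community(n) = sqrt(phi) * n**(x*(2-b)/2)
                      * sqrt(a) * sum_i m1_i**(b/2) / sum_i m1_i.

The mean-abundance effect is 1 whenever b = 2 (CV independent of mean), is
destabilising (increasing in n) when x > 0 and b < 2 or x < 0 and b > 2,
and stabilising otherwise.

When all species share the same variance, the synchrony index has the
closed form ``phi = (1 + (n - 1) * rho_bar) / n`` in terms of the mean
pairwise correlation; it declines asymptotically to ``rho_bar`` as
richness grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .community import CommunityMoments, validate_moments

__all__ = [
    "ScalingParams",
    "GradientSpec",
    "species_mean_at_diversity",
    "taylor_variance",
    "phi_closed_form",
    "perfect_asynchrony_phi",
    "mean_abundance_effect",
    "monoculture_weighted_cv",
    "community_cv_theory",
    "theoretical_moments",
    "equicorrelation_matrix",
    "DEFAULT_RICHNESS_GRID",
]

#: log-spaced default richness grid (figures in this field use a log axis)
DEFAULT_RICHNESS_GRID = (1, 2, 4, 8, 16, 32, 64)


@dataclass(frozen=True)
class ScalingParams:
    """Taylor coefficients (a, b) and overyielding exponent x.

    ``a > 0`` and ``b`` (typically 1-3) govern mean-variance scaling
    ``v = a*m**b``; ``x`` governs how mean abundances change with richness:
    x = 1 fixes total community abundance, x < 1 is overyielding (total
    abundance grows with diversity), x = 0 makes species means
    diversity-independent, x < 0 makes them increase, and x > 1 is
    underyielding.
    """

    a: float = 1.0
    b: float = 2.0
    x: float = 0.0

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"Taylor coefficient a must be positive, got {self.a}")


@dataclass(frozen=True)
class GradientSpec:
    """Description of a diversity gradient to evaluate or simulate.

    ``assembly`` controls which species of the pool enter an ``n``-species
    community: a fresh uniform random subset, or species added in order of
    increasing/decreasing mean abundance (mimicking succession-ordered
    addition). ``rho_model`` is one of ``"sampled"`` (random correlation
    matrices via the hyperspherical parameterisation),
    ``"perfect_synchrony"``, ``"perfect_asynchrony"``, or a float
    (constant pairwise correlation).
    """

    richness_grid: tuple = field(default=DEFAULT_RICHNESS_GRID)
    assembly: str = "random"
    rho_model: Union[str, float] = "sampled"

    def __post_init__(self):
        grid = tuple(int(n) for n in self.richness_grid)
        if any(n < 1 for n in grid) or list(grid) != sorted(set(grid)):
            raise ValueError("richness_grid must be increasing positive integers")
        object.__setattr__(self, "richness_grid", grid)
        if self.assembly not in ("random", "ordered_increasing", "ordered_decreasing"):
            raise ValueError(f"unknown assembly rule {self.assembly!r}")
        if isinstance(self.rho_model, str):
            if self.rho_model not in (
                "sampled",
                "perfect_synchrony",
                "perfect_asynchrony",
            ):
                raise ValueError(f"unknown rho_model {self.rho_model!r}")
        else:
            rho = float(self.rho_model)
            nmax = max(grid)
            lower = -1.0 / (nmax - 1) if nmax > 1 else -1.0
            if not (lower <= rho <= 1.0):
                raise ValueError(
                    f"constant correlation {rho} outside PSD bound "
                    f"[{lower:.4g}, 1] for richness up to {nmax}"
                )


def species_mean_at_diversity(m1: float, n: int, x: float) -> float:
    """Mean abundance of a species in an ``n``-species mixture: ``m1 / n**x``."""
    if m1 <= 0:
        raise ValueError(f"monoculture mean must be positive, got {m1}")
    if n < 1:
        raise ValueError(f"richness must be >= 1, got {n}")
    return m1 / n**x


def taylor_variance(m: float, a: float, b: float) -> float:
    """Temporal variance of abundance under Taylor's power law: ``a * m**b``."""
    if m <= 0:
        raise ValueError(f"mean abundance must be positive, got {m}")
    if a <= 0:
        raise ValueError(f"Taylor coefficient a must be positive, got {a}")
    return a * m**b


def phi_closed_form(n: int, rho_bar: float) -> float:
    """Synchrony index for equal species variances and mean pairwise
    correlation ``rho_bar``: ``(1 + (n - 1) * rho_bar) / n``.

    Returns 1 for a monoculture. ``rho_bar`` must respect the PSD bound
    ``-1/(n-1) <= rho_bar <= 1`` of an equicorrelation matrix.
    """
    if n < 1:
        raise ValueError(f"richness must be >= 1, got {n}")
    if n == 1:
        return 1.0
    lower = -1.0 / (n - 1)
    if rho_bar < lower - 1e-12 or rho_bar > 1 + 1e-12:
        raise ValueError(
            f"mean correlation {rho_bar} outside PSD bound [{lower:.6g}, 1] "
            f"for n = {n}"
        )
    return (1.0 + (n - 1) * min(max(rho_bar, lower), 1.0)) / n


def perfect_asynchrony_phi(n: int) -> float:
    """Synchrony index at the perfect-asynchrony limit: 1 in monoculture,
    0 for any n > 1 (the mean correlation sits at its lower bound
    ``-1/(n-1)``, so total abundance is constant)."""
    if n < 1:
        raise ValueError(f"richness must be >= 1, got {n}")
    return 1.0 if n == 1 else 0.0


def mean_abundance_effect(n: int, x: float, b: float) -> float:
    """Factor ``n**(x*(2-b)/2)`` by which diversity-driven changes in mean
    abundance scale the weighted mean species CV."""
    if n < 1:
        raise ValueError(f"richness must be >= 1, got {n}")
    return float(n) ** (x * (2.0 - b) / 2.0)


def monoculture_weighted_cv(m1, a: float, b: float) -> float:
    """Average single-species variability: the weighted mean monoculture CV
    ``sqrt(a) * sum_i m1_i**(b/2) / sum_i m1_i``."""
    m1 = np.asarray(m1, dtype=float).ravel()
    if m1.size == 0:
        raise ValueError("monoculture mean vector is empty")
    if (m1 <= 0).any():
        raise ValueError("monoculture means must be strictly positive")
    if a <= 0:
        raise ValueError(f"Taylor coefficient a must be positive, got {a}")
    return float(math.sqrt(a) * (m1 ** (b / 2.0)).sum() / m1.sum())


def community_cv_theory(n: int, phi: float, scaling: ScalingParams, m1) -> float:
    """Predicted community CV:
    ``sqrt(phi) * mean_abundance_effect(n, x, b) * monoculture_weighted_cv``.
    """
    if not (0.0 <= phi <= 1.0):
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    return (
        math.sqrt(phi)
        * mean_abundance_effect(n, scaling.x, scaling.b)
        * monoculture_weighted_cv(m1, scaling.a, scaling.b)
    )


def equicorrelation_matrix(n: int, rho: float) -> np.ndarray:
    """Correlation matrix with all off-diagonal entries equal to ``rho``."""
    if n < 1:
        raise ValueError(f"richness must be >= 1, got {n}")
    if n > 1:
        lower = -1.0 / (n - 1)
        if rho < lower - 1e-12 or rho > 1 + 1e-12:
            raise ValueError(
                f"correlation {rho} outside PSD bound [{lower:.6g}, 1] for n = {n}"
            )
    R = np.full((n, n), float(rho))
    np.fill_diagonal(R, 1.0)
    return R


def theoretical_moments(
    n: int,
    scaling: ScalingParams,
    m1,
    correlation: Union[np.ndarray, float],
) -> CommunityMoments:
    """Build exact community moments from the scaling laws.

    Species means are ``m1_i / n**x``, variances follow Taylor's law, and
    the covariance matrix is ``D R D`` with ``D = diag(sd)`` and ``R`` the
    given correlation matrix (a float is expanded to an equicorrelation
    matrix). The result validates, so a non-PSD ``R`` raises.
    """
    m1 = np.asarray(m1, dtype=float).ravel()
    if m1.size != n:
        raise ValueError(f"m1 has length {m1.size}, expected n = {n}")
    m = np.array([species_mean_at_diversity(v, n, scaling.x) for v in m1])
    sd = np.sqrt([taylor_variance(v, scaling.a, scaling.b) for v in m])
    if np.isscalar(correlation) or isinstance(correlation, float):
        R = equicorrelation_matrix(n, float(correlation))
    else:
        R = np.asarray(correlation, dtype=float)
        if R.shape != (n, n):
            raise ValueError(f"correlation matrix has shape {R.shape}, expected ({n}, {n})")
    V = R * np.outer(sd, sd)
    return validate_moments(CommunityMoments(m=m, V=V))
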