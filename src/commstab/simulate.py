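"""Stochastic community generation.

Synthetic communities are assembled from a species pool whose mean
abundances are lognormal (``exp(Normal(mu, sigma))``; ``sigma`` controls
unevenness), with species variances from Taylor's law and correlation
matrices drawn via the hyperspherical (Cholesky-angle) parameterisation:
each of the ``n(n-1)/2`` angles is uniform on ``[0, pi]``, which spans the
whole space of valid correlation matrices and gives an expected mean
pairwise correlation of zero at every richness and evenness. This isolates
the effect of unevenness on synchrony from any built-in correlation
structure.

Time series, when requested, are i.i.d. multivariate Gaussian draws around
the target moments — the framework only constrains stationary first and
second moments, so no temporal autocorrelation is imposed. Gaussian
marginals can dip below zero at individual time points; values are not
clipped by default because clipping biases the moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import AbundanceMatrix, CommunityMoments, MomentStructureError, validate_moments
from .estimators import evenness_evar, summarize
from .theory import (
    GradientSpec,
    ScalingParams,
    equicorrelation_matrix,
    theoretical_moments,
)

__all__ = [
    "CorrelationAngles",
    "LognormalPool",
    "angles_to_correlation",
    "sample_correlation",
    "sample_pool",
    "simulate_timeseries",
    "simulate_gradient",
]


@dataclass(frozen=True)
class CorrelationAngles:
    """Hyperspherical parameterisation of an ``n x n`` correlation matrix.

    ``theta`` holds the ``n(n-1)/2`` angles in ``[0, pi]`` row by row:
    angles for matrix row ``i`` (0-based, ``i >= 1``) occupy positions
    ``i(i-1)/2 .. i(i-1)/2 + i - 1``.
    """

    n: int
    theta: np.ndarray

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float).ravel()
        object.__setattr__(self, "theta", theta)
        expected = self.n * (self.n - 1) // 2
        if theta.size != expected:
            raise ValueError(
                f"expected {expected} angles for n = {self.n}, got {theta.size}"
            )
        if ((theta < 0) | (theta > math.pi)).any():
            raise ValueError("all angles must lie in [0, pi]")


@dataclass(frozen=True)
class LognormalPool:
    """Species pool with lognormal mean abundances.

    ``mu`` and ``sigma`` are the mean and standard deviation of log
    abundance; ``sigma = 0`` gives a perfectly even pool at ``exp(mu)``.
    """

    mu: float = 1.0
    sigma: float = 1.0
    pool_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.pool_size < 1:
            raise ValueError(f"pool_size must be >= 1, got {self.pool_size}")


def angles_to_correlation(angles: CorrelationAngles) -> np.ndarray:
    """Build the correlation matrix ``R = L L'`` from hyperspherical angles.

    ``L`` is lower triangular with unit-norm rows: ``L[0,0] = 1`` and for
    row ``i >= 1``, ``L[i,j] = cos(theta_ij) * prod_{k<j} sin(theta_ik)``
    for ``j < i`` and ``L[i,i] = prod_{k<i} sin(theta_ik)``. ``R`` has unit
    diagonal and is positive semi-definite for *any* angles in range.
    """
    n = angles.n
    L = np.zeros((n, n))
    L[0, 0] = 1.0
    pos = 0
    for i in range(1, n):
        prod = 1.0
        for j in range(i):
            th = angles.theta[pos + j]
            L[i, j] = math.cos(th) * prod
            prod *= math.sin(th)
        L[i, i] = prod
        pos += i
    R = L @ L.T
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return R


def sample_correlation(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a random correlation matrix: angles i.i.d. uniform on [0, pi].

    Over replicates the expected mean pairwise correlation is zero at any
    richness.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 to sample a correlation matrix, got {n}")
    theta = rng.uniform(0.0, math.pi, size=n * (n - 1) // 2)
    return angles_to_correlation(CorrelationAngles(n=n, theta=theta))


def sample_pool(pool: LognormalPool, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``pool_size`` lognormal mean abundances from the pool spec."""
    if rng is None:
        rng = np.random.default_rng(pool.seed)
    return np.exp(rng.normal(pool.mu, pool.sigma, size=pool.pool_size))


def simulate_timeseries(
    moments: CommunityMoments,
    T: int,
    rng: np.random.Generator,
    clip_zero: bool = False,
) -> AbundanceMatrix:
    """Draw ``T`` independent time points from a multivariate Gaussian with
    the community's mean vector and covariance matrix.

    Sample moments converge to the population moments as ``T`` grows. The
    covariance square root comes from an eigendecomposition with tiny
    negative eigenvalues (PSD tolerance) floored at zero.

    ``clip_zero=True`` truncates negative abundances at zero; this biases
    the sample moments upward/inward and is off by default.
    """
    if T < 3:
        raise ValueError(f"need T >= 3 time points, got {T}")
    moments = validate_moments(moments)
    eigvals, eigvecs = np.linalg.eigh(moments.V)
    if eigvals[-1] > 0 and eigvals[0] < -1e-8 * eigvals[-1]:
        raise MomentStructureError(
            f"covariance not PSD: smallest eigenvalue {eigvals[0]:.6g}"
        )
    root = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    z = rng.standard_normal(size=(T, moments.n))
    values = moments.m + z @ root.T
    if clip_zero:
        values = np.clip(values, 0.0, None)
    return AbundanceMatrix(values=values, species_ids=moments.species_ids)


def _select_subset(m1_pool: np.ndarray, n: int, assembly: str, rng) -> np.ndarray:
    if n > m1_pool.size:
        raise ValueError(
            f"richness {n} exceeds pool size {m1_pool.size}"
        )
    if assembly == "random":
        idx = rng.choice(m1_pool.size, size=n, replace=False)
        return m1_pool[idx]
    order = np.sort(m1_pool)
    if assembly == "ordered_increasing":
        return order[:n]
    if assembly == "ordered_decreasing":
        return order[::-1][:n]
    raise ValueError(f"unknown assembly rule {assembly!r}")


def _correlation_for(rho_model, n: int, rng) -> np.ndarray:
    if isinstance(rho_model, str):
        if rho_model == "sampled":
            return sample_correlation(n, rng) if n > 1 else np.ones((1, 1))
        if rho_model == "perfect_synchrony":
            return np.ones((n, n))
        if rho_model == "perfect_asynchrony":
            rho = -1.0 / (n - 1) if n > 1 else 1.0
            return equicorrelation_matrix(n, rho)
        raise ValueError(f"unknown rho_model {rho_model!r}")
    return equicorrelation_matrix(n, float(rho_model))


def simulate_gradient(
    pool: LognormalPool,
    grid: GradientSpec,
    scaling: ScalingParams,
    replicates: int = 200,
    seed: int = 0,
    timeseries_length: int | None = None,
    nested: bool = False,
) -> pd.DataFrame:
    """Assemble replicate communities along a richness gradient and
    summarise their stability.

    For each replicate a fresh pool of lognormal mean abundances is drawn;
    for each richness ``n`` a subset is selected per the assembly rule,
    species means follow the overyielding law ``m1/n**x``, variances follow
    Taylor's law, and the correlation matrix follows ``grid.rho_model``.
    Stability statistics are computed analytically from the constructed
    moments (no sampling noise); pass ``timeseries_length`` to instead
    estimate them from a finite simulated time series of that length.

    With ``nested=True`` subsets are nested across richness levels within a
    replicate (under random assembly); default is an independent subset at
    each richness.

    Returns a tidy DataFrame with one row per (replicate, n): columns
    ``replicate, n, phi, rho_bar, cv_community, cv_weighted, total_mean,
    e_var, cv_unweighted``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    master = np.random.SeedSequence(seed)
    rep_seqs = master.spawn(replicates)
    rows = []
    for r, rep_seq in enumerate(rep_seqs):
        n_seqs = rep_seq.spawn(len(grid.richness_grid) + 1)
        pool_rng = np.random.default_rng(n_seqs[0])
        m1_pool = sample_pool(pool, pool_rng)
        perm = None
        if nested and grid.assembly == "random":
            perm = pool_rng.permutation(m1_pool.size)
        for k, n in enumerate(grid.richness_grid):
            rng = np.random.default_rng(n_seqs[k + 1])
            if perm is not None:
                m1 = m1_pool[perm[:n]]
            else:
                m1 = _select_subset(m1_pool, n, grid.assembly, rng)
            R = _correlation_for(grid.rho_model, n, rng)
            moments = theoretical_moments(n, scaling, m1, R)
            if timeseries_length is not None:
                ts = simulate_timeseries(moments, timeseries_length, rng)
                from .community import moments_from_timeseries

                moments = moments_from_timeseries(ts)
            s = summarize(moments, validate=False)
            sd = np.sqrt(np.diag(moments.V))
            rows.append(
                {
                    "replicate": r,
                    "n": n,
                    "phi": s.phi,
                    "rho_bar": s.rho_bar,
                    "cv_community": s.cv_community,
                    "cv_weighted": s.cv_weighted,
                    "total_mean": s.total_mean,
                    "e_var": evenness_evar(m1).e_var if n > 1 else float("nan"),
                    "cv_unweighted": float(np.mean(sd / moments.m)),
                }
            )
    return pd.DataFrame(rows)
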