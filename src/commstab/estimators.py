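"""Empirical stability statistics for a community.

The central quantity is the synchrony index

    phi = v_c / (sum_i sd_i)^2

where ``v_c`` is the variance of total community abundance (the sum of all
entries of the covariance matrix ``V``) and the denominator is the variance
the community would have if all species fluctuated in perfect synchrony
(same species variances, all pairwise correlations one). ``phi`` ranges
from 0 (constant total abundance) to 1 (perfect synchrony) at any richness.

Two coefficients of variation connect population and community stability:
the community CV ``sqrt(v_c) / M`` (``M`` = total mean abundance) and the
abundance-weighted mean species CV ``sum_i sd_i / M``. They obey the exact
identity

    CV_community = sqrt(phi) * CV_weighted

so community variability is the product of a synchrony term and a
population-variability term, with no assumptions on evenness, variances or
correlations. Since phi <= 1, community variability never exceeds weighted
population variability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .community import CommunityMoments, MomentStructureError, validate_moments

__all__ = [
    "SynchronySummary",
    "TaylorFit",
    "EvennessValue",
    "CVDecomposition",
    "estimate_phi",
    "mean_correlation",
    "weighted_cv",
    "community_cv",
    "summarize",
    "fit_taylor",
    "evenness_evar",
    "decompose_cv",
]

#: phi values in (1, 1 + PHI_CLAMP_TOL] are clamped to 1 (rounding overshoot);
#: larger overshoot is an error. Same tolerance below 0.
PHI_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class SynchronySummary:
    """Bundle of community stability statistics.

    ``rho_bar`` is NaN for a monoculture (the mean pairwise correlation is
    only defined for n > 1).
    """

    n: int
    phi: float
    rho_bar: float
    cv_community: float
    cv_weighted: float
    total_mean: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TaylorFit:
    """Power-law fit of temporal variance against temporal mean, v = a * m^b.

    Fitted by ordinary least squares on log-log axes, the standard approach
    for mean-variance scaling. ``b_hat`` near 2 means CV is independent of
    mean abundance; ``b_hat`` < 2 means larger populations are relatively
    more stable.
    """

    a_hat: float
    b_hat: float
    r_squared: float
    n_species: int


@dataclass(frozen=True)
class EvennessValue:
    """Smith & Wilson's E_var evenness index, in (0, 1]; 1 = perfectly even."""

    e_var: float


@dataclass(frozen=True)
class CVDecomposition:
    """Decomposition of predicted community CV into synchrony, a
    mean-abundance effect ``n**(x*(2-b)/2)`` and average single-species
    (monoculture) variability."""

    phi: float
    mean_abundance_effect: float
    cv_monoculture_weighted: float
    cv_community_predicted: float


def _clamp_phi(phi: float) -> float:
    if phi > 1.0:
        if phi > 1.0 + PHI_CLAMP_TOL:
            raise MomentStructureError(
                f"synchrony index {phi!r} exceeds 1 beyond rounding tolerance"
            )
        return 1.0
    if phi < 0.0:
        if phi < -PHI_CLAMP_TOL:
            raise MomentStructureError(
                f"synchrony index {phi!r} is negative beyond rounding tolerance"
            )
        return 0.0
    return phi


def estimate_phi(moments: CommunityMoments) -> float:
    """Synchrony index: total community variance over its perfect-synchrony
    value ``(sum_i sd_i)**2``.

    Returns 1.0 for a monoculture. Values overshooting [0, 1] by less than
    ``PHI_CLAMP_TOL`` (floating-point rounding) are clamped.

    Raises
    ------
    ValueError
        If all species variances are zero (synchrony undefined for a
        constant community).
    """
    if moments.n == 1:
        return 1.0
    diag = np.diag(moments.V)
    denom = np.sqrt(diag).sum() ** 2
    if denom == 0.0:
        raise ValueError("synchrony undefined: all species variances are zero")
    return _clamp_phi(moments.total_variance / denom)


def mean_correlation(moments: CommunityMoments) -> float:
    """Unweighted mean of the n(n-1)/2 distinct pairwise Pearson
    correlations — the naive synchrony measure that, unlike phi, ignores
    differences in species variances.

    Raises
    ------
    ValueError
        For a monoculture (only defined for n > 1) or if any species
        variance is zero.
    """
    n = moments.n
    if n < 2:
        raise ValueError("mean correlation is only defined for n > 1")
    diag = np.diag(moments.V)
    if (diag <= 0).any():
        raise ValueError("mean correlation undefined: zero species variance")
    sd = np.sqrt(diag)
    corr = moments.V / np.outer(sd, sd)
    iu = np.triu_indices(n, k=1)
    return float(corr[iu].mean())


def weighted_cv(moments: CommunityMoments) -> float:
    """Mean species CV weighted by relative mean abundance,
    ``sum_i (m_i/M) * (sd_i/m_i)``, which collapses to
    ``sum_i sd_i / M``.

    More abundant populations contribute proportionally more; this is the
    population-variability term of the CV identity.
    """
    M = moments.total_mean
    if M <= 0:
        raise ValueError(f"total mean abundance must be positive, got {M}")
    return float(np.sqrt(np.diag(moments.V)).sum() / M)


def community_cv(moments: CommunityMoments) -> float:
    """Coefficient of variation of total community abundance,
    ``sqrt(sum of all entries of V) / M``."""
    M = moments.total_mean
    if M <= 0:
        raise ValueError(f"total mean abundance must be positive, got {M}")
    v_c = moments.total_variance
    if v_c < 0:
        scale = float(np.abs(moments.V).sum())
        if scale > 0 and -v_c > 1e-12 * scale:
            raise MomentStructureError(
                f"total community variance is negative: {v_c:.6g}"
            )
        v_c = 0.0
    return float(math.sqrt(v_c) / M)


def summarize(moments: CommunityMoments, validate: bool = True) -> SynchronySummary:
    """Compute the full set of stability statistics from moments."""
    if validate:
        moments = validate_moments(moments)
    n = moments.n
    diag = np.diag(moments.V)
    rho_bar = (
        float("nan")
        if n == 1 or (diag <= 0).any()
        else mean_correlation(moments)
    )
    return SynchronySummary(
        n=n,
        phi=estimate_phi(moments),
        rho_bar=rho_bar,
        cv_community=community_cv(moments),
        cv_weighted=weighted_cv(moments),
        total_mean=moments.total_mean,
    )


def fit_taylor(mean_variance_pairs) -> TaylorFit:
    """Fit Taylor's power law v = a * m^b across species by OLS of
    log variance on log mean.

    Parameters
    ----------
    mean_variance_pairs : iterable of (mean, variance)
        One pair per species; pairs with zero variance are dropped with a
        warning provided at least 3 positive pairs remain.

    Raises
    ------
    ValueError
        If fewer than 3 pairs with positive mean and variance are available.
    """
    pairs = np.asarray(list(mean_variance_pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected an iterable of (mean, variance) pairs")
    if (pairs[:, 0] <= 0).any():
        raise ValueError("Taylor fit requires strictly positive means")
    keep = pairs[:, 1] > 0
    if not keep.all():
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} species with zero variance "
            "from Taylor fit",
            stacklevel=2,
        )
        pairs = pairs[keep]
    if pairs.shape[0] < 3:
        raise ValueError(
            f"Taylor fit needs at least 3 species with positive mean and "
            f"variance, got {pairs.shape[0]}"
        )
    res = stats.linregress(np.log(pairs[:, 0]), np.log(pairs[:, 1]))
    return TaylorFit(
        a_hat=float(np.exp(res.intercept)),
        b_hat=float(res.slope),
        r_squared=float(res.rvalue**2) if not np.isnan(res.rvalue) else 1.0,
        n_species=int(pairs.shape[0]),
    )


def evenness_evar(m) -> EvennessValue:
    """Smith & Wilson's evenness index

        E_var = 1 - (2/pi) * arctan( var_n(ln m) )

    with the population (1/n) variance of log abundances. Equal abundances
    give 1; the index decreases towards 0 as the log-abundance spread grows.
    """
    m = np.asarray(m, dtype=float).ravel()
    if m.size < 2:
        raise ValueError("evenness requires at least 2 species")
    if (m <= 0).any():
        raise ValueError("evenness requires strictly positive abundances")
    logm = np.log(m)
    logvar = np.mean((logm - logm.mean()) ** 2)
    return EvennessValue(e_var=float(1.0 - (2.0 / math.pi) * math.atan(logvar)))


def decompose_cv(moments: CommunityMoments, scaling, monoculture_means) -> CVDecomposition:
    """Decompose predicted community CV into synchrony x mean-abundance
    effect x weighted monoculture CV.

    ``scaling`` supplies the Taylor coefficients (a, b) and the overyielding
    exponent x; ``monoculture_means`` are the species' mean abundances in
    monoculture (they cannot in general be inferred from mixture data, so
    they are explicit input). When the moments were built exactly from the
    same scaling law and monoculture means, the prediction equals the
    directly computed community CV.
    """
    from .theory import mean_abundance_effect, monoculture_weighted_cv

    m1 = np.asarray(monoculture_means, dtype=float).ravel()
    if m1.size != moments.n:
        raise MomentStructureError(
            f"monoculture_means has length {m1.size}, expected {moments.n}"
        )
    phi = estimate_phi(moments)
    mae = mean_abundance_effect(moments.n, scaling.x, scaling.b)
    cv1 = monoculture_weighted_cv(m1, scaling.a, scaling.b)
    return CVDecomposition(
        phi=phi,
        mean_abundance_effect=mae,
        cv_monoculture_weighted=cv1,
        cv_community_predicted=math.sqrt(phi) * mae * cv1,
    )
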