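"""Moment-level description of a community.

A community of ``n`` species fluctuating around a stochastic equilibrium
("stationarity") is summarised by the vector ``m`` of temporal mean
abundances and the temporal variance-covariance matrix ``V`` of abundances.
Every stability statistic in this package is a function of ``(m, V)``;
observed or simulated species-by-time tables are reduced to these moments
before anything else happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMoments",
    "AbundanceMatrix",
    "MomentStructureError",
    "validate_moments",
    "moments_from_timeseries",
]

#: relative tolerance on the smallest eigenvalue of V (scaled by the largest)
PSD_RTOL = 1e-8
#: relative tolerance on asymmetry of V before symmetrisation is refused
SYM_RTOL = 1e-10


class MomentStructureError(ValueError):
    """Raised when a variance-covariance matrix is structurally invalid
    (asymmetric beyond tolerance, or not positive semi-definite)."""


@dataclass(frozen=True)
class CommunityMoments:
    """First and second temporal moments of an ``n``-species community.

    Parameters
    ----------
    m : array of shape (n,)
        Temporal mean abundance of each species; strictly positive
        (coefficients of variation are undefined otherwise).
    V : array of shape (n, n)
        Temporal variances (diagonal) and covariances (off-diagonal) of
        species abundances. Symmetric positive semi-definite.
    species_ids : optional sequence of n labels.
    """

    m: np.ndarray
    V: np.ndarray
    species_ids: tuple = field(default=None)

    def __post_init__(self):
        object.__setattr__(self, "m", np.asarray(self.m, dtype=float).ravel())
        object.__setattr__(self, "V", np.atleast_2d(np.asarray(self.V, dtype=float)))
        if self.species_ids is not None:
            object.__setattr__(self, "species_ids", tuple(self.species_ids))

    @property
    def n(self) -> int:
        """Species richness."""
        return self.m.size

    @property
    def total_mean(self) -> float:
        """Temporal mean of total community abundance (sum of species means)."""
        return float(self.m.sum())

    @property
    def total_variance(self) -> float:
        """Variance of total community abundance (sum of all entries of V)."""
        return float(self.V.sum())


@dataclass(frozen=True)
class AbundanceMatrix:
    """A species-by-time abundance table (time in rows, species in columns).

    Requires at least 3 time points so that sample variances and
    correlations are estimable, and no missing entries. Individual values
    may be negative (e.g. Gaussian simulations); only species *means* must
    be positive for downstream statistics.
    """

    values: np.ndarray
    species_ids: tuple = None
    time_ids: tuple = None

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        T, n = values.shape
        if T < 3:
            raise ValueError(
                f"need at least 3 time points to estimate moments, got {T}"
            )
        if np.isnan(values).any():
            raise ValueError("abundance matrix contains missing values")
        if self.species_ids is None:
            object.__setattr__(
                self, "species_ids", tuple(f"sp{i + 1}" for i in range(n))
            )
        else:
            object.__setattr__(self, "species_ids", tuple(self.species_ids))
            if len(self.species_ids) != n:
                raise ValueError("species_ids length does not match columns")
        if self.time_ids is None:
            object.__setattr__(self, "time_ids", tuple(range(T)))
        else:
            object.__setattr__(self, "time_ids", tuple(self.time_ids))
            if len(self.time_ids) != T:
                raise ValueError("time_ids length does not match rows")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.time_ids), columns=list(self.species_ids)
        )


def validate_moments(
    moments: CommunityMoments,
    psd_rtol: float = PSD_RTOL,
    sym_rtol: float = SYM_RTOL,
) -> CommunityMoments:
    """Validate (and lightly repair) a :class:`CommunityMoments`.

    ``V`` is symmetrised by averaging with its transpose when the asymmetry
    is within ``sym_rtol`` (relative to the largest absolute entry); larger
    asymmetry raises :class:`MomentStructureError`. Positive
    semi-definiteness is checked as smallest eigenvalue >= -psd_rtol *
    largest eigenvalue — floating-point hygiene for the square roots taken
    downstream.

    Returns the validated moments (with symmetrised ``V``).

    Raises
    ------
    MomentStructureError
        If ``V`` has the wrong shape, is asymmetric beyond tolerance, is not
        PSD, or has a negative diagonal entry.
    ValueError
        If any species mean is non-positive.
    """
    m, V = moments.m, moments.V
    n = m.size
    if V.shape != (n, n):
        raise MomentStructureError(
            f"V has shape {V.shape}, expected ({n}, {n}) to match m"
        )
    scale = np.abs(V).max() if V.size else 0.0
    asym = np.abs(V - V.T).max()
    if scale > 0 and asym > sym_rtol * scale:
        raise MomentStructureError(
            f"V asymmetric: max|V - V.T| = {asym:.3g} exceeds tolerance"
        )
    V = 0.5 * (V + V.T)
    diag = np.diag(V)
    if (diag < 0).any():
        i = int(np.argmin(diag))
        raise MomentStructureError(
            f"negative variance {diag[i]:.3g} for species index {i}"
        )
    if n > 0 and scale > 0:
        eigvals = np.linalg.eigvalsh(V)
        if eigvals[0] < -psd_rtol * eigvals[-1]:
            raise MomentStructureError(
                f"V is not positive semi-definite: smallest eigenvalue "
                f"{eigvals[0]:.6g} (largest {eigvals[-1]:.6g})"
            )
    nonpos = np.flatnonzero(m <= 0)
    if nonpos.size:
        i = int(nonpos[0])
        label = moments.species_ids[i] if moments.species_ids else i
        raise ValueError(
            f"species {label!r} has non-positive mean abundance {m[i]:.3g}; "
            "coefficients of variation are undefined"
        )
    return CommunityMoments(m=m, V=V, species_ids=moments.species_ids)


def moments_from_timeseries(ts: AbundanceMatrix) -> CommunityMoments:
    """Estimate community moments from a species-by-time table.

    ``m`` is the vector of column means and ``V`` the sample covariance
    matrix with denominator ``T - 1`` (unbiased). Sample covariance matrices
    are PSD by construction, so the result always validates.

    Raises
    ------
    ValueError
        If any species has sample mean <= 0.
    """
    values = ts.values
    m = values.mean(axis=0)
    V = np.atleast_2d(np.cov(values, rowvar=False, ddof=1))
    return validate_moments(
        CommunityMoments(m=m, V=V, species_ids=ts.species_ids)
    )
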