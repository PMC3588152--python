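"""Model/Results interface for community stability analysis.

:class:`CommunityStability` wraps a species-by-time abundance table;
``fit()`` reduces it to temporal moments and returns a
:class:`CommunityStabilityResults` carrying the synchrony index, the
community and weighted-population CVs, an optional Taylor-law fit and the
E_var evenness of the mean abundances, with a ``summary()`` table in the
style of statsmodels. ``Results.simulate()`` draws new stationary time
series from the fitted moments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import AbundanceMatrix, CommunityMoments, moments_from_timeseries
from .estimators import (
    SynchronySummary,
    TaylorFit,
    evenness_evar,
    fit_taylor,
    summarize,
)
from .io import read_abundance_csv
from .simulate import simulate_timeseries


class CommunityStability:
    """Community stability model for a species-by-time abundance table.

    Parameters
    ----------
    endog : array-like of shape (T, n), AbundanceMatrix, or DataFrame
        Abundances with time in rows and species in columns; at least 3
        time points, no missing entries.
    species_ids, time_ids : optional labels (ignored when endog carries
        its own).

    Examples
    --------
    >>> model = CommunityStability.from_dataframe(df)
    >>> res = model.fit()
    >>> res.phi, res.cv_community
    """

    def __init__(self, endog, species_ids=None, time_ids=None):
        if isinstance(endog, AbundanceMatrix):
            self.data = endog
        elif isinstance(endog, pd.DataFrame):
            self.data = AbundanceMatrix(
                values=endog.to_numpy(dtype=float),
                species_ids=tuple(map(str, endog.columns)),
                time_ids=tuple(endog.index),
            )
        else:
            self.data = AbundanceMatrix(
                values=np.asarray(endog, dtype=float),
                species_ids=species_ids,
                time_ids=time_ids,
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CommunityStability":
        """Build from a DataFrame with time in the index and one species
        per column."""
        return cls(df)

    @classmethod
    def from_csv(cls, path, format: str = "auto") -> "CommunityStability":
        """Build from a wide or long abundance CSV (see :mod:`commstab.io`)."""
        return cls(read_abundance_csv(path, format=format))

    @property
    def n_species(self) -> int:
        return self.data.n_species

    @property
    def n_time(self) -> int:
        return self.data.n_time

    def fit(self, taylor: bool | None = None) -> "CommunityStabilityResults":
        """Estimate moments and stability statistics.

        ``taylor=None`` (default) fits Taylor's power law when at least 3
        species have positive mean and variance and skips it quietly
        otherwise; ``True`` forces the fit (raising if infeasible);
        ``False`` skips it.
        """
        moments = moments_from_timeseries(self.data)
        summary = summarize(moments, validate=False)
        pairs = list(zip(moments.m, np.diag(moments.V)))
        taylor_fit = None
        if taylor is not False:
            feasible = sum(1 for m, v in pairs if m > 0 and v > 0) >= 3
            if taylor is True or feasible:
                taylor_fit = fit_taylor(pairs)
        e_var = evenness_evar(moments.m).e_var if moments.n > 1 else float("nan")
        return CommunityStabilityResults(self, moments, summary, taylor_fit, e_var)


class CommunityStabilityResults:
    """Fitted stability statistics for one community.

    Attributes
    ----------
    moments : CommunityMoments
    phi, rho_bar, cv_community, cv_weighted, total_mean : float
        See :class:`commstab.estimators.SynchronySummary`.
    taylor : TaylorFit or None
    e_var : float
        Evenness of mean abundances (NaN for a monoculture).
    """

    def __init__(
        self,
        model: CommunityStability,
        moments: CommunityMoments,
        summary: SynchronySummary,
        taylor: TaylorFit | None,
        e_var: float,
    ):
        self.model = model
        self.moments = moments
        self._summary = summary
        self.taylor = taylor
        self.e_var = e_var

    n = property(lambda self: self._summary.n)
    phi = property(lambda self: self._summary.phi)
    rho_bar = property(lambda self: self._summary.rho_bar)
    cv_community = property(lambda self: self._summary.cv_community)
    cv_weighted = property(lambda self: self._summary.cv_weighted)
    total_mean = property(lambda self: self._summary.total_mean)

    def to_dict(self) -> dict:
        out = self._summary.to_dict()
        out["e_var"] = self.e_var
        if self.taylor is not None:
            out.update(
                taylor_a=self.taylor.a_hat,
                taylor_b=self.taylor.b_hat,
                taylor_r2=self.taylor.r_squared,
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])

    def simulate(self, T: int, seed=None) -> AbundanceMatrix:
        """Draw a stationary Gaussian time series of length ``T`` from the
        fitted moments."""
        rng = np.random.default_rng(seed)
        return simulate_timeseries(self.moments, T, rng)

    def plot(self, ax=None):
        """Plot the observed abundance time series (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.model.data
        for j, sp in enumerate(data.species_ids):
            ax.plot(range(data.n_time), data.values[:, j], label=str(sp))
        ax.plot(
            range(data.n_time),
            data.values.sum(axis=1),
            color="k",
            lw=2,
            label="total",
        )
        ax.set_xlabel("time")
        ax.set_ylabel("abundance")
        ax.legend(fontsize="small")
        return ax

    def summary(self) -> str:
        """Readable summary table of the fitted statistics."""
        s = self._summary
        lines = [
            "Community Stability Results",
            "=" * 44,
            f"{'No. species':<28}{s.n:>16d}",
            f"{'No. time points':<28}{self.model.n_time:>16d}",
            f"{'Synchrony index (phi)':<28}{s.phi:>16.4f}",
            f"{'Mean pairwise correlation':<28}{s.rho_bar:>16.4f}",
            f"{'Community CV':<28}{s.cv_community:>16.4f}",
            f"{'Weighted population CV':<28}{s.cv_weighted:>16.4f}",
            f"{'Total mean abundance':<28}{s.total_mean:>16.4f}",
            f"{'Evenness (E_var)':<28}{self.e_var:>16.4f}",
        ]
        if self.taylor is not None:
            t = self.taylor
            lines += [
                "-" * 44,
                "Taylor power law  v = a * m^b",
                f"{'  a':<28}{t.a_hat:>16.4f}",
                f"{'  b':<28}{t.b_hat:>16.4f}",
                f"{'  R-squared':<28}{t.r_squared:>16.4f}",
            ]
        lines.append("=" * 44)
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<CommunityStabilityResults n={self.n} phi={self.phi:.4f} "
            f"cv_community={self.cv_community:.4f}>"
        )
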