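"""Experiment drivers: tidy tables tracing how synchrony, the
mean-abundance effect, community CV and evenness behave along diversity
gradients.

Each driver returns a long-format DataFrame (one row per evaluated point)
so any plotting layer can reproduce the corresponding line plots. The CLI
writes them as CSV with the full configuration and seed embedded in
``#``-prefixed header lines, making re-runs with the same seed
byte-identical.

Default parameter grids: constant mean correlations {0.7, 0.1, 0} plus the
perfect-synchrony and perfect-asynchrony limits; Taylor exponents
b in {1.5, 2, 2.5} (below, at and above the CV-neutral value 2);
overyielding exponents x in {-0.5, 0, 0.5, 1, 1.5}, covering means that
increase with diversity, diversity-independence, overyielding,
constant-total-abundance and underyielding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .estimators import evenness_evar
from .simulate import LognormalPool, sample_pool, simulate_gradient
from .theory import (
    DEFAULT_RICHNESS_GRID,
    GradientSpec,
    ScalingParams,
    community_cv_theory,
    mean_abundance_effect,
    perfect_asynchrony_phi,
    phi_closed_form,
)

__all__ = [
    "ExperimentConfig",
    "EXPERIMENTS",
    "synchrony_richness_table",
    "mean_abundance_effect_table",
    "community_cv_table",
    "evenness_synchrony_table",
    "evenness_population_cv_table",
    "population_cv_richness_table",
    "evenness_overyielding_table",
    "run_experiment",
    "write_table",
]

DEFAULT_RHO_CURVES = ("perfect_synchrony", 0.7, 0.1, 0.0, "perfect_asynchrony")
DEFAULT_B_VALUES = (1.5, 2.0, 2.5)
DEFAULT_X_VALUES = (-0.5, 0.0, 0.5, 1.0, 1.5)
DEFAULT_SIGMA_LEVELS = (0.0, 0.5, 1.0, 2.0)


def _curve_label(rho) -> str:
    return rho if isinstance(rho, str) else f"rho={rho:g}"


def _curve_phi(rho, n: int) -> float:
    if rho == "perfect_synchrony":
        return 1.0
    if rho == "perfect_asynchrony":
        return perfect_asynchrony_phi(n)
    return phi_closed_form(n, float(rho))


def synchrony_richness_table(
    n_grid=DEFAULT_RICHNESS_GRID, rho_curves=DEFAULT_RHO_CURVES
) -> pd.DataFrame:
    """Closed-form synchrony index across a richness grid, one curve per
    correlation model (equal species variances assumed)."""
    rows = [
        {"n": n, "curve": _curve_label(rho), "phi": _curve_phi(rho, n)}
        for rho in rho_curves
        for n in n_grid
    ]
    return pd.DataFrame(rows)


def mean_abundance_effect_table(
    n_grid=DEFAULT_RICHNESS_GRID,
    b_values=DEFAULT_B_VALUES,
    x_values=DEFAULT_X_VALUES,
) -> pd.DataFrame:
    """Diversity-dependence of the mean-abundance effect n**(x(2-b)/2) over
    a (b, x) grid."""
    rows = [
        {
            "n": n,
            "b": b,
            "x": x,
            "mean_abundance_effect": mean_abundance_effect(n, x, b),
        }
        for b in b_values
        for x in x_values
        for n in n_grid
    ]
    return pd.DataFrame(rows)


def community_cv_table(
    n_grid=DEFAULT_RICHNESS_GRID,
    rho_curves=DEFAULT_RHO_CURVES,
    b_values=DEFAULT_B_VALUES,
    x_values=DEFAULT_X_VALUES,
    m1: float = 1.0,
    a: float = 1.0,
) -> pd.DataFrame:
    """Predicted community CV over the cross-product of synchrony curves and
    scaling grids, with equal monoculture means ``m1``."""
    rows = []
    for rho in rho_curves:
        for b in b_values:
            for x in x_values:
                scaling = ScalingParams(a=a, b=b, x=x)
                for n in n_grid:
                    phi = _curve_phi(rho, n)
                    rows.append(
                        {
                            "n": n,
                            "rho_curve": _curve_label(rho),
                            "b": b,
                            "x": x,
                            "phi": phi,
                            "cv_community": community_cv_theory(
                                n, phi, scaling, np.full(n, m1)
                            ),
                        }
                    )
    return pd.DataFrame(rows)


def evenness_synchrony_table(
    seed: int = 0,
    sigma_levels=DEFAULT_SIGMA_LEVELS,
    n_grid=DEFAULT_RICHNESS_GRID,
    replicates: int = 200,
    mu: float = 1.0,
    a: float = 1.0,
    pool_size: int = 256,
) -> pd.DataFrame:
    """Mean synchrony index versus richness for increasingly uneven pools
    (lognormal sigma levels), with hyperspherically sampled correlations
    and b = 2."""
    rows = []
    for i, sigma in enumerate(sigma_levels):
        df = simulate_gradient(
            LognormalPool(mu=mu, sigma=sigma, pool_size=pool_size),
            GradientSpec(richness_grid=tuple(n_grid), rho_model="sampled"),
            ScalingParams(a=a, b=2.0, x=0.0),
            replicates=replicates,
            seed=seed + i,
        )
        agg = df.groupby("n")["phi"].mean().reset_index()
        agg["sigma"] = sigma
        rows.append(agg)
    return pd.concat(rows, ignore_index=True)[["sigma", "n", "phi"]]


def evenness_population_cv_table(
    seed: int = 0,
    sigma_max: float = 3.0,
    sigma_steps: int = 13,
    n: int = 16,
    replicates: int = 200,
    mu: float = 1.0,
    a: float = 1.0,
    b_values=DEFAULT_B_VALUES,
) -> pd.DataFrame:
    """Weighted mean monoculture CV against evenness (E_var), for
    communities of fixed richness drawn at lognormal sigma in
    [0, sigma_max]."""
    rng = np.random.default_rng(seed)
    rows = []
    for sigma in np.linspace(0.0, sigma_max, sigma_steps):
        for r in range(replicates):
            m = sample_pool(LognormalPool(mu=mu, sigma=sigma, pool_size=n), rng)
            e_var = evenness_evar(m).e_var
            for b in b_values:
                cv = float(np.sqrt(a) * (m ** (b / 2.0)).sum() / m.sum())
                rows.append(
                    {
                        "sigma": sigma,
                        "replicate": r,
                        "b": b,
                        "e_var": e_var,
                        "cv_weighted": cv,
                    }
                )
    return pd.DataFrame(rows)


def population_cv_richness_table(
    seed: int = 0,
    sigma: float = 2.0,
    n_grid=DEFAULT_RICHNESS_GRID,
    replicates: int = 200,
    mu: float = 1.0,
    a: float = 1.0,
    b_values=DEFAULT_B_VALUES,
) -> pd.DataFrame:
    """Mean weighted population CV versus richness at x = 0 for Taylor
    exponents below, at and above 2 — the unevenness-driven trend."""
    rows = []
    for i, b in enumerate(b_values):
        df = simulate_gradient(
            LognormalPool(mu=mu, sigma=sigma, pool_size=256),
            GradientSpec(richness_grid=tuple(n_grid), rho_model="sampled"),
            ScalingParams(a=a, b=b, x=0.0),
            replicates=replicates,
            seed=seed + i,
        )
        agg = (
            df.groupby("n")[["cv_weighted", "cv_unweighted"]].mean().reset_index()
        )
        agg["b"] = b
        rows.append(agg)
    return pd.concat(rows, ignore_index=True)[
        ["b", "n", "cv_weighted", "cv_unweighted"]
    ]


def evenness_overyielding_table(
    seed: int = 0,
    sigma: float = 2.0,
    n_grid=DEFAULT_RICHNESS_GRID,
    replicates: int = 200,
    mu: float = 1.0,
    a: float = 1.0,
    x_values=(0.0, 0.5, 1.0),
    b_values=(1.5, 2.5),
) -> pd.DataFrame:
    """Mean weighted population CV versus richness for combinations of
    overyielding exponent x and Taylor exponent b, showing how unevenness
    and the mean-abundance effect can act in countervailing directions."""
    rows = []
    i = 0
    for x in x_values:
        for b in b_values:
            df = simulate_gradient(
                LognormalPool(mu=mu, sigma=sigma, pool_size=256),
                GradientSpec(richness_grid=tuple(n_grid), rho_model="sampled"),
                ScalingParams(a=a, b=b, x=x),
                replicates=replicates,
                seed=seed + i,
            )
            agg = df.groupby("n")["cv_weighted"].mean().reset_index()
            agg["x"] = x
            agg["b"] = b
            rows.append(agg)
            i += 1
    return pd.concat(rows, ignore_index=True)[["x", "b", "n", "cv_weighted"]]


#: registry of named experiments for the CLI
EXPERIMENTS = {
    "synchrony": synchrony_richness_table,
    "mean-abundance-effect": mean_abundance_effect_table,
    "community-cv": community_cv_table,
    "evenness-synchrony": evenness_synchrony_table,
    "evenness-population-cv": evenness_population_cv_table,
    "population-cv-richness": population_cv_richness_table,
    "evenness-overyielding": evenness_overyielding_table,
}

_STOCHASTIC = {
    "evenness-synchrony",
    "evenness-population-cv",
    "population-cv-richness",
    "evenness-overyielding",
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Name, parameter overrides, seed and output path for one experiment."""

    name: str
    overrides: dict = field(default_factory=dict)
    seed: int = 0
    output: str | None = None

    def __post_init__(self):
        if self.name not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.name!r}; choose from "
                f"{sorted(EXPERIMENTS)}"
            )


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run a named experiment and return its tidy table."""
    fn = EXPERIMENTS[config.name]
    kwargs = dict(config.overrides)
    if config.name in _STOCHASTIC:
        kwargs.setdefault("seed", config.seed)
    return fn(**kwargs)


def write_table(df: pd.DataFrame, config: ExperimentConfig, path) -> None:
    """Write a tidy table as CSV with the config embedded in comment lines,
    so the output is self-describing and byte-identical across re-runs."""
    meta = asdict(config)
    meta.pop("output", None)
    with open(path, "w") as fh:
        fh.write(f"# experiment: {config.name}\n")
        fh.write(f"# config: {json.dumps(meta, sort_keys=True)}\n")
        df.to_csv(fh, index=False)
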