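"""How many environments does a stable stability estimate need?

The procedure: fix a sampled population of genotypes (SPG), repeatedly
draw sampled populations of environments (SPE) of increasing size N_env,
recompute a stability index (typically the genotypic superiority measure
P_i) within every SPG-by-SPE subset, and summarize the sampling spread of
the index per genotype as the coefficient of variation across SPE
replicates.  CV falls with N_env approximately as a power law
``CV = α·N_env^β`` (β ≈ −1/2, the square-root law of a mean), and the
minimal N_env for a target precision is the smallest integer with
``α·N^β ≤ threshold``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import GxETable, substream
from .indices import compute_index
from .sampling import sample_environments

__all__ = [
    "index_over_spe",
    "cv_across_spe",
    "fit_power_law",
    "min_env_for_threshold",
    "PowerLawFit",
    "min_env_experiment",
]


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted CV = α·N^β with standard errors and original-scale R²."""

    alpha: float
    beta: float
    se_alpha: float = float("nan")
    se_beta: float = float("nan")
    r_squared: float = float("nan")
    genotype: str | None = None
    index_name: str | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")

    def predict(self, n_env) -> np.ndarray:
        return self.alpha * np.asarray(n_env, dtype=float) ** self.beta

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def index_over_spe(
    pool: GxETable,
    genotypes,
    n_env_grid,
    n_spe: int,
    index: str,
    seed: int,
    lambda_: float | None = None,
) -> pd.DataFrame:
    """Recompute one index over repeated environment draws.

    For every N_env in ``n_env_grid`` and each of ``n_spe`` independent
    SPE draws, the index is computed for every genotype of the SPG within
    that SPG-by-SPE subset (marginals included).  Returns a tidy frame
    with columns ``genotype``, ``n_env``, ``spe``, ``value``.  Grid points
    where the index's preconditions fail (e.g. deviation mean squares with
    fewer than three environments) are skipped with a warning.
    """
    genotypes = list(genotypes)
    env_pool = pool.environment_ids.to_numpy()
    if max(n_env_grid) > len(env_pool):
        raise ValueError("n_env grid exceeds the environment pool")
    records = []
    sub_rows = pool.data.loc[genotypes]
    for n_env in n_env_grid:
        for rep in range(n_spe):
            rng = substream(seed, "spe", int(n_env), rep)
            envs = sample_environments(env_pool, int(n_env), rng)
            table = GxETable(pool.trait, sub_rows[list(envs)], pool.units)
            try:
                values = compute_index(table, index, lambda_)
            except ValueError as exc:
                warnings.warn(
                    f"index {index} skipped at n_env={n_env}: {exc}", stacklevel=2
                )
                break
            records.append(
                pd.DataFrame(
                    {
                        "genotype": values.index,
                        "n_env": int(n_env),
                        "spe": rep,
                        "value": values.to_numpy(),
                    }
                )
            )
    if not records:
        raise ValueError("no grid point satisfied the index preconditions")
    return pd.concat(records, ignore_index=True)


def cv_across_spe(table: pd.DataFrame) -> pd.DataFrame:
    """Coefficient of variation of the index across SPE replicates.

    One row per (genotype, n_env) with the mean, sd (ddof=1) and
    CV = sd/mean over the SPE draws.  Cells whose mean is not positive get
    an undefined CV (NaN) and are flagged.
    """
    counts = table.groupby(["genotype", "n_env"])["value"].size()
    if (counts < 2).all():
        raise ValueError("CV across SPE needs at least 2 replicates per cell")
    g = table.groupby(["genotype", "n_env"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n_spe="size").reset_index()
    defined = out["mean"] > 0
    out["cv"] = np.where(defined, out["sd"] / out["mean"], np.nan)
    out["cv_defined"] = defined
    if (~defined).any():
        warnings.warn(
            f"CV undefined (mean <= 0) for {int((~defined).sum())} cells",
            stacklevel=2,
        )
    return out


def fit_power_law(
    curve: pd.DataFrame,
    genotype=None,
    index_name: str | None = None,
) -> PowerLawFit:
    """Nonlinear least-squares fit of CV = α·N_env^β for one genotype.

    Fitted on the original CV scale (not log–log); the log–log ordinary
    least-squares estimate only seeds the optimizer and serves as the
    fallback if the nonlinear fit does not converge (flagged).  R² is the
    original-scale coefficient of determination.
    """
    sub = curve if genotype is None else curve[curve["genotype"] == genotype]
    sub = sub.dropna(subset=["cv"])
    sub = sub[sub["cv"] > 0]
    if len(sub) < 3:
        raise ValueError("power-law fit needs >= 3 grid points with defined CV")
    n = sub["n_env"].to_numpy(dtype=float)
    cv = sub["cv"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(np.log(n), np.log(cv), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    converged = True
    try:
        popt, pcov = curve_fit(
            lambda x, a, b: a * x**b, n, cv, p0=p0, maxfev=10000
        )
        se = np.sqrt(np.diag(pcov))
    except RuntimeError:
        warnings.warn(
            "nonlinear power-law fit did not converge; using log-log estimate",
            stacklevel=2,
        )
        popt, se, converged = p0, (np.nan, np.nan), False
    pred = popt[0] * n ** popt[1]
    ss_res = float(np.sum((cv - pred) ** 2))
    ss_tot = float(np.sum((cv - cv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return PowerLawFit(
        alpha=float(popt[0]),
        beta=float(popt[1]),
        se_alpha=float(se[0]),
        se_beta=float(se[1]),
        r_squared=r2,
        genotype=genotype,
        index_name=index_name,
        converged=converged,
    )


def min_env_for_threshold(fit: PowerLawFit, threshold: float) -> int:
    """Smallest integer N_env with α·N^β ≤ threshold ("at least N environments").

    Closed form ``ceil((α/threshold)^(−1/β))``; a tiny tolerance keeps
    exact integer solutions from being rounded up spuriously.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if fit.beta >= 0:
        raise ValueError("beta must be negative for the CV to reach the threshold")
    n_star = (fit.alpha / threshold) ** (-1.0 / fit.beta)
    n = ceil(n_star - 1e-9)
    if n > 0 and fit.alpha * n**fit.beta > threshold * (1 + 1e-12):
        n += 1
    return max(n, 1)


def min_env_experiment(
    pool: GxETable,
    genotypes,
    n_env_grid,
    n_spe: int,
    seed: int,
    index: str = "superiority_measure",
    thresholds: tuple[float, ...] = (0.05, 0.10),
    lambda_: float | None = None,
    sqrt_index: bool = True,
    aggregate: str = "per_genotype",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full minimal-environment pipeline for one SPG.

    Returns the CV curve (per genotype and N_env) and a fit table with
    one row per genotype: α, β, their standard errors, R² and the minimal
    N_env for each requested CV threshold.  ``sqrt_index=True`` analyses
    the square-rooted index when it has squared trait units, matching the
    unit-consistency convention used everywhere else.  With
    ``aggregate="across_spg"`` the CV is instead taken over all genotypes
    and SPE jointly per N_env (a population-level variant), producing a
    single pooled fit.
    """
    from .indices import SQUARED_UNIT_INDICES

    values = index_over_spe(pool, genotypes, n_env_grid, n_spe, index, seed, lambda_)
    if sqrt_index and index in SQUARED_UNIT_INDICES:
        values = values.assign(value=np.sqrt(values["value"]))
    if aggregate == "across_spg":
        values = values.assign(genotype="__pooled__")
    elif aggregate != "per_genotype":
        raise ValueError("aggregate must be 'per_genotype' or 'across_spg'")
    curve = cv_across_spe(values)
    fits = []
    for g in curve["genotype"].unique():
        try:
            fit = fit_power_law(curve, g, index_name=index)
        except ValueError:
            continue
        row = asdict(fit)
        for thr in thresholds:
            try:
                row[f"min_n_env_at_{int(round(thr * 100))}pct"] = (
                    min_env_for_threshold(fit, thr)
                )
            except ValueError:
                row[f"min_n_env_at_{int(round(thr * 100))}pct"] = np.nan
        fits.append(row)
    return curve, pd.DataFrame(fits)
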