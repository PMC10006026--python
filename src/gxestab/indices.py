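"""Eleven per-genotype yield-stability indices for complete G-by-E tables.

Notation used throughout: a table holds trait values ``x_ij`` for genotype
``i`` in environment ``j``; ``x̄_i.`` is the genotype mean, ``x̄_.j`` the
environment mean, ``x̄_..`` the grand mean, and ``I_j = x̄_.j − x̄_..`` the
environment index of the joint-regression (Finlay–Wilkinson) analysis.

Two indices follow the *static* concept of stability (a stable genotype
keeps the same trait value everywhere): the environmental variance and the
adjusted coefficient of variation.  The remaining nine follow the *dynamic*
concept (a stable genotype tracks the environmental mean response):
coefficient of regression, coefficient of determination, deviation mean
squares, ecovalence (plus its environment-count-normalized variant),
genotypic stability, genotypic superiority measure, safety-first index,
stability variance and the nonparametric variance of rank.

All functions take a :class:`~gxestab.core.GxETable` and return a
``pandas.Series`` indexed by genotype.  Marginal means are always computed
within the table handed in — when indices are evaluated on a sampled
population, the sample itself defines the marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GxETable

__all__ = [
    "environmental_variance",
    "adjusted_cv",
    "coefficient_of_regression",
    "coefficient_of_determination",
    "deviation_mean_squares",
    "ecovalence",
    "genotypic_stability",
    "superiority_measure",
    "safety_first_index",
    "stability_variance",
    "variance_of_rank",
    "compute_all",
    "apply_unit_transform",
    "StabilityResult",
    "SQUARED_UNIT_INDICES",
    "EXTENDED_SQUARED_UNIT_INDICES",
    "ALL_INDICES",
]

#: indices whose units are the squared trait units; square-rooted by default
#: so that index-versus-trait relationships stay dimensionally linear
SQUARED_UNIT_INDICES = (
    "superiority_measure",
    "ecovalence",
    "ecovalence_modified",
    "variance_of_rank",
)

#: further squared-unit indices that may optionally be square-rooted
EXTENDED_SQUARED_UNIT_INDICES = SQUARED_UNIT_INDICES + (
    "environmental_variance",
    "deviation_mean_squares",
    "genotypic_stability",
    "stability_variance",
)

ALL_INDICES = (
    "environmental_variance",
    "adjusted_cv",
    "coefficient_of_regression",
    "coefficient_of_determination",
    "deviation_mean_squares",
    "ecovalence",
    "ecovalence_modified",
    "genotypic_stability",
    "superiority_measure",
    "safety_first_index",
    "stability_variance",
    "variance_of_rank",
)


def _values(t: GxETable) -> np.ndarray:
    return t.data.to_numpy(dtype=float)


def environmental_variance(t: GxETable) -> pd.Series:
    """Environmental variance S²_i = Σ_j (x_ij − x̄_i.)² / (E − 1).

    Static-concept index: the plain across-environment variance of each
    genotype.  Not invariant to shifting a single environment column.
    """
    if t.n_environments < 2:
        raise ValueError("environmental variance needs E >= 2")
    return t.data.var(axis=1, ddof=1).rename("environmental_variance")


def adjusted_cv(t: GxETable) -> pd.Series:
    """Adjusted coefficient of variation (%), scale-corrected via Taylor's power law.

    Across genotypes, log10 variance is regressed on log10 mean,
    ``log10 S²_i = a + b·log10 x̄_i.``; each genotype's log-variance is then
    adjusted to the slope-2 (constant-CV) line,
    ``ṽ_i = v_i + (2 − b)(m_i − m̄)``, and reported as
    ``ã_i = 100·10^(ṽ_i/2 − m_i)``.  When the fitted slope is exactly 2
    this reduces to the ordinary CV, 100·S_i/x̄_i.
    """
    means = t.genotype_means
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"adjusted CV requires positive genotype means; got {bad}")
    var = t.data.var(axis=1, ddof=1)
    usable = var > 0
    if not usable.all():
        warnings.warn(
            f"genotypes with zero variance excluded from adjusted CV: "
            f"{list(var.index[~usable])}",
            stacklevel=2,
        )
    m = np.log10(means[usable].to_numpy())
    v = np.log10(var[usable].to_numpy())
    if m.size < 2:
        raise ValueError("adjusted CV needs >= 2 genotypes with positive variance")
    b = np.polyfit(m, v, 1)[0]
    v_adj = v + (2.0 - b) * (m - m.mean())
    out = pd.Series(np.nan, index=t.genotype_ids, name="adjusted_cv")
    out[usable.index[usable]] = 100.0 * 10.0 ** (v_adj / 2.0 - m)
    return out


def coefficient_of_regression(t: GxETable) -> pd.Series:
    """Finlay–Wilkinson slope b_i = Σ_j (x_ij − x̄_i.)·I_j / Σ_j I_j².

    The regression of each genotype on the environment index.  b_i = 1
    means average responsiveness; the genotype-mean of b_i is exactly 1 on
    any complete table.
    """
    i_j = t.environment_index.to_numpy()
    ss = float(np.sum(i_j**2))
    if ss <= 0:
        raise ValueError("all environment means are equal; slope undefined")
    x = _values(t)
    centered = x - x.mean(axis=1, keepdims=True)
    b = centered @ i_j / ss
    return pd.Series(b, index=t.genotype_ids, name="coefficient_of_regression")


def coefficient_of_determination(t: GxETable) -> pd.Series:
    """R²_i of the joint regression: b_i²·Σ_j I_j² / Σ_j (x_ij − x̄_i.)².

    Fraction of a genotype's across-environment variation explained by the
    environment index; missing (with a warning) for constant genotypes.
    """
    b = coefficient_of_regression(t).to_numpy()
    i_j = t.environment_index.to_numpy()
    x = _values(t)
    ss_tot = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    out = np.full(len(b), np.nan)
    ok = ss_tot > 0
    if not ok.all():
        warnings.warn(
            f"constant genotypes have undefined R²: "
            f"{list(t.genotype_ids[~ok])}",
            stacklevel=2,
        )
    out[ok] = b[ok] ** 2 * float(np.sum(i_j**2)) / ss_tot[ok]
    return pd.Series(out, index=t.genotype_ids, name="coefficient_of_determination")


def deviation_mean_squares(t: GxETable) -> pd.Series:
    """Deviation mean squares s²_d,i = Σ_j (x_ij − x̄_i. − b_i·I_j)² / (E − 2).

    Residual variance around each genotype's joint-regression line.
    """
    if t.n_environments < 3:
        raise ValueError("deviation mean squares needs E >= 3")
    b = coefficient_of_regression(t).to_numpy()
    i_j = t.environment_index.to_numpy()
    x = _values(t)
    resid = x - x.mean(axis=1, keepdims=True) - np.outer(b, i_j)
    s2d = (resid**2).sum(axis=1) / (t.n_environments - 2)
    return pd.Series(s2d, index=t.genotype_ids, name="deviation_mean_squares")


def ecovalence(t: GxETable, modified: bool = False) -> pd.Series:
    """Wricke's ecovalence W_i = Σ_j (x_ij − x̄_i. − x̄_.j + x̄_..)².

    Each genotype's share of the G-by-E interaction sum of squares; the
    W_i sum over genotypes equals the full interaction SS.  With
    ``modified=True`` returns W'_i = W_i / E, which is comparable across
    analyses run with different numbers of environments.
    """
    if t.n_genotypes < 2:
        raise ValueError("ecovalence needs G >= 2")
    x = _values(t)
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
    w = (resid**2).sum(axis=1)
    if modified:
        return pd.Series(
            w / t.n_environments, index=t.genotype_ids, name="ecovalence_modified"
        )
    return pd.Series(w, index=t.genotype_ids, name="ecovalence")


def genotypic_stability(t: GxETable) -> pd.Series:
    """Hanson's genotypic stability D²_i = Σ_j (x_ij − x̄_i. − b_min·I_j)².

    Squared deviation from the shallowest regression response in the
    analyzed population (b_min = min_i b_i over the genotypes present).
    """
    b = coefficient_of_regression(t).to_numpy()
    b_min = b.min()
    i_j = t.environment_index.to_numpy()
    x = _values(t)
    resid = x - x.mean(axis=1, keepdims=True) - b_min * i_j[None, :]
    return pd.Series(
        (resid**2).sum(axis=1), index=t.genotype_ids, name="genotypic_stability"
    )


def superiority_measure(t: GxETable) -> pd.Series:
    """Lin & Binns genotypic superiority P_i = Σ_j (x_ij − M_j)² / (2E).

    Mean squared distance from the best genotype in each environment
    (M_j = max_i x_ij).  Small P_i = high *and* stable; P_i = 0 iff the
    genotype attains the environment maximum everywhere.  Invariant to
    adding a constant to an entire environment column.
    """
    if t.n_genotypes < 2:
        warnings.warn(
            "superiority measure computed on a single genotype is identically 0",
            stacklevel=2,
        )
    x = _values(t)
    m_j = x.max(axis=0)
    p = ((x - m_j[None, :]) ** 2).sum(axis=1) / (2 * t.n_environments)
    return pd.Series(p, index=t.genotype_ids, name="superiority_measure")


def safety_first_index(t: GxETable, lambda_: float) -> pd.Series:
    """Eskridge's safety-first index: P(trait < λ) under a normal approximation.

    SF_i = Φ((λ − x̄_i.)/S_i) with S_i the environmental standard
    deviation — the approximate probability that genotype i falls below the
    critical level λ (trait units).  Decreasing in the genotype mean.
    Zero-variance genotypes degenerate to a 0/1 step at λ (warned).
    """
    if not np.isfinite(lambda_):
        raise ValueError("critical level lambda must be finite")
    means = t.genotype_means.to_numpy()
    sd = t.data.std(axis=1, ddof=1).to_numpy()
    out = np.empty_like(means)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            "zero-variance genotypes: safety-first index is a 0/1 step",
            stacklevel=2,
        )
        out[zero] = (means[zero] < lambda_).astype(float)
    out[~zero] = stats.norm.cdf((lambda_ - means[~zero]) / sd[~zero])
    return pd.Series(out, index=t.genotype_ids, name="safety_first_index")


def stability_variance(t: GxETable) -> pd.Series:
    """Shukla's stability variance, an unbiased per-genotype interaction variance.

    σ²_i = G·W_i / ((G−2)(E−1)) − Σ_k W_k / ((G−1)(G−2)(E−1)).

    May legitimately be negative (unbiased estimator of a variance
    component).
    """
    g, e = t.n_genotypes, t.n_environments
    if g < 3:
        raise ValueError("stability variance needs G >= 3")
    if e < 2:
        raise ValueError("stability variance needs E >= 2")
    w = ecovalence(t).to_numpy()
    sigma2 = g * w / ((g - 2) * (e - 1)) - w.sum() / ((g - 1) * (g - 2) * (e - 1))
    return pd.Series(sigma2, index=t.genotype_ids, name="stability_variance")


def variance_of_rank(t: GxETable) -> pd.Series:
    """Nassar & Hühn's variance of corrected ranks S⁽⁴⁾_i.

    Genotype effects are removed first (x*_ij = x_ij − x̄_i. + x̄_..), the
    corrected values are ranked within each environment (ascending, ties
    get the average rank) and the across-environment variance of each
    genotype's ranks is returned.
    """
    if t.n_genotypes < 2:
        raise ValueError("variance of rank needs G >= 2")
    x = _values(t)
    corrected = x - x.mean(axis=1, keepdims=True) + x.mean()
    ranks = np.apply_along_axis(stats.rankdata, 0, corrected)
    s4 = ranks.var(axis=1, ddof=1)
    return pd.Series(s4, index=t.genotype_ids, name="variance_of_rank")


# ---------------------------------------------------------------------------
# aggregate result
# ---------------------------------------------------------------------------


@dataclass
class StabilityResult:
    """Per-genotype mean trait and stability-index values.

    ``table`` has one row per genotype: ``mean`` plus one column per
    computed index.  ``sqrt_applied`` records which squared-unit columns
    hold square-rooted values; ``flags`` collects per-index notes (e.g. a
    transform skipped because of negative values).
    """

    trait: str
    table: pd.DataFrame
    sqrt_applied: dict[str, bool] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        for name, applied in self.sqrt_applied.items():
            if name in out.columns:
                out[f"sqrt_{name}"] = applied
        out.to_csv(path, index_label="genotype")


_DISPATCH = {
    "environmental_variance": environmental_variance,
    "adjusted_cv": adjusted_cv,
    "coefficient_of_regression": coefficient_of_regression,
    "coefficient_of_determination": coefficient_of_determination,
    "deviation_mean_squares": deviation_mean_squares,
    "ecovalence": ecovalence,
    "ecovalence_modified": lambda t: ecovalence(t, modified=True),
    "genotypic_stability": genotypic_stability,
    "superiority_measure": superiority_measure,
    "stability_variance": stability_variance,
    "variance_of_rank": variance_of_rank,
}


def compute_index(t: GxETable, name: str, lambda_: float | None = None) -> pd.Series:
    """Compute a single index by name (see :data:`ALL_INDICES`)."""
    if name == "safety_first_index":
        if lambda_ is None:
            raise ValueError("safety_first_index requires the critical level lambda")
        return safety_first_index(t, lambda_)
    if name not in _DISPATCH:
        raise KeyError(f"unknown stability index {name!r}")
    return _DISPATCH[name](t)


def compute_all(
    t: GxETable,
    indices: tuple[str, ...] | str = "all",
    lambda_: float | None = None,
    sqrt_squared_units: bool = True,
) -> StabilityResult:
    """Compute the requested stability indices on one table.

    Indices whose preconditions fail on this table (e.g. Shukla's variance
    with fewer than three genotypes) are reported as missing with a
    warning; the run continues.
    """
    if indices == "all":
        wanted = ALL_INDICES
    else:
        wanted = tuple(indices)
        unknown = set(wanted) - set(ALL_INDICES)
        if unknown:
            raise KeyError(f"unknown indices {sorted(unknown)}")
    if "safety_first_index" in wanted and lambda_ is None:
        raise ValueError("safety_first_index requested but no lambda supplied")

    table = pd.DataFrame({"mean": t.genotype_means})
    flags: dict[str, str] = {}
    for name in wanted:
        try:
            table[name] = compute_index(t, name, lambda_)
        except (ValueError, KeyError) as exc:
            warnings.warn(f"index {name} skipped: {exc}", stacklevel=2)
            flags[name] = str(exc)
            table[name] = np.nan
    result = StabilityResult(t.trait, table, flags=flags)
    if sqrt_squared_units:
        result = apply_unit_transform(result)
    return result


def apply_unit_transform(
    result: StabilityResult, extended: bool = False
) -> StabilityResult:
    """Square-root the squared-unit indices so units match the trait.

    The default set is the superiority measure, the (modified) ecovalence
    and the variance of rank; ``extended=True`` additionally transforms the
    environmental variance, deviation mean squares, genotypic stability and
    Shukla's variance.  Dimension-less indices are never touched.  A column
    containing negative values (possible for Shukla's variance) is left
    untransformed and flagged, preserving within-column comparability.
    """
    targets = EXTENDED_SQUARED_UNIT_INDICES if extended else SQUARED_UNIT_INDICES
    table = result.table.copy()
    applied = dict(result.sqrt_applied)
    flags = dict(result.flags)
    for name in targets:
        if name not in table.columns or applied.get(name):
            continue
        col = table[name]
        if col.isna().all():
            continue
        if (col < 0).any():
            flags[name] = "negative values; square-root transform skipped"
            applied[name] = False
            continue
        table[name] = np.sqrt(col)
        applied[name] = True
    return StabilityResult(result.trait, table, applied, flags)
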