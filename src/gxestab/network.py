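"""Correlation networks linking physiological parameters to a trait and its
superiority measure, the tendency index, and network similarity.

For one sampled population of genotypes (SPG) grown in one sampled
population of environments (SPE), a per-genotype table of
[mean trait, P_i, parameter 1..P] is correlated column-against-column
(Pearson) into an *r-matrix*.  Discarding the parameter–parameter block
leaves the *r-vector* of 2P+1 entries: the trait–P_i correlation, the P
trait–parameter correlations and the P P_i–parameter correlations.  The
per-parameter *tendency* T = |r(P_i, param)| / |r(trait, param)| says
whether a parameter explains stability (T > 1) or mean performance
(T < 1) better.

Repeating the analysis over many SPG yields many r-vectors; the mean
squared Pearson correlation between them (off-diagonal of the
"edge-r-matrix") is the network *similarity* S ∈ [0, 1].  S grows with
the number of genotypes per SPG and is summarized by the asymptotic law
``S = N_gen / (k + N_gen)``; solving it for a target S gives the number
of genotypes needed for a reproducible network.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import GxETable, ParameterTable, substream
from .indices import superiority_measure
from .sampling import sample_environments, sample_genotypes

__all__ = [
    "spg_analysis_table",
    "r_matrix",
    "r_vector",
    "tendency",
    "network_edges",
    "edge_r_matrix",
    "similarity_S",
    "fit_asymptotic",
    "n_gen_for_similarity",
    "AsymptoticFit",
    "similarity_experiment",
    "tendency_experiment",
]

TRAIT_COL = "mean_trait"
PI_COL = "superiority"


def spg_analysis_table(
    pool: GxETable,
    params: ParameterTable,
    genotypes,
    environments=None,
    sqrt_pi: bool = True,
) -> pd.DataFrame:
    """Per-genotype analysis table [mean trait, P_i, parameters].

    Mean trait and the superiority measure are computed *within* the
    SPG-by-SPE subset: environment maxima are taken over the sampled
    genotypes only, so each sampled population is self-contained.  P_i is
    square-rooted by default for unit consistency with the trait.
    """
    sub = pool.subset(genotypes, environments)
    pi = superiority_measure(sub)
    if sqrt_pi:
        pi = np.sqrt(pi)
    df = pd.DataFrame({TRAIT_COL: sub.genotype_means, PI_COL: pi})
    return df.join(params.data.loc[df.index])


def r_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix between all columns of an SPG table.

    Constant columns carry no correlation information and are dropped
    with a warning.
    """
    if len(table) < 3:
        raise ValueError("correlation matrix needs >= 3 genotypes")
    sd = table.std(ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"constant columns dropped: {list(constant)}", stacklevel=2)
        table = table.drop(columns=constant)
    return table.corr(method="pearson")


def r_vector(
    m: pd.DataFrame, trait_col: str = TRAIT_COL, pi_col: str = PI_COL
) -> pd.Series:
    """Flatten an r-matrix to the canonical 2P+1 r-vector.

    Order: the (trait, P_i) entry first, then (trait, parameter) for each
    parameter in matrix column order, then (P_i, parameter) in the same
    order.  Parameter–parameter correlations are excluded.
    """
    for col in (trait_col, pi_col):
        if col not in m.columns:
            raise KeyError(f"r-matrix lacks the {col!r} column")
    params = [c for c in m.columns if c not in (trait_col, pi_col)]
    labels = [f"{trait_col}~{pi_col}"]
    values = [m.loc[trait_col, pi_col]]
    for col, tag in ((trait_col, trait_col), (pi_col, pi_col)):
        for p in params:
            labels.append(f"{tag}~{p}")
            values.append(m.loc[col, p])
    return pd.Series(values, index=labels, name="r", dtype=float)


def tendency(
    v: pd.Series, trait_col: str = TRAIT_COL, pi_col: str = PI_COL
) -> pd.DataFrame:
    """Tendency index per parameter: T = |r(P_i, param)| / |r(trait, param)|.

    T > 1 marks a parameter more related to stability than to mean
    performance.  Near-zero denominators (|r(trait, param)| < 1e-6) give
    an infinite T with the ``degenerate`` flag set.
    """
    trait_r = {}
    pi_r = {}
    for label, value in v.items():
        left, _, right = label.partition("~")
        if right == pi_col or right == trait_col:
            continue
        if left == trait_col:
            trait_r[right] = value
        elif left == pi_col:
            pi_r[right] = value
    if set(trait_r) != set(pi_r):
        raise ValueError("r-vector is incomplete: trait and P_i parameter sets differ")
    rows = []
    for p in trait_r:
        denom, numer = abs(trait_r[p]), abs(pi_r[p])
        degenerate = denom < 1e-6
        rows.append(
            {
                "parameter": p,
                "T": np.inf if degenerate else numer / denom,
                "abs_r_superiority": numer,
                "abs_r_trait": denom,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def network_edges(m: pd.DataFrame, r_threshold: float = 0.33) -> list[tuple]:
    """Edges (node, node, r) with |r| strictly above the display threshold."""
    cols = list(m.columns)
    edges = []
    for i, u in enumerate(cols):
        for v in cols[i + 1 :]:
            r = float(m.loc[u, v])
            if abs(r) > r_threshold:
                edges.append((u, v, r))
    return edges


def edge_r_matrix(vectors) -> np.ndarray:
    """Pearson correlations between every pair of r-vectors.

    ``vectors`` is a sequence of equal-length, identically ordered
    r-vectors (or a DataFrame with one row per SPG).
    """
    if isinstance(vectors, pd.DataFrame):
        arr = vectors.to_numpy(dtype=float)
    else:
        vectors = list(vectors)
        lengths = {len(v) for v in vectors}
        if len(lengths) > 1:
            raise ValueError(f"r-vectors differ in length: {sorted(lengths)}")
        arr = np.asarray([np.asarray(v, dtype=float) for v in vectors])
    if arr.shape[0] < 2:
        raise ValueError("edge-r-matrix needs >= 2 r-vectors")
    return np.corrcoef(arr)


def similarity_S(edge_m: np.ndarray) -> float:
    """Network similarity: mean squared off-diagonal correlation.

    Squaring turns each pairwise correlation into the share of variance
    one r-vector explains of another; the mean over distinct pairs is 1
    for identical networks and ~0 for unrelated ones.  The diagonal
    self-correlations are excluded — they carry no similarity information.
    """
    edge_m = np.asarray(edge_m, dtype=float)
    n = edge_m.shape[0]
    if edge_m.ndim != 2 or edge_m.shape[1] != n or n < 2:
        raise ValueError("edge-r-matrix must be square with >= 2 vectors")
    iu = np.triu_indices(n, k=1)
    return float(np.mean(edge_m[iu] ** 2))


@dataclass(frozen=True)
class AsymptoticFit:
    """Fitted S = N_gen / (k + N_gen); k has genotype-count units."""

    k: float
    se_k: float = float("nan")
    r_squared: float = float("nan")
    n_obs: int = 0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("k must be positive")

    def predict(self, n_gen) -> np.ndarray:
        n = np.asarray(n_gen, dtype=float)
        return n / (self.k + n)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def fit_asymptotic(obs: pd.DataFrame) -> AsymptoticFit:
    """Least-squares fit of S = N_gen/(k + N_gen) over (N_gen, S) points.

    Observations at different N_env are pooled (similarity saturates with
    genotype number, not environment number).  A single observation has
    the closed-form solution k = N(1−S)/S.
    """
    n = obs["n_gen"].to_numpy(dtype=float)
    s = obs["S"].to_numpy(dtype=float)
    if len(n) == 0:
        raise ValueError("no observations")
    if np.all(s <= 0) or np.all(s >= 1):
        raise ValueError("S observations must lie in (0, 1) for the fit")
    if len(n) == 1:
        return AsymptoticFit(k=float(n[0] * (1 - s[0]) / s[0]), n_obs=1)
    if np.allclose(s, s[0]) and len(np.unique(n)) > 1:
        raise ValueError("degenerate data: S constant across distinct N_gen")
    valid = (s > 0) & (s < 1)
    k0 = float(np.median(n[valid] * (1 - s[valid]) / s[valid]))
    popt, pcov = curve_fit(
        lambda x, k: x / (k + x), n, s, p0=(max(k0, 1e-6),), maxfev=10000
    )
    pred = n / (popt[0] + n)
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 - float(np.sum((s - pred) ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return AsymptoticFit(
        k=float(popt[0]),
        se_k=float(np.sqrt(pcov[0, 0])),
        r_squared=r2,
        n_obs=len(n),
    )


def n_gen_for_similarity(fit: AsymptoticFit | float, s_target: float) -> int:
    """Smallest integer N_gen with N/(k + N) ≥ s_target."""
    k = fit.k if isinstance(fit, AsymptoticFit) else float(fit)
    if not 0.0 < s_target < 1.0:
        raise ValueError("target similarity must lie in (0, 1)")
    from math import ceil

    n = ceil(k * s_target / (1.0 - s_target) - 1e-9)
    return max(n, 1)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------


def _spg_r_vectors(
    pool: GxETable,
    params: ParameterTable,
    n_gen: int,
    n_env: int,
    n_spg: int,
    seed: int,
    method: str = "random",
    key: str = "",
) -> pd.DataFrame:
    """One r-vector per SPG (rows) for a fixed (N_gen, N_env)."""
    pool_means = pool.genotype_means
    env_ids = pool.environment_ids.to_numpy()
    rows = []
    for rep in range(n_spg):
        rng = substream(seed, "spg", key, int(n_gen), int(n_env), rep)
        genotypes = sample_genotypes(pool_means, n_gen, method, rng)
        envs = sample_environments(env_ids, n_env, rng)
        table = spg_analysis_table(pool, params, genotypes, envs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny SPG may hit constant columns
            rows.append(r_vector(r_matrix(table)))
    return pd.DataFrame(rows).reset_index(drop=True)


def similarity_experiment(
    pool: GxETable,
    params: ParameterTable,
    n_gen_grid,
    n_env_grid,
    n_spg: int,
    seed: int,
    method: str = "random",
) -> pd.DataFrame:
    """Similarity S for every (N_gen, N_env) combination.

    For each grid cell, ``n_spg`` SPG are drawn, their r-vectors computed
    and S taken as the mean squared pairwise correlation between them.
    """
    records = []
    for n_gen in n_gen_grid:
        for n_env in n_env_grid:
            vectors = _spg_r_vectors(
                pool, params, int(n_gen), int(n_env), n_spg, seed, method,
                key="similarity",
            )
            records.append(
                {
                    "n_gen": int(n_gen),
                    "n_env": int(n_env),
                    "n_spg": n_spg,
                    "S": similarity_S(edge_r_matrix(vectors)),
                }
            )
    return pd.DataFrame(records)


def tendency_experiment(
    pool: GxETable,
    params: ParameterTable,
    n_gen: int,
    n_env: int,
    n_spg: int,
    seed: int,
    method: str = "random",
) -> pd.DataFrame:
    """Tendency index per parameter for each of ``n_spg`` sampled populations.

    Returns a tidy frame (spg, parameter, T, |r| values) for studying
    which parameters explain stability versus mean performance.
    """
    pool_means = pool.genotype_means
    env_ids = pool.environment_ids.to_numpy()
    frames = []
    for rep in range(n_spg):
        rng = substream(seed, "spg", "tendency", int(n_gen), int(n_env), rep)
        genotypes = sample_genotypes(pool_means, n_gen, method, rng)
        envs = sample_environments(env_ids, n_env, rng)
        table = spg_analysis_table(pool, params, genotypes, envs)
        t = tendency(r_vector(r_matrix(table))).reset_index()
        t.insert(0, "spg", rep)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
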