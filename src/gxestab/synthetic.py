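"""Synthetic genotype-by-environment phenotype generator.

Emulates, at desk scale, the statistical structure of a large in-silico
wheat experiment in which thousands of virtual genotypes — created by
perturbing ~90 physiological parameters within ±20% of a reference
cultivar — are grown across thousands of environments.

The generative model is deliberately small.  Each genotype carries a
parameter vector θ_i (uniform in [1−δ, 1+δ] per parameter).  A few
designated parameters load on an additive main effect,
``a_i = Σ_p w_mean[p]·(θ_ip − 1)``, and a few *distinct* parameters load on
a multiplicative environmental sensitivity,
``s_i = Σ_p w_sens[p]·(θ_ip − 1)``.  Environment j has a quality
``q_j ~ N(0, σ_q²)`` and the primary trait is

    x_ij = (1 + s_i)·(μ + q_j) + a_i + ε_ij,   ε_ij ~ N(0, σ_ε²),

truncated at zero.  Sensitivity parameters scale the whole environmental
response — the way radiation-use-efficiency-like parameters scale yield
potential — so they load on both the genotype mean (through μ·s_i) and on
the G-by-E interaction, while mean parameters load on the mean only.  The
Finlay–Wilkinson slope of genotype i is (1 + s_i) up to normalization.

Secondary traits (straw yield, grain protein, grain number, grain size,
LAI) are affine functions of the primary trait plus noise, with a negative
protein–yield trade-off and positive straw and grain-number couplings.

Ground truth (a_i, s_i, q_j and the loading vectors) is recorded in a
:class:`SyntheticTruth` so recovery tests can compare fitted quantities
against the generating values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GxETable, ParameterTable, substream

__all__ = [
    "GenerativeModel",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "SECONDARY_TRAITS",
]

#: secondary trait -> (intercept, slope on primary trait, noise sd)
SECONDARY_TRAITS = {
    "straw_yield": (1.0, 1.1, 0.4),       # t/ha, grows with grain yield
    "grain_protein": (16.0, -1.2, 0.5),   # %, dilution trade-off
    "grain_number": (4000.0, 2500.0, 800.0),  # grains/m2
    "grain_size": (30.0, 2.0, 1.5),       # mg
    "lai": (2.0, 0.8, 0.3),               # m2/m2
}


@dataclass(frozen=True)
class GenerativeModel:
    """Defaults of the synthetic G-by-E generator.

    Parameters
    ----------
    n_params : int
        Number of physiological parameters per genotype.
    delta : float
        Half-width of the uniform parameter range around the reference
        value 1.0 (0.2 → ±20%).
    mu : float
        Base trait mean for the reference genotype in an average
        environment (t/ha for yield).
    sigma_q : float
        Standard deviation of environment quality (trait units).
    sigma_eps : float
        Residual standard deviation (trait units).
    w_mean, w_sens : dict[int, float]
        Sparse loading vectors, parameter position -> weight.  By default
        parameters 0–2 carry the additive mean loading and parameters 3–5
        the multiplicative sensitivity loading.  Magnitudes are calibrated
        so the correlation between a loaded parameter and mean yield (or
        the superiority measure) falls in the 0.2–0.8 band under the
        default sample sizes.
    """

    n_params: int = 90
    delta: float = 0.2
    mu: float = 4.0
    sigma_q: float = 1.5
    sigma_eps: float = 0.3
    w_mean: dict[int, float] = field(default_factory=lambda: {0: 3.0, 1: 3.0, 2: 3.0})
    w_sens: dict[int, float] = field(default_factory=lambda: {3: 0.5, 4: 0.5, 5: 0.5})
    secondary_traits: tuple[str, ...] = ()
    truncate_at_zero: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must lie in [0, 1)")
        if self.sigma_q < 0 or self.sigma_eps < 0:
            raise ValueError("noise scales must be non-negative")
        for w in (self.w_mean, self.w_sens):
            if any(p < 0 or p >= self.n_params for p in w):
                raise ValueError("loading positions must index a parameter")
            if not all(np.isfinite(list(w.values()))):
                raise ValueError("loading weights must be finite")
        unknown = set(self.secondary_traits) - set(SECONDARY_TRAITS)
        if unknown:
            raise ValueError(f"unknown secondary traits {sorted(unknown)}")

    def loading_vector(self, which: str) -> np.ndarray:
        w = np.zeros(self.n_params)
        for p, weight in (self.w_mean if which == "mean" else self.w_sens).items():
            w[p] = weight
        return w

    @property
    def mean_loaded_params(self) -> list[str]:
        return [_param_name(p, self.n_params) for p in sorted(self.w_mean)]

    @property
    def sensitivity_loaded_params(self) -> list[str]:
        return [_param_name(p, self.n_params) for p in sorted(self.w_sens)]

    def content_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["w_mean"] = sorted(payload["w_mean"].items())
        payload["w_sens"] = sorted(payload["w_sens"].items())
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating quantities, recorded exactly as used.

    a : per-genotype additive main effect (trait units)
    s : per-genotype multiplicative sensitivity (dimensionless)
    q : per-environment quality (trait units)
    """

    a: pd.Series
    s: pd.Series
    q: pd.Series
    mean_loaded_params: tuple[str, ...]
    sensitivity_loaded_params: tuple[str, ...]

    def to_json(self, path) -> None:
        payload = {
            "a": self.a.to_dict(),
            "s": self.s.to_dict(),
            "q": self.q.to_dict(),
            "mean_loaded_params": list(self.mean_loaded_params),
            "sensitivity_loaded_params": list(self.sensitivity_loaded_params),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class SyntheticDataset:
    """Phenotype tables (one per trait) plus parameters and ground truth."""

    params: ParameterTable
    tables: dict[str, GxETable]
    truth: SyntheticTruth

    @property
    def primary(self) -> GxETable:
        return self.tables["yield"]


def _param_name(p: int, n_params: int) -> str:
    width = len(str(n_params))
    return f"param_{p + 1:0{width}d}"


def _genotype_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def _environment_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"e{j + 1:0{width}d}" for j in range(n)]


def simulate_genotypes(
    model: GenerativeModel, n_gen: int, seed: int
) -> ParameterTable:
    """Draw ``n_gen`` virtual genotypes: θ_ip ~ U(1−δ, 1+δ), independent."""
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    rng = substream(seed, "genotypes")
    theta = rng.uniform(1 - model.delta, 1 + model.delta, size=(n_gen, model.n_params))
    cols = [_param_name(p, model.n_params) for p in range(model.n_params)]
    return ParameterTable(pd.DataFrame(theta, index=_genotype_ids(n_gen), columns=cols))


def simulate_phenotypes(
    params: ParameterTable,
    model: GenerativeModel,
    n_env: int,
    seed: int,
    traits: tuple[str, ...] | None = None,
    _q: np.ndarray | None = None,
    _noise_key: int = 0,
) -> SyntheticDataset:
    """Simulate the primary trait (and any secondary traits) for all genotypes.

    Returns a :class:`SyntheticDataset` holding one complete
    :class:`~gxestab.core.GxETable` per trait plus the generating truth.
    ``traits`` defaults to ``model.secondary_traits``.  The private ``_q``
    and ``_noise_key`` arguments let the chunked writer share one set of
    environment qualities across genotype chunks while keeping residual
    noise independent between chunks.
    """
    if n_env < 2:
        raise ValueError("n_env must be >= 2")
    if traits is None:
        traits = model.secondary_traits
    theta = params.data.to_numpy()
    centered = theta - 1.0
    a = centered @ model.loading_vector("mean")
    s = centered @ model.loading_vector("sens")
    if _q is None:
        q = substream(seed, "environment-quality").normal(0.0, model.sigma_q, size=n_env)
    else:
        q = np.asarray(_q, dtype=float)
        if q.size != n_env:
            raise ValueError("supplied environment qualities do not match n_env")
    rng = substream(seed, "phenotype-noise", _noise_key)
    eps = rng.normal(0.0, model.sigma_eps, size=(len(a), n_env))
    x = (1.0 + s)[:, None] * (model.mu + q)[None, :] + a[:, None] + eps
    if model.truncate_at_zero:
        np.clip(x, 0.0, None, out=x)

    gids = params.data.index
    eids = _environment_ids(n_env)
    tables = {"yield": GxETable("yield", pd.DataFrame(x, index=gids, columns=eids), "t/ha")}
    for trait in traits:
        intercept, slope, noise_sd = SECONDARY_TRAITS[trait]
        noise = rng.normal(0.0, noise_sd, size=x.shape)
        y = intercept + slope * x + noise
        if trait != "grain_protein":  # physical traits cannot be negative
            np.clip(y, 0.0, None, out=y)
        tables[trait] = GxETable(trait, pd.DataFrame(y, index=gids, columns=eids))

    truth = SyntheticTruth(
        a=pd.Series(a, index=gids, name="a"),
        s=pd.Series(s, index=gids, name="s"),
        q=pd.Series(q, index=eids, name="q"),
        mean_loaded_params=tuple(model.mean_loaded_params),
        sensitivity_loaded_params=tuple(model.sensitivity_loaded_params),
    )
    return SyntheticDataset(params, tables, truth)


def simulate_dataset(
    model: GenerativeModel,
    n_gen: int,
    n_env: int,
    seed: int,
    outdir: str | Path,
    force: bool = False,
    chunk_size: int = 500,
) -> dict[str, Path]:
    """Simulate and write a dataset: parameters, long phenotypes, truth, manifest.

    Phenotypes are written genotype-chunk by genotype-chunk so that
    full-scale emulations (tens of millions of rows) never need the whole
    long table in memory.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "parameters": outdir / "parameters.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.json",
        "manifest": outdir / "manifest.json",
    }
    clashes = [p for p in paths.values() if p.exists()]
    if clashes and not force:
        raise FileExistsError(f"output exists (use force=True): {clashes[0]}")

    params = simulate_genotypes(model, n_gen, seed)
    params.data.to_csv(paths["parameters"], index_label="genotype")

    trait_names = ["yield", *model.secondary_traits]
    first = True
    truth_parts: list[SyntheticTruth] = []
    # environment qualities are shared across genotype chunks; residual
    # noise gets an independent substream per chunk
    q = substream(seed, "environment-quality").normal(0.0, model.sigma_q, size=n_env)
    for start in range(0, n_gen, chunk_size):
        chunk = ParameterTable(params.data.iloc[start : start + chunk_size])
        ds = simulate_phenotypes(chunk, model, n_env, seed, _q=q, _noise_key=start)
        long = ds.tables["yield"].to_long()
        for trait in model.secondary_traits:
            long[trait] = ds.tables[trait].to_long()[trait]
        long.to_csv(paths["phenotypes"], mode="w" if first else "a",
                    header=first, index=False)
        truth_parts.append(ds.truth)
        first = False

    truth = SyntheticTruth(
        a=pd.concat([t.a for t in truth_parts]),
        s=pd.concat([t.s for t in truth_parts]),
        q=truth_parts[0].q,
        mean_loaded_params=truth_parts[0].mean_loaded_params,
        sensitivity_loaded_params=truth_parts[0].sensitivity_loaded_params,
    )
    truth.to_json(paths["truth"])

    manifest = {
        "seed": seed,
        "n_gen": n_gen,
        "n_env": n_env,
        "traits": trait_names,
        "model_hash": model.content_hash(),
        "file_sha256": {
            name: hashlib.sha256(p.read_bytes()).hexdigest()
            for name, p in paths.items()
            if name != "manifest" and p.exists()
        },
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return paths
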