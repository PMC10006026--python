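"""Genotype and environment sampling schemes for multi-environment trials.

A sampled population of genotypes (SPG) is drawn from the pool by one of
three schemes — simple random, even (decile-stratified on pool mean yield)
or top-20 (random within the top quintile of pool mean yield) — and a
sampled population of environments (SPE) is always a simple random draw.
Deciles and percentiles are always computed on the *full* pool, never on
the sample, and every draw is without replacement.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import substream

__all__ = [
    "sample_random",
    "sample_even",
    "sample_top20",
    "sample_environments",
    "sample_genotypes",
    "METHODS",
]

log = logging.getLogger(__name__)

METHODS = ("random", "even", "top20")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return substream(int(seed_or_rng), "sampling")


def sample_random(pool_means: pd.Series, n: int, seed) -> np.ndarray:
    """Simple random sample of ``n`` genotype ids, without replacement."""
    if n > len(pool_means):
        raise ValueError(f"cannot sample {n} from pool of {len(pool_means)}")
    rng = _rng(seed)
    return rng.choice(pool_means.index.to_numpy(), size=n, replace=False)


def _decile_bins(pool_means: pd.Series) -> np.ndarray:
    """Assign each pool genotype to a mean-yield decile (0..9).

    Decile edges use the inclusive linear-interpolation quantile
    convention on the full pool.
    """
    values = pool_means.to_numpy(dtype=float)
    edges = np.quantile(values, np.arange(1, 10) / 10.0, method="linear")
    return np.searchsorted(edges, values, side="left")


def sample_even(pool_means: pd.Series, n: int, seed) -> np.ndarray:
    """Decile-stratified sample: n/10 genotypes per mean-yield decile.

    When ``n`` is not divisible by 10 the remainder slots are assigned one
    each to the lowest-numbered deciles (and logged).
    """
    if n > len(pool_means):
        raise ValueError(f"cannot sample {n} from pool of {len(pool_means)}")
    rng = _rng(seed)
    bins = _decile_bins(pool_means)
    base, remainder = divmod(n, 10)
    counts = np.full(10, base)
    counts[:remainder] += 1
    if remainder:
        log.info(
            "even sampling: n=%d not divisible by 10; one extra slot in "
            "deciles 1..%d", n, remainder,
        )
    ids = pool_means.index.to_numpy()
    chosen = []
    for d in range(10):
        members = ids[bins == d]
        if len(members) < counts[d]:
            raise ValueError(
                f"decile {d + 1} holds {len(members)} genotypes, "
                f"need {counts[d]}"
            )
        if counts[d]:
            chosen.append(rng.choice(members, size=counts[d], replace=False))
    return np.concatenate(chosen)


def sample_top20(pool_means: pd.Series, n: int, seed) -> np.ndarray:
    """Random sample among genotypes whose pool mean exceeds the 80th percentile.

    Eligibility is strict (mean > percentile), matching the definition of
    the top-quintile population.
    """
    rng = _rng(seed)
    cutoff = np.quantile(pool_means.to_numpy(dtype=float), 0.8, method="linear")
    eligible = pool_means.index.to_numpy()[pool_means.to_numpy() > cutoff]
    if len(eligible) == 0:
        raise ValueError("no genotype strictly exceeds the 80th percentile")
    if n > len(eligible):
        raise ValueError(
            f"cannot sample {n} from {len(eligible)} eligible top-20 genotypes"
        )
    return rng.choice(eligible, size=n, replace=False)


def sample_genotypes(pool_means: pd.Series, n: int, method: str, seed) -> np.ndarray:
    """Dispatch to one of the three genotype-sampling schemes."""
    if method not in METHODS:
        raise ValueError(f"unknown sampling method {method!r}; choose from {METHODS}")
    fn = {"random": sample_random, "even": sample_even, "top20": sample_top20}[method]
    return fn(pool_means, n, seed)


def sample_environments(env_ids, n: int, seed) -> np.ndarray:
    """Simple random sample of environment ids without replacement."""
    env_ids = np.asarray(env_ids)
    if n > len(env_ids):
        raise ValueError(f"cannot sample {n} from pool of {len(env_ids)}")
    rng = _rng(seed)
    return rng.choice(env_ids, size=n, replace=False)
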