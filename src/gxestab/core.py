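"""Canonical data model and file I/O for genotype-by-environment trials.

The package works on complete two-way phenotype tables: one value per
(genotype, environment) cell for a single trait.  On disk the canonical
representation is a long-format table (``genotype``, ``environment``, one
column per trait); in memory a :class:`GxETable` holds the wide
genotype-by-environment matrix together with its marginal means, which is
what every stability index consumes.

Environments are opaque composite keys: a site-year-management combination
is a single environment as far as the analysis is concerned.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GxETable",
    "ParameterTable",
    "RunConfig",
    "CompletenessError",
    "read_gxe_table",
    "write_gxe_table",
    "read_parameter_table",
    "write_graphml",
    "substream",
]


class CompletenessError(ValueError):
    """Raised when a genotype-by-environment table has missing cells."""


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Return a named, reproducible random substream.

    All randomness in the package flows from a single user seed; each
    stochastic stage draws from its own substream identified by string
    keys, so adding draws to one stage never perturbs another.
    """
    coded = [int(seed)]
    for k in keys:
        coded.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return np.random.default_rng(np.random.SeedSequence(coded))


@dataclass(frozen=True)
class GxETable:
    """Complete phenotype matrix for one trait.

    Parameters
    ----------
    trait : str
        Trait name (e.g. ``"yield"``).
    data : pandas.DataFrame
        Wide matrix, rows indexed by genotype id, columns by environment
        id.  Every cell must be present and finite.
    units : str, optional
        Trait units, e.g. ``"t/ha"``; informational only.
    """

    trait: str
    data: pd.DataFrame
    units: str | None = None

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            raise ValueError("duplicate genotype ids")
        if d.columns.has_duplicates:
            raise ValueError("duplicate environment ids")
        if d.shape[0] < 1 or d.shape[1] < 2:
            raise ValueError(
                f"table must have >=1 genotype and >=2 environments, got {d.shape}"
            )
        values = d.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))
            pairs = [(d.index[i], d.columns[j]) for i, j in bad[:10]]
            raise CompletenessError(f"non-finite cells at {pairs}")
        d = d.astype(float).rename_axis(index="genotype", columns="environment")
        object.__setattr__(self, "data", d)

    # -- marginals ---------------------------------------------------------
    @property
    def n_genotypes(self) -> int:
        return self.data.shape[0]

    @property
    def n_environments(self) -> int:
        return self.data.shape[1]

    @property
    def genotype_ids(self) -> pd.Index:
        return self.data.index

    @property
    def environment_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def genotype_means(self) -> pd.Series:
        return self.data.mean(axis=1)

    @property
    def environment_means(self) -> pd.Series:
        return self.data.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        return float(self.data.to_numpy().mean())

    @property
    def environment_index(self) -> pd.Series:
        """Environment index I_j = environment mean minus grand mean."""
        return self.environment_means - self.grand_mean

    def subset(
        self,
        genotypes: Sequence | None = None,
        environments: Sequence | None = None,
    ) -> "GxETable":
        """Return the table restricted to the given genotypes/environments."""
        d = self.data
        if genotypes is not None:
            d = d.loc[list(genotypes)]
        if environments is not None:
            d = d[list(environments)]
        return GxETable(self.trait, d, self.units)

    def to_long(self) -> pd.DataFrame:
        long = self.data.stack().rename(self.trait).reset_index()
        long.columns = ["genotype", "environment", self.trait]
        return long


@dataclass(frozen=True)
class ParameterTable:
    """Genotype-to-physiological-parameter mapping.

    Values are normalized so the reference genotype is 1.0 per parameter.
    """

    data: pd.DataFrame  # index: genotype id, columns: parameter names

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            raise ValueError("duplicate genotype ids")
        if d.shape[1] < 1:
            raise ValueError("at least one parameter column required")
        if not np.all(np.isfinite(d.to_numpy(dtype=float))):
            raise ValueError("parameter values must be finite")
        object.__setattr__(self, "data", d.astype(float))

    @property
    def n_parameters(self) -> int:
        return self.data.shape[1]

    @property
    def parameter_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; the seed is mandatory."""

    seed: int
    trait: str = "yield"
    indices: tuple[str, ...] | str = "all"
    cv_threshold: float = 0.10
    r_threshold: float = 0.33
    method: str = "random"
    n_gen: int = 100
    n_env: int = 100
    n_spg: int = 100
    n_spe: int = 100
    safety_first_lambda: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_gen", "n_env", "n_spg", "n_spe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.cv_threshold < 1.0:
            raise ValueError("cv_threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".parquet", ".pq"}:
        return pd.read_parquet(path)
    return pd.read_csv(path)


def read_gxe_table(path: str | Path, trait: str) -> GxETable:
    """Read a long-format phenotype file into a complete :class:`GxETable`.

    The file needs ``genotype`` and ``environment`` columns plus a numeric
    column named *trait*; additional trait columns are ignored.  Duplicate
    (genotype, environment) rows and missing cells are hard errors — the
    index formulas assume a complete two-way table and no imputation is
    attempted.
    """
    df = _read_frame(path)
    for col in ("genotype", "environment", trait):
        if col not in df.columns:
            raise KeyError(f"required column {col!r} not found in {path}")
    if not pd.api.types.is_numeric_dtype(pd.to_numeric(df[trait], errors="coerce")):
        raise ValueError(f"trait column {trait!r} is not numeric")
    vals = pd.to_numeric(df[trait], errors="coerce")
    if vals.isna().any():
        bad = df.loc[vals.isna(), ["genotype", "environment"]].head(10)
        raise ValueError(f"non-numeric trait values at\n{bad}")
    dup = df.duplicated(subset=["genotype", "environment"])
    if dup.any():
        pairs = df.loc[dup, ["genotype", "environment"]].head(10).to_records(index=False)
        raise ValueError(f"duplicate (genotype, environment) rows: {list(pairs)}")
    wide = df.pivot(index="genotype", columns="environment", values=trait)
    if wide.isna().any().any():
        missing = [
            (g, e)
            for g in wide.index
            for e in wide.columns[wide.loc[g].isna()]
        ]
        raise CompletenessError(
            f"incomplete table: {len(missing)} missing (genotype, environment) "
            f"pairs, first few: {missing[:10]}"
        )
    if wide.shape[0] < 2:
        raise ValueError("table must contain at least 2 genotypes")
    return GxETable(trait, wide)


def write_gxe_table(table: GxETable, path: str | Path) -> None:
    """Write a table in the canonical long CSV (or Parquet) format."""
    path = Path(path)
    long = table.to_long()
    if path.suffix.lower() in {".parquet", ".pq"}:
        long.to_parquet(path, index=False)
    else:
        long.to_csv(path, index=False)


def read_parameter_table(path: str | Path) -> ParameterTable:
    """Read a genotype-to-parameter CSV (genotype column + numeric columns)."""
    df = _read_frame(path)
    if "genotype" not in df.columns:
        raise KeyError("parameter table needs a 'genotype' column")
    return ParameterTable(df.set_index("genotype"))


def write_graphml(
    edges: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    """Write a correlation network as GraphML.

    Each edge carries the Pearson r as ``weight`` plus a ``sign``
    attribute (``"positive"``/``"negative"``) so that tools which drop
    negative weights still keep the sign information.
    """
    g = nx.Graph()
    edges = list(edges)
    if not edges:
        warnings.warn("writing an empty correlation network", stacklevel=2)
    for u, v, r in edges:
        if g.has_edge(u, v):
            raise ValueError(f"duplicate edge ({u}, {v})")
        g.add_edge(u, v, weight=float(r), sign="negative" if r < 0 else "positive")
    nx.write_graphml(g, str(path))
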