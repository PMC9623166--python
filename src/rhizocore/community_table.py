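"""OTU-table processing.

Rarefaction, relative abundance, alpha diversity, z-scoring, and selection
of the dominant OTU set that seeds network construction.

Conventions
-----------
* Tables are samples x OTUs; sample ids key the rows.
* Shannon diversity uses the natural logarithm (vegan's default).
* "Relative abundance in the total community" is read as the mean per-OTU
  relative abundance across samples, so that one node set serves all samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "RelativeAbundanceTable",
    "DiversityResult",
    "rarefy",
    "relative_abundance",
    "shannon_diversity",
    "zscore",
    "select_top_otus",
]


class ZeroVarianceWarning(UserWarning):
    """Raised (as a warning) when a constant vector is z-scored."""


@dataclass
class OtuTable:
    """Integer count matrix (samples x OTUs) with ids and optional taxonomy.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per sample.
    sample_ids, otu_ids
        Unique row / column labels.
    taxonomy
        Optional map OTU id -> semicolon-delimited lineage string.
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x OTUs matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        n_s, n_o = self.counts.shape
        if len(self.sample_ids) != n_s:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n_s} rows")
        if len(self.otu_ids) != n_o:
            raise ValueError(f"{len(self.otu_ids)} OTU ids for {n_o} columns")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != n_o:
            raise ValueError("duplicate OTU ids")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, taxonomy: dict[str, str] | None = None) -> "OtuTable":
        return cls(
            counts=df.to_numpy(),
            sample_ids=[str(s) for s in df.index],
            otu_ids=[str(o) for o in df.columns],
            taxonomy=taxonomy,
        )


@dataclass
class RelativeAbundanceTable:
    """Row-normalized proportions with the same ids as the source table."""

    proportions: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        row_sums = self.proportions.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("rows of a RelativeAbundanceTable must sum to 1")
        if ((self.proportions < 0) | (self.proportions > 1)).any():
            raise ValueError("proportions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.sample_ids, columns=self.otu_ids)

    def restrict(self, otu_ids: list[str]) -> pd.DataFrame:
        """Columns for the given OTUs, in the given order (not renormalized)."""
        return self.to_frame()[list(otu_ids)]

    def mean_abundance(self) -> pd.Series:
        return self.to_frame().mean(axis=0)


@dataclass
class DiversityResult:
    """Per-sample Shannon index (nats) and observed richness."""

    shannon: pd.Series
    richness: pd.Series = field(repr=False)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    All-zero OTU columns are retained so that OTU ids stay aligned across
    tables. Raises ``ValueError`` naming the first sample whose total is
    below ``depth``.
    """
    depth = int(depth)
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.sample_totals()
    deficient = np.flatnonzero(totals < depth)
    if deficient.size:
        sid = table.sample_ids[deficient[0]]
        raise ValueError(
            f"sample {sid!r} has {totals[deficient[0]]} reads, fewer than depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return OtuTable(out, list(table.sample_ids), list(table.otu_ids), table.taxonomy)


def relative_abundance(table: OtuTable) -> RelativeAbundanceTable:
    """Divide each sample's counts by its total."""
    totals = table.sample_totals()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"sample {table.sample_ids[zero[0]]!r} has zero total count")
    props = table.counts / totals[:, None]
    return RelativeAbundanceTable(props, list(table.sample_ids), list(table.otu_ids))


def shannon_diversity(table: OtuTable) -> DiversityResult:
    """Shannon index H = -sum p_i ln p_i over nonzero OTUs, plus richness."""
    rel = relative_abundance(table)
    p = rel.proportions
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    shannon = pd.Series(terms.sum(axis=1), index=table.sample_ids, name="shannon")
    richness = pd.Series(
        (table.counts > 0).sum(axis=1), index=table.sample_ids, name="richness"
    )
    return DiversityResult(shannon=shannon, richness=richness)


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sd 1 (sample sd, n-1 denominator).

    A zero-variance vector maps to all zeros and emits a
    :class:`ZeroVarianceWarning` instead of raising, so constant background
    OTUs cannot crash the pipeline.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("zscore requires a 1-D vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance vector z-scored to zeros", ZeroVarianceWarning)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def select_top_otus(rel: RelativeAbundanceTable, coverage: float = 0.80) -> list[str]:
    """Dominant OTUs: shortest mean-abundance-ranked prefix covering ``coverage``.

    OTUs are sorted by mean relative abundance across samples (descending,
    ties broken by OTU id ascending); the returned prefix is the shortest
    whose cumulative mean abundance reaches ``coverage`` (inclusive).
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    means = rel.mean_abundance()
    order = sorted(means.index, key=lambda o: (-means[o], o))
    ordered = means[order]
    nonzero = ordered[ordered > 0]
    cum = nonzero.cumsum()
    hit = np.flatnonzero(cum.to_numpy() >= coverage - 1e-12)
    if hit.size == 0:
        return list(nonzero.index)  # float shortfall at coverage ~ 1
    return list(nonzero.index[: hit[0] + 1])
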