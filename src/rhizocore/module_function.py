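"""Module abundance / richness and their linkage to soil functional potential.

Module abundance per sample is the mean of the member OTUs' z-scored
relative abundances. Module x functional-variable Spearman matrices then
designate the "core" module: the one with the most significant positive
associations with functional potential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community_table import OtuTable, RelativeAbundanceTable, zscore
from .correlation_network import ModulePartition, spearman_xy

__all__ = [
    "GENE_COLUMNS",
    "RATE_COLUMNS",
    "FUNCTION_COLUMNS",
    "FunctionalProfile",
    "CoreModuleReport",
    "RegressionResult",
    "module_abundance",
    "module_richness",
    "module_function_correlation",
    "designate_core",
    "richness_function_regression",
]

GENE_COLUMNS = ["cbbL", "beta_glu", "ChiA", "nifH", "AOB_amoA", "narG", "nirK", "cnorB"]
RATE_COLUMNS = ["rubisco", "pnr", "dea"]
FUNCTION_COLUMNS = GENE_COLUMNS + RATE_COLUMNS


@dataclass
class FunctionalProfile:
    """Per-sample functional-gene abundances and process rates.

    ``data`` is samples x variables on the original (positive) scale:
    gene copies per g dry soil for the eight assayed genes, plus the
    rubisco / pnr / dea process rates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FUNCTION_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"functional profile missing columns: {missing}")
        if (self.data[FUNCTION_COLUMNS] < 0).any().any():
            raise ValueError("functional values must be >= 0 on the original scale")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def functional_potential_z(self) -> pd.DataFrame:
        """Per-variable z-scores (sample sd); the 'soil functional potential'."""
        out = {}
        for col in FUNCTION_COLUMNS:
            out[col] = zscore(self.data[col].to_numpy())
        return pd.DataFrame(out, index=self.data.index)


@dataclass
class CoreModuleReport:
    """Module x functional-variable association matrix and core designation."""

    rho: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    sig_positive_counts: pd.Series
    core_module_id: int | None = None


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def module_abundance(
    rel: RelativeAbundanceTable, part: ModulePartition, modules: list[int] | None = None
) -> pd.DataFrame:
    """Per-sample module abundance: mean of member OTUs' z-scored abundances.

    Returns a samples x modules DataFrame (columns = ``modules``,
    defaulting to the partition's main modules). A requested module with
    no member present in the table raises ``ValueError``.
    """
    df = rel.to_frame()
    modules = list(part.main_modules) if modules is None else list(modules)
    cols: dict[int, np.ndarray] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant members z-score to zeros
        for m in modules:
            members = [o for o in part.members(m) if o in df.columns]
            if not members:
                raise ValueError(f"module {m} has no members in the abundance table")
            z = np.column_stack([zscore(df[o].to_numpy()) for o in members])
            cols[m] = z.mean(axis=1)
    return pd.DataFrame(cols, index=df.index)


def module_richness(table: OtuTable, part: ModulePartition, module_id: int) -> pd.Series:
    """Per-sample count of module-member OTUs with count > 0."""
    if module_id not in part.sizes():
        raise ValueError(f"unknown module id {module_id}")
    members = [o for o in part.members(module_id) if o in table.otu_ids]
    df = table.to_frame()
    return (df[members] > 0).sum(axis=1).rename(f"module_{module_id}_richness")


def module_function_correlation(
    ma: pd.DataFrame, fp: FunctionalProfile
) -> CoreModuleReport:
    """Spearman rho/p for every (module, functional variable) pair.

    Uses the functional-potential z-scores (rank-equivalent to the raw
    values). Significance stars at p < 0.05 / 0.01 / 0.001.
    """
    fz = fp.functional_potential_z()
    unmatched = sorted(set(map(str, ma.index)) ^ set(map(str, fz.index)))
    if unmatched:
        raise ValueError(f"sample ids do not match between tables: {unmatched}")
    fz = fz.loc[ma.index]
    modules = list(ma.columns)
    rho = pd.DataFrame(index=modules, columns=FUNCTION_COLUMNS, dtype=float)
    p = pd.DataFrame(index=modules, columns=FUNCTION_COLUMNS, dtype=float)
    for m in modules:
        for v in FUNCTION_COLUMNS:
            r, pv = spearman_xy(ma[m].to_numpy(), fz[v].to_numpy())
            rho.loc[m, v] = r
            p.loc[m, v] = pv
    stars = p.map(_stars)
    sig_pos = ((p < 0.05) & (rho > 0)).sum(axis=1)
    return CoreModuleReport(rho=rho, p=p, stars=stars, sig_positive_counts=sig_pos)


def designate_core(
    report: CoreModuleReport, alpha: float = 0.05, bh_correct: bool = False
) -> int | None:
    """Pick the core module from a :class:`CoreModuleReport`.

    Core = module with the greatest count of significant (p < ``alpha``)
    positive correlations across functional variables; ties broken by
    larger mean rho over the significant positives, then by larger module
    id position in the report (listed first = larger module). Returns
    ``None`` with a warning when no module has any significant positive
    association. ``bh_correct`` applies Benjamini-Hochberg across the whole
    module x variable matrix first (off by default).
    """
    p = report.p.copy()
    if bh_correct:
        flat = p.to_numpy().ravel()
        adj = stats.false_discovery_control(flat, method="bh")
        p = pd.DataFrame(
            adj.reshape(p.shape), index=p.index, columns=p.columns
        )
    sig = (p < alpha) & (report.rho > 0)
    counts = sig.sum(axis=1)
    report.sig_positive_counts = counts
    if counts.max() == 0:
        warnings.warn("no module has a significant positive functional association")
        report.core_module_id = None
        return None

    def key(m):
        c = counts[m]
        mean_rho = report.rho.loc[m][sig.loc[m]].mean() if c else -np.inf
        pos = list(report.p.index).index(m)  # earlier = larger module
        return (-c, -mean_rho, pos)

    core = min(report.p.index, key=key)
    report.core_module_id = int(core)
    return int(core)


def richness_function_regression(
    richness: pd.Series | np.ndarray, fz: pd.Series | np.ndarray
) -> RegressionResult:
    """OLS of a functional-potential z-score on module richness.

    R^2 is the squared correlation; p from the t-test on the slope with
    n - 2 df.
    """
    x = np.asarray(richness, dtype=float)
    y = np.asarray(fz, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("richness has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
    )
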