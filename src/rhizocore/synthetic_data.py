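"""Synthetic communities with planted statistical structure.

Every downstream stage of the pipeline is testable offline against these
generators, which plant: block-correlated OTU modules driven by per-sample
latent factors, one "core" module whose factor drives the functional-gene
abundances and process rates, noisy linear time series for the rate assays,
and 16S/genome sequence pairs at exact nucleotide identities.

The generative choices (latent-factor log-normal intensities, multinomial
read sampling) are stand-ins: no distributional model of real community
data is implied, only the within-module correlation structure the network
analysis assumes.

Seeding: one global seed expands to per-stage child seeds by fixed
offsets (community +0, functions +1, rates +2, sequences +3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_table import OtuTable
from .module_function import FUNCTION_COLUMNS, FunctionalProfile
from .process_rates import TimeSeries

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SequenceFixture",
    "DEFAULT_RATE_TIMES",
    "simulate_community",
    "simulate_functions",
    "simulate_rate_timeseries",
    "simulate_sequences",
    "treatment_labels",
]

#: default sampling grid (hours) for the rate-assay time series
DEFAULT_RATE_TIMES = (24.0, 48.0, 72.0, 96.0, 130.0, 154.0)

_COMMUNITY_SEED_OFFSET = 0
_FUNCTION_SEED_OFFSET = 1
_RATE_SEED_OFFSET = 2
_SEQUENCE_SEED_OFFSET = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the planted-structure community generator."""

    n_samples: int = 18
    n_modules: int = 3
    otus_per_module: int = 25
    n_background_otus: int = 25
    loading: float = 0.9
    noise_sd: float = 0.3
    core_module_index: int = 0
    function_effect: float = 1.0
    sequencing_depth: int = 28_795
    n_treatments: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_modules", "otus_per_module", "n_treatments"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_background_otus < 0:
            raise ValueError("n_background_otus must be >= 0")
        if self.noise_sd <= 0 or self.sequencing_depth <= 0:
            raise ValueError("noise_sd and sequencing_depth must be > 0")
        if self.loading < 0:
            raise ValueError("loading must be >= 0")
        if not 0 <= self.core_module_index < self.n_modules:
            raise ValueError("core_module_index must index a planted module")

    @property
    def n_otus(self) -> int:
        return self.n_modules * self.otus_per_module + self.n_background_otus


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    module_of_otu: dict[str, int | None]
    core_module_id: int
    factor_values: np.ndarray  # samples x modules
    gene_effects: dict[str, float] = field(default_factory=dict)
    rate_slopes: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def planted_labels(self, otu_ids: list[str]) -> list[int]:
        """Module labels for planted OTUs only (background excluded)."""
        return [self.module_of_otu[o] for o in otu_ids if self.module_of_otu[o] is not None]


@dataclass
class SequenceFixture:
    """OTU representative sequences paired with mutated genome 16S copies."""

    otu_seqs: dict[str, str]
    genome_seqs: dict[str, str]
    mutations: dict[str, list[int]]  # genome id -> mutated positions
    identities: dict[str, float]  # genome id -> realized identity


def _otu_ids(config: SimulationConfig) -> list[str]:
    return [f"OTU_{i + 1:04d}" for i in range(config.n_otus)]


def treatment_labels(config: SimulationConfig) -> list[str]:
    """Cyclic treatment assignment T1..Tk over the samples."""
    return [f"T{(i % config.n_treatments) + 1}" for i in range(config.n_samples)]


def simulate_community(config: SimulationConfig) -> tuple[OtuTable, SyntheticTruth]:
    """Draw an OTU count table with block-correlated planted modules.

    Per sample s and module m a latent factor f_m(s) ~ N(0, 1) is drawn.
    Member OTU log-intensity = loading * f_m(s) + noise_sd * eps;
    background OTUs are pure noise. Intensities are exponentiated,
    normalized to proportions, and counts drawn multinomially at
    ``sequencing_depth``.
    """
    rng = np.random.default_rng(config.seed + _COMMUNITY_SEED_OFFSET)
    s, m, k = config.n_samples, config.n_modules, config.n_otus
    factors = rng.standard_normal((s, m))
    log_int = config.noise_sd * rng.standard_normal((s, k))
    module_of: dict[str, int | None] = {}
    ids = _otu_ids(config)
    for j, otu in enumerate(ids):
        mod = j // config.otus_per_module
        if mod < m:
            log_int[:, j] += config.loading * factors[:, mod]
            module_of[otu] = mod
        else:
            module_of[otu] = None
    intensity = np.exp(log_int)
    props = intensity / intensity.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(config.sequencing_depth, props[i]) for i in range(s)]
    )
    table = OtuTable(
        counts=counts,
        sample_ids=[f"S{i + 1:03d}" for i in range(s)],
        otu_ids=ids,
    )
    truth = SyntheticTruth(
        module_of_otu=module_of,
        core_module_id=config.core_module_index,
        factor_values=factors,
        seed=config.seed,
    )
    return table, truth


def simulate_functions(truth: SyntheticTruth, config: SimulationConfig) -> FunctionalProfile:
    """Functional profile driven by the core module's latent factor.

    Per variable v: log-value = function_effect * f_core(s) + noise_sd * eps,
    stored exponentiated (all values > 0). True slopes land in
    ``truth.gene_effects`` / ``truth.rate_slopes``.
    """
    if truth.core_module_id >= truth.factor_values.shape[1]:
        raise ValueError(f"unknown core module id {truth.core_module_id}")
    rng = np.random.default_rng(config.seed + _FUNCTION_SEED_OFFSET)
    f_core = truth.factor_values[:, truth.core_module_id]
    data = {}
    for v in FUNCTION_COLUMNS:
        logv = config.function_effect * f_core + config.noise_sd * rng.standard_normal(
            len(f_core)
        )
        data[v] = np.exp(logv)
        truth.gene_effects[v] = config.function_effect
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    return FunctionalProfile(pd.DataFrame(data, index=sample_ids))


def simulate_rate_timeseries(
    slope: float,
    intercept: float,
    times: tuple[float, ...] = DEFAULT_RATE_TIMES,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "S001",
    assay: str = "PNR",
) -> TimeSeries:
    """Noisy linear concentration series: value = slope*t + intercept + eps."""
    t = np.asarray(times, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time points")
    rng = np.random.default_rng(seed + _RATE_SEED_OFFSET)
    values = slope * t + intercept + noise_sd * rng.standard_normal(len(t))
    return TimeSeries(sample_id=sample_id, times=t, values=values, assay=assay)


_BASES = np.array(list("ACGT"))


def simulate_sequences(
    n_genomes: int,
    length: int,
    identity_to_otu: float | list[float],
    seed: int = 0,
) -> SequenceFixture:
    """Random OTU 16S sequences with genome copies at exact identities.

    Genome i's 16S sequence is OTU i's sequence with exactly
    ``round((1 - identity_i) * length)`` positions mutated to different
    bases, so the realized identity is deterministic.
    """
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    if np.isscalar(identity_to_otu):
        identities = [float(identity_to_otu)] * n_genomes
    else:
        identities = [float(x) for x in identity_to_otu]
        if len(identities) != n_genomes:
            raise ValueError("one identity per genome required")
    if any(not 0 <= x <= 1 for x in identities):
        raise ValueError("identities must lie in [0, 1]")
    rng = np.random.default_rng(seed + _SEQUENCE_SEED_OFFSET)
    otu_seqs: dict[str, str] = {}
    genome_seqs: dict[str, str] = {}
    mutations: dict[str, list[int]] = {}
    realized: dict[str, float] = {}
    for i in range(n_genomes):
        otu_id, genome_id = f"OTU_{i + 1:04d}", f"GENOME_{i + 1:03d}"
        seq = rng.choice(_BASES, size=length)
        otu_seqs[otu_id] = "".join(seq)
        n_mut = int(round((1 - identities[i]) * length))
        pos = sorted(rng.choice(length, size=n_mut, replace=False).tolist())
        mutated = seq.copy()
        for p in pos:
            choices = [b for b in "ACGT" if b != mutated[p]]
            mutated[p] = choices[rng.integers(3)]
        genome_seqs[genome_id] = "".join(mutated)
        mutations[genome_id] = pos
        realized[genome_id] = 1 - n_mut / length
    return SequenceFixture(
        otu_seqs=otu_seqs,
        genome_seqs=genome_seqs,
        mutations=mutations,
        identities=realized,
    )
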