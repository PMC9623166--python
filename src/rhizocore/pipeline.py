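"""End-to-end orchestration: OTU table -> network -> core module -> report.

The report is fully determined by (inputs, config, seeds): no timestamps
or machine state land in it, so identical invocations produce
byte-identical report files.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, community_table, correlation_network, group_stats, io
from . import module_function as mf

logger = logging.getLogger("rhizocore")


@dataclass
class RunConfig:
    """Thresholds and seeds for a full pipeline run (defaults as published)."""

    otu_table: str | None = None
    metadata: str | None = None
    functional_profile: str | None = None
    out_dir: str = "rhizocore_out"
    coverage: float = 0.80
    r_min: float = 0.8
    p_max: float = 0.01
    keystone_k: int = 20
    min_module_size: int = 5
    rarefaction_depth: int = 28_795
    identity_threshold: float = 0.97
    rarefy: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must lie in (0, 1]")
        if not 0 < self.r_min <= 1 or not 0 < self.p_max <= 1:
            raise ValueError("r_min and p_max must lie in (0, 1]")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction depth must be >= 1")
        if not 0 <= self.identity_threshold <= 1:
            raise ValueError("identity threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = io.read_yaml(path)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _setup_run_log(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        stderr = logging.StreamHandler(sys.stderr)
        stderr.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(stderr)
    logger.setLevel(logging.INFO)
    return handler


class _Stage:
    """Context manager logging stage name, elapsed time and record counts."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage=%s status=start", self.name)
        return self

    def done(self, **counts):
        self.counts = counts

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.t0
        if exc_type is not None:
            logger.error("stage=%s status=error error=%r", self.name, exc)
            return False
        extras = " ".join(f"{k}={v}" for k, v in getattr(self, "counts", {}).items())
        logger.info("stage=%s status=done elapsed=%.3fs %s", self.name, elapsed, extras)
        return False


def run_pipeline(
    config: RunConfig,
    table: community_table.OtuTable | None = None,
    functions: mf.FunctionalProfile | None = None,
    metadata: pd.DataFrame | None = None,
) -> dict:
    """Execute community -> network -> core-module (-> group stats) stages.

    Inputs may be passed in-memory or read from the paths in ``config``.
    Writes all artifacts plus ``report.json`` into ``config.out_dir`` and
    returns the report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(out)
    report: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }
    try:
        with _Stage("load") as st:
            if table is None:
                if config.otu_table is None:
                    raise ValueError("no OTU table provided")
                table = io.read_otu_table(config.otu_table)
            if functions is None and config.functional_profile:
                functions = io.read_functional_profile(config.functional_profile)
            if metadata is None and config.metadata:
                metadata = io.read_metadata(config.metadata)
            st.done(samples=table.n_samples, otus=table.n_otus)

        with _Stage("community") as st:
            if config.rarefy:
                depth = min(config.rarefaction_depth, int(table.sample_totals().min()))
                if depth < config.rarefaction_depth:
                    logger.warning(
                        "rarefaction depth lowered to %d (shallowest sample)", depth
                    )
                table = community_table.rarefy(table, depth, seed=config.seed)
            rel = community_table.relative_abundance(table)
            div = community_table.shannon_diversity(table)
            top = community_table.select_top_otus(rel, coverage=config.coverage)
            st.done(top_otus=len(top))
            report["stages"]["community"] = {
                "n_samples": table.n_samples,
                "n_otus": table.n_otus,
                "n_top_otus": len(top),
                "mean_shannon": round(float(div.shannon.mean()), 6),
            }

        with _Stage("network") as st:
            corr = correlation_network.spearman_matrix(rel, otu_ids=top)
            net = correlation_network.filter_edges(corr, config.r_min, config.p_max)
            n_edges = net.number_of_edges()
            io.write_network(net, out / "network.graphml", out / "edges.tsv")
            report["stages"]["network"] = {
                "n_nodes": net.number_of_nodes(),
                "n_edges": n_edges,
            }
            st.done(nodes=net.number_of_nodes(), edges=n_edges)

        part = None
        if net.number_of_edges() > 0:
            with _Stage("modules") as st:
                part = correlation_network.detect_modules(
                    net, seed=config.seed, min_size=config.min_module_size
                )
                io.write_partition(part, out / "partition.json")
                sizes = part.sizes()
                report["stages"]["modules"] = {
                    "n_modules": len(sizes),
                    "main_modules": part.main_modules,
                    "main_module_sizes": {str(m): sizes[m] for m in part.main_modules},
                    "modularity": round(part.modularity, 6),
                }
                st.done(modules=len(sizes), main=len(part.main_modules))

            with _Stage("keystones") as st:
                cent = correlation_network.centralities(net)
                ks = correlation_network.select_keystones(cent, k=config.keystone_k)
                io.write_keystones(ks, out / "keystones.json")
                report["stages"]["keystones"] = {"nodes": ks.nodes}
                st.done(keystones=len(ks.nodes))
        else:
            report["stages"]["modules"] = {"n_modules": 0, "main_modules": []}
            report["stages"]["keystones"] = {"nodes": []}
            logger.warning("empty network: module/keystone stages skipped")

        if part is not None and functions is not None and part.main_modules:
            with _Stage("core_module") as st:
                ma = mf.module_abundance(rel, part)
                rep = mf.module_function_correlation(ma, functions)
                core = mf.designate_core(rep)
                overlap = 0
                if core is not None:
                    members = set(part.members(core))
                    overlap = sum(1 for n in ks.nodes if n in members)
                report["stages"]["core_module"] = {
                    "core_module_id": core,
                    "sig_positive_counts": {
                        str(m): int(c) for m, c in rep.sig_positive_counts.items()
                    },
                    "keystone_core_overlap": overlap,
                }
                rep.rho.to_csv(out / "module_function_rho.tsv", sep="\t")
                rep.p.to_csv(out / "module_function_p.tsv", sep="\t")
                st.done(core=core, overlap=overlap)

        if metadata is not None and functions is not None and "treatment" in metadata:
            with _Stage("group_stats") as st:
                groups = [str(g) for g in metadata.loc[functions.data.index, "treatment"]]
                anova = {}
                for col in functions.data.columns:
                    gc = group_stats.anova_tukey(
                        functions.data[col].to_numpy(), groups, variable=col
                    )
                    anova[col] = {
                        "F": round(gc.f_statistic, 6),
                        "p": round(gc.p, 6),
                        "letters": gc.letters,
                    }
                bc = group_stats.bray_curtis(rel)
                perm = group_stats.permanova(bc, groups, seed=config.seed)
                report["stages"]["group_stats"] = {
                    "anova": anova,
                    "permanova": {
                        "pseudo_F": round(perm.pseudo_f, 6),
                        "R2": round(perm.r_squared, 6),
                        "p": perm.p,
                    },
                }
                st.done(variables=len(anova))

        io.write_json(report, out / "report.json")
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
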