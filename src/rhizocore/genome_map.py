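"""OTU -> reference-genome mapping by 16S identity and gene-content comparison.

A small global aligner with free end gaps (match +1, mismatch -1, gap -2)
replaces BLAST at desk scale; identity is matches over aligned columns,
excluding end-gap overhangs ("across the sequenced regions"). Mapped
genomes inherit the network module of their best-identity OTU, and their
normalized functional-gene content (percentage of genes per genome) is
compared between modules with Mann-Whitney U tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .correlation_network import ModulePartition

__all__ = [
    "GenomeRecord",
    "OtuGenomeMap",
    "ModuleGeneComparison",
    "C_CYCLING_GENES",
    "N_CYCLING_GENES",
    "pairwise_identity",
    "map_otus_to_genomes",
    "normalized_gene_copies",
    "compare_module_gene_content",
]

# Reference gene panels for per-genome functional content. Seeded with the
# canonical C-cycling (18) and N-cycling (14) marker genes; extensible by
# passing custom categories to normalized_gene_copies.
C_CYCLING_GENES = [
    "abfA", "accA", "acsA", "acsE", "amyA", "bglX", "cbbL", "cbbM", "cdhA",
    "chiA", "cooS", "frdA", "korA", "manB", "mcrA", "pccA", "smtA", "xylA",
]
N_CYCLING_GENES = [
    "amoA", "anfG", "gdhA", "hao", "hdhA", "napA", "narG", "nasA", "nifH",
    "nirK", "nirS", "norB", "nosZ", "nrfA",
]
DEFAULT_CATEGORIES = {"C_cycling": C_CYCLING_GENES, "N_cycling": N_CYCLING_GENES}

_VALID = set("ACGTN")

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_SCORE = -2.0


@dataclass
class GenomeRecord:
    """A reference genome: 16S copies plus annotated gene copy counts."""

    genome_id: str
    ssu_sequences: list[str]
    gene_counts: dict[str, int] = field(default_factory=dict)
    total_genes: int = 0

    def __post_init__(self) -> None:
        if not self.ssu_sequences or any(not s for s in self.ssu_sequences):
            raise ValueError("ssu_sequences must be non-empty")
        listed = sum(self.gene_counts.values())
        if self.total_genes and self.total_genes < listed:
            raise ValueError("total_genes below the sum of listed gene copies")


#: OTU id -> [(genome id, best-copy identity)], identity-descending
OtuGenomeMap = dict[str, list[tuple[str, float]]]


@dataclass
class ModuleGeneComparison:
    """Per-module gene-content distributions and pairwise rank tests."""

    module_of_genome: dict[str, int]
    per_module_stats: pd.DataFrame  # (module, column) -> mean/median/n
    pairwise_tests: pd.DataFrame  # rows: (module_a, module_b, column, U, p)


def _build_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    # free end gaps
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # biopython < 1.88 spelling
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = _build_aligner()


def _validate(seq: str) -> str:
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Identity fraction from a free-end-gap global alignment.

    Matches / aligned columns, where end-gap overhangs are excluded from
    the column count and N never counts as a match.
    """
    a, b = _validate(seq_a), _validate(seq_b)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if b < a:  # canonical order: co-optimal alignments would otherwise break symmetry
        a, b = b, a
    aln = _ALIGNER.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # trim end overhangs: leading/trailing columns where either row is gapped
    start, end = 0, len(sa)
    while start < end and (sa[start] == "-" or sb[start] == "-"):
        start += 1
    while end > start and (sa[end - 1] == "-" or sb[end - 1] == "-"):
        end -= 1
    if end == start:
        return 0.0
    matches = sum(
        1
        for x, y in zip(sa[start:end], sb[start:end])
        if x == y and x != "-" and x != "N"
    )
    return matches / (end - start)


def map_otus_to_genomes(
    otu_seqs: dict[str, str],
    genomes: list[GenomeRecord],
    threshold: float = 0.97,
) -> OtuGenomeMap:
    """All-vs-all identity mapping at the given threshold.

    A genome maps to an OTU when ANY of its 16S copies reaches the
    threshold; the best copy's identity is recorded. Lists are sorted by
    identity descending (ties by genome id).
    """
    if not otu_seqs or not genomes:
        raise ValueError("otu_seqs and genomes must be non-empty")
    out: OtuGenomeMap = {}
    for otu_id, oseq in otu_seqs.items():
        hits: list[tuple[str, float]] = []
        for g in genomes:
            best = max(pairwise_identity(oseq, s) for s in g.ssu_sequences)
            if best >= threshold:
                hits.append((g.genome_id, best))
        hits.sort(key=lambda h: (-h[1], h[0]))
        out[otu_id] = hits
    return out


def normalized_gene_copies(
    genomes: list[GenomeRecord],
    genes: list[str] | None = None,
    categories: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Percentage of genes per genome: 100 * copies / total_genes.

    One column per gene plus one per category (sum over member genes).
    """
    if categories is None:
        categories = DEFAULT_CATEGORIES
    if genes is None:
        genes = sorted({g for members in categories.values() for g in members})
    rows = {}
    for g in genomes:
        if g.total_genes <= 0:
            raise ValueError(f"genome {g.genome_id} has zero total_genes")
        row = {
            gene: 100.0 * g.gene_counts.get(gene, 0) / g.total_genes for gene in genes
        }
        for cat, members in categories.items():
            row[cat] = sum(row.get(gene, 0.0) for gene in members)
        rows[g.genome_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def _genome_module(
    otu_map: OtuGenomeMap, part: ModulePartition
) -> dict[str, int]:
    """Assign each mapped genome the module of its best-identity OTU."""
    best: dict[str, tuple[float, str]] = {}
    for otu_id, hits in otu_map.items():
        if otu_id not in part.module_of_node:
            continue
        for genome_id, ident in hits:
            cur = best.get(genome_id)
            # higher identity wins; ties broken by lexicographic OTU id
            if cur is None or ident > cur[0] or (ident == cur[0] and otu_id < cur[1]):
                best[genome_id] = (ident, otu_id)
    return {g: part.module_of_node[otu] for g, (_, otu) in best.items()}


def compare_module_gene_content(
    otu_map: OtuGenomeMap,
    part: ModulePartition,
    percentages: pd.DataFrame,
    columns: list[str] | None = None,
) -> ModuleGeneComparison:
    """Compare per-genome gene percentages between network modules.

    Genomes take the module of their best-identity OTU; modules with
    fewer than 2 mapped genomes are dropped with a warning. Pairwise
    two-sided Mann-Whitney U tests per column between remaining modules.
    """
    module_of_genome = {
        g: m for g, m in _genome_module(otu_map, part).items() if g in percentages.index
    }
    counts: dict[int, int] = {}
    for m in module_of_genome.values():
        counts[m] = counts.get(m, 0) + 1
    kept = sorted(m for m, c in counts.items() if c >= 2)
    dropped = sorted(set(counts) - set(kept))
    if dropped:
        warnings.warn(f"modules with < 2 mapped genomes excluded: {dropped}")
    if len(kept) < 2:
        raise ValueError("need >= 2 modules with >= 2 mapped genomes each")
    if columns is None:
        columns = list(percentages.columns)

    stat_rows = []
    for m in kept:
        members = [g for g, mm in module_of_genome.items() if mm == m]
        sub = percentages.loc[members, columns]
        for col in columns:
            stat_rows.append(
                {
                    "module": m,
                    "column": col,
                    "n": len(members),
                    "mean": float(sub[col].mean()),
                    "median": float(sub[col].median()),
                }
            )
    test_rows = []
    for ma, mb in itertools.combinations(kept, 2):
        ga = [g for g, mm in module_of_genome.items() if mm == ma]
        gb = [g for g, mm in module_of_genome.items() if mm == mb]
        for col in columns:
            u, p = stats.mannwhitneyu(
                percentages.loc[ga, col],
                percentages.loc[gb, col],
                alternative="two-sided",
            )
            test_rows.append(
                {"module_a": ma, "module_b": mb, "column": col, "U": float(u), "p": float(p)}
            )
    return ModuleGeneComparison(
        module_of_genome=module_of_genome,
        per_module_stats=pd.DataFrame(stat_rows),
        pairwise_tests=pd.DataFrame(test_rows),
    )
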