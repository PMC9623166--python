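# rhizocore

Co-occurrence network inference for soil microbiome OTU tables: from counts
and soil functional measurements to a designated **core network module**,
its **keystone taxa**, and their linkage to C/N-cycling **functional
potential**.

The pipeline chain is:

1. **community_table** — rarefaction (default depth 28,795), relative
   abundance, Shannon/richness, selection of the dominant OTUs covering
   ≥ 80% of mean relative abundance.
2. **correlation_network** — all-pairs Spearman correlations (exact
   permutation p for n ≤ 9 samples, t-approximation otherwise), edge filter
   |rho| ≥ 0.8 and p ≤ 0.01, seeded Louvain module detection, degree /
   closeness / betweenness centralities, top-20 keystone taxa by composite
   rank sum (high degree, high closeness, low betweenness).
3. **module_function** — per-sample module abundance (mean of member
   z-scores), module × functional-variable Spearman matrix, core-module
   designation (most significant positive associations; optional
   Benjamini–Hochberg correction), richness–function regression.
4. **process_rates** — slope-based PNR/DEA rates (DEA restricted to the
   latest four time points), qPCR standard curves with QC gates
   (R² > 0.98, efficiency ≥ 85%), absolute quantification, spectrophotometric
   RubisCO activity.
5. **genome_map** — OTU→genome mapping by 16S identity (free-end-gap global
   alignment, ≥ 97% threshold), normalized per-genome gene-copy percentages,
   module-wise gene-content comparison (Mann–Whitney U).
6. **group_stats** — ANOVA + Tukey HSD with compact letter display,
   Bray–Curtis, PERMANOVA (seeded, add-one permutation p).
7. **synthetic_data** — planted-structure community generator (latent-factor
   log-normal intensities, multinomial reads) so every stage is testable
   offline. The generative model is a stand-in with planted correlation
   structure, not a model of real community data.

## CLI

```sh
# generate a synthetic community with planted modules + truth.json
rhizocore simulate --out sim/ --seed 1

# full pipeline: network -> modules -> keystones -> core module -> stats
rhizocore run --otu-table sim/otu_table.tsv \
              --functions sim/functional_profile.tsv \
              --metadata sim/metadata.tsv \
              --seed 1 --out out/
```

Subcommands `community`, `network`, `core-module`, `rates`, `genome-map`
and `stats` run individual stages; see `rhizocore <cmd> --help`. Every run
writes structured per-stage logs to stderr and `<out>/run.log`, and `run`
produces a deterministic `report.json` (byte-identical under the same seed).

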