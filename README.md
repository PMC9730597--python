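# regevo

Comparative epigenomics of regulatory elements (REs) across mammals, as a
tested, reusable Python pipeline. The package covers the analysis chain used
in cross-species liver regulome studies:

1. **Consensus peak calling** — replicate H3K27ac / H3K4me3 peak sets are
   reduced to consensus peaks (reproducible in ≥ 2 biological replicates at
   ≥ 50% overlap of either peak's length, then merged).
2. **Promoter / enhancer classification** — a consensus H3K27ac region
   co-marked by H3K4me3 at ≥ 50% overlap is a *promoter*; one with zero
   H3K4me3 overlap is an *enhancer*; sub-threshold overlaps go to an explicit
   *ambiguous* bin so the classes partition the input.
3. **Cross-species conservation** — anchor-species REs are projected through
   a pairwise interval map (an EPO-alignment stand-in) and labelled
   all-conserved (AC), clade-specific (e.g. ruminant-specific, RS),
   species-specific (CS), or "other" by where class-matched activity is
   shared. Per-species counts decompose as

   N_i = N_N + N_L + N_C,   N_s = N_N + N_L,

   where N_N counts REs with no DNA alignment in any other species, N_L those
   alignable but active nowhere else, and N_C those with activity shared in
   ≥ 1 other species.
4. **Omics phylogenies** — interspecies distances 1 − ρ (Spearman's rank
   correlation over orthologous features), neighbor-joining trees, and
   feature-bootstrap total branch lengths to compare evolution rates across
   omics data types (expression, H3K27ac, H3K4me3, accessibility,
   methylation).
5. **RE-to-gene linking** — GREAT-style basal regulatory domains (5 kb
   upstream / 1 kb downstream of the TSS), gene categories
   (Both / Promoter / Enhancer / None), expression-matched comparisons
   (caliper in SD units), and exact/asymptotic Wilcoxon tests.
6. **Enrichment** — regioneR-style permutation tests of region overlap
   (fold = observed / mean permuted) and the count-based marker-set GWAS
   test: T_count = Σ_j I(p_j < t_o) over the c SNPs inside the (50-kb
   windowed) region set, tested against a hypergeometric null with
   t_o = 0.01 and significance at P < 1e−5.

A synthetic-data module generates every input with known ground truth —
multi-species replicate peak sets with a planted conservation mix, a
cross-species map with known alignability, signal matrices evolved by
Brownian motion on a known species tree, and GWAS summary statistics with
planted in-region enrichment — so every stage is verifiable without any
sequencing data.

Intended users: computational biologists who want the statistical machinery
of cross-species regulome comparisons (or a ground-truthed sandbox for it)
without the upstream read-processing stack. Coordinates are 0-based
half-open (BED convention) throughout.

## Worked example

```python
import pandas as pd
from regevo import SimulationConfig, simulate_multispecies_res, simulate_gwas, RegionSet
from regevo.annotation import consensus_peaks, classify_res
from regevo.conservation import classify_conservation, species_specific_counts
from regevo.enrichment import count_based_gwas_test

cfg = SimulationConfig(seed=7, n_res=300, n_private_res=100, n_snps=50_000)
sim = simulate_multispecies_res(cfg)

re_sets = {}
for sp in cfg.species:
    cons = {m: consensus_peaks([sim.peaks[(sp, m, f"rep{r+1}")] for r in range(3)])
            for m in ("H3K27ac", "H3K4me3")}
    promoters, enhancers, _ = classify_res(cons["H3K27ac"], cons["H3K4me3"])
    re_sets[sp] = {"promoter": promoters, "enhancer": enhancers}

labels = pd.concat([
    classify_conservation(re_sets["cattle"][cls], re_sets, sim.cross_map,
                          dict(cfg.clades), "cattle", re_class=cls)
    for cls in ("promoter", "enhancer")], ignore_index=True)
counts = species_specific_counts(labels, "cattle")

planted = RegionSet(sim.ground_truth.re_table[["chrom", "start", "end"]],
                    sim.genomes["cattle"])
gwas, _ = simulate_gwas(cfg, planted)
result = count_based_gwas_test(gwas, planted, window=0)
```

Output (the numbers this prints):

```
cattle: 47 promoters, 253 enhancers
other                       120
species_specific             75
clade_specific(ruminant)     60
all_conserved                45
N_total=300  N_unaligned=30  N_aligned_unshared=45  N_shared=225  N_species_specific=75
T_count=23 of c=496 in-region SNPs (K=521, N=50000); hypergeometric P=3.86e-09; significant=True
```

Reading it: 300 cattle REs called from noisy replicate peaks split into 47
promoters and 253 enhancers; their conservation labels recover the planted
mix exactly (15% AC, 20% RS, 10% + 15% = 25% CS, 40% other), and the count
identities hold (30 + 45 + 225 = 300; 30 + 45 = 75 species-specific). The
GWAS test sees 23 of 496 in-region SNPs below t_o = 0.01 where ~5 would be
expected by chance (K/N ≈ 1%), detecting the planted 5× enrichment at
P ≈ 4e−9.

## Command line

The same stages run end-to-end from a TOML config:

```sh
regevo run-all --config run.toml --seed 7 --outdir out/
```

Subcommands: `simulate`, `call-res`, `classify-conservation`, `link-genes`,
`phylo`, `enrich-regions`, `enrich-gwas`, `run-all`. Each writes its outputs
plus a JSON manifest (parameters, seed, output SHA-256 hashes); re-running
with the same config and seed is byte-identical.

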