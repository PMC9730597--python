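"""Synthetic multi-species regulatory data with known ground truth.

Every input the pipeline consumes can be generated here: replicate
histone-mark peak sets with controlled cross-species sharing, a pairwise
cross-species interval map with known alignability, omics signal matrices
evolved on a known species tree, gene models, expression/methylation tables,
and GWAS summary statistics with planted enrichment inside chosen regions.

All generators are pure functions of (config, seed): a single global seed
fans out to fixed, independent per-generator streams, so regenerating one
stage never perturbs another.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .conservation import ABSENT, MAP_COLUMNS, CrossSpeciesMap
from .intervals import Genome, RegionSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedRegulome",
    "simulate_multispecies_res",
    "simulate_signal_matrix",
    "simulate_gwas",
    "simulate_gene_models",
    "simulate_expression",
    "simulate_methylation",
    "simulate_gene_scores",
]

FINE_LABELS = (
    "all_conserved",
    "clade_specific",
    "species_specific_unalignable",
    "species_specific_alignable",
    "other",
)

# fixed stream offsets: reproducibility is per-generator, not per-call-order
_STREAMS = {
    "res": 1,
    "signal": 2,
    "gwas": 3,
    "genes": 4,
    "expression": 5,
    "methylation": 6,
    "scores": 7,
}

DEFAULT_TREE = (
    "((cattle:0.3,(sheep:0.15,goat:0.15):0.15):0.2,"
    "(pig:0.4,(human:0.2,mouse:0.2):0.2):0.1);"
)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate a desk-scale version of a six-mammal liver regulome:
    six species in two clades (ruminants vs non-ruminants), three replicates
    per histone mark, ~21% of REs promoters, RE coordinate jitter capped at
    20% of length so 50%-overlap relations survive replicate noise.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 10_000_000
    species: tuple = ("cattle", "sheep", "goat", "pig", "human", "mouse")
    clades: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "ruminant": ("cattle", "sheep", "goat"),
            "nonruminant": ("pig", "human", "mouse"),
        }
    )
    anchor: str = "cattle"
    n_res: int = 2000
    promoter_fraction: float = 0.21
    conservation_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "all_conserved": 0.15,
            "clade_specific": 0.20,
            "species_specific_unalignable": 0.10,
            "species_specific_alignable": 0.15,
            "other": 0.40,
        }
    )
    n_private_res: int = 500
    n_replicates: int = 3
    replicate_dropout: float = 0.0
    jitter: float = 0.2
    re_length_range: tuple = (500, 2000)
    n_genes: int = 1000
    n_snps: int = 100_000
    gwas_effect: float = 5.0
    t_o: float = 0.01
    species_tree: str = DEFAULT_TREE
    omics_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "expression": 0.5,
            "h3k27ac": 1.0,
            "h3k4me3": 1.0,
            "accessibility": 1.0,
            "methylation": 2.0,
        }
    )
    n_features: int = 2000
    n_expr_samples: int = 9
    n_cpgs: int = 5000
    mean_coverage: float = 10.0
    gene_score_shift: float = 1.0

    def __post_init__(self):
        mix = dict(self.conservation_mix)
        unknown = set(mix) - set(FINE_LABELS)
        if unknown:
            raise ConfigurationError(f"unknown conservation labels {sorted(unknown)}")
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"conservation mix must sum to 1, got {total}")
        if not (0 <= self.replicate_dropout < 0.5):
            raise ConfigurationError("replicate_dropout must be in [0, 0.5)")
        if any(r <= 0 for r in self.omics_rates.values()):
            raise ConfigurationError("omics rates must be > 0")
        if self.gwas_effect < 1:
            raise ConfigurationError("gwas_effect < 1 (depletion is not modeled)")
        if self.anchor not in self.species:
            raise ConfigurationError(f"anchor {self.anchor!r} not among species")
        clade = self._anchor_clade()
        if mix.get("clade_specific", 0) > 0 and len(clade) < 2:
            raise ConfigurationError(
                "clade_specific fraction > 0 requires the anchor clade to have >= 2 species"
            )
        if mix.get("other", 0) > 0 and len(self.species) < 4:
            raise ConfigurationError(
                "'other' patterns require at least 4 species to be distinguishable"
            )
        self.conservation_mix = mix

    def _anchor_clade(self) -> tuple:
        for members in self.clades.values():
            if self.anchor in members:
                return tuple(members)
        raise ConfigurationError(f"anchor {self.anchor!r} not in any clade")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def genome(self, species: str) -> Genome:
        sizes = {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}
        return Genome(species, sizes)


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream verification."""

    re_table: pd.DataFrame  # per anchor RE: coords, class, fine/coarse label, pattern
    species_tree: str
    planted_regions: RegionSet | None = None
    gwas_in_region: np.ndarray | None = None

    def coarse_labels(self) -> pd.Series:
        return self.re_table["coarse_label"]

    def expected_counts(self) -> dict:
        """Eq.-style decomposition implied by the planted labels."""
        t = self.re_table
        n_n = int((t["fine_label"] == "species_specific_unalignable").sum())
        n_l = int((t["fine_label"] == "species_specific_alignable").sum())
        return {
            "n_total": len(t),
            "n_unaligned": n_n,
            "n_aligned_unshared": n_l,
            "n_shared": len(t) - n_n - n_l,
            "n_species_specific": n_n + n_l,
        }


@dataclass
class SimulatedRegulome:
    config: SimulationConfig
    genomes: Mapping[str, Genome]
    peaks: Mapping[tuple, RegionSet]  # (species, mark, replicate) -> RegionSet
    true_res: Mapping[str, Mapping[str, RegionSet]]  # species -> class -> RegionSet
    cross_map: CrossSpeciesMap
    ground_truth: GroundTruth


def _exact_counts(fractions: Mapping[str, float], n: int) -> dict:
    """Integer label counts matching the requested fractions as closely as
    possible (largest-remainder rounding), summing exactly to n."""
    labels = list(FINE_LABELS)
    raw = np.array([fractions.get(l, 0.0) * n for l in labels])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for k in range(rem):
        base[order[k % len(labels)]] += 1
    return dict(zip(labels, base))


def simulate_multispecies_res(cfg: SimulationConfig) -> SimulatedRegulome:
    """Generate per-species, per-mark, per-replicate peak sets plus the
    cross-species map and ground truth.

    Construction guarantees: for each anchor RE, orthologous intervals exist
    in exactly the species dictated by its planted label; H3K4me3 replicate
    peaks exist only over promoter REs; replicate jitter is capped at 20% of
    RE length so no 50%-overlap relation is destroyed.
    """
    rng = cfg.rng("res")
    species = list(cfg.species)
    anchor = cfg.anchor
    others = [s for s in species if s != anchor]
    clade_others = frozenset(s for s in cfg._anchor_clade() if s != anchor)
    all_others = frozenset(others)
    genomes = {s: cfg.genome(s) for s in species}

    lo, hi = cfg.re_length_range
    slot = hi * 2 + 1000  # margin >> max jitter keeps planted REs isolated
    ortho_per_chrom = int(0.70 * cfg.chrom_length) // slot
    priv_per_chrom = int(0.24 * cfg.chrom_length) // slot
    priv_base = int(0.75 * cfg.chrom_length)
    if cfg.n_res > ortho_per_chrom * cfg.n_chroms:
        raise ConfigurationError(
            f"n_res={cfg.n_res} exceeds available orthologous slots "
            f"({ortho_per_chrom * cfg.n_chroms}); enlarge the genome"
        )
    if cfg.n_private_res > priv_per_chrom * cfg.n_chroms:
        raise ConfigurationError("n_private_res exceeds available private slots")

    def slot_interval(slot_idx: int, length: int, r: np.random.Generator, base=0):
        chrom = f"chr{slot_idx % cfg.n_chroms + 1}"
        s0 = base + (slot_idx // cfg.n_chroms) * slot
        off = int(r.integers(500, slot - length - 500))
        return chrom, s0 + off, s0 + off + length

    # --- anchor REs with planted labels -------------------------------------
    counts = _exact_counts(cfg.conservation_mix, cfg.n_res)
    fine = np.repeat(list(counts), list(counts.values()))
    rng.shuffle(fine)
    lengths = rng.integers(lo, hi + 1, size=cfg.n_res)
    classes = np.where(rng.random(cfg.n_res) < cfg.promoter_fraction, "promoter", "enhancer")

    rows = []
    for i in range(cfg.n_res):
        chrom, s, e = slot_interval(i, int(lengths[i]), rng)
        lab = fine[i]
        if lab == "all_conserved":
            pattern = all_others
        elif lab == "clade_specific":
            pattern = clade_others
        elif lab in ("species_specific_unalignable", "species_specific_alignable"):
            pattern = frozenset()
        else:  # other: any pattern distinct from the named ones
            while True:
                mask = rng.random(len(others)) < 0.5
                pattern = frozenset(np.array(others)[mask])
                if pattern not in (frozenset(), all_others, clade_others):
                    break
        alignable = frozenset() if lab == "species_specific_unalignable" else all_others
        rows.append(
            {
                "re_id": f"re{i:05d}",
                "chrom": chrom,
                "start": s,
                "end": e,
                "re_class": classes[i],
                "fine_label": lab,
                "coarse_label": {
                    "species_specific_unalignable": "species_specific",
                    "species_specific_alignable": "species_specific",
                }.get(lab, lab),
                "pattern": ";".join(sorted(pattern)),
                "alignable": ";".join(sorted(alignable)),
            }
        )
    truth = pd.DataFrame(rows)

    # --- orthologous positions and the cross-species map --------------------
    map_rows = []
    target_pos: dict[str, list] = {s: [None] * cfg.n_res for s in others}
    for s in others:
        perm = rng.permutation(cfg.n_res)  # rearranged gene order per species
        for i in range(cfg.n_res):
            chrom, ts, te = slot_interval(int(perm[i]), int(lengths[i]), rng)
            target_pos[s][i] = (chrom, ts, te)
    for i, row in truth.iterrows():
        alignable = set(row["alignable"].split(";")) if row["alignable"] else set()
        for s in others:
            if s in alignable:
                chrom, ts, te = target_pos[s][i]
                map_rows.append(
                    (row["chrom"], row["start"], row["end"], s, chrom, ts, te, 1)
                )
            else:
                map_rows.append(
                    (row["chrom"], row["start"], row["end"], s, ABSENT, ABSENT, ABSENT, 0)
                )
    cross_map = CrossSpeciesMap(
        anchor, pd.DataFrame(map_rows, columns=MAP_COLUMNS)
    )

    # --- per-species true RE sets -------------------------------------------
    true_res: dict[str, dict[str, RegionSet]] = {}
    for s in species:
        recs = {"promoter": [], "enhancer": []}
        if s == anchor:
            for _, row in truth.iterrows():
                recs[row["re_class"]].append((row["chrom"], row["start"], row["end"]))
        else:
            for i, row in truth.iterrows():
                pattern = set(row["pattern"].split(";")) if row["pattern"] else set()
                if s in pattern:
                    recs[row["re_class"]].append(target_pos[s][i])
            priv_slots = rng.choice(
                priv_per_chrom * cfg.n_chroms, size=cfg.n_private_res, replace=False
            )
            priv_len = rng.integers(lo, hi + 1, size=cfg.n_private_res)
            priv_cls = np.where(
                rng.random(cfg.n_private_res) < cfg.promoter_fraction,
                "promoter",
                "enhancer",
            )
            for k in range(cfg.n_private_res):
                chrom, ps, pe = slot_interval(int(priv_slots[k]), int(priv_len[k]), rng,
                                              base=priv_base)
                recs[priv_cls[k]].append((chrom, ps, pe))
        true_res[s] = {
            cls: RegionSet.from_intervals(iv, genome=genomes[s])
            if iv
            else RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]), genomes[s])
            for cls, iv in recs.items()
        }

    # --- replicate peak sets -------------------------------------------------
    peaks: dict[tuple, RegionSet] = {}
    half = cfg.jitter / 2  # per-endpoint shift cap; total displacement <= jitter * L
    for s in species:
        prom = true_res[s]["promoter"].df
        enh = true_res[s]["enhancer"].df
        for mark, base_df in (
            ("H3K27ac", pd.concat([prom, enh], ignore_index=True)),
            ("H3K4me3", prom),
        ):
            for r in range(cfg.n_replicates):
                if len(base_df) == 0:
                    peaks[(s, mark, f"rep{r + 1}")] = RegionSet(
                        pd.DataFrame(columns=["chrom", "start", "end"]), genomes[s]
                    )
                    continue
                keep = rng.random(len(base_df)) >= cfg.replicate_dropout
                df = base_df.loc[keep, ["chrom", "start", "end"]].copy()
                L = (df["end"] - df["start"]).to_numpy()
                d1 = (rng.uniform(-half, half, size=len(df)) * L).astype(np.int64)
                d2 = (rng.uniform(-half, half, size=len(df)) * L).astype(np.int64)
                df["start"] = np.maximum(df["start"] + d1, 0)
                df["end"] = np.minimum(
                    df["end"] + d2, df["chrom"].map(genomes[s].chrom_sizes)
                )
                peaks[(s, mark, f"rep{r + 1}")] = RegionSet(df, genomes[s])

    gt = GroundTruth(re_table=truth, species_tree=cfg.species_tree)
    return SimulatedRegulome(cfg, genomes, peaks, true_res, cross_map, gt)


def _parse_tree(tree) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    return TreeNode.read(io.StringIO(str(tree)))


def simulate_signal_matrix(
    cfg: SimulationConfig,
    tree=None,
    rate: float = 1.0,
    n_features: int | None = None,
    seed=None,
    root_sd: float = 1.0,
) -> pd.DataFrame:
    """Features x species matrix evolved by Brownian motion on the species tree.

    Each feature draws an ancestral value ~ N(0, root_sd^2) at the root, then
    accumulates independent N(0, rate * branch_length) increments along every
    branch. The ancestral spread anchors the interspecies correlation, so a
    larger rate yields stochastically larger 1 - rho distances (rate -> 0
    collapses all species onto identical columns).
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    t = _parse_tree(tree if tree is not None else cfg.species_tree)
    leaves = [tip.name for tip in t.tips()]
    if len(leaves) < 3:
        raise ValueError("tree must have >= 3 leaves")
    n = int(n_features if n_features is not None else cfg.n_features)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
        if seed is not None
        else cfg.rng("signal")
    )
    values = {id(t): rng.normal(0.0, root_sd, size=n)}
    for node in t.preorder(include_self=False):
        bl = float(node.length or 0.0)
        inc = rng.normal(0.0, np.sqrt(rate * bl), size=n) if bl > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + inc
    return pd.DataFrame(
        {tip.name: values[id(tip)] for tip in t.tips()},
        index=[f"feat{i:05d}" for i in range(n)],
    )


def simulate_gwas(
    cfg: SimulationConfig,
    planted: RegionSet,
    genome: Genome | None = None,
    seed=None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """SNP table with planted p-value enrichment inside ``planted`` regions.

    SNP positions are uniform; p-values are Uniform(0,1) outside the planted
    regions and Beta(a, 1) inside, with a = 1 + ln(effect)/ln(t_o) so that
    P(p < t_o) = effect * t_o exactly (point-mass-free; effect 1 recovers the
    uniform null).
    """
    if cfg.gwas_effect < 1:
        raise ConfigurationError("gwas_effect < 1 (depletion is not modeled)")
    genome = genome or planted.genome or cfg.genome(cfg.anchor)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
        if seed is not None
        else cfg.rng("gwas")
    )
    names = list(genome.chrom_sizes)
    sizes = np.array([genome.size(c) for c in names], dtype=float)
    chrom_idx = rng.choice(len(names), size=cfg.n_snps, p=sizes / sizes.sum())
    pos = rng.integers(0, sizes[chrom_idx].astype(np.int64))
    chroms = np.array(names, dtype=object)[chrom_idx]
    inside = planted.contains_points(chroms, pos)

    effect, t_o = float(cfg.gwas_effect), float(cfg.t_o)
    pvals = rng.uniform(size=cfg.n_snps)
    if effect > 1 and inside.any():
        a = 1.0 + np.log(effect) / np.log(t_o)
        target = effect * t_o
        if target >= 1:  # capped: everything inside is a signal
            a = np.inf
        pvals[inside] = (
            rng.uniform(size=inside.sum()) ** (1.0 / a) if np.isfinite(a) else 0.0
        )
    df = pd.DataFrame(
        {
            "snp_id": [f"snp{i:07d}" for i in range(cfg.n_snps)],
            "chrom": chroms,
            "pos": pos,
            "pvalue": pvals,
            "_inside": inside,
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    gt = GroundTruth(
        re_table=pd.DataFrame(),
        species_tree=cfg.species_tree,
        planted_regions=planted,
        gwas_in_region=df.pop("_inside").to_numpy(),
    )
    return df, gt


def simulate_gene_models(
    cfg: SimulationConfig, genome: Genome | None = None, seed=None
) -> pd.DataFrame:
    """Gene table (gene_id, chrom, strand, tss) with non-overlapping TSSs."""
    genome = genome or cfg.genome(cfg.anchor)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
        if seed is not None
        else cfg.rng("genes")
    )
    names = list(genome.chrom_sizes)
    pitch = 20_000  # candidate TSS grid; >> regulatory-domain span avoids overlap
    candidates = [
        (c, int(p))
        for c in names
        for p in range(10_000, genome.size(c) - 10_000, pitch)
    ]
    if cfg.n_genes > len(candidates):
        raise ConfigurationError("n_genes exceeds available TSS grid positions")
    pick = rng.choice(len(candidates), size=cfg.n_genes, replace=False)
    pick.sort()
    rows = [
        {
            "gene_id": f"gene{k:05d}",
            "chrom": candidates[i][0],
            "strand": "+" if rng.random() < 0.5 else "-",
            "tss": candidates[i][1] + int(rng.integers(-5000, 5001)),
        }
        for k, i in enumerate(pick)
    ]
    return pd.DataFrame(rows)


def simulate_expression(
    cfg: SimulationConfig, seed=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal expression: returns (counts, CPM-normalized) gene x sample frames.

    ~20% of genes are lowly expressed so the CPM > 1-in-20%-of-samples filter
    has something to remove.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
        if seed is not None
        else cfg.rng("expression")
    )
    n, m = cfg.n_genes, cfg.n_expr_samples
    low = rng.random(n) < 0.2
    mu = np.where(low, -4.0, rng.normal(4.0, 2.0, size=n))
    log2_expr = mu[:, None] + rng.normal(0.0, 0.5, size=(n, m))
    rel = 2.0 ** log2_expr
    lib = rng.integers(800_000, 1_200_000, size=m)
    lam = rel / rel.sum(axis=0, keepdims=True) * lib
    counts = rng.poisson(lam)
    genes = [f"gene{i:05d}" for i in range(n)]
    samples = [f"s{j + 1}" for j in range(m)]
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    cpm = counts_df / counts_df.sum(axis=0) * 1e6
    return counts_df, cpm


def simulate_methylation(cfg: SimulationConfig, seed=None) -> pd.DataFrame:
    """Per-CpG (meth count, total count) table with known true levels.

    Coverage is Poisson around ``mean_coverage`` (so some CpGs fall below the
    >= 5 filter); true levels follow a bimodal beta mixture as in real WGBS.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
        if seed is not None
        else cfg.rng("methylation")
    )
    n = cfg.n_cpgs
    hyper = rng.random(n) < 0.7
    level = np.where(hyper, rng.beta(8, 2, size=n), rng.beta(2, 8, size=n))
    total = rng.poisson(cfg.mean_coverage, size=n)
    meth = rng.binomial(total, level)
    chroms = [f"chr{1 + i % cfg.n_chroms}" for i in range(n)]
    pos = [100 + 50 * (i // cfg.n_chroms) for i in range(n)]
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "meth": meth,
            "total": total,
            "true_level": level,
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def simulate_gene_scores(
    cfg: SimulationConfig,
    has_re: np.ndarray | None = None,
    shift: float | None = None,
    seed=None,
) -> pd.DataFrame:
    """Per-gene conservation-like scores with a planted additive shift.

    Genes flagged in ``has_re`` (default: fair coin per gene) receive a
    ``shift``-SD upward shift, so comparisons of score distributions between
    RE-bearing and RE-free genes have a known direction and magnitude.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
        if seed is not None
        else cfg.rng("scores")
    )
    shift = cfg.gene_score_shift if shift is None else float(shift)
    if has_re is None:
        has_re = rng.random(cfg.n_genes) < 0.5
    has_re = np.asarray(has_re, dtype=bool)
    score = rng.normal(0.0, 1.0, size=len(has_re)) + shift * has_re
    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(len(has_re))],
            "score": score,
            "has_re": has_re,
        }
    )
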