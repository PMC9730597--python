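"""GREAT-style RE-to-gene assignment and the matched gene-category comparisons.

A gene's basal regulatory association domain spans 5 kb upstream to 1 kb
downstream of its TSS (strand-aware). REs link to every gene whose domain
they overlap by >= 1 bp. Genes are then categorized by their RE complement
(Both / Promoter / Enhancer / None) and split into single-vs-multiple groups
(multiple: enhancers >= 3, promoters >= 2) for comparisons of expression
stability and conservation-like scores, optionally after expression matching
with a caliper in SD units.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Genome, RegionSet

__all__ = [
    "regulatory_domains",
    "assign_targets",
    "categorize_genes",
    "match_by_covariate",
    "rank_sum_test",
    "compare_gene_scores",
    "expression_stability",
]

CATEGORIES = ("Both", "Promoter", "Enhancer", "None")


def regulatory_domains(
    genes: pd.DataFrame,
    up: int = 5000,
    down: int = 1000,
    genome: Genome | None = None,
    extension: int = 0,
) -> RegionSet:
    """One basal domain per gene: [tss - up, tss + down) on +, mirrored on -.

    With ``extension > 0`` each basal domain is additionally grown up to
    ``extension`` bp on both sides, stopping at the adjacent gene's basal
    domain (GREAT-style nearest-gene extension); extension never shrinks a
    domain below its basal span. Domains are clipped to the chromosome. The
    returned RegionSet carries the gene_id in its ``name`` column.
    """
    strand = genes["strand"].to_numpy()
    if not set(strand) <= {"+", "-"}:
        raise ValueError("gene strand must be '+' or '-'")
    tss = genes["tss"].to_numpy(dtype=np.int64)
    start = np.where(strand == "+", tss - up, tss - down)
    end = np.where(strand == "+", tss + down, tss + up)
    df = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.maximum(start, 0),
            "end": end,
            "name": genes["gene_id"],
        }
    )
    if genome is not None:
        df["end"] = np.minimum(df["end"], df["chrom"].map(genome.chrom_sizes))
    if extension > 0:
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        new_start = df["start"].to_numpy().copy()
        new_end = df["end"].to_numpy().copy()
        for _, idx in df.groupby("chrom", sort=False).groups.items():
            idx = np.asarray(idx)
            s, e = df["start"].to_numpy()[idx], df["end"].to_numpy()[idx]
            prev_end = np.concatenate([[0], e[:-1]])
            next_start = np.concatenate([s[1:], [np.iinfo(np.int64).max]])
            new_start[idx] = np.minimum(s, np.maximum(s - extension, prev_end))
            new_end[idx] = np.maximum(e, np.minimum(e + extension, next_start))
        df["start"], df["end"] = new_start, new_end
        if genome is not None:
            df["end"] = np.minimum(df["end"], df["chrom"].map(genome.chrom_sizes))
    return RegionSet(df, genome=genome)


def assign_targets(res: RegionSet, domains: RegionSet) -> tuple[pd.DataFrame, pd.Series]:
    """Link REs to genes whose regulatory domain they overlap (>= 1 bp).

    Returns (links, per-gene counts): ``links`` has one row per (RE, gene)
    pair with the RE row index and gene_id; ``counts`` is indexed by gene_id
    over all genes in ``domains`` (zero for unlinked genes).
    """
    if "name" not in domains.df.columns:
        raise ValueError("domains must carry gene ids in their 'name' column")
    pairs = res.overlap_pairs(domains)
    links = pd.DataFrame(
        {
            "re_idx": pairs["idx"].to_numpy(),
            "gene_id": domains.df["name"].to_numpy()[pairs["jdx"].to_numpy()],
        }
    )
    counts = (
        links.groupby("gene_id")
        .size()
        .reindex(domains.df["name"].unique(), fill_value=0)
        .rename("n_res")
    )
    return links, counts


def categorize_genes(
    promoter_counts: pd.Series,
    enhancer_counts: pd.Series,
    multi_enhancers: int = 3,
    multi_promoters: int = 2,
) -> pd.DataFrame:
    """Gene categories from RE presence, plus single/multiple groups.

    Category: Both (>=1 of each), Promoter, Enhancer, None. Multiplicity:
    ``multiple`` iff enhancer count >= multi_enhancers (enhancer analysis) or
    promoter count >= multi_promoters (promoter analysis).
    """
    genes = promoter_counts.index.union(enhancer_counts.index)
    p = promoter_counts.reindex(genes, fill_value=0)
    e = enhancer_counts.reindex(genes, fill_value=0)
    category = np.select(
        [(p > 0) & (e > 0), p > 0, e > 0],
        ["Both", "Promoter", "Enhancer"],
        default="None",
    )
    return pd.DataFrame(
        {
            "promoter_count": p,
            "enhancer_count": e,
            "category": category,
            "enhancer_group": np.where(e >= multi_enhancers, "multiple", "single"),
            "promoter_group": np.where(p >= multi_promoters, "multiple", "single"),
        },
        index=genes,
    )


def match_by_covariate(
    treated: pd.Series,
    control: pd.Series,
    caliper: float = 0.5,
) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    A pair is admitted iff |covariate difference| <= caliper * SD of the
    covariate over all genes (both groups pooled) — the caliper-in-SD-units
    convention. Returns matched pairs plus unmatched treated ids flagged.
    """
    if len(treated) == 0 or len(control) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([treated.to_numpy(float), control.to_numpy(float)])
    sd = float(np.std(pooled, ddof=1))
    if sd == 0:
        raise ValueError("zero covariate SD: matching is undefined")
    limit = caliper * sd
    avail = control.copy()
    rows = []
    for tid, tval in treated.items():
        if len(avail) == 0:
            rows.append((tid, None, tval, np.nan, False))
            continue
        diffs = (avail - tval).abs()
        cid = diffs.idxmin()
        if diffs[cid] <= limit:
            rows.append((tid, cid, tval, avail[cid], True))
            avail = avail.drop(cid)
        else:
            rows.append((tid, None, tval, np.nan, False))
    return pd.DataFrame(
        rows, columns=["treated", "control", "treated_value", "control_value", "matched"]
    )


def rank_sum_test(x, y, paired: bool = False) -> tuple[float, float]:
    """Wilcoxon rank-sum (unpaired) or signed-rank (paired) two-sided test.

    Unpaired tests use the exact null distribution for combined n <= 20
    without ties, otherwise the normal approximation with tie correction.
    Paired tests are exact for n <= 25 without zeros/ties. Returns
    (statistic, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test needs equal lengths")
        d = x - y
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return 0.0, 1.0
        # scipy's exact signed-rank null handles ties via midranks; zeros do not
        method = "exact" if (len(d) <= 25 and not (d == 0).any()) else "approx"
        res = stats.wilcoxon(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2), 1.0
    exact = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def compare_gene_scores(
    categories: pd.Series, scores: pd.Series
) -> tuple[pd.Series, pd.DataFrame]:
    """Median score per gene category plus all pairwise rank-sum p-values.

    Empty categories are skipped with a warning; with a single non-empty
    category only the medians are returned.
    """
    cats = [c for c in pd.unique(categories) if (categories == c).any()]
    groups = {}
    for c in cats:
        vals = scores.reindex(categories.index[categories == c]).dropna()
        if len(vals) == 0:
            warnings.warn(f"category {c!r} has no scored genes; skipped")
            continue
        groups[c] = vals.to_numpy()
    medians = pd.Series({c: float(np.median(v)) for c, v in groups.items()}, name="median")
    rows = []
    for a, b in itertools.combinations(groups, 2):
        stat, p = rank_sum_test(groups[a], groups[b])
        rows.append({"group_a": a, "group_b": b, "statistic": stat, "pvalue": p})
    return medians, pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "pvalue"])


def expression_stability(expr: pd.DataFrame) -> pd.Series:
    """Cross-species transcriptional stability per gene.

    Measured as the negative coefficient of variation of a gene's expression
    across species columns (higher = more stable). This is one reasonable
    operationalization of interspecies expression stability; it is exposed so
    callers can substitute their own.
    """
    mean = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean.abs()
    return (-cv).rename("stability")
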