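"""Region and GWAS-signal enrichment tests.

Two engines: (1) a regioneR-style permutation test that compares an observed
overlap statistic against random placements of the query regions, and (2) the
count-based marker-set GWAS test — T_count, the number of SNPs inside a
(50-kb-windowed) region set with GWAS p below a cutoff t_o = 0.01, tested
against a hypergeometric null over all genome-wide SNPs, significant at
P < 1e-5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genes import rank_sum_test
from .intervals import Genome, RegionSet, extend_and_clip, random_placement

__all__ = [
    "EnrichmentResult",
    "GwasEnrichmentResult",
    "permutation_enrichment",
    "count_based_gwas_test",
    "snp_density_profile",
    "inside_outside_pvalues",
    "read_gwas_tsv",
]


@dataclass
class EnrichmentResult:
    """Permutation-test summary for one query/annotation pair."""

    observed: float
    perm_mean: float
    perm_sd: float
    fold: float  # observed / mean(permuted); NaN when undefined
    z: float
    p_empirical: float  # (1 + #{perm >= observed}) / (n_perm + 1)
    n_perm: int
    statistic: str
    seed: int | None = None


@dataclass
class GwasEnrichmentResult:
    """Count-based marker-set test summary for one region set."""

    label: str
    n_snps_in_set: int  # c: SNPs in the windowed region set
    t_count: int  # SNPs in set with p < t_o
    k_genomewide: int  # genome-wide SNPs with p < t_o
    n_total: int  # all SNPs
    pvalue: float  # hypergeometric upper tail P(X >= T_count)
    significant: bool
    window: int
    t_o: float


def hypergeom_upper_tail(t: int, n: int, k: int, c: int) -> float:
    """Inclusive upper tail P(X >= t) for X ~ Hypergeometric(N=n, K=k, draws=c)."""
    return float(stats.hypergeom.sf(t - 1, n, k, c))


def _overlap_statistic(query: RegionSet, annotation: RegionSet, statistic: str) -> float:
    if statistic == "overlap_count":
        return float((query.count_overlaps(annotation) > 0).sum())
    if statistic == "overlapping_bases":
        pairs = query.overlap_pairs(annotation.merge())
        return float(pairs["overlap"].sum()) if len(pairs) else 0.0
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_enrichment(
    query: RegionSet,
    annotation: RegionSet,
    genome: Genome | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "overlap_count",
    mode: str = "per_chromosome",
) -> EnrichmentResult:
    """Observed overlap statistic vs ``n_perm`` random placements of the query.

    Each permutation re-places every query interval uniformly (by default on
    its own chromosome), preserving interval lengths. Empirical p uses the
    add-one rule, so its floor is 1/(n_perm + 1).
    """
    genome = genome or query.genome
    if genome is None:
        raise ValueError("permutation_enrichment needs a genome")
    if len(annotation) == 0:
        warnings.warn("empty annotation: fold undefined")
        return EnrichmentResult(
            observed=0.0, perm_mean=0.0, perm_sd=0.0, fold=float("nan"),
            z=float("nan"), p_empirical=1.0, n_perm=n_perm, statistic=statistic,
            seed=seed,
        )
    observed = _overlap_statistic(query, annotation, statistic)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for i in range(n_perm):
        placed = random_placement(query, genome, rng, mode=mode)
        perms[i] = _overlap_statistic(placed, annotation, statistic)
    mean = float(perms.mean())
    sd = float(perms.std(ddof=1)) if n_perm > 1 else 0.0
    return EnrichmentResult(
        observed=observed,
        perm_mean=mean,
        perm_sd=sd,
        fold=observed / mean if mean > 0 else float("nan"),
        z=(observed - mean) / sd if sd > 0 else float("nan"),
        p_empirical=float((1 + (perms >= observed).sum()) / (n_perm + 1)),
        n_perm=n_perm,
        statistic=statistic,
        seed=seed,
    )


def count_based_gwas_test(
    gwas: pd.DataFrame,
    regions: RegionSet,
    window: int = 50_000,
    t_o: float = 0.01,
    threshold: float = 1.0e-5,
    label: str = "regions",
    window_mode: str = "per_side",
) -> GwasEnrichmentResult:
    """Count-based marker-set test of GWAS-signal enrichment in a region set.

    Membership is computed against the region set grown by ``window`` bp on
    each side (then merged); ``window_mode="total"`` reads ``window`` as the
    total added width instead (window/2 per side). T_count counts member SNPs
    with p strictly below t_o; significance is the inclusive hypergeometric
    upper tail P(X >= T_count) drawing c from a population of N SNPs with K
    genome-wide sub-threshold SNPs.
    """
    if not (0 < t_o < 1):
        raise ValueError(f"t_o must be in (0, 1), got {t_o}")
    if window_mode not in ("per_side", "total"):
        raise ValueError(f"unknown window_mode {window_mode!r}")
    if len(gwas) == 0:
        raise ValueError("need at least one SNP")
    pvals = gwas["pvalue"].to_numpy(dtype=float)
    if not np.isfinite(pvals).all() or (pvals <= 0).any() or (pvals > 1).any():
        raise ValueError("GWAS p-values must be finite and in (0, 1]")
    flank = window if window_mode == "per_side" else window // 2
    windowed = extend_and_clip(regions, flank) if flank > 0 else regions.merge()
    inside = windowed.contains_points(gwas["chrom"].to_numpy(), gwas["pos"].to_numpy())
    n = len(gwas)
    k = int((pvals < t_o).sum())
    c = int(inside.sum())
    t_count = int((pvals[inside] < t_o).sum())
    if c == 0:
        warnings.warn(f"no SNPs fall in region set {label!r}; p = 1")
        p = 1.0
    else:
        p = hypergeom_upper_tail(t_count, n, k, c)
    return GwasEnrichmentResult(
        label=label,
        n_snps_in_set=c,
        t_count=t_count,
        k_genomewide=k,
        n_total=n,
        pvalue=p,
        significant=bool(p < threshold),
        window=window,
        t_o=t_o,
    )


def snp_density_profile(
    gwas: pd.DataFrame, res: RegionSet, max_dist: int, bin_size: int
) -> pd.DataFrame:
    """SNP density (SNPs per bp per RE) by distance to the nearest RE boundary.

    Distance is 0 for SNPs inside an RE, else the gap to the nearest RE on
    the same chromosome; SNPs farther than max_dist are dropped. Bin edges
    are [0, bin, 2*bin, ..., max_dist]; bin 0 is "inside".
    """
    if len(res) == 0:
        raise ValueError("no reference regions")
    if max_dist % bin_size != 0:
        raise ValueError("bin size must divide max_dist")
    merged = res.merge().df
    dist = np.full(len(gwas), np.inf)
    chroms = gwas["chrom"].to_numpy()
    pos = gwas["pos"].to_numpy()
    for chrom, grp in merged.groupby("chrom", observed=True, sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        p = pos[sel]
        k = np.searchsorted(starts, p, side="right") - 1
        inside = (k >= 0) & (p < ends[np.maximum(k, 0)])
        gap_left = np.where(k >= 0, p - ends[np.maximum(k, 0)], np.inf)
        nxt = np.minimum(k + 1, len(starts) - 1)
        gap_right = np.where(k + 1 < len(starts), starts[nxt] - p, np.inf)
        d = np.minimum(np.maximum(gap_left, 0), np.maximum(gap_right, 0))
        d[inside] = 0
        dist[sel] = d
    edges = np.arange(0, max_dist + bin_size, bin_size)
    hist, _ = np.histogram(dist[np.isfinite(dist)], bins=edges)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "n_snps": hist,
            "density": hist / (bin_size * len(res)),
        }
    )


def inside_outside_pvalues(
    gwas: pd.DataFrame, res: RegionSet, window: int = 0
) -> tuple[float, float]:
    """Two-sided rank-sum p comparing -log10 GWAS p of SNPs inside vs outside
    the region set (unwindowed by default)."""
    regions = extend_and_clip(res, window) if window > 0 else res
    inside = regions.contains_points(gwas["chrom"].to_numpy(), gwas["pos"].to_numpy())
    if inside.all():
        raise ValueError("no SNPs outside the region set")
    if not inside.any():
        raise ValueError("no SNPs inside the region set")
    neglog = -np.log10(gwas["pvalue"].to_numpy(dtype=float))
    return rank_sum_test(neglog[inside], neglog[~inside], paired=False)


def adjust_pvalues_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values across a family of tests.

    Optional post-step for multi-trait runs; the marker-set test itself uses
    only its fixed significance threshold.
    """
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


def read_gwas_tsv(path) -> pd.DataFrame:
    """Read a GWAS summary TSV with required header snp_id, chrom, pos, pvalue."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"snp_id", "chrom", "pos", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GWAS table missing columns {sorted(missing)}")
    return df
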