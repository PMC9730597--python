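"""Consensus peak calling and promoter/enhancer classification.

Regulatory elements are inferred from two histone marks: H3K27ac flags active
regulatory regions, H3K4me3 flags active promoters. A consensus peak must be
reproducible across biological replicates (>= 50% overlap of either peak's
length, in at least two replicates). A consensus H3K27ac region co-marked by
H3K4me3 at >= 50% overlap is a promoter; one with zero H3K4me3 overlap is an
enhancer; partial overlaps below the threshold go to an explicit "ambiguous"
bin so the three classes partition the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import Genome, RegionSet, merge

__all__ = [
    "PeakSet",
    "consensus_peaks",
    "classify_res",
    "tss_proximity",
    "tissue_specificity",
]


@dataclass
class PeakSet:
    """Replicate peak calls for one species/tissue/mark."""

    species: str
    mark: str  # H3K27ac or H3K4me3
    regions: RegionSet
    tissue: str = "liver"
    replicate: str = "rep1"

    def __post_init__(self):
        if not self.species or not self.mark:
            raise ValueError("species and mark must be nonempty")


def consensus_peaks(
    replicates: list[PeakSet | RegionSet],
    min_replicates: int = 2,
    min_frac: float = 0.5,
) -> RegionSet:
    """Merge peaks reproducible in at least ``min_replicates`` replicates.

    A peak is reproducible iff it overlaps a peak in >= (min_replicates - 1)
    *other* replicates at >= min_frac of either peak's length. The result is
    the merge of all reproducible peaks from all replicates.
    """
    sets = [p.regions if isinstance(p, PeakSet) else p for p in replicates]
    if len(sets) < 2:
        raise ValueError(
            "consensus needs >= 2 replicates; pass a single replicate through "
            "explicitly if that is intended"
        )
    species = {p.species for p in replicates if isinstance(p, PeakSet)}
    marks = {p.mark for p in replicates if isinstance(p, PeakSet)}
    if len(species) > 1 or len(marks) > 1:
        raise ValueError(f"replicates mix species/marks: {species}/{marks}")

    reproducible = []
    for i, a in enumerate(sets):
        if len(a) == 0:
            continue
        support = np.zeros(len(a), dtype=int)
        for j, b in enumerate(sets):
            if i == j or len(b) == 0:
                continue
            pairs = a.overlap_pairs(b)
            hit = pairs[(pairs["frac_a"] >= min_frac) | (pairs["frac_b"] >= min_frac)]
            support[np.unique(hit["idx"].to_numpy())] += 1
        keep = support >= (min_replicates - 1)
        if keep.any():
            reproducible.append(a.df.loc[keep, ["chrom", "start", "end"]])
    genome = next((s.genome for s in sets if s.genome is not None), None)
    if not reproducible:
        return RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]), genome)
    return merge(RegionSet(pd.concat(reproducible, ignore_index=True), genome))


def classify_res(
    h3k27ac: RegionSet,
    h3k4me3: RegionSet,
    min_frac: float = 0.5,
) -> tuple[RegionSet, RegionSet, RegionSet]:
    """Split consensus H3K27ac peaks into (promoters, enhancers, ambiguous).

    promoter: some H3K4me3 peak overlaps at >= min_frac of either length;
    enhancer: zero H3K4me3 overlap (not even 1 bp);
    ambiguous: overlapping but below threshold. The three outputs partition
    the H3K27ac input.
    """
    if len(h3k27ac) == 0:
        warnings.warn("empty H3K27ac input: no REs to classify")
        empty = RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]), h3k27ac.genome)
        return empty, empty, empty
    pairs = h3k27ac.overlap_pairs(h3k4me3)
    overlapped = np.zeros(len(h3k27ac), dtype=bool)
    promoter = np.zeros(len(h3k27ac), dtype=bool)
    if len(pairs):
        overlapped[np.unique(pairs["idx"].to_numpy())] = True
        hit = pairs[(pairs["frac_a"] >= min_frac) | (pairs["frac_b"] >= min_frac)]
        promoter[np.unique(hit["idx"].to_numpy())] = True
    enhancer = ~overlapped
    ambiguous = overlapped & ~promoter
    core = h3k27ac.df[["chrom", "start", "end"]]
    g = h3k27ac.genome
    return (
        RegionSet(core[promoter], g),
        RegionSet(core[enhancer], g),
        RegionSet(core[ambiguous], g),
    )


def tss_proximity(
    res: RegionSet, genes: pd.DataFrame, threshold: int = 5000
) -> pd.DataFrame:
    """Distance of each RE to the nearest TSS, and a proximal/distal label.

    Distance is 0 when a TSS lies inside the half-open RE, else the gap
    between the TSS and the nearest RE boundary (TSS - end when TSS >= end,
    start - TSS when TSS < start). Proximal iff distance <= threshold. REs on
    chromosomes without genes are labelled distal with infinite distance.
    """
    dist = np.full(len(res), np.inf)
    for chrom, grp in res.df.groupby("chrom", observed=True, sort=False):
        tss = np.sort(genes.loc[genes["chrom"] == chrom, "tss"].to_numpy())
        if len(tss) == 0:
            warnings.warn(f"no genes on {chrom}; REs there labelled distal")
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # nearest TSS on each side of the interval
        right = np.searchsorted(tss, starts, side="left")
        left_gap = np.where(right > 0, starts - tss[np.maximum(right - 1, 0)], np.inf)
        k = np.searchsorted(tss, ends, side="left")  # first TSS >= end; gap 0 at TSS == end
        right_gap = np.where(k < len(tss), tss[np.minimum(k, len(tss) - 1)] - ends, np.inf)
        inside = (np.searchsorted(tss, ends, side="left")
                  - np.searchsorted(tss, starts, side="left")) > 0
        d = np.minimum(left_gap, right_gap)
        d[inside] = 0
        dist[grp.index.to_numpy()] = d
    return pd.DataFrame(
        {
            "distance": dist,
            "proximity": np.where(dist <= threshold, "proximal", "distal"),
        },
        index=res.df.index,
    )


def tissue_specificity(
    tissue_res: RegionSet,
    other_tissue_res: list[RegionSet],
    min_frac: float = 0.5,
) -> np.ndarray:
    """Per-RE boolean: specific iff it fails the >= min_frac (either-length)
    overlap against every RE of every other tissue."""
    if len(other_tissue_res) == 0:
        raise ValueError("need at least one other tissue")
    specific = np.ones(len(tissue_res), dtype=bool)
    for other in other_tissue_res:
        pairs = tissue_res.overlap_pairs(other)
        if len(pairs) == 0:
            continue
        hit = pairs[(pairs["frac_a"] >= min_frac) | (pairs["frac_b"] >= min_frac)]
        specific[np.unique(hit["idx"].to_numpy())] = False
    return specific
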