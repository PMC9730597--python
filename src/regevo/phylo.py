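"""Omics phylogenies: Spearman distances, neighbor joining, bootstrap branch
lengths, and the matrix-preparation filters (methylation levels, expression).

Interspecies distance for a signal matrix (orthologous features x species) is
1 - rho, where rho is Spearman's rank correlation between two species'
columns. Trees are built by Saitou-Nei neighbor joining, which recovers the
true tree exactly on additive distance matrices. Branch-length uncertainty is
assessed by bootstrapping features with replacement and recording the total
branch length of each replicate tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

__all__ = [
    "methylation_levels",
    "region_methylation",
    "filter_expressed",
    "spearman_distance",
    "nj_tree",
    "total_branch_length",
    "bootstrap_tree_lengths",
    "compare_tree_lengths",
    "BootstrapResult",
]


def methylation_levels(cpgs: pd.DataFrame, min_cov: int = 5) -> pd.DataFrame:
    """Per-CpG methylation level = meth / total, keeping CpGs with coverage
    >= min_cov.

    ``cpgs`` needs columns ``meth`` and ``total`` (methylated Cs and
    methylated-plus-unmethylated read counts at the site).
    """
    if (cpgs["meth"] > cpgs["total"]).any() or (cpgs[["meth", "total"]] < 0).any().any():
        raise ValueError("need 0 <= meth <= total at every CpG")
    kept = cpgs[cpgs["total"] >= min_cov].copy()
    kept["level"] = kept["meth"] / kept["total"]
    return kept


def region_methylation(
    cpgs: pd.DataFrame, regions, min_cov: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Mean retained-CpG level per region; regions with no retained CpG are
    returned as NaN with a companion boolean mask."""
    kept = methylation_levels(cpgs, min_cov=min_cov)
    levels = np.full(len(regions), np.nan)
    has = np.zeros(len(regions), dtype=bool)
    for chrom, grp in regions.df.groupby("chrom", observed=True, sort=False):
        sub = kept[kept["chrom"] == chrom]
        if len(sub) == 0:
            continue
        pos = sub["pos"].to_numpy()
        lv = sub["level"].to_numpy()
        order = np.argsort(pos)
        pos, lv = pos[order], lv[order]
        cum = np.concatenate([[0.0], np.cumsum(lv)])
        lo = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, grp["end"].to_numpy(), side="left")
        n = hi - lo
        idx = grp.index.to_numpy()
        nz = n > 0
        levels[idx[nz]] = (cum[hi[nz]] - cum[lo[nz]]) / n[nz]
        has[idx[nz]] = True
    return levels, has


def filter_expressed(
    normalized: pd.DataFrame, min_cpm: float = 1.0, min_frac: float = 0.20
) -> pd.DataFrame:
    """Keep features with value > min_cpm (strict) in >= min_frac of samples."""
    frac = (normalized > min_cpm).sum(axis=1) / normalized.shape[1]
    return normalized.loc[frac >= min_frac]


def spearman_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - rho distance matrix between species columns.

    rho is the Pearson correlation of midranks (average ranks on ties), so
    distances lie in [0, 2]. A zero-variance column has no defined ranks and
    is reported as an error naming the species.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need >= 3 features to estimate rank correlations")
    for col in matrix.columns:
        if matrix[col].nunique() <= 1:
            raise ValueError(f"zero variance in species column {col!r}")
    rho, _ = stats.spearmanr(matrix.to_numpy())
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def _clamp_negative_branches(tree: TreeNode) -> TreeNode:
    """Clamp negative NJ branch lengths to 0, moving the deficit onto the
    sibling edge (raw lengths kept in ``node.raw_length``)."""
    for node in tree.postorder(include_self=False):
        node.raw_length = node.length
    for node in list(tree.postorder(include_self=False)):
        if node.length is not None and node.length < 0:
            deficit = node.length
            node.length = 0.0
            siblings = [c for c in node.parent.children if c is not node]
            if siblings and siblings[0].length is not None:
                siblings[0].length = max(siblings[0].length + deficit, 0.0)
    return tree


def nj_tree(d: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    On an additive matrix the true tree and branch lengths are recovered
    exactly. Negative branch lengths (possible on non-additive input) are
    clamped to zero with the deficit transferred to the sibling edge; raw
    values remain on each node as ``raw_length``.
    """
    arr = np.asarray(d, dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if arr.shape[0] < 3:
        raise ValueError("need >= 3 taxa")
    ids = [str(c) for c in d.columns] if isinstance(d, pd.DataFrame) else None
    tree = _skbio_nj(SkbioDM(arr, ids=ids), neg_as_zero=False)
    return _clamp_negative_branches(tree)


def total_branch_length(tree: TreeNode) -> float:
    return float(sum(n.length or 0.0 for n in tree.postorder(include_self=False)))


@dataclass
class BootstrapResult:
    """Total branch lengths of B feature-bootstrap replicate trees."""

    lengths: np.ndarray
    n_redrawn: int = 0

    @property
    def B(self) -> int:
        return len(self.lengths)

    def median(self) -> float:
        return float(np.median(self.lengths))


def bootstrap_tree_lengths(
    matrix: pd.DataFrame, B: int = 1000, seed=0, max_redraws: int = 100
) -> BootstrapResult:
    """Bootstrap features with replacement; record each replicate tree's
    total branch length.

    Degenerate replicates (a zero-variance species column, which leaves rank
    correlation undefined) are redrawn and counted.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need >= 3 features to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = matrix.shape[0]
    values = matrix.to_numpy()
    lengths = np.empty(B)
    redrawn = 0
    for b in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            sub = values[idx]
            if all(len(np.unique(sub[:, j])) > 1 for j in range(sub.shape[1])):
                break
            redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap replicate")
        rho, _ = stats.spearmanr(sub)
        dmat = 1.0 - np.atleast_2d(rho)
        np.fill_diagonal(dmat, 0.0)
        tree = nj_tree(pd.DataFrame(dmat, index=matrix.columns, columns=matrix.columns))
        lengths[b] = total_branch_length(tree)
    return BootstrapResult(lengths=lengths, n_redrawn=redrawn)


def compare_tree_lengths(
    a: BootstrapResult, b: BootstrapResult, method: str = "paired"
) -> float:
    """Two-sided p for a difference in bootstrap total branch lengths.

    ``paired`` (default) pairs replicates by index and uses the empirical
    sign frequency: p = 2 * min(#(a>=b)+1, #(a<=b)+1) / (B+1), capped at 1.
    ``mannwhitney`` is an unpaired alternative.
    """
    if method == "mannwhitney":
        return float(stats.mannwhitneyu(a.lengths, b.lengths, alternative="two-sided").pvalue)
    if a.B != b.B:
        raise ValueError("paired comparison needs equal B")
    ge = int((a.lengths >= b.lengths).sum())
    le = int((a.lengths <= b.lengths).sum())
    p = 2.0 * min(ge + 1, le + 1) / (a.B + 1)
    return float(min(p, 1.0))


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path))
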