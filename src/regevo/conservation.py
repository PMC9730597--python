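"""Cross-species conservation of regulatory elements.

Anchor-species REs are projected through a pairwise interval map (a stand-in
for Ensembl EPO whole-genome alignments) into each target species and
classified by where their regulatory activity is shared:

* ``all_conserved``   — activity shared with every other species,
* ``clade_specific``  — shared with exactly the anchor's clade,
* ``species_specific``— shared with no other species (either because the DNA
  is unalignable, or alignable but inactive elsewhere),
* ``other``           — any remaining sharing pattern.

The species-specific decomposition per species i is
``N_i = N_N + N_L + N_C`` and ``N_s = N_N + N_L``, where N_N counts REs with
no DNA alignment to any other species, N_L those alignable but active
nowhere else, and N_C those with activity shared in at least one other
species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import RegionSet

__all__ = [
    "CrossSpeciesMap",
    "ConservationLabel",
    "SpeciesSpecificCounts",
    "project",
    "classify_conservation",
    "species_specific_counts",
]

ABSENT = "."

MAP_COLUMNS = [
    "anchor_chrom",
    "anchor_start",
    "anchor_end",
    "target_species",
    "target_chrom",
    "target_start",
    "target_end",
    "alignable",
]


class CrossSpeciesMap:
    """Anchor -> target interval pairs with alignability flags.

    Rows with ``alignable == 0`` carry ``.`` in the target coordinate columns
    and record that the anchor interval has no DNA alignment in that species.
    """

    def __init__(self, anchor_species: str, records: pd.DataFrame):
        df = records.copy()
        missing = [c for c in MAP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cross-species map missing columns {missing}")
        df["alignable"] = df["alignable"].astype(int)
        bad = df[(df["alignable"] == 0) & (df["target_chrom"] != ABSENT)]
        if len(bad):
            raise ValueError("unalignable map rows must have ABSENT target coordinates")
        self.anchor_species = anchor_species
        self.records = df.reset_index(drop=True)

    @property
    def target_species(self) -> list[str]:
        return sorted(self.records["target_species"].unique())

    def for_target(self, species: str) -> pd.DataFrame:
        if species not in set(self.records["target_species"]):
            raise ValueError(f"species {species!r} absent from cross-species map")
        return self.records[self.records["target_species"] == species]

    def write_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, anchor_species: str) -> "CrossSpeciesMap":
        df = pd.read_csv(path, sep="\t", dtype={"target_chrom": str})
        return cls(anchor_species, df)


@dataclass(frozen=True)
class ConservationLabel:
    """Label plus the sharing pattern (other species where activity is shared)."""

    kind: str  # all_conserved | clade_specific | species_specific | other
    clade: str | None = None
    pattern: frozenset = frozenset()

    def __str__(self) -> str:
        if self.kind == "clade_specific":
            return f"clade_specific({self.clade})"
        return self.kind


@dataclass
class SpeciesSpecificCounts:
    species: str
    n_total: int  # N_i
    n_unaligned: int  # N_N: no DNA alignment to any other species
    n_aligned_unshared: int  # N_L: alignable, activity shared nowhere
    n_shared: int  # N_C: activity shared in >= 1 other species

    @property
    def n_species_specific(self) -> int:  # N_s
        return self.n_unaligned + self.n_aligned_unshared

    def __post_init__(self):
        if min(self.n_total, self.n_unaligned, self.n_aligned_unshared, self.n_shared) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_total != self.n_unaligned + self.n_aligned_unshared + self.n_shared:
            raise ValueError(
                "count identity violated: N_i != N_N + N_L + N_C "
                f"({self.n_total} != {self.n_unaligned} + "
                f"{self.n_aligned_unshared} + {self.n_shared})"
            )


def project(res: RegionSet, cs_map: CrossSpeciesMap, target: str) -> pd.DataFrame:
    """Project each RE into ``target`` through the map.

    The projection is the alignable map record whose anchor interval overlaps
    the RE most (ties broken by leftmost target interval). Returns a frame
    indexed like ``res.df`` with columns ``target_chrom/target_start/
    target_end`` (ABSENT/NaN when unalignable) and ``n_blocks`` (number of
    overlapping alignable records, to flag multi-block REs).
    """
    recs = cs_map.for_target(target)
    align = recs[recs["alignable"] == 1].copy()
    # target coordinate columns may be object-typed (ABSENT rows carry ".")
    align["target_start"] = pd.to_numeric(align["target_start"])
    align["target_end"] = pd.to_numeric(align["target_end"])
    out = pd.DataFrame(
        {
            "target_chrom": ABSENT,
            "target_start": np.nan,
            "target_end": np.nan,
            "n_blocks": 0,
        },
        index=res.df.index,
    )
    if len(align) == 0 or len(res) == 0:
        return out
    anchor_rs = RegionSet(
        align.rename(
            columns={
                "anchor_chrom": "chrom",
                "anchor_start": "start",
                "anchor_end": "end",
            }
        )[["chrom", "start", "end"]]
    )
    # anchor_rs is sorted; map its rows back to the original record rows
    order = (
        align[["anchor_chrom", "anchor_start", "anchor_end"]]
        .reset_index(drop=True)
        .sort_values(["anchor_chrom", "anchor_start", "anchor_end"], kind="mergesort")
        .index.to_numpy()
    )
    align = align.iloc[order].reset_index(drop=True)
    pairs = res.overlap_pairs(anchor_rs)
    if len(pairs) == 0:
        return out
    pairs = pairs.merge(
        align[["target_chrom", "target_start", "target_end"]].reset_index(drop=True),
        left_on="jdx",
        right_index=True,
    )
    nb = pairs.groupby("idx").size()
    out.loc[nb.index, "n_blocks"] = nb.to_numpy()
    # max overlap, ties -> leftmost target interval
    pairs = pairs.sort_values(
        ["idx", "overlap", "target_chrom", "target_start"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = pairs.drop_duplicates("idx", keep="first").set_index("idx")
    out.loc[best.index, "target_chrom"] = best["target_chrom"].astype(str).to_numpy()
    out.loc[best.index, "target_start"] = pd.to_numeric(best["target_start"]).astype(float).to_numpy()
    out.loc[best.index, "target_end"] = pd.to_numeric(best["target_end"]).astype(float).to_numpy()
    return out


def _shared_with(
    projections: pd.DataFrame,
    target_res: RegionSet,
    min_frac: float,
    mode: str,
) -> np.ndarray:
    """Boolean per anchor RE: projected interval overlaps a target RE at threshold.

    ``anchor`` mode thresholds the fraction of the projected interval covered.
    """
    shared = np.zeros(len(projections), dtype=bool)
    ok = projections["target_chrom"] != ABSENT
    if not ok.any() or len(target_res) == 0:
        return shared
    proj = RegionSet(
        pd.DataFrame(
            {
                "chrom": projections.loc[ok, "target_chrom"],
                "start": projections.loc[ok, "target_start"].astype(np.int64),
                "end": projections.loc[ok, "target_end"].astype(np.int64),
            }
        )
    )
    # RegionSet sorts; track original positions
    orig = (
        pd.DataFrame(
            {
                "chrom": projections.loc[ok, "target_chrom"],
                "start": projections.loc[ok, "target_start"].astype(np.int64),
                "end": projections.loc[ok, "target_end"].astype(np.int64),
                "orig": projections.index[ok],
            }
        )
        .sort_values(["chrom", "start", "end"], kind="mergesort")["orig"]
        .to_numpy()
    )
    pairs = proj.overlap_pairs(target_res)
    if len(pairs) == 0:
        return shared
    if mode == "anchor":
        hit = pairs["frac_a"] >= min_frac
    elif mode == "either":
        hit = (pairs["frac_a"] >= min_frac) | (pairs["frac_b"] >= min_frac)
    elif mode == "reciprocal":
        hit = (pairs["frac_a"] >= min_frac) & (pairs["frac_b"] >= min_frac)
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    hit_idx = np.unique(pairs.loc[hit, "idx"].to_numpy())
    shared[orig[hit_idx]] = True
    return shared


def classify_conservation(
    anchor_res: RegionSet,
    re_sets: Mapping[str, Mapping[str, RegionSet]] | Mapping[str, RegionSet],
    cs_map: CrossSpeciesMap,
    clades: Mapping[str, Sequence[str]],
    anchor_species: str,
    re_class: str | None = None,
    min_frac: float = 0.5,
    mode: str = "anchor",
) -> pd.DataFrame:
    """Classify each anchor RE by its cross-species sharing pattern.

    ``re_sets`` maps target species either to a RegionSet (class-agnostic) or
    to ``{re_class: RegionSet}`` (class-matched, the default behaviour when
    ``re_class`` is given). Sharing with species s requires the RE's
    projection into s to overlap an RE of s at ``min_frac`` of the projected
    interval (``anchor`` mode).

    Returns a frame with per-RE columns ``label`` (string form),
    ``label_kind``, ``pattern`` (';'-joined shared species), ``alignable_any``
    and ``n_blocks_max``.
    """
    clade_of_anchor = None
    for name, members in clades.items():
        if anchor_species in members:
            if clade_of_anchor is not None:
                raise ValueError(f"anchor {anchor_species!r} in more than one clade")
            clade_of_anchor = name
    if clade_of_anchor is None:
        raise ValueError(f"anchor {anchor_species!r} not in any clade")
    clade_others = {s for s in clades[clade_of_anchor] if s != anchor_species}

    targets = [s for s in cs_map.target_species if s != anchor_species]
    shared = {}
    alignable = np.zeros(len(anchor_res), dtype=bool)
    nblocks = np.zeros(len(anchor_res), dtype=int)
    for s in targets:
        proj = project(anchor_res, cs_map, s)
        alignable |= (proj["target_chrom"] != ABSENT).to_numpy()
        nblocks = np.maximum(nblocks, proj["n_blocks"].to_numpy())
        tset = re_sets.get(s)
        if tset is None:
            warnings.warn(f"no RE set for target species {s!r}; treated as not shared")
            shared[s] = np.zeros(len(anchor_res), dtype=bool)
            continue
        if isinstance(tset, Mapping):
            if re_class is None:
                raise ValueError("per-class RE sets given but re_class not specified")
            if re_class not in tset:
                warnings.warn(
                    f"RE class {re_class!r} missing for species {s!r}; treated as not shared"
                )
                shared[s] = np.zeros(len(anchor_res), dtype=bool)
                continue
            tset = tset[re_class]
        shared[s] = _shared_with(proj, tset, min_frac, mode)

    labels = []
    for i in range(len(anchor_res)):
        pattern = frozenset(s for s in targets if shared[s][i])
        if len(pattern) == 0:
            lab = ConservationLabel("species_specific", pattern=pattern)
        elif pattern == set(targets):
            lab = ConservationLabel("all_conserved", pattern=pattern)
        elif pattern == clade_others and clade_others:
            lab = ConservationLabel("clade_specific", clade=clade_of_anchor, pattern=pattern)
        else:
            lab = ConservationLabel("other", pattern=pattern)
        labels.append(lab)

    return pd.DataFrame(
        {
            "label": [str(l) for l in labels],
            "label_kind": [l.kind for l in labels],
            "pattern": [";".join(sorted(l.pattern)) for l in labels],
            "alignable_any": alignable,
            "n_blocks_max": nblocks,
        },
        index=anchor_res.df.index,
    )


def species_specific_counts(
    classification: pd.DataFrame, species: str
) -> SpeciesSpecificCounts:
    """Decompose a classification into the N_i = N_N + N_L + N_C identity."""
    unshared = classification["pattern"] == ""
    n_n = int((unshared & ~classification["alignable_any"]).sum())
    n_l = int((unshared & classification["alignable_any"]).sum())
    n_c = int((~unshared).sum())
    return SpeciesSpecificCounts(
        species=species,
        n_total=len(classification),
        n_unaligned=n_n,
        n_aligned_unshared=n_l,
        n_shared=n_c,
    )
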