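"""Core genomic-interval model: genomes, region sets, BED I/O and overlap arithmetic.

All coordinates are 0-based half-open (BED convention). GFF-style 1-based
inputs must be converted at the reader boundary (start - 1) before entering
this module.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "Genome",
    "GenomicInterval",
    "RegionSet",
    "SignalTrack",
    "read_bed",
    "read_chrom_sizes",
    "overlap_fraction",
    "overlaps_at",
    "merge",
    "extend_and_clip",
    "random_placement",
    "mean_signal",
]

OVERLAP_MODES = ("either", "anchor", "reciprocal")


class BedParseError(ValueError):
    """Malformed BED input (reported with the offending line number)."""


class IntervalValidationError(ValueError):
    """Interval violates genome bounds or the half-open invariant."""


@dataclass(frozen=True)
class Genome:
    """A named genome given by its chromosome size table."""

    name: str
    chrom_sizes: Mapping[str, int]

    def __post_init__(self):
        sizes = dict(self.chrom_sizes)
        if len(sizes) == 0:
            raise ValueError("genome needs at least one chromosome")
        for chrom, size in sizes.items():
            if int(size) <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
        object.__setattr__(self, "chrom_sizes", sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def size(self, chrom: str) -> int:
        return int(self.chrom_sizes[chrom])

    def total_size(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def to_file(self, path) -> None:
        pd.DataFrame(
            {"chrom": list(self.chrom_sizes), "size": list(self.chrom_sizes.values())}
        ).to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path, name: str | None = None) -> Genome:
    """Read a two-column chrom-sizes TSV into a :class:`Genome`."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return Genome(name or Path(path).stem, dict(zip(df["chrom"], df["size"].astype(int))))


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise IntervalValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise IntervalValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Fraction of a's length and of b's length covered by their overlap.

    Intervals on different chromosomes overlap by zero bases.
    """
    if a.chrom != b.chrom:
        return 0.0, 0.0
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return ov / len(a), ov / len(b)


def overlaps_at(
    a: GenomicInterval,
    b: GenomicInterval,
    min_frac: float,
    mode: str = "either",
) -> bool:
    """Overlap test at a fractional threshold.

    ``either``: >= min_frac of a OR of b; ``anchor``: of a; ``reciprocal``: of both.
    """
    if not (0 < min_frac <= 1):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    if mode not in OVERLAP_MODES:
        raise ValueError(f"mode must be one of {OVERLAP_MODES}, got {mode!r}")
    fa, fb = overlap_fraction(a, b)
    if mode == "either":
        return fa >= min_frac or fb >= min_frac
    if mode == "anchor":
        return fa >= min_frac
    return fa >= min_frac and fb >= min_frac


class RegionSet:
    """An ordered set of genomic intervals on a genome.

    Backed by a DataFrame with columns ``chrom, start, end`` plus optional
    ``name`` and ``score``. Canonically sorted by (chrom, start, end) on
    construction and after every mutating operation.
    """

    _CORE = ["chrom", "start", "end"]

    def __init__(self, df: pd.DataFrame, genome: Genome | None = None, validate: bool = True):
        df = df.copy()
        for col in self._CORE:
            if col not in df.columns:
                raise ValueError(f"RegionSet frame needs column {col!r}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df = df.sort_values(self._CORE, kind="mergesort").reset_index(drop=True)
        self.df = df
        self.genome = genome
        if validate:
            self._validate()

    def _validate(self) -> None:
        bad = self.df[(self.df["start"] < 0) | (self.df["start"] >= self.df["end"])]
        if len(bad):
            r = bad.iloc[0]
            raise IntervalValidationError(
                f"invalid interval {r['chrom']}:{r['start']}-{r['end']}"
            )
        if self.genome is not None:
            for chrom, grp in self.df.groupby("chrom", observed=True, sort=False):
                if chrom not in self.genome:
                    raise IntervalValidationError(
                        f"chromosome {chrom!r} not in genome {self.genome.name!r}"
                    )
                if (grp["end"] > self.genome.size(chrom)).any():
                    r = grp[grp["end"] > self.genome.size(chrom)].iloc[0]
                    raise IntervalValidationError(
                        f"interval {chrom}:{r['start']}-{r['end']} off the end of "
                        f"{chrom} (size {self.genome.size(chrom)})"
                    )

    # -- construction helpers ------------------------------------------------
    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval | tuple], genome: Genome | None = None
    ) -> "RegionSet":
        rows = []
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                rows.append((iv.chrom, iv.start, iv.end))
            else:
                rows.append(tuple(iv)[:3])
        return cls(pd.DataFrame(rows, columns=cls._CORE), genome=genome)

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, int(s), int(e))
            for c, s, e in zip(self.df["chrom"], self.df["start"], self.df["end"])
        ]

    # -- basic facts ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        a = self.df[self._CORE].reset_index(drop=True)
        b = other.df[self._CORE].reset_index(drop=True)
        return a.equals(b)

    def total_bases(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def to_pyranges(self, **extra_cols) -> pr.PyRanges:
        d = pd.DataFrame(
            {
                "Chromosome": self.df["chrom"],
                "Start": self.df["start"],
                "End": self.df["end"],
            }
        )
        d["_idx"] = np.arange(len(d))
        for k, v in extra_cols.items():
            d[k] = v
        return pr.PyRanges(d)

    # -- I/O -----------------------------------------------------------------
    def write_bed(self, path) -> None:
        cols = list(self._CORE)
        if "name" in self.df.columns:
            cols.append("name")
            if "score" in self.df.columns:
                cols.append("score")
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)

    # -- operations ----------------------------------------------------------
    def merge(self) -> "RegionSet":
        return merge(self)

    def extend_and_clip(self, flank: int) -> "RegionSet":
        return extend_and_clip(self, flank)

    def random_placement(self, seed, genome: Genome | None = None, mode="per_chromosome"):
        return random_placement(self, genome or self.genome, seed, mode=mode)

    def overlap_pairs(self, other: "RegionSet") -> pd.DataFrame:
        """All overlapping pairs (>= 1 bp) between self and other.

        Returns columns ``idx`` (row in self), ``jdx`` (row in other),
        ``overlap`` (bases), ``frac_a``, ``frac_b``.
        """
        empty = pd.DataFrame(
            {
                "idx": pd.Series(dtype=np.int64),
                "jdx": pd.Series(dtype=np.int64),
                "overlap": pd.Series(dtype=np.int64),
                "frac_a": pd.Series(dtype=float),
                "frac_b": pd.Series(dtype=float),
            }
        )
        if len(self) == 0 or len(other) == 0:
            return empty
        ga = self.to_pyranges()
        gb = other.to_pyranges()
        gb.columns = [c if c != "_idx" else "_jdx" for c in gb.columns]
        j = ga.join(gb).df
        if len(j) == 0:
            return empty
        ov = np.minimum(j["End"], j["End_b"]) - np.maximum(j["Start"], j["Start_b"])
        out = pd.DataFrame(
            {
                "idx": j["_idx"].to_numpy(),
                "jdx": j["_jdx"].to_numpy(),
                "overlap": ov.to_numpy(),
                "frac_a": (ov / (j["End"] - j["Start"])).to_numpy(),
                "frac_b": (ov / (j["End_b"] - j["Start_b"])).to_numpy(),
            }
        )
        return out[out["overlap"] > 0].sort_values(["idx", "jdx"]).reset_index(drop=True)

    def count_overlaps(self, other: "RegionSet") -> np.ndarray:
        """Number of intervals of ``other`` overlapping each interval of self."""
        counts = np.zeros(len(self), dtype=np.int64)
        pairs = self.overlap_pairs(other)
        if len(pairs):
            idx, n = np.unique(pairs["idx"].to_numpy(), return_counts=True)
            counts[idx] = n
        return counts

    def contains_points(self, chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean membership of points (chrom, pos) in the merged region set."""
        merged = self.merge().df
        out = np.zeros(len(pos), dtype=bool)
        chroms = np.asarray(chroms)
        pos = np.asarray(pos)
        for chrom, grp in merged.groupby("chrom", observed=True, sort=False):
            sel = chroms == chrom
            if not sel.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            k = np.searchsorted(starts, pos[sel], side="right") - 1
            ok = k >= 0
            ok[ok] &= pos[sel][ok] < ends[k[ok]]
            out[sel] = ok
        return out


def read_bed(path, genome: Genome | None = None) -> RegionSet:
    """Read a 3+-column, tab-separated, headerless BED file.

    Columns 4 and 5 are captured as ``name`` and ``score`` when present.
    Malformed lines raise :class:`BedParseError` with the line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval {parts[0]}:{start}-{end}"
                )
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) >= 4:
                row["name"] = parts[3]
            if len(parts) >= 5:
                row["score"] = float(parts[4])
            rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    df = df.dropna(axis=1, how="all")
    if len(rows) == 0:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return RegionSet(df, genome=genome)


def merge(rs: RegionSet) -> RegionSet:
    """Merge overlapping and touching intervals (bedtools-merge semantics)."""
    if len(rs) == 0:
        return RegionSet(rs.df[RegionSet._CORE], genome=rs.genome)
    out = []
    for chrom, grp in rs.df.groupby("chrom", observed=True, sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # touching (s == cur_e) merges
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return RegionSet(pd.DataFrame(out, columns=RegionSet._CORE), genome=rs.genome)


def extend_and_clip(rs: RegionSet, flank: int) -> RegionSet:
    """Grow every interval by ``flank`` bp on both sides, clip to the chromosome,
    then merge."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    df = rs.df[RegionSet._CORE].copy()
    df["start"] = np.maximum(df["start"] - flank, 0)
    if rs.genome is not None:
        sizes = df["chrom"].map(rs.genome.chrom_sizes).to_numpy()
        df["end"] = np.minimum(df["end"] + flank, sizes)
    else:
        df["end"] = df["end"] + flank
    return merge(RegionSet(df, genome=rs.genome))


def random_placement(
    rs: RegionSet, genome: Genome, seed, mode: str = "per_chromosome"
) -> RegionSet:
    """Place each interval uniformly at random, preserving its length.

    ``per_chromosome`` (default) keeps each interval on its original
    chromosome; ``genome_wide`` draws the chromosome with probability
    proportional to the number of valid start positions.
    """
    if genome is None:
        raise ValueError("random_placement needs a genome")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = rs.lengths()
    chroms = rs.df["chrom"].to_numpy()
    if mode == "per_chromosome":
        new_chroms = chroms
    elif mode == "genome_wide":
        names = list(genome.chrom_sizes)
        sizes = np.array([genome.size(c) for c in names], dtype=float)
        new_chroms = np.empty(len(rs), dtype=object)
        for i, L in enumerate(lengths):
            slots = sizes - L + 1
            if (slots <= 0).all():
                raise IntervalValidationError(
                    f"interval of length {L} longer than every chromosome"
                )
            p = np.clip(slots, 0, None)
            new_chroms[i] = names[rng.choice(len(names), p=p / p.sum())]
    else:
        raise ValueError(f"unknown placement mode {mode!r}")
    sizes = np.array([genome.size(c) for c in new_chroms], dtype=np.int64)
    slots = sizes - lengths + 1
    if (slots <= 0).any():
        i = int(np.argmax(slots <= 0))
        raise IntervalValidationError(
            f"interval of length {lengths[i]} longer than chromosome {new_chroms[i]}"
        )
    starts = rng.integers(0, slots)
    df = pd.DataFrame({"chrom": new_chroms, "start": starts, "end": starts + lengths})
    return RegionSet(df, genome=genome)


@dataclass
class SignalTrack:
    """bedGraph-style step function: non-overlapping steps with numeric values."""

    genome: Genome | None
    steps: pd.DataFrame  # chrom, start, end, value

    def __post_init__(self):
        df = self.steps.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        if not np.isfinite(df["value"]).all():
            raise ValueError("signal track values must be finite")
        for chrom, grp in df.groupby("chrom", observed=True, sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping steps on {chrom}")
        self.steps = df

    @classmethod
    def read_bedgraph(cls, path, genome: Genome | None = None) -> "SignalTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
        )
        return cls(genome, df)

    def write_bedgraph(self, path) -> None:
        self.steps.to_csv(path, sep="\t", header=False, index=False)


def mean_signal(track: SignalTrack, rs: RegionSet) -> np.ndarray:
    """Base-weighted mean track value over each interval (uncovered bases count 0)."""
    out = np.zeros(len(rs), dtype=float)
    steps = track.steps
    for chrom, grp in rs.df.groupby("chrom", observed=True, sort=False):
        st = steps[steps["chrom"] == chrom]
        if len(st) == 0:
            continue
        s_start = st["start"].to_numpy()
        s_end = st["end"].to_numpy()
        s_val = st["value"].to_numpy()
        for i, (a, b) in zip(grp.index, zip(grp["start"], grp["end"])):
            lo = np.searchsorted(s_end, a, side="right")
            hi = np.searchsorted(s_start, b, side="left")
            if hi > lo:
                ov = np.minimum(s_end[lo:hi], b) - np.maximum(s_start[lo:hi], a)
                out[i] = float((ov * s_val[lo:hi]).sum()) / (b - a)
    return out
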