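"""Genomic interval containers, BED I/O, and interval arithmetic.

All coordinates are 0-based half-open (the BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``.  Strand is deliberately
absent from the interval types — accessibility peaks are unstranded; gene
orientation is handled where gene models are built.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GenomicIntervalSet",
    "read_genome",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "midpoint_assign",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class GenomicIntervalSet:
    """An ordered collection of intervals with optional chromosome sizes.

    Parameters
    ----------
    intervals
        Intervals in any order; input order is preserved.
    genome
        Mapping ``chrom -> length`` in bp.  When given, every interval must
        lie within its chromosome.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Mapping[str, int] | None = None,
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.genome: dict[str, int] | None = dict(genome) if genome is not None else None
        if self.genome is not None:
            for iv in self.intervals:
                if iv.chrom not in self.genome:
                    raise ValueError(f"interval chromosome {iv.chrom!r} not in genome")
                if iv.end > self.genome[iv.chrom]:
                    raise ValueError(
                        f"interval {iv.chrom}:[{iv.start},{iv.end}) exceeds "
                        f"chromosome length {self.genome[iv.chrom]}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def sorted(self) -> "GenomicIntervalSet":
        return GenomicIntervalSet(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
            genome=self.genome,
        )

    def ids(self) -> list[str | None]:
        return [iv.id for iv in self.intervals]

    def total_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "id": [iv.id for iv in self.intervals],
            }
        )


def read_genome(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` genome file."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed genome line {lineno}: {line!r}")
            genome[parts[0]] = int(parts[1])
    return genome


_DIALECT_MIN_COLS = {"bed3": 3, "bed6": 4, "narrowPeak": 4}


def read_bed(
    path: str | Path,
    dialect: str = "bed3",
    genome: Mapping[str, int] | None = None,
) -> GenomicIntervalSet:
    """Read BED3/BED6/narrowPeak into a :class:`GenomicIntervalSet`.

    The 4th column, when present, becomes the interval id; score/strand and
    the narrowPeak statistics columns are ignored.  Input order is preserved.
    """
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"non-integer coordinate at line {lineno}: {line!r}") from exc
            if end <= start:
                raise ValueError(f"end ≤ start at line {lineno}")
            name = parts[3] if dialect != "bed3" and len(parts) > 3 else None
            intervals.append(GenomicInterval(chrom, start, end, id=name))
    return GenomicIntervalSet(intervals, genome=genome)


def write_bed(ivs: GenomicIntervalSet, path: str | Path) -> None:
    """Write intervals as BED3 (or BED4 when ids are present)."""
    with open(path, "w") as fh:
        for iv in ivs:
            if iv.id is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _check_same_genome(sets: Iterable[GenomicIntervalSet]) -> dict[str, int] | None:
    genome = None
    seen = False
    for s in sets:
        if s.genome is None:
            continue
        if not seen:
            genome, seen = s.genome, True
        elif s.genome != genome:
            raise ValueError("interval sets carry mismatched genomes")
    return genome


def merge_intervals(
    sets: Iterable[GenomicIntervalSet],
    min_gap: int = 0,
) -> GenomicIntervalSet:
    """Union-merge intervals across sets into disjoint sorted intervals.

    Intervals closer than or equal to ``min_gap`` bp apart (edge-to-edge) are
    joined; ``min_gap=0`` joins only overlapping or book-ended intervals.
    Output ids are ``peak_00001`` etc. in sorted genomic order.
    """
    sets = list(sets)
    genome = _check_same_genome(sets)
    pooled = sorted(
        (iv for s in sets for iv in s),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    merged: list[GenomicInterval] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    out_idx = 0

    def flush() -> None:
        nonlocal out_idx
        if cur_chrom is not None:
            out_idx += 1
            merged.append(
                GenomicInterval(cur_chrom, cur_start, cur_end, id=f"peak_{out_idx:05d}")
            )

    for iv in pooled:
        if iv.chrom == cur_chrom and iv.start <= cur_end + min_gap:
            cur_end = max(cur_end, iv.end)
        else:
            flush()
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    flush()
    return GenomicIntervalSet(merged, genome=genome)


def build_trees(ivs: GenomicIntervalSet) -> dict[str, IntervalTree]:
    """Index intervals per chromosome for overlap/stabbing queries.

    Each tree payload is the position of the interval in the input order.
    """
    trees: dict[str, IntervalTree] = {}
    for pos, iv in enumerate(ivs):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, pos)
    return trees


def midpoint_assign(
    regions: GenomicIntervalSet,
    domains: GenomicIntervalSet,
) -> dict[str, list[str]]:
    """Assign each region to every domain containing its midpoint.

    The midpoint is ``floor((start+end)/2)`` and containment is half-open, so
    a midpoint equal to a domain start is inside and one equal to a domain
    end is outside.  Regions and domains are matched by their ``id`` fields.
    """
    trees = build_trees(domains)
    domain_ids = domains.ids()
    out: dict[str, list[str]] = {}
    for pos, region in enumerate(regions):
        rid = region.id if region.id is not None else f"region_{pos}"
        tree = trees.get(region.chrom)
        if tree is None:
            out[rid] = []
            continue
        hits = sorted(h.data for h in tree.at(region.midpoint))
        out[rid] = [domain_ids[h] if domain_ids[h] is not None else f"domain_{h}" for h in hits]
    return out
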