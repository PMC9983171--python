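"""Domain types and text-format I/O shared by every stage of the pipeline.

All coordinates are BED-convention 0-based half-open ``[start, end)``.  The
helpers :func:`to_one_based` / :func:`from_one_based` convert at the API
boundary for tools that speak 1-based inclusive coordinates.

Formats handled here are deliberately plain text: BED3/BED6, bedGraph and
tab-separated tables with a header row.  Signal values are written with six
decimal places, which is enough for lossless round-trips of CPM-scaled
coverage.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "SignalTrack",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_table",
    "write_table",
    "to_one_based",
    "from_one_based",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally named and scored."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"zero- or negative-width interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-resolved transcription start site.

    The TSS is ``start`` on the + strand and ``end - 1`` on the - strand, so it
    always lies inside ``[start, end)``.
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, got {self.interval.strand!r}"
            )

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class SignalTrack:
    """Piecewise-constant per-base coverage with bedGraph semantics.

    Internally one triple of numpy arrays ``(starts, ends, values)`` per
    chromosome, sorted and non-overlapping.  Bases not covered by any record
    have value 0; zero-valued records are canonicalised away on construction so
    equality and round-trips are well defined.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in sorted(data):
            starts, ends, values = (np.asarray(a) for a in data[chrom])
            starts = starts.astype(np.int64)
            ends = ends.astype(np.int64)
            values = values.astype(np.float64)
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite signal value on {chrom}")
            if np.any(values < 0):
                raise ValueError(f"negative signal value on {chrom}")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"empty bedGraph record on {chrom}")
            if starts.size and np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping bedGraph records on {chrom} near position {starts[i + 1]}"
                )
            keep = values > 0
            self._data[chrom] = (starts[keep], ends[keep], values[keep])

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        data = {}
        for chrom, recs in by_chrom.items():
            arr = np.array(recs, dtype=np.float64).reshape(-1, 3)
            data[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(data)

    @classmethod
    def empty(cls) -> "SignalTrack":
        return cls({})

    # -- basic queries -----------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._data.get(
            chrom,
            (
                np.empty(0, np.int64),
                np.empty(0, np.int64),
                np.empty(0, np.float64),
            ),
        )

    def iter_records(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom, (starts, ends, values) in self._data.items():
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def total_area(self) -> float:
        """Sum of value * width over all records."""
        return float(
            sum(
                np.sum((e - s) * v)
                for s, e, v in self._data.values()
            )
        )

    def chrom_extent(self, chrom: str) -> int:
        _, ends, _ = self.arrays(chrom)
        return int(ends[-1]) if ends.size else 0

    def area_in(self, chrom: str, start: int, end: int) -> float:
        """Integral of the track over ``[start, end)``."""
        starts, ends, values = self.arrays(chrom)
        if not starts.size:
            return 0.0
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * values[lo:hi]))

    def scale(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self._data.items()}
        )

    def bin_sums(self, bin_size: int, extents: dict[str, int] | None = None) -> dict[str, np.ndarray]:
        """Per-bin integral of the track, tiling each chromosome.

        ``extents`` optionally fixes chromosome lengths (defaults to the last
        covered base, rounded up to a whole bin).
        """
        out: dict[str, np.ndarray] = {}
        chroms = set(self._data) | set(extents or {})
        for chrom in sorted(chroms):
            length = (extents or {}).get(chrom, self.chrom_extent(chrom))
            n_bins = int(np.ceil(length / bin_size)) if length else 0
            sums = np.zeros(n_bins)
            starts, ends, values = self.arrays(chrom)
            for s, e, v in zip(starts, ends, values):
                b0 = int(s // bin_size)
                b1 = int((e - 1) // bin_size)
                if b0 == b1:
                    sums[b0] += (e - s) * v
                    continue
                sums[b0] += ((b0 + 1) * bin_size - s) * v
                if b1 > b0 + 1:
                    sums[b0 + 1 : b1] += bin_size * v
                sums[b1] += (e - b1 * bin_size) * v
            out[chrom] = sums
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        return all(
            np.array_equal(a[i], b[i])
            for c in self.chroms
            for a, b in [(self._data[c], other._data[c])]
            for i in range(3)
        )


# -- coordinate conversions ------------------------------------------------

def to_one_based(interval: GenomicInterval) -> tuple[str, int, int]:
    """BED half-open -> 1-based inclusive ``(chrom, start, end)``."""
    return interval.chrom, interval.start + 1, interval.end


def from_one_based(chrom: str, start: int, end: int, **kwargs) -> GenomicInterval:
    """1-based inclusive -> BED half-open interval."""
    return GenomicInterval(chrom, start - 1, end, **kwargs)


# -- BED -------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; extra columns beyond 6 are ignored.

    Malformed lines raise :class:`ValueError` naming the line number.  Input
    order is preserved.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(_fmt_number(iv.score) if iv.score is not None else ".")
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Read a BED6 gene file into :class:`GeneModel` records (name = gene id)."""
    genes = []
    for i, iv in enumerate(read_bed(path)):
        gene_id = iv.name if iv.name is not None else f"gene_{i}"
        genes.append(GeneModel(gene_id, iv))
    return genes


def write_genes_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    write_bed(
        [replace(g.interval, name=g.gene_id, score=0.0) for g in genes], path
    )


# -- bedGraph --------------------------------------------------------------

def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Records may be unsorted; overlaps or negative values raise ``ValueError``.
    An empty file yields an empty (all-zero) track.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph record") from exc
            if records[-1][3] < 0:
                raise ValueError(f"{path}:{lineno}: negative signal value")
            if records[-1][2] <= records[-1][1]:
                raise ValueError(f"{path}:{lineno}: end <= start")
    return SignalTrack.from_records(records)


def write_bedgraph(track: SignalTrack, path: str | Path, precision: int = 6) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.{precision}f}\n")


# -- tables ----------------------------------------------------------------

def read_table(path: str | Path | io.StringIO) -> pd.DataFrame:
    """Read a TSV with a header of sample names and a first column of feature ids.

    All cells must be numeric; duplicated feature ids raise ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated feature id: {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        row, col = bad[bad].index[0]
        raise ValueError(f"non-numeric cell at feature {row!r}, sample {col!r}")
    numeric.index = numeric.index.astype(str)
    return numeric


def write_table(df: pd.DataFrame, path: str | Path, float_precision: int = 6) -> None:
    df.to_csv(path, sep="\t", float_format=f"%.{float_precision}g")


def _fmt_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"
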