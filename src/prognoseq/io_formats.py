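"""Readers and writers for the tabular and genomic formats the pipeline touches.

All genomic coordinates are 0-based half-open ([start, end)), the native
convention of both BED and UCSC refFlat, and are preserved end-to-end.
Count matrices are stored features-in-rows (the ~20k x 136 orientation the
screening loop iterates over).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

FEATURE_CLASSES = ("refseq", "intron", "intergenic")


class FormatError(ValueError):
    """Raised for malformed input files; the message names the offending line."""


# ---------------------------------------------------------------------------
# Core record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RefFlatRecord:
    """One row of a UCSC refFlat.txt gene annotation (11 tab-separated columns).

    Exon coordinate lists are parallel arrays of length ``exon_count``; exons
    are sorted, non-overlapping and contained in ``[tx_start, tx_end)``.
    """

    gene_name: str
    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_count: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise FormatError(
                f"{self.name}: txStart ({self.tx_start}) must be < txEnd ({self.tx_end})"
            )
        if len(self.exon_starts) != self.exon_count or len(self.exon_ends) != self.exon_count:
            raise FormatError(
                f"{self.name}: exon list lengths ({len(self.exon_starts)}, "
                f"{len(self.exon_ends)}) do not match exonCount ({self.exon_count})"
            )
        prev_end = self.tx_start - 1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise FormatError(f"{self.name}: exon [{s},{e}) outside transcript span")
            if s < prev_end:
                raise FormatError(f"{self.name}: exons unsorted or overlapping at [{s},{e})")
            prev_end = e


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an attached pooled read count."""

    chrom: str
    start: int
    end: int
    count: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(f"interval start ({self.start}) must be < end ({self.end})")
        if self.count < 0:
            raise FormatError(f"interval count must be >= 0, got {self.count}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-patient follow-up: time to recurrence/breast-cancer death (months)
    and event indicator (1 = event, 0 = censored at last follow-up)."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise FormatError(f"{self.sample_id}: time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise FormatError(f"{self.sample_id}: event must be 0 or 1, got {self.event}")


@dataclass
class CountMatrix:
    """Feature x sample expression values with a feature-class label.

    ``values`` holds features in rows and samples in columns; ``feature_class``
    is one of refseq | intron | intergenic and selects which reference set is
    used downstream for quartile normalization.
    """

    values: pd.DataFrame
    feature_class: str = "refseq"

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise FormatError(
                f"feature_class must be one of {FEATURE_CLASSES}, got {self.feature_class!r}"
            )
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature IDs: {dupes[:5]}")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# refFlat
# ---------------------------------------------------------------------------


def _parse_coord_list(text: str) -> tuple[int, ...]:
    # UCSC writes exon lists with a trailing comma ("100,200,"); tolerate it.
    return tuple(int(tok) for tok in text.strip().split(",") if tok != "")


def read_refflat(path: str | Path) -> list[RefFlatRecord]:
    """Parse a UCSC refFlat.txt file (11 tab-separated columns, no header)."""
    records: list[RefFlatRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 11:
                raise FormatError(
                    f"{path}: line {lineno}: expected 11 tab-separated columns, got {len(cols)}"
                )
            try:
                records.append(
                    RefFlatRecord(
                        gene_name=cols[0],
                        name=cols[1],
                        chrom=cols[2],
                        strand=cols[3],
                        tx_start=int(cols[4]),
                        tx_end=int(cols[5]),
                        cds_start=int(cols[6]),
                        cds_end=int(cols[7]),
                        exon_count=int(cols[8]),
                        exon_starts=_parse_coord_list(cols[9]),
                        exon_ends=_parse_coord_list(cols[10]),
                    )
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_refflat(records: Iterable[RefFlatRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            starts = ",".join(str(s) for s in r.exon_starts) + ","
            ends = ",".join(str(e) for e in r.exon_ends) + ","
            fh.write(
                "\t".join(
                    [
                        r.gene_name,
                        r.name,
                        r.chrom,
                        r.strand,
                        str(r.tx_start),
                        str(r.tx_end),
                        str(r.cds_start),
                        str(r.cds_end),
                        str(r.exon_count),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Count matrices (TSV, features in rows)
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | Path, feature_class: str = "refseq") -> CountMatrix:
    """Read a tab-separated feature x sample count matrix.

    The first column holds feature IDs; remaining columns are samples.
    Non-numeric cells and negative values are rejected with the offending
    row/column named.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: matrix has no {'rows' if df.shape[0] == 0 else 'columns'}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric value at row {bad[0]!r}, column {col!r}: "
                f"{df.loc[bad[0], col]!r}"
            )
        df[col] = numeric
    if df.isna().any().any():
        row, col = next(zip(*np.where(df.isna().to_numpy())))
        raise FormatError(f"{path}: missing value at row {df.index[row]!r}, column {df.columns[col]!r}")
    if (df.to_numpy() < 0).any():
        row, col = next(zip(*np.where(df.to_numpy() < 0)))
        raise FormatError(
            f"{path}: negative value at row {df.index[row]!r}, column {df.columns[col]!r}"
        )
    df.index.name = None  # round-trip identity regardless of the header label
    return CountMatrix(values=df, feature_class=feature_class)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# Survival records (CSV: sample_id,time,event)
# ---------------------------------------------------------------------------


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    records: list[SurvivalRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "time", "event"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: header must contain columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    SurvivalRecord(
                        sample_id=row["sample_id"],
                        time=float(row["time"]),
                        event=int(row["event"]),
                    )
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "time", "event"])
        for r in records:
            writer.writerow([r.sample_id, repr(r.time) if isinstance(r.time, float) else r.time, r.event])


def align_survival(
    records: Sequence[SurvivalRecord], sample_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Order survival records to match count-matrix columns.

    Returns (time, event) arrays aligned to ``sample_ids``; raises listing
    every sample present on one side only.
    """
    by_id = {r.sample_id: r for r in records}
    missing = [s for s in sample_ids if s not in by_id]
    extra = [r.sample_id for r in records if r.sample_id not in set(sample_ids)]
    if missing or extra:
        raise FormatError(
            f"survival/count-matrix sample mismatch: missing from survival {missing[:10]}, "
            f"absent from matrix {extra[:10]}"
        )
    time = np.array([by_id[s].time for s in sample_ids], dtype=float)
    event = np.array([by_id[s].event for s in sample_ids], dtype=int)
    return time, event


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED with name (label) and score (pooled count) columns."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t{iv.count}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >=3 columns")
            try:
                label = cols[3] if len(cols) > 3 and cols[3] != "." else ""
                count = int(cols[4]) if len(cols) > 4 else 1
                intervals.append(
                    GenomicInterval(cols[0], int(cols[1]), int(cols[2]), count=count, label=label)
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


# ---------------------------------------------------------------------------
# Graphs (SIF / GraphML)
# ---------------------------------------------------------------------------


def write_graph(graph: nx.Graph, path: str | Path, fmt: str = "sif") -> None:
    """Write a co-expression graph as SIF ("A coexp B") or GraphML.

    SIF lists isolated nodes as bare single-column lines (the Cytoscape
    convention); edge weights survive only in GraphML.
    """
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(tuple(sorted((str(a), str(b)))) for a, b in graph.edges()):
                fh.write(f"{u}\tcoexp\t{v}\n")
            for node in sorted(str(n) for n in nx.isolates(graph)):
                fh.write(f"{node}\n")
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}; use 'sif' or 'graphml'")


def read_graph(path: str | Path, fmt: str = "sif") -> nx.Graph:
    if fmt == "sif":
        g: nx.Graph = nx.Graph()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                cols = line.split("\t")
                if len(cols) == 1:
                    g.add_node(cols[0])
                elif len(cols) == 3:
                    g.add_edge(cols[0], cols[2])
                else:
                    raise FormatError(f"{path}: line {lineno}: SIF line must have 1 or 3 columns")
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown graph format {fmt!r}; use 'sif' or 'graphml'")
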