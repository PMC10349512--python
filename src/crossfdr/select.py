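"""Threshold-based SNP selection, Manhattan-plot data, and annotation joins."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._chrom import CHROMOSOMES, chrom_order, sort_genomic
from .errors import EmptyInputError, ValidationError

CFDR_COLUMNS = ("cfdr_a_given_b", "cfdr_b_given_a", "ccfdr")

#: gap between chromosomes on the cumulative plotting axis, in position units
CHROM_GAP = 1


@dataclass
class SelectionReport:
    column: str
    threshold: float
    table: pd.DataFrame  # selected rows, sorted by (chr, pos)
    counts_per_chrom: dict[str, int] = field(default_factory=dict)
    annotation_columns: list[str] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return len(self.table)


def select_by_threshold(table: pd.DataFrame, column: str, threshold: float) -> SelectionReport:
    """Rows with ``column`` strictly below ``threshold``, sorted genomically."""
    if column not in CFDR_COLUMNS:
        raise ValidationError(f"unknown selection column {column!r}; expected one of {CFDR_COLUMNS}")
    if column not in table.columns:
        raise ValidationError(f"table has no column {column!r}")
    if not (0 <= threshold < 1):
        raise ValidationError(f"threshold must be in [0, 1), got {threshold}")

    sel = sort_genomic(table.loc[table[column] < threshold])
    counts = sel["chr"].value_counts().to_dict()
    return SelectionReport(
        column=column,
        threshold=float(threshold),
        table=sel,
        counts_per_chrom={str(k): int(v) for k, v in counts.items()},
    )


@dataclass
class ManhattanData:
    points: pd.DataFrame  # snp, chr, pos, coord, neglog10
    line: Optional[float] = None  # -log10(threshold)


def manhattan_data(
    table: pd.DataFrame, column: str, threshold: Optional[float] = None
) -> ManhattanData:
    """Cumulative plotting coordinates and -log10 values for a Manhattan plot.

    Chromosomes are laid out in 1..22, X order with a fixed one-unit gap; the
    output ordering is independent of input row order.
    """
    if column not in table.columns:
        raise ValidationError(f"table has no column {column!r}")
    if table.empty:
        raise EmptyInputError("table is empty")

    df = sort_genomic(table)
    coord = np.empty(len(df), dtype=np.int64)
    offset = 0
    for c in CHROMOSOMES:
        mask = (df["chr"] == c).to_numpy()
        if not mask.any():
            continue
        pos = df.loc[mask, "pos"].to_numpy(np.int64)
        coord[mask] = offset + pos
        offset += int(pos.max()) + CHROM_GAP
    # tied positions (e.g. rounded coordinates) are nudged so the plotting
    # coordinate is strictly increasing in genome order
    for i in range(1, len(coord)):
        if coord[i] <= coord[i - 1]:
            coord[i] = coord[i - 1] + 1

    points = pd.DataFrame(
        {
            "snp": df["snp"],
            "chr": df["chr"],
            "pos": df["pos"],
            "coord": coord,
            "neglog10": -np.log10(df[column].to_numpy(float)),
        }
    )
    line = None if threshold is None else float(-np.log10(threshold))
    return ManhattanData(points=points, line=line)


def annotate_selection(report: SelectionReport, annotation: pd.DataFrame) -> SelectionReport:
    """Left-join annotation columns (keyed by rsID) onto a selection report.

    Unmatched SNPs keep empty annotation; no rows are gained or lost.
    Duplicate annotation keys raise :class:`ValidationError`.
    """
    key = "snp" if "snp" in annotation.columns else annotation.columns[0]
    if annotation[key].duplicated().any():
        dups = annotation.loc[annotation[key].duplicated(), key].tolist()
        raise ValidationError(f"duplicate annotation keys: {dups[:5]}")

    ann = annotation.rename(columns={key: "snp"})
    new_cols = [c for c in ann.columns if c != "snp"]
    joined = report.table.merge(ann, on="snp", how="left")
    for c in new_cols:
        if joined[c].dtype == object:
            joined[c] = joined[c].fillna("")
    return SelectionReport(
        column=report.column,
        threshold=report.threshold,
        table=joined,
        counts_per_chrom=dict(report.counts_per_chrom),
        annotation_columns=report.annotation_columns + new_cols,
    )


def deannotate_selection(report: SelectionReport) -> SelectionReport:
    """Drop previously joined annotation columns (inverse of annotate_selection)."""
    return SelectionReport(
        column=report.column,
        threshold=report.threshold,
        table=report.table.drop(columns=report.annotation_columns),
        counts_per_chrom=dict(report.counts_per_chrom),
        annotation_columns=[],
    )


def write_selection(report: SelectionReport, path: str | Path) -> Path:
    path = Path(path)
    report.table.to_csv(path, sep="\t", index=False)
    return path


def to_bed(report: SelectionReport, path: str | Path) -> Path:
    """Export a selection as BED (0-based half-open); score is -log10(value)
    scaled by 100 and capped at 1000 for genome-browser display."""
    df = report.table
    score = np.minimum(1000, np.round(100 * -np.log10(df[report.column].to_numpy(float)))).astype(int)
    bed = pd.DataFrame(
        {
            "chrom": "chr" + df["chr"].astype(str),
            "chromStart": df["pos"].astype(np.int64) - 1,
            "chromEnd": df["pos"].astype(np.int64),
            "name": df["snp"],
            "score": score,
        }
    )
    path = Path(path)
    bed.to_csv(path, sep="\t", index=False, header=False)
    return path
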