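"""Reading, validating and writing GWAS summary-statistics tables.

The canonical in-memory layout is a :class:`pandas.DataFrame` with columns
``snp, chr, pos, p`` and optionally ``beta, se, a1, a2, maf``, wrapped in
:class:`SumStats` together with row-drop bookkeeping.  On disk the de-facto
whitespace/tab/comma-delimited sumstats layout with a header row is used
(columns ``SNP, CHR, POS, P`` plus optional ``BETA, SE, A1, A2, MAF``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._chrom import normalize_chrom, sort_genomic
from .errors import EmptyInputError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: default mapping from canonical field name to on-disk column name
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp": "SNP",
    "chr": "CHR",
    "pos": "POS",
    "p": "P",
    "beta": "BETA",
    "se": "SE",
    "a1": "A1",
    "a2": "A2",
    "maf": "MAF",
}

REQUIRED_FIELDS = ("snp", "chr", "pos", "p")
OPTIONAL_FIELDS = ("beta", "se", "a1", "a2", "maf")


@dataclass
class SumStatRecord:
    """One SNP's association evidence for a single trait."""

    snp: str
    chr: str
    pos: int
    p: float
    beta: Optional[float] = None
    se: Optional[float] = None
    a1: Optional[str] = None
    a2: Optional[str] = None
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"p must be in (0, 1], got {self.p!r} for {self.snp}")
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos!r} for {self.snp}")
        if self.beta is not None and self.se is None:
            raise ValidationError(f"beta present without se for {self.snp}")
        if self.se is not None and self.se <= 0:
            raise ValidationError(f"se must be > 0, got {self.se!r} for {self.snp}")
        if self.maf is not None and not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"maf must be in (0, 0.5], got {self.maf!r} for {self.snp}")


@dataclass
class SumStats:
    """Validated summary statistics for one trait.

    ``table`` holds canonical columns, sorted by (chr, pos); ``n_dropped``
    counts input rows removed during validation/deduplication so that
    ``len(table) + n_dropped`` equals the input row count.
    """

    table: pd.DataFrame
    n_dropped: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def records(self) -> list[SumStatRecord]:
        cols = [c for c in DEFAULT_COLUMN_MAP if c in self.table.columns]
        out = []
        for row in self.table[cols].itertuples(index=False):
            kwargs = dict(zip(cols, row))
            out.append(SumStatRecord(**{k: (None if pd.isna(v) else v) for k, v in kwargs.items()}))
        return out


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if "\t" in line:
                    return "\t"
                if "," in line:
                    return ","
                return r"\s+"
    raise EmptyInputError(f"{path} is empty")


def _count(reasons: dict[str, int], key: str, n: int) -> None:
    if n:
        reasons[key] = reasons.get(key, 0) + int(n)


def _to_float(s: pd.Series) -> pd.Series:
    """Exact float parsing (Python's round-trip parser) with NaN on failure."""
    if s.dtype != object:
        return pd.to_numeric(s, errors="coerce")

    def conv(v):
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    return s.map(conv).astype(float)


def validate_sumstats(df: pd.DataFrame) -> SumStats:
    """Validate a raw canonical-column frame, dropping and counting bad rows.

    Rules: p in (0, 1]; pos a positive integer; chromosome in 1-22/X;
    se > 0 wherever beta is present; maf in (0, 0.5].  Duplicate rsIDs keep
    the smallest p.  The result is sorted by (chr, pos).
    """
    n_in = len(df)
    reasons: dict[str, int] = {}
    df = df.copy()

    df["snp"] = df["snp"].astype(str)
    df["chr"] = normalize_chrom(df["chr"])
    df["pos"] = _to_float(df["pos"])
    df["p"] = _to_float(df["p"])
    for col in ("beta", "se", "maf"):
        if col in df.columns:
            df[col] = _to_float(df[col])

    ok = df["chr"].notna()
    _count(reasons, "bad_chromosome", (~ok).sum())
    keep = ok

    ok = df["pos"].notna() & (df["pos"] >= 1) & (df["pos"] == np.floor(df["pos"].fillna(0)))
    _count(reasons, "bad_position", (keep & ~ok).sum())
    keep &= ok

    ok = df["p"].notna() & (df["p"] > 0) & (df["p"] <= 1)
    _count(reasons, "bad_p", (keep & ~ok).sum())
    keep &= ok

    if "beta" in df.columns:
        has_beta = df["beta"].notna()
        ok = ~has_beta | (df.get("se", pd.Series(np.nan, index=df.index)).notna() & (df["se"] > 0))
        _count(reasons, "beta_without_valid_se", (keep & ~ok).sum())
        keep &= ok
    if "maf" in df.columns:
        ok = df["maf"].isna() | ((df["maf"] > 0) & (df["maf"] <= 0.5))
        _count(reasons, "bad_maf", (keep & ~ok).sum())
        keep &= ok

    df = df.loc[keep].copy()
    df["pos"] = df["pos"].astype(np.int64)

    # duplicate rsIDs: keep the smallest p (stable on ties)
    before = len(df)
    df = df.sort_values("p", kind="stable").drop_duplicates("snp", keep="first")
    _count(reasons, "duplicate_rsid", before - len(df))

    df = sort_genomic(df)
    n_dropped = n_in - len(df)
    if n_dropped:
        logger.info("dropped %d/%d rows during validation: %s", n_dropped, n_in, reasons)
    return SumStats(table=df, n_dropped=n_dropped, drop_reasons=reasons)


def read_sumstats(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
) -> SumStats:
    """Read a summary-statistics text file.

    ``column_map`` maps canonical field names (``snp, chr, pos, p`` required;
    ``beta, se, a1, a2, maf`` optional) to the file's column names; by default
    the standard upper-case names are used and optional columns are picked up
    when present.  Rows failing validation are dropped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, engine="python" if sep == r"\s+" else "c")

    explicit = column_map is not None
    cmap = dict(column_map) if explicit else dict(DEFAULT_COLUMN_MAP)
    for fld in REQUIRED_FIELDS:
        if fld not in cmap:
            raise FormatError(f"column_map is missing the required field {fld!r}")
        if cmap[fld] not in raw.columns:
            raise FormatError(f"required column {cmap[fld]!r} (field {fld!r}) not found in {path}")

    data = {}
    for fld, col in cmap.items():
        if fld in REQUIRED_FIELDS or col in raw.columns:
            if col not in raw.columns:
                raise FormatError(f"mapped column {col!r} (field {fld!r}) not found in {path}")
            data[fld] = raw[col]
        elif explicit:
            # an explicitly mapped optional column must exist
            raise FormatError(f"mapped column {col!r} (field {fld!r}) not found in {path}")
    df = pd.DataFrame(data)

    ss = validate_sumstats(df)
    if len(ss.table) == 0:
        raise EmptyInputError(f"no valid rows remain after filtering {path}")
    return ss


def write_sumstats(stats: SumStats | pd.DataFrame, path: str | Path) -> Path:
    """Write summary statistics as a tab-delimited text file.

    Inverse of :func:`read_sumstats` on the retained columns; an empty table
    produces a header-only file.
    """
    df = stats.table if isinstance(stats, SumStats) else stats
    cols = [c for c in DEFAULT_COLUMN_MAP if c in df.columns]
    out = df[cols].rename(columns={c: DEFAULT_COLUMN_MAP[c] for c in cols})
    path = Path(path)
    # %.17g guarantees binary round-trip of doubles through the text file
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def records_to_frame(records: Sequence[SumStatRecord]) -> pd.DataFrame:
    """Assemble a canonical frame from individual records (optional columns kept if any record sets them)."""
    base = pd.DataFrame([vars(r) for r in records])
    if base.empty:
        return pd.DataFrame(columns=list(REQUIRED_FIELDS))
    drop = [c for c in OPTIONAL_FIELDS if c in base.columns and base[c].isna().all()]
    return base.drop(columns=drop)
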