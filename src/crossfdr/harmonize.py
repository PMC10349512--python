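"""Merge two traits' summary statistics on their common SNP set."""

from __future__ import annotations

import logging
import warnings

import pandas as pd

from ._chrom import sort_genomic
from .errors import EmptyInputError
from .sumstats import SumStats

logger = logging.getLogger(__name__)

PAIRED_COLUMNS = ("snp", "chr", "pos", "p_a", "p_b")


def _as_frame(x) -> pd.DataFrame:
    return x.table if isinstance(x, SumStats) else x


def merge_traits(records_a, records_b) -> pd.DataFrame:
    """Intersect two traits' SNP sets into a paired table.

    The result carries exactly the rsID intersection, with ``p_a``/``p_b``
    from each source; chromosome and position are taken from trait A (a
    warning is emitted when B disagrees).  MAF is carried from trait A when
    present, else from trait B.  Raises :class:`EmptyInputError` on an empty
    intersection.
    """
    a = _as_frame(records_a)
    b = _as_frame(records_b)

    left = a[[c for c in ("snp", "chr", "pos", "p", "maf") if c in a.columns]]
    right = b[[c for c in ("snp", "chr", "pos", "p", "maf") if c in b.columns]]
    merged = left.merge(right, on="snp", how="inner", suffixes=("_a", "_b"))
    if merged.empty:
        raise EmptyInputError("the two traits share no rsIDs")

    mismatch = (merged["chr_a"] != merged["chr_b"]) | (merged["pos_a"] != merged["pos_b"])
    if mismatch.any():
        warnings.warn(
            f"{int(mismatch.sum())} SNPs have conflicting coordinates between traits; "
            "trait A coordinates retained",
            stacklevel=2,
        )

    out = pd.DataFrame(
        {
            "snp": merged["snp"],
            "chr": merged["chr_a"],
            "pos": merged["pos_a"],
            "p_a": merged["p_a"],
            "p_b": merged["p_b"],
        }
    )
    if "maf_a" in merged.columns:
        out["maf"] = merged["maf_a"]
        if "maf_b" in merged.columns:
            out["maf"] = out["maf"].fillna(merged["maf_b"])
    elif "maf_b" in merged.columns:
        out["maf"] = merged["maf_b"]

    out = sort_genomic(out)
    logger.info("merged %d x %d SNPs -> %d common", len(a), len(b), len(out))
    return out
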