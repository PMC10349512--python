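"""Chromosome label handling: autosomes 1-22 plus X, in genome plotting order."""

from __future__ import annotations

import numpy as np
import pandas as pd

CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)
_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}


def normalize_chrom(values) -> pd.Series:
    """Map chromosome labels to canonical strings; unknown labels become NaN."""
    s = pd.Series(values, copy=True).astype(str).str.strip()
    s = s.str.replace("^chr", "", regex=True, case=False)
    # "1.0" style labels from numeric columns
    s = s.str.replace(r"\.0$", "", regex=True)
    s = s.str.upper()
    return s.where(s.isin(CHROMOSOMES))


def chrom_order(values) -> np.ndarray:
    """Integer sort key for canonical chromosome labels."""
    return pd.Series(values).map(_ORDER).to_numpy()


def sort_genomic(df: pd.DataFrame, chrom_col: str = "chr", pos_col: str = "pos") -> pd.DataFrame:
    """Sort by (chromosome order, position), resetting the index.

    rsID is the final tie-break so the ordering is invariant to input row order.
    """
    key = chrom_order(df[chrom_col])
    keys = [df[pos_col].to_numpy(), key]
    if "snp" in df.columns:
        keys.insert(0, df["snp"].to_numpy(str))
    idx = np.lexsort(tuple(keys))
    return df.iloc[idx].reset_index(drop=True)
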