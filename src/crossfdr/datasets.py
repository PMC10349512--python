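"""Bundled small text datasets."""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: column mapping from the published pleiotropic-locus table to canonical names;
#: trait A is birth weight ("BW"), trait B is neuroticism ("NE")
_LOCI_RENAME = {
    "SNP": "snp",
    "CHR": "chr",
    "POS": "pos",
    "cFDR.BW": "cfdr_a_given_b",
    "cFDR.NE": "cfdr_b_given_a",
    "ccfdr": "ccfdr",
}


def load_pleiotropic_loci() -> pd.DataFrame:
    """62 published pleiotropic SNPs with their two conditional FDR values and
    the conjunction value, in canonical CfdrTable column names plus ``gene``."""
    ref = resources.files("crossfdr.data").joinpath("pleiotropic_loci.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df = df.rename(columns=_LOCI_RENAME)
    df["chr"] = df["chr"].astype(str)
    return df
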