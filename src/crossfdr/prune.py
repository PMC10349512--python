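"""Sliding-window greedy LD pruning of a paired summary-statistics table.

Within each window, while any surviving pair has r^2 above the threshold,
the member of the currently worst (highest-r^2) pair with the smaller MAF is
removed; ties on MAF remove the SNP later in (chr, pos) order.  The r^2
source is pluggable: squared Pearson correlation of genotype-score vectors,
or a precomputed pair list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from ._chrom import sort_genomic
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PruneConfig:
    r2_threshold: float = 0.2
    window_size: int = 50
    window_step: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold < 1):
            raise ValidationError(f"r2_threshold must be in (0, 1), got {self.r2_threshold}")
        if self.window_size < 2:
            raise ValidationError(f"window_size must be >= 2, got {self.window_size}")
        if not (1 <= self.window_step <= self.window_size):
            raise ValidationError(
                f"window_step must be in [1, window_size], got {self.window_step}"
            )


class R2Source(Protocol):
    """Pairwise r^2 provider for SNPs on the same chromosome."""

    def r2_matrix(self, snps: Sequence[str]) -> np.ndarray: ...


class GenotypeMatrixR2:
    """r^2 as squared Pearson correlation of per-SNP genotype/latent score vectors.

    ``scores`` is a SNP x sample frame indexed by rsID.
    """

    def __init__(self, scores: pd.DataFrame):
        self.scores = scores

    @classmethod
    def from_file(cls, path: str | Path) -> "GenotypeMatrixR2":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def r2_matrix(self, snps: Sequence[str]) -> np.ndarray:
        missing = [s for s in snps if s not in self.scores.index]
        if missing:
            raise ConfigurationError(f"no genotype scores for SNPs: {missing[:5]}")
        x = self.scores.loc[list(snps)].to_numpy(float)
        sd = x.std(axis=1)
        if np.any(sd == 0):
            raise ConfigurationError("constant genotype-score vector; r^2 undefined")
        r = np.corrcoef(x)
        np.fill_diagonal(r, 0.0)  # self-pairs are never pruned
        return r**2


class PairListR2:
    """r^2 from a precomputed (snp1, snp2, r2) pair list; absent pairs are 0."""

    def __init__(self, pairs: dict[frozenset, float]):
        self.pairs = pairs

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairListR2":
        return cls(
            {
                frozenset((str(r.snp1), str(r.snp2))): float(r.r2)
                for r in df.itertuples(index=False)
            }
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PairListR2":
        return cls.from_frame(pd.read_csv(path, sep=r"\s+", engine="python"))

    def r2_matrix(self, snps: Sequence[str]) -> np.ndarray:
        n = len(snps)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                v = self.pairs.get(frozenset((str(snps[i]), str(snps[j]))), 0.0)
                m[i, j] = m[j, i] = v
        return m


def _prune_indices(
    idx: list[int],
    r2: np.ndarray,
    maf: np.ndarray,
    removed: set[int],
    threshold: float,
) -> bool:
    """Greedy removal inside one window; returns True if anything was removed."""
    changed = False
    alive = [k for k, i in enumerate(idx) if i not in removed]
    while True:
        best = None
        best_r2 = threshold
        for a_pos, ka in enumerate(alive):
            for kb in alive[a_pos + 1 :]:
                v = r2[ka, kb]
                if v > best_r2:
                    best_r2 = v
                    best = (ka, kb)
        if best is None:
            return changed
        ka, kb = best
        ia, ib = idx[ka], idx[kb]
        if np.isnan(maf[ia]) or np.isnan(maf[ib]):
            raise ConfigurationError(
                f"MAF missing for a SNP in a linked pair (rows {ia}, {ib})"
            )
        # remove smaller MAF; tie -> the one later in (chr, pos) order (larger row index)
        if maf[ia] < maf[ib]:
            drop = ka
        elif maf[ib] < maf[ia]:
            drop = kb
        else:
            drop = kb if ib > ia else ka
        removed.add(idx[drop])
        alive.remove(drop)
        changed = True


def ld_prune(
    paired: pd.DataFrame,
    r2_source: R2Source,
    cfg: PruneConfig = PruneConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Prune linked SNPs from a paired table; returns (kept, removed).

    Row order of the input is irrelevant: SNPs are sorted genomically and
    windows slide per chromosome.  Window passes repeat until no window
    removes anything, so no surviving pair inside any window exceeds the
    threshold.
    """
    if "maf" not in paired.columns:
        raise ConfigurationError("ld_prune requires a 'maf' column")
    df = sort_genomic(paired)
    maf = df["maf"].to_numpy(float)
    snps = df["snp"].to_numpy()

    removed: set[int] = set()
    for _, group in df.groupby("chr", sort=False):
        rows = list(group.index)
        if len(rows) < 2:
            continue
        gsnps = snps[rows]
        r2 = r2_source.r2_matrix(list(gsnps))
        while True:
            any_change = False
            start = 0
            while start < len(rows):
                stop = min(start + cfg.window_size, len(rows))
                widx = list(range(start, stop))
                sub = r2[np.ix_(widx, widx)]
                if _prune_indices([rows[k] for k in widx], sub, maf, removed, cfg.r2_threshold):
                    any_change = True
                if stop == len(rows):
                    break
                start += cfg.window_step
            if not any_change:
                break

    keep_mask = ~df.index.isin(list(removed))
    kept = df.loc[keep_mask].reset_index(drop=True)
    dropped = df.loc[~keep_mask].reset_index(drop=True)
    logger.info("LD pruning removed %d/%d SNPs (r2 > %s)", len(dropped), len(df), cfg.r2_threshold)
    return kept, dropped
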