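"""Synthetic paired GWAS summary statistics and MR instrument sets.

Paired p-values arise from a four-component mixture over z-scores
(null/null, trait-A-only, trait-B-only, shared non-null); non-null z-scores
are drawn from a symmetric scale mixture Normal(0, sigma^2) with sigma > 1,
so shared SNPs share the non-null indicator but not the effect size.
Optionally, block-correlated latent genotype scores and per-SNP MAFs are
attached to exercise the LD-pruning stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

#: component codes in the label array
NULL, A_ONLY, B_ONLY, SHARED = 0, 1, 2, 3

P_FLOOR = 1e-300  # keeps -log10(p) finite


@dataclass(frozen=True)
class MixtureSpec:
    """Four-component mixture over per-SNP z-score pairs."""

    pi00: float
    pi10: float
    pi01: float
    pi11: float
    n_snps: int
    sigma_a: float = 3.0
    sigma_b: float = 3.0
    seed: int = 0
    n_chrom: int = 22
    spacing: int = 10_000  # fixed inter-SNP spacing in bp

    def __post_init__(self) -> None:
        for name in ("pi00", "pi10", "pi01", "pi11"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be nonnegative, got {v}")
        total = self.pi00 + self.pi10 + self.pi01 + self.pi11
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"mixture proportions must sum to 1, got {total!r}")
        for name in ("sigma_a", "sigma_b"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.n_snps < 1:
            raise ValidationError(f"n_snps must be >= 1, got {self.n_snps}")
        if not (1 <= self.n_chrom <= 22):
            raise ValidationError(f"n_chrom must be in 1..22, got {self.n_chrom}")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.pi00, self.pi10, self.pi01, self.pi11])


@dataclass(frozen=True)
class LDBlockSpec:
    """Block-wise equicorrelated latent genotype scores with per-SNP MAF."""

    block_size: int = 10
    rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_samples: int = 500

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValidationError(f"block_size must be >= 1, got {self.block_size}")
        if not (abs(self.rho) < 1):
            raise ValidationError(f"|rho| must be < 1, got {self.rho}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")


@dataclass(frozen=True)
class MRSimSpec:
    """Instrument-level two-sample MR generative model."""

    n_instruments: int
    true_effect: float
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    se_exp: float = 0.05
    se_out: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instruments < 3:
            raise ValidationError(
                f"n_instruments must be >= 3 (Egger needs >= 3), got {self.n_instruments}"
            )
        for name in ("pleiotropy_sd", "se_exp", "se_out"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class SimulatedPair:
    """Output of :func:`simulate_paired_stats`."""

    table: pd.DataFrame  # snp, chr, pos, p_a, p_b [, maf]
    labels: np.ndarray  # per-SNP component code (NULL/A_ONLY/B_ONLY/SHARED)
    z_a: np.ndarray
    z_b: np.ndarray
    latent_scores: Optional[pd.DataFrame] = None  # SNP x sample, index = snp id
    ld: Optional[LDBlockSpec] = None


def _positions(spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sequential positions with fixed spacing, SNPs split evenly over chromosomes."""
    per = int(np.ceil(spec.n_snps / spec.n_chrom))
    chrom = np.repeat(np.arange(1, spec.n_chrom + 1), per)[: spec.n_snps]
    offset = np.concatenate([np.arange(min(per, spec.n_snps - i * per)) for i in range(spec.n_chrom) if i * per < spec.n_snps])
    pos = (offset + 1) * spec.spacing
    return chrom.astype(str), pos.astype(np.int64)


def _block_scores(rng: np.random.Generator, n_snps: int, ld: LDBlockSpec) -> np.ndarray:
    """Latent scores (n_snps x n_samples) with within-block correlation rho."""
    scores = np.empty((n_snps, ld.n_samples))
    start = 0
    while start < n_snps:
        m = min(ld.block_size, n_snps - start)
        if m == 1:
            scores[start] = rng.standard_normal(ld.n_samples)
        else:
            cov = np.full((m, m), ld.rho)
            np.fill_diagonal(cov, 1.0)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as err:
                raise ValidationError(
                    f"rho={ld.rho} is not a valid equicorrelation for block_size={m}"
                ) from err
            scores[start : start + m] = chol @ rng.standard_normal((m, ld.n_samples))
        start += m
    return scores


def two_sided_p(z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value, clamped to [1e-300, 1]."""
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)


def simulate_paired_stats(spec: MixtureSpec, ld: Optional[LDBlockSpec] = None) -> SimulatedPair:
    """Simulate paired per-SNP summary statistics with known component labels."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_snps

    labels = rng.choice(4, size=n, p=spec.proportions)
    nonnull_a = np.isin(labels, (A_ONLY, SHARED))
    nonnull_b = np.isin(labels, (B_ONLY, SHARED))

    z_a = rng.standard_normal(n)
    z_b = rng.standard_normal(n)
    z_a[nonnull_a] *= spec.sigma_a
    z_b[nonnull_b] *= spec.sigma_b

    chrom, pos = _positions(spec)
    snp = np.array([f"rs{i + 1}" for i in range(n)])
    table = pd.DataFrame(
        {"snp": snp, "chr": chrom, "pos": pos, "p_a": two_sided_p(z_a), "p_b": two_sided_p(z_b)}
    )

    latent = None
    if ld is not None:
        table["maf"] = rng.uniform(ld.maf_range[0], ld.maf_range[1], size=n)
        latent = pd.DataFrame(_block_scores(rng, n, ld), index=snp)

    return SimulatedPair(table=table, labels=labels, z_a=z_a, z_b=z_b, latent_scores=latent, ld=ld)


def split_traits(sim: SimulatedPair) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trait canonical sumstats frames from a simulated pair."""
    base = sim.table[["snp", "chr", "pos"]]
    a = base.assign(p=sim.table["p_a"])
    b = base.assign(p=sim.table["p_b"])
    if "maf" in sim.table.columns:
        a = a.assign(maf=sim.table["maf"])
        b = b.assign(maf=sim.table["maf"])
    return a, b


def simulate_mr_instruments(spec: MRSimSpec) -> pd.DataFrame:
    """Simulate an aligned MR instrument table.

    Observed outcome effects follow
    ``beta_out = true_effect * beta_exp + alpha + Normal(0, se_out)`` with
    direct (pleiotropic) effects ``alpha ~ Normal(pleiotropy_mean,
    pleiotropy_sd^2)``; exposure effects are positive so the Egger intercept
    estimates ``pleiotropy_mean`` directly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_instruments
    gamma = rng.uniform(0.05, 0.5, size=n)
    beta_exp = gamma + rng.normal(0.0, spec.se_exp, size=n)
    alpha = spec.pleiotropy_mean + spec.pleiotropy_sd * rng.standard_normal(n)
    beta_out = spec.true_effect * beta_exp + alpha + rng.normal(0.0, spec.se_out, size=n)
    return pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(n)],
            "beta_exp": beta_exp,
            "se_exp": np.full(n, float(spec.se_exp)),
            "beta_out": beta_out,
            "se_out": np.full(n, float(spec.se_out)),
            "effect_allele": "A",
            "other_allele": "G",
        }
    )
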