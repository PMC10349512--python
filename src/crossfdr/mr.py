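"""Two-sample Mendelian randomization estimators.

Five estimators over instrument-level summary effects: inverse-variance
weighted (fixed or multiplicative random effects), Egger regression (slope +
directional-pleiotropy intercept), weighted median, and the simple/weighted
mode-based estimators, plus forest/scatter plot data.  Per-instrument Wald
ratios use the first-order standard error se_out / |beta_exp|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, InstrumentError, ValidationError

PALINDROMIC = ({"A", "T"}, {"C", "G"})

INSTRUMENT_COLUMNS = ("snp", "beta_exp", "se_exp", "beta_out", "se_out")


@dataclass
class MRInstrumentSet:
    """Harmonized instrument-level effects (same effect allele for both traits)."""

    table: pd.DataFrame  # snp, beta_exp, se_exp, beta_out, se_out
    n_palindromic_dropped: int = 0
    n_mismatch_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in INSTRUMENT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"instrument table missing columns: {missing}")
        if len(self.table) < 1:
            raise EmptyInputError("instrument set is empty")
        if (self.table[["se_exp", "se_out"]].to_numpy(float) < 0).any():
            raise ValidationError("standard errors must be nonnegative")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MRInstrumentSet":
        return cls(table=df[[c for c in df.columns if c in INSTRUMENT_COLUMNS]].copy())


@dataclass
class MRResult:
    method: str
    b: float
    se: float
    p: float
    n_snp: int
    wald_ratios: Optional[pd.DataFrame] = None
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None
    q_statistic: Optional[float] = None


def _is_palindromic(a1: str, a2: str) -> bool:
    return {str(a1).upper(), str(a2).upper()} in PALINDROMIC


def harmonize_instruments(
    exposure: pd.DataFrame, outcome: pd.DataFrame
) -> MRInstrumentSet:
    """Align outcome effects to the exposure effect allele.

    Both inputs need columns ``snp, beta, se, effect_allele, other_allele``.
    Outcome betas are sign-flipped where the allele order is swapped;
    palindromic (A/T, C/G) SNPs and irreconcilable allele pairs are dropped
    with counts.  Instruments are the rsID intersection.
    """
    m = exposure.merge(outcome, on="snp", suffixes=("_exp", "_out"))
    rows, n_pal, n_mis = [], 0, 0
    for r in m.itertuples(index=False):
        ea_e, oa_e = str(r.effect_allele_exp).upper(), str(r.other_allele_exp).upper()
        ea_o, oa_o = str(r.effect_allele_out).upper(), str(r.other_allele_out).upper()
        if _is_palindromic(ea_e, oa_e) or _is_palindromic(ea_o, oa_o):
            n_pal += 1
            continue
        if (ea_o, oa_o) == (ea_e, oa_e):
            beta_out = r.beta_out
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_out = -r.beta_out
        else:
            n_mis += 1
            continue
        rows.append(
            {
                "snp": r.snp,
                "beta_exp": r.beta_exp,
                "se_exp": r.se_exp,
                "beta_out": beta_out,
                "se_out": r.se_out,
            }
        )
    if not rows:
        raise EmptyInputError("no instruments remain after harmonization")
    return MRInstrumentSet(
        table=pd.DataFrame(rows), n_palindromic_dropped=n_pal, n_mismatch_dropped=n_mis
    )


def wald_ratios(iset: MRInstrumentSet) -> pd.DataFrame:
    """Per-instrument causal-effect ratios theta = beta_out / beta_exp with
    first-order se = se_out / |beta_exp|, preserving instrument order."""
    df = iset.table
    zero = df.loc[df["beta_exp"] == 0, "snp"].tolist()
    if zero:
        raise InstrumentError(f"zero exposure effect for instruments: {zero}")
    be = df["beta_exp"].to_numpy(float)
    return pd.DataFrame(
        {
            "snp": df["snp"],
            "theta": df["beta_out"].to_numpy(float) / be,
            "se": df["se_out"].to_numpy(float) / np.abs(be),
        }
    )


def _norm_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _require(iset: MRInstrumentSet, n: int, method: str) -> None:
    if len(iset) < n:
        raise ValidationError(f"{method} requires >= {n} instruments, got {len(iset)}")


def ivw(iset: MRInstrumentSet, random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    Fixed-effect se is sqrt(1 / sum w); with ``random_effects`` (default) the
    se is inflated multiplicatively by max(1, sqrt(Q / (n - 1))) where Q is
    Cochran's heterogeneity statistic.
    """
    _require(iset, 2, "IVW")
    wr = wald_ratios(iset)
    theta = wr["theta"].to_numpy()
    se = wr["se"].to_numpy()
    if np.any(se <= 0):
        raise ValidationError("IVW requires strictly positive ratio standard errors")
    w = 1.0 / se**2
    b = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (theta - b) ** 2))
    scale = max(1.0, np.sqrt(q / (len(theta) - 1))) if random_effects else 1.0
    se_b = se_fixed * scale
    return MRResult(
        method="Inverse variance weighted" if random_effects else "Inverse variance weighted (fixed)",
        b=b,
        se=se_b,
        p=_norm_p(b / se_b),
        n_snp=len(theta),
        wald_ratios=wr,
        q_statistic=q,
    )


def egger(iset: MRInstrumentSet) -> MRResult:
    """Egger regression: weighted least squares of beta_out on beta_exp with an
    intercept, weights 1 / se_out^2, orientation fixed so all beta_exp >= 0.

    The intercept estimates directional pleiotropy.  Standard errors use the
    multiplicative random-effects convention (residual scale floored at 1);
    p-values use the t distribution with n - 2 degrees of freedom.
    """
    _require(iset, 3, "Egger")
    df = iset.table
    flip = np.sign(df["beta_exp"].to_numpy(float))
    flip[flip == 0] = 1.0
    x = df["beta_exp"].to_numpy(float) * flip
    y = df["beta_out"].to_numpy(float) * flip
    so = df["se_out"].to_numpy(float)
    if np.any(so <= 0):
        raise ValidationError("Egger requires strictly positive outcome standard errors")
    if np.allclose(x, x[0]):
        raise ValidationError("Egger requires variation in beta_exp (collinear design)")

    w = 1.0 / so**2
    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    dof = len(x) - 2
    if dof <= 0:
        raise ValidationError("Egger requires > 2 instruments")
    sigma2 = float(np.sum(w * resid**2) / dof)
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    b, intercept = float(coef[1]), float(coef[0])

    def t_p(z: float) -> float:
        return float(min(1.0, 2.0 * stats.t.sf(abs(z), dof)))

    return MRResult(
        method="MR Egger",
        b=b,
        se=se_slope,
        p=t_p(b / se_slope),
        n_snp=len(x),
        wald_ratios=wald_ratios(iset),
        intercept=intercept,
        intercept_se=se_int,
        intercept_p=t_p(intercept / se_int) if se_int > 0 else 1.0,
    )


def _weighted_median_estimate(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median via the step CDF of the ordered ratios.

    The estimate is the ratio whose cumulative (normalized) weight interval
    contains 0.5; when 0.5 falls exactly on a boundary the two straddling
    ratios are averaged.  An instrument holding a majority of the weight is
    therefore returned exactly.
    """
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w)
    k = int(np.searchsorted(cum, 0.5, side="left"))
    if k >= len(th):  # numerical guard
        return float(th[-1])
    if np.isclose(cum[k], 0.5) and k + 1 < len(th):
        return float(0.5 * (th[k] + th[k + 1]))
    return float(th[k])


def _parametric_bootstrap(
    iset: MRInstrumentSet,
    estimator,
    n_boot: int,
    seed: int,
) -> float:
    """SD of the estimator over instrument tables re-drawn from their normal errors."""
    rng = np.random.default_rng(seed)
    df = iset.table
    be = df["beta_exp"].to_numpy(float)
    se_e = df["se_exp"].to_numpy(float)
    bo = df["beta_out"].to_numpy(float)
    se_o = df["se_out"].to_numpy(float)
    est = np.empty(n_boot)
    for i in range(n_boot):
        b_exp = be + rng.normal(0.0, 1.0, be.size) * se_e
        b_out = bo + rng.normal(0.0, 1.0, bo.size) * se_o
        b_exp[b_exp == 0] = np.finfo(float).tiny
        theta = b_out / b_exp
        se_theta = se_o / np.abs(b_exp)
        est[i] = estimator(theta, se_theta)
    return float(est.std(ddof=1))


def weighted_median(iset: MRInstrumentSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median estimator; se from a seeded parametric bootstrap."""
    _require(iset, 3, "weighted median")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; bootstrap se will be noisy", stacklevel=2)
    wr = wald_ratios(iset)
    theta = wr["theta"].to_numpy()
    se = wr["se"].to_numpy()
    if np.any(se <= 0):
        raise ValidationError("weighted median requires strictly positive ratio standard errors")
    b = _weighted_median_estimate(theta, 1.0 / se**2)
    se_b = _parametric_bootstrap(
        iset, lambda th, s: _weighted_median_estimate(th, 1.0 / s**2), n_boot, seed
    )
    se_b = max(se_b, np.finfo(float).tiny)
    return MRResult(
        method="Weighted median", b=b, se=se_b, p=_norm_p(b / se_b), n_snp=len(theta), wald_ratios=wr
    )


def _mode_bandwidth(theta: np.ndarray, factor: float) -> float:
    """Modified Silverman rule: 0.9 * min(sd, normalized MAD) * n^(-1/5)."""
    sd = float(np.std(theta, ddof=1)) if theta.size > 1 else 0.0
    mad = float(stats.median_abs_deviation(theta, scale="normal"))
    spread = min([s for s in (sd, mad) if s > 0], default=0.0)
    return factor * 0.9 * spread * theta.size ** (-1 / 5)


def _mode_estimate(theta: np.ndarray, weights: np.ndarray, h: float) -> float:
    """Argmax of the weighted normal-kernel density of the ratios on a dense grid."""
    if h <= 0 or np.allclose(theta, theta[0]):
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 2048)
    dens = (weights[:, None] * stats.norm.pdf((grid[None, :] - theta[:, None]) / h)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def mode_based(
    iset: MRInstrumentSet,
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Mode-based estimator (simple or inverse-variance weighted).

    The estimate is the argmax of a normal-kernel density of the Wald ratios
    with bandwidth = bandwidth_factor x modified-Silverman; se from a seeded
    parametric bootstrap.  Degenerate spread (all ratios equal) returns the
    common ratio.
    """
    _require(iset, 3, "mode-based estimator")
    if bandwidth_factor <= 0:
        raise ValidationError(f"bandwidth_factor must be > 0, got {bandwidth_factor}")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; bootstrap se will be noisy", stacklevel=2)
    wr = wald_ratios(iset)
    theta = wr["theta"].to_numpy()
    se = wr["se"].to_numpy()
    if weighted and np.any(se <= 0):
        raise ValidationError("weighted mode requires strictly positive ratio standard errors")

    def weights_of(s: np.ndarray) -> np.ndarray:
        return 1.0 / s**2 if weighted else np.ones_like(s)

    def estimate(th: np.ndarray, s: np.ndarray) -> float:
        return _mode_estimate(th, weights_of(s), _mode_bandwidth(th, bandwidth_factor))

    b = estimate(theta, se)
    se_b = max(_parametric_bootstrap(iset, estimate, n_boot, seed), np.finfo(float).tiny)
    return MRResult(
        method="Weighted mode" if weighted else "Simple mode",
        b=b,
        se=se_b,
        p=_norm_p(b / se_b),
        n_snp=len(theta),
        wald_ratios=wr,
    )


def run_all_methods(
    iset: MRInstrumentSet, n_boot: int = 1000, seed: int = 0
) -> list[MRResult]:
    """The five standard estimators in reporting order."""
    return [
        egger(iset),
        weighted_median(iset, n_boot=n_boot, seed=seed),
        ivw(iset),
        mode_based(iset, weighted=False, n_boot=n_boot, seed=seed + 1),
        mode_based(iset, weighted=True, n_boot=n_boot, seed=seed + 2),
    ]


def results_table(
    results: Sequence[MRResult], exposure: str = "trait_A", outcome: str = "trait_B"
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "exposure": exposure,
            "outcome": outcome,
            "method": [r.method for r in results],
            "b": [r.b for r in results],
            "se": [r.se for r in results],
            "p_value": [r.p for r in results],
            "n_snp": [r.n_snp for r in results],
        }
    )


def mr_plot_data(
    iset: MRInstrumentSet, results: Sequence[MRResult]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(forest, scatter) plot tables.

    Forest: one row per instrument (Wald ratio +- 1.96 se) and one combined
    row per method.  Scatter: per-instrument effect pairs plus one fitted
    line per method (slope b; Egger additionally carries its intercept).
    """
    if not results:
        raise ValidationError("results must be non-empty")
    wr = wald_ratios(iset)
    snp_rows = pd.DataFrame(
        {
            "label": wr["snp"],
            "kind": "snp",
            "b": wr["theta"],
            "se": wr["se"],
            "lo": wr["theta"] - 1.96 * wr["se"],
            "hi": wr["theta"] + 1.96 * wr["se"],
        }
    )
    method_rows = pd.DataFrame(
        {
            "label": [r.method for r in results],
            "kind": "method",
            "b": [r.b for r in results],
            "se": [r.se for r in results],
            "lo": [r.b - 1.96 * r.se for r in results],
            "hi": [r.b + 1.96 * r.se for r in results],
        }
    )
    forest = pd.concat([snp_rows, method_rows], ignore_index=True)

    points = iset.table[["snp", "beta_exp", "se_exp", "beta_out", "se_out"]].assign(
        kind="point", method="", slope=np.nan, intercept=np.nan
    )
    lines = pd.DataFrame(
        {
            "kind": "line",
            "snp": "",
            "beta_exp": np.nan,
            "se_exp": np.nan,
            "beta_out": np.nan,
            "se_out": np.nan,
            "method": [r.method for r in results],
            "slope": [r.b for r in results],
            "intercept": [r.intercept if r.intercept is not None else 0.0 for r in results],
        }
    )
    cols = ["kind", "snp", "beta_exp", "se_exp", "beta_out", "se_out", "method", "slope", "intercept"]
    scatter = pd.concat([points[cols], lines[cols]], ignore_index=True)
    return forest, scatter
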