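"""Stratified conditional Q-Q curves, conditional FDR, and conjunctional FDR.

For SNP i with primary-trait p-value ``p_i`` and conditioning-trait p-value
``q_i``, the conditional FDR is the empirical counting estimator

    cfdr_i = min(1, p_i * #{j : q_j <= q_i} / #{j : p_j <= p_i and q_j <= q_i})

with inclusive comparisons (SNP i is in both counts, so the denominator is
always >= 1).  The conjunctional FDR is the element-wise maximum of the two
conditioning directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ValidationError

#: default conditioning strata for the Q-Q curves
DEFAULT_STRATA: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001, 0.0001)


def _check_p(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if p.size == 0:
        raise EmptyInputError(f"{name} is empty")
    if not np.all((p > 0) & (p <= 1)):
        raise ValidationError(f"{name} must lie in (0, 1]")
    return p


def _prefix_counts(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """#{j : pa_j <= pa_i and pb_j <= pb_i} for every i, via a Fenwick tree.

    O(n log n): process SNPs in pa order; inside a tie group on pa, insert the
    whole group before querying so tied values count each other (inclusive
    semantics on both axes).
    """
    n = pa.size
    uniq_b = np.unique(pb)
    rank_b = np.searchsorted(uniq_b, pb) + 1  # 1-based Fenwick ranks
    m = uniq_b.size
    tree = [0] * (m + 1)

    def add(i: int) -> None:
        while i <= m:
            tree[i] += 1
            i += i & (-i)

    def query(i: int) -> int:
        s = 0
        while i > 0:
            s += tree[i]
            i -= i & (-i)
        return s

    order = np.argsort(pa, kind="stable")
    out = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        v = pa[order[i]]
        while j < n and pa[order[j]] == v:
            j += 1
        for k in range(i, j):
            add(int(rank_b[order[k]]))
        for k in range(i, j):
            out[order[k]] = query(int(rank_b[order[k]]))
        i = j
    return out


def compute_cfdr(p_primary, p_conditional) -> np.ndarray:
    """Per-SNP conditional FDR of the primary trait given the conditioning trait.

    Output order matches input order; values are capped at 1.  With a constant
    conditioning vector this reduces exactly to ``p * N / rank`` (the
    unconditional empirical FDR).
    """
    pa = _check_p(p_primary, "p_primary")
    pb = _check_p(p_conditional, "p_conditional")
    if pa.size != pb.size:
        raise ValidationError(f"length mismatch: {pa.size} vs {pb.size}")

    sorted_pb = np.sort(pb)
    numer = np.searchsorted(sorted_pb, pb, side="right")  # #{j : pb_j <= pb_i}
    denom = _prefix_counts(pa, pb)
    return np.minimum(1.0, pa * numer / denom)


def conjunction_ccfdr(cfdr_ab, cfdr_ba) -> np.ndarray:
    """Conjunctional FDR: the larger of the two conditional FDRs, element-wise."""
    a = np.asarray(cfdr_ab, dtype=float)
    b = np.asarray(cfdr_ba, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size and (a.min() < 0 or b.min() < 0 or a.max() > 1 or b.max() > 1):
        raise ValidationError("cFDR inputs must lie in [0, 1]")
    return np.maximum(a, b)


def cfdr_table(paired: pd.DataFrame) -> pd.DataFrame:
    """Full per-SNP cFDR table (both directions) plus the conjunction column."""
    ab = compute_cfdr(paired["p_a"].to_numpy(), paired["p_b"].to_numpy())
    ba = compute_cfdr(paired["p_b"].to_numpy(), paired["p_a"].to_numpy())
    out = paired[["snp", "chr", "pos", "p_a", "p_b"]].copy()
    out["cfdr_a_given_b"] = ab
    out["cfdr_b_given_a"] = ba
    out["ccfdr"] = conjunction_ccfdr(ab, ba)
    return out


@dataclass
class QQCurveSet:
    """Stratified conditional Q-Q curves for both conditioning orientations.

    ``curves`` is long-format: orientation ('A|B' or 'B|A'), stratum, x, y
    with x = -log10 of the within-stratum empirical CDF of the principal
    p-value and y = -log10 of the p-value itself.
    """

    curves: pd.DataFrame
    counts: pd.DataFrame  # orientation, stratum, n
    empty_strata: list[tuple[str, float]] = field(default_factory=list)


def _one_orientation(
    p_principal: np.ndarray, p_cond: np.ndarray, orientation: str, strata: tuple[float, ...]
) -> tuple[list[pd.DataFrame], list[dict], list[tuple[str, float]]]:
    frames, counts, empty = [], [], []
    for t in strata:
        sel = p_cond <= t
        n_t = int(sel.sum())
        counts.append({"orientation": orientation, "stratum": t, "n": n_t})
        if n_t == 0:
            empty.append((orientation, t))
            continue
        ps = np.sort(p_principal[sel])
        x = -np.log10(np.arange(1, n_t + 1) / n_t)
        frames.append(
            pd.DataFrame(
                {"orientation": orientation, "stratum": t, "x": x, "y": -np.log10(ps)}
            )
        )
    return frames, counts, empty


def conditional_qq(paired: pd.DataFrame, strata=DEFAULT_STRATA) -> QQCurveSet:
    """Stratified conditional Q-Q curves in both orientations.

    ``strata`` must be strictly descending thresholds in (0, 1] so that the
    strata are nested; the stratum for threshold t uses exactly the SNPs whose
    conditioning-trait p-value is <= t.
    """
    strata = tuple(float(t) for t in strata)
    if len(strata) == 0:
        raise ValidationError("strata must be non-empty")
    if any(not (0 < t <= 1) for t in strata):
        raise ValidationError("strata thresholds must lie in (0, 1]")
    if any(strata[i] <= strata[i + 1] for i in range(len(strata) - 1)):
        raise ValidationError("strata must be strictly descending (nested)")
    if paired.empty:
        raise EmptyInputError("paired table is empty")

    pa = paired["p_a"].to_numpy(float)
    pb = paired["p_b"].to_numpy(float)
    frames: list[pd.DataFrame] = []
    counts: list[dict] = []
    empty: list[tuple[str, float]] = []
    for principal, cond, name in ((pa, pb, "A|B"), (pb, pa, "B|A")):
        f, c, e = _one_orientation(principal, cond, name, strata)
        frames.extend(f)
        counts.extend(c)
        empty.extend(e)

    curves = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["orientation", "stratum", "x", "y"])
    )
    return QQCurveSet(curves=curves, counts=pd.DataFrame(counts), empty_strata=empty)
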