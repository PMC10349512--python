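import numpy as np
import pandas as pd
import pytest

from crossfdr import MixtureSpec, simulate_paired_stats


@pytest.fixture(scope="session")
def mixture_sim():
    """A modest shared-signal simulation reused across tests."""
    spec = MixtureSpec(0.9, 0.04, 0.04, 0.02, n_snps=20_000, sigma_a=3.0, sigma_b=3.0, seed=42)
    return simulate_paired_stats(spec)


@pytest.fixture
def small_paired():
    rng = np.random.default_rng(7)
    n = 200
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(n)],
            "chr": np.repeat([str(c) for c in range(1, 5)], n // 4),
            "pos": np.tile(np.arange(1, n // 4 + 1) * 1000, 4),
            "p_a": rng.uniform(1e-6, 1, n),
            "p_b": rng.uniform(1e-6, 1, n),
        }
    )


def cfdr_bruteforce(p_primary, p_conditional):
    """Direct double-loop transcription of the conditional-FDR counting formula.

    Independent oracle for compute_cfdr: inclusive comparisons on both axes,
    capped at 1.
    """
    pa = np.asarray(p_primary, float)
    pb = np.asarray(p_conditional, float)
    out = np.empty(pa.size)
    for i in range(pa.size):
        num = int(np.sum(pb <= pb[i]))
        den = int(np.sum((pa <= pa[i]) & (pb <= pb[i])))
        out[i] = min(1.0, pa[i] * num / den)
    return out


def prune_bruteforce(snps, r2, maf, pos_order, threshold):
    """Exhaustive greedy prune of one block: repeatedly drop the smaller-MAF
    member of the worst remaining pair (tie: the later SNP), until no pair
    exceeds the threshold.  Returns the kept snp ids in input order."""
    alive = list(range(len(snps)))
    while True:
        best, best_r2 = None, threshold
        for ii, a in enumerate(alive):
            for b in alive[ii + 1 :]:
                if r2[a, b] > best_r2:
                    best_r2 = r2[a, b]
                    best = (a, b)
        if best is None:
            return [snps[i] for i in alive]
        a, b = best
        if maf[a] < maf[b]:
            drop = a
        elif maf[b] < maf[a]:
            drop = b
        else:
            drop = b if pos_order[b] > pos_order[a] else a
        alive.remove(drop)
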