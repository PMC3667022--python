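"""Two-library exact-test differential expression.

The Audic–Claverie (1997) statistic models tag counts from two sequencing
libraries of depths N1 and N2 as Poisson samples of a shared underlying
rate. Conditional on observing ``x`` reads for a unigene in library 1, the
count ``y`` in library 2 follows

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1))

which is the negative-binomial pmf with ``r = x + 1`` successes and success
probability ``p = N1/(N1+N2)``. Tail probabilities are therefore computed
through the regularized incomplete beta function (via scipy's nbinom),
which is stable for x+y well beyond 1e5. The two-sided p-value doubles the
smaller tail and caps at 1.

Significance combines an FDR gate (Benjamini–Hochberg ``q <= 0.001`` by
default) with a fold-change gate on the RPKM ratio
(``|log2(rpkm2/rpkm1)| >= 1``). The log2 ratio is oriented sample 2 over
sample 1; a zero RPKM on one side yields a signed-infinity ratio and can
still be called significant, while a unigene with zero counts in both
libraries is emitted with p = 1 and ratio 0, never significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from denovotx.expression import rpkm

__all__ = ["ac_term", "ac_pvalue", "bh_fdr", "classify", "dge_table", "DGERecord"]

UP_IN_1 = "up_in_1"
UP_IN_2 = "up_in_2"
NOT_SIG = "not_significant"


@dataclass
class DGERecord:
    """One unigene's two-library comparison."""

    unigene_id: str
    x: int
    y: int
    N1: int
    N2: int
    rpkm1: float
    rpkm2: float
    log2_ratio: float
    p: float
    q: float = np.nan
    direction: str = NOT_SIG


def _check_counts(x, y, N1, N2):
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts x, y must be nonnegative")
    if np.any(x != np.floor(x)) or np.any(y != np.floor(y)):
        raise ValueError("counts x, y must be integers")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals N1, N2 must be positive")
    return x.astype(np.int64), y.astype(np.int64)


def ac_term(x, y, N1, N2):
    """Single-term conditional probability p(y | x) of the exact test.

    Evaluated in log space:
    ``exp(y*log(N2/N1) + lgamma(x+y+1) - lgamma(x+1) - lgamma(y+1)
    - (x+y+1)*log1p(N2/N1))``. Accepts scalars or arrays.
    """
    x, y = _check_counts(x, y, N1, N2)
    r = N2 / N1
    logp = (
        y * np.log(r)
        + special.gammaln(x + y + 1)
        - special.gammaln(x + 1)
        - special.gammaln(y + 1)
        - (x + y + 1) * np.log1p(r)
    )
    out = np.exp(logp)
    return out if out.ndim else float(out)


def ac_pvalue(x, y, N1, N2):
    """Two-sided exact p-value: ``min(1, 2*min(P(Y<=y|x), P(Y>=y|x)))``.

    The conditional law of ``y`` given ``x`` is negative binomial with
    ``r = x+1`` and ``p = N1/(N1+N2)``; both tails include the observed
    ``y``. Vectorized over ``x`` and ``y``.
    """
    x, y = _check_counts(x, y, N1, N2)
    p = N1 / (N1 + N2)
    lower = stats.nbinom.cdf(y, x + 1, p)          # P(Y <= y | x)
    upper = stats.nbinom.sf(y - 1, x + 1, p)       # P(Y >= y | x)
    out = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return out if out.ndim else float(out)


def bh_fdr(pvalues):
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; adjusted values are monotone along the
    sorted p-values and clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([])
    return stats.false_discovery_control(p, method="bh")


def classify(q: float, log2_ratio: float, fdr_cutoff: float = 0.001, lfc_cutoff: float = 1.0) -> str:
    """Direction call combining the FDR gate and the fold-change gate."""
    if q <= fdr_cutoff:
        if log2_ratio >= lfc_cutoff:
            return UP_IN_2
        if log2_ratio <= -lfc_cutoff:
            return UP_IN_1
    return NOT_SIG


def _log2_ratio(rpkm1, rpkm2):
    """log2(rpkm2 / rpkm1) with signed infinity for one-sided zeros, 0 for double zeros."""
    rpkm1 = np.asarray(rpkm1, dtype=float)
    rpkm2 = np.asarray(rpkm2, dtype=float)
    out = np.zeros(np.broadcast(rpkm1, rpkm2).shape)
    both = (rpkm1 > 0) & (rpkm2 > 0)
    out[both] = np.log2(rpkm2[both] / rpkm1[both])
    out[(rpkm1 == 0) & (rpkm2 > 0)] = np.inf
    out[(rpkm1 > 0) & (rpkm2 == 0)] = -np.inf
    return out


def dge_table(
    counts1,
    counts2,
    lengths,
    fdr_cutoff: float = 0.001,
    lfc_cutoff: float = 1.0,
):
    """Full two-library comparison over a shared unigene set.

    Parameters
    ----------
    counts1, counts2
        Mappings (or Series) unigene id -> raw count for library 1 and 2.
        Both must cover exactly the same unigene set.
    lengths
        Mapping unigene id -> length in bp.
    fdr_cutoff, lfc_cutoff
        Significance gates (defaults: q <= 0.001 and |log2 ratio| >= 1).

    Returns
    -------
    (DataFrame, dict)
        Per-unigene table with columns x, y, rpkm1, rpkm2, log2_ratio,
        p, q, direction; and a summary dict with keys ``total``,
        ``up_in_1``, ``up_in_2``, ``N1``, ``N2`` satisfying
        ``total == up_in_1 + up_in_2``.
    """
    c1 = pd.Series(dict(counts1) if not isinstance(counts1, pd.Series) else counts1)
    c2 = pd.Series(dict(counts2) if not isinstance(counts2, pd.Series) else counts2)
    if set(c1.index) != set(c2.index):
        raise ValueError("count tables cover different unigene sets")
    c2 = c2.reindex(c1.index)
    x = c1.to_numpy(dtype=np.int64)
    y = c2.to_numpy(dtype=np.int64)
    N1 = int(x.sum())
    N2 = int(y.sum())
    L = np.array([lengths[u] for u in c1.index], dtype=float)

    r1 = rpkm(x, N1, L)
    r2 = rpkm(y, N2, L)
    lr = _log2_ratio(r1, r2)
    p = np.asarray(ac_pvalue(x, y, N1, N2))
    p[(x == 0) & (y == 0)] = 1.0
    q = bh_fdr(p)
    direction = np.array(
        [classify(qi, li, fdr_cutoff, lfc_cutoff) for qi, li in zip(q, lr)], dtype=object
    )

    df = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "rpkm1": r1,
            "rpkm2": r2,
            "log2_ratio": lr,
            "p": p,
            "q": q,
            "direction": direction,
        },
        index=c1.index,
    )
    df.index.name = "unigene_id"
    up1 = int((direction == UP_IN_1).sum())
    up2 = int((direction == UP_IN_2).sum())
    summary = {"total": up1 + up2, "up_in_1": up1, "up_in_2": up2, "N1": N1, "N2": N2}
    return df, summary
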