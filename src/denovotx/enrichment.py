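"""Hypergeometric term over-representation of a differentially expressed gene set.

For a background of N annotated unigenes of which n are differentially
expressed, and a term annotating M of the background, the probability of
seeing at least the observed m DE members by chance is the upper
hypergeometric tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) * C(N-M, n-i) / C(N, n)

Only over-representation is tested (no depletion). Multiple testing is
corrected either by Bonferroni (GO-style: multiply by the number of terms
actually tested, cap at 1) or by Benjamini–Hochberg FDR (KEGG-style);
either way the significance cutoff on the corrected value is 0.05 by
default. The background is the annotated unigene set, not the whole
transcriptome, and the Bonferroni divisor counts only terms with at least
one background member.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Set

import numpy as np
import pandas as pd
from scipy import stats

from denovotx.dge import bh_fdr

__all__ = ["hypergeom_pvalue", "enrich", "TermMap"]


class TermMap:
    """Term -> member-unigene sets over an annotated background.

    Parameters
    ----------
    term_members
        Mapping term id -> iterable of member unigene ids.
    categories
        Optional mapping term id -> category label.
    background
        The annotated unigene universe; defaults to the union of all
        members. Every member must belong to it.
    """

    def __init__(
        self,
        term_members: Mapping[str, Iterable[str]],
        categories: Mapping[str, str] | None = None,
        background: Iterable[str] | None = None,
    ):
        self.members = {t: frozenset(ms) for t, ms in term_members.items()}
        union = frozenset().union(*self.members.values()) if self.members else frozenset()
        self.background = frozenset(background) if background is not None else union
        stray = union - self.background
        if stray:
            raise ValueError(
                f"term members outside the background: {sorted(stray)[:5]}"
            )
        self.categories = dict(categories or {})

    def __len__(self):
        return len(self.members)


def hypergeom_pvalue(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m).

    N: annotated background size; n: DE genes in the background;
    M: background members of the term; m: DE genes in the term.
    """
    if not (0 <= m and 0 <= n <= N and 0 <= M <= N):
        raise ValueError(f"infeasible hypergeometric quadruple N={N} n={n} M={M} m={m}")
    if m > min(n, M):
        raise ValueError(f"m={m} exceeds min(n={n}, M={M})")
    # sf(m-1) = P(X >= m); exact at m = 0 (probability 1)
    return float(stats.hypergeom.sf(m - 1, N, M, n))


def enrich(
    de_set: Set[str] | Iterable[str],
    term_map: TermMap,
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every term for over-representation in ``de_set``.

    Parameters
    ----------
    de_set
        Differentially expressed unigenes; must be a subset of the
        term map's background.
    term_map
        Annotation universe (see :class:`TermMap`).
    correction
        ``"bonferroni"`` (corrected p = p * number of tested terms,
        capped at 1) or ``"bh"`` (Benjamini–Hochberg q-values).
    alpha
        Significance cutoff applied to the corrected value.

    Returns
    -------
    DataFrame with one row per term with at least one background member,
    columns: category, N, n, M, m, p, corrected_p, significant.
    """
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    de = frozenset(de_set)
    outside = de - term_map.background
    if outside:
        raise ValueError(f"DE genes outside the annotated background: {sorted(outside)[:5]}")

    N = len(term_map.background)
    n = len(de)
    rows = []
    for term, members in sorted(term_map.members.items()):
        M = len(members)
        if M < 1:
            continue
        m = len(members & de)
        rows.append((term, term_map.categories.get(term, ""), N, n, M, m,
                     hypergeom_pvalue(N, n, M, m)))
    df = pd.DataFrame(
        rows, columns=["term_id", "category", "N", "n", "M", "m", "p"]
    ).set_index("term_id")
    if len(df) == 0:
        df["corrected_p"] = []
        df["significant"] = []
        return df
    if correction == "bonferroni":
        df["corrected_p"] = np.minimum(1.0, df["p"].to_numpy() * len(df))
    else:
        df["corrected_p"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["corrected_p"] <= alpha
    return df
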