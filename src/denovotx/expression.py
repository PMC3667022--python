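"""RPKM normalization of raw per-unigene read counts.

RPKM (reads per kilobase of transcript per million mapped reads) rescales
a raw count ``C`` by transcript length ``L`` (bp) and library depth ``N``
(total mapped reads):

    RPKM = 1e9 * C / (N * L)

``N`` is the realized sum of assigned reads in the library, not the raw
sequencer yield. Zero-count rows are retained with RPKM 0; no pseudocount
is added here — zero handling is the caller's concern.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

__all__ = ["rpkm", "rpkm_table"]


def rpkm(C, N, L):
    """Reads per kilobase per million mapped reads.

    Parameters
    ----------
    C : int or array-like
        Reads mapped to the unigene (``>= 0``).
    N : int
        Total mapped reads in the library (``> 0``).
    L : int or array-like
        Unigene length in bp (``> 0``).

    Returns
    -------
    float or ndarray
        ``1e9 * C / (N * L)``.
    """
    C = np.asarray(C, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(C < 0):
        raise ValueError("count C must be nonnegative")
    if N <= 0:
        raise ValueError("library total N must be positive")
    if np.any(L <= 0):
        raise ValueError("unigene length L must be positive")
    out = 1e9 * C / (float(N) * L)
    return out if out.ndim else float(out)


def rpkm_table(counts: Mapping[str, int] | pd.Series, lengths: Mapping[str, int]) -> pd.DataFrame:
    """Per-unigene RPKM table from raw counts and unigene lengths.

    Parameters
    ----------
    counts
        Mapping (or Series) unigene id -> raw count for one library.
        The library total N is the sum of these counts.
    lengths
        Mapping unigene id -> length in bp; must cover every counted id.

    Returns
    -------
    DataFrame indexed by unigene id with columns
    ``length``, ``count``, ``rpkm``. Rows with count 0 are retained.
    """
    counts = pd.Series(dict(counts) if not isinstance(counts, pd.Series) else counts)
    missing = [u for u in counts.index if u not in lengths]
    if missing:
        raise KeyError(f"no length known for unigene(s): {', '.join(map(str, missing[:5]))}")
    N = int(counts.sum())
    if N <= 0:
        raise ValueError("library total N must be positive (all counts are zero)")
    L = np.array([lengths[u] for u in counts.index], dtype=float)
    df = pd.DataFrame(
        {
            "length": L.astype(int),
            "count": counts.to_numpy(dtype=int),
            "rpkm": rpkm(counts.to_numpy(dtype=float), N, L),
        },
        index=counts.index,
    )
    df.index.name = "unigene_id"
    return df
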