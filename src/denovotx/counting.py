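"""Seed-and-verify read assignment with a mismatch budget.

Reads are assigned to unigenes by full-length ungapped alignment allowing
at most two substitutions (default), emulating a strict short-read mapper.
Candidate placements come from a k-mer index of the unigene set (every
k-mer of the read is looked up, so any placement sharing one exact k-mer
with the read is found; for a read of length >= k*(m+1)+m with at most m
mismatches the pigeonhole principle guarantees such a k-mer exists).
Reverse-complement alignment is on by default. A read whose best placement
ties across distinct unigenes is left unassigned — counts are
deterministic and conservative. ``N``, the library total, counts assigned
reads only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping

import pandas as pd
from Bio.Seq import reverse_complement

__all__ = ["KmerIndex", "build_index", "count_reads"]

logger = logging.getLogger(__name__)


@dataclass
class KmerIndex:
    """Exact k-mer -> (unigene id, offset) occurrence map (forward strand)."""

    k: int
    unigenes: dict[str, str]
    entries: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.entries.get(kmer, [])

    @property
    def n_entries(self) -> int:
        return sum(len(v) for v in self.entries.values())


def build_index(unigenes: Mapping[str, str], k: int = 21) -> KmerIndex:
    """Index every length-k substring occurrence of every unigene.

    ``k`` must be at least 11 and no longer than the shortest unigene.
    """
    unigenes = {u: s.upper() for u, s in unigenes.items()}
    if k < 11:
        raise ValueError(f"k must be >= 11, got {k}")
    if unigenes and k > min(len(s) for s in unigenes.values()):
        raise ValueError("k exceeds the shortest unigene length")
    index = KmerIndex(k=k, unigenes=unigenes)
    for uid, seq in unigenes.items():
        for i in range(len(seq) - k + 1):
            index.entries.setdefault(seq[i : i + k], []).append((uid, i))
    return index


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatch count with early exit past ``limit``; N never matches."""
    mm = 0
    for ca, cb in zip(a, b):
        if ca != cb or ca == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def _candidates(read: str, index: KmerIndex):
    k = index.k
    seen = set()
    for i in range(len(read) - k + 1):
        for uid, off in index.lookup(read[i : i + k]):
            start = off - i
            if start >= 0 and start + len(read) <= len(index.unigenes[uid]):
                seen.add((uid, start))
    return seen


def count_reads(
    reads: Iterable[tuple[str, str]] | Iterable[str],
    index: KmerIndex,
    max_mismatch: int = 2,
    reverse_complement_mapping: bool = True,
):
    """Assign reads to unigenes and tabulate raw counts.

    Parameters
    ----------
    reads
        Iterable of (read id, sequence) pairs, or of bare sequences.
    index
        KmerIndex built from the target unigene set.
    max_mismatch
        Substitution budget for a full-length ungapped placement.
    reverse_complement_mapping
        Also try the reverse complement of each read (unstranded
        libraries); disable for stranded data.

    Returns
    -------
    (Series, dict)
        Counts indexed by unigene id (zeros retained; sum == N), and a
        stats dict with n_reads, assigned, tied, unassigned, N.
    """
    counts = {uid: 0 for uid in index.unigenes}
    stats = {"n_reads": 0, "assigned": 0, "tied": 0, "unassigned": 0}
    for item in reads:
        rid, seq = item if isinstance(item, tuple) else (None, item)
        seq = seq.upper()
        stats["n_reads"] += 1
        if len(seq) < index.k:
            logger.warning("read %s shorter than k=%d: unassigned", rid, index.k)
            stats["unassigned"] += 1
            continue
        queries = [seq]
        if reverse_complement_mapping:
            queries.append(reverse_complement(seq))
        best_mm = max_mismatch + 1
        best_uids: set[str] = set()
        for q in queries:
            for uid, start in _candidates(q, index):
                mm = _hamming(q, index.unigenes[uid][start : start + len(q)], max_mismatch)
                if mm < best_mm:
                    best_mm = mm
                    best_uids = {uid}
                elif mm == best_mm:
                    best_uids.add(uid)
        if best_mm > max_mismatch or not best_uids:
            stats["unassigned"] += 1
        elif len(best_uids) > 1:
            stats["tied"] += 1
        else:
            counts[next(iter(best_uids))] += 1
            stats["assigned"] += 1
    series = pd.Series(counts, name="count")
    series.index.name = "unigene_id"
    stats["N"] = int(series.sum())
    logger.info(
        "mapped %d/%d reads (%d ambiguous, %d unassigned), N=%d",
        stats["assigned"], stats["n_reads"], stats["tied"], stats["unassigned"], stats["N"],
    )
    return series, stats
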