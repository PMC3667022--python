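"""Perfect-microsatellite (EST-SSR) mining and marker-locus selection.

A microsatellite locus is a maximal perfect tandem repeat of a primitive
2–6 bp motif repeated at least 5 times (defaults). Motifs are classified
into canonical classes under cyclic rotation only — reverse complements
are NOT merged, so there are 6 dinucleotide and 20 trinucleotide classes
(merging complements would give 4 and 10). Coordinates are 0-based
half-open throughout.

Marker-candidate selection emulates the locus filters used for EST-SSR
primer design: the host unigene must be unique (no long exact window
shared with another unigene, computed on SSR-masked sequence as a proxy
for an all-against-all BLAST on soft-masked input), the flanking regions
must be free of short repeats, and the flanks must leave room for a PCR
product of at least 150 bp spanning the locus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SSRLocus",
    "MarkerCandidate",
    "canonical_motif",
    "is_primitive",
    "enumerate_motif_classes",
    "detect_ssrs",
    "summarize_ssrs",
    "select_marker_loci",
    "summarize_table1",
]

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class SSRLocus:
    """A detected microsatellite: ``sequence[start:end] == unit * n_repeats``."""

    unigene_id: str
    start: int
    end: int
    unit: str
    canonical: str
    n_repeats: int

    @property
    def span_bp(self) -> int:
        return self.end - self.start


@dataclass
class MarkerCandidate:
    """An SSR locus annotated with the primer-design eligibility filters."""

    locus: SSRLocus
    left_flank_bp: int
    right_flank_bp: int
    unique: bool
    flank_repeat_free: bool
    eligible: bool = field(init=False)
    _min_flank_bp: int = 50
    _min_product_bp: int = 150

    def __post_init__(self):
        long_enough = (
            self.left_flank_bp >= self._min_flank_bp
            and self.right_flank_bp >= self._min_flank_bp
            and self.left_flank_bp + self.locus.span_bp + self.right_flank_bp
            >= self._min_product_bp
        )
        self.eligible = self.unique and self.flank_repeat_free and long_enough


def is_primitive(unit: str) -> bool:
    """True if ``unit`` is not a whole-number repetition of a shorter string."""
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


def canonical_motif(unit: str) -> str:
    """Lexicographically minimal rotation of a primitive DNA motif.

    Raises ``ValueError`` for non-ACGT characters, out-of-range lengths,
    or non-primitive units (e.g. ``"ATAT"``, which equals ``"AT"`` twice).
    """
    if not 1 <= len(unit) <= 6:
        raise ValueError(f"motif length must be 1-6, got {len(unit)}")
    if not set(unit) <= _DNA:
        raise ValueError(f"motif {unit!r} contains non-ACGT characters")
    if not is_primitive(unit):
        raise ValueError(f"motif {unit!r} is not primitive")
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def enumerate_motif_classes(k: int) -> int:
    """Number of primitive length-k DNA motifs up to cyclic rotation.

    Enumerates all 4**k strings, discards non-primitive units, and groups
    the rest by minimal rotation. k=2 gives 6 classes, k=3 gives 20.
    """
    if not 1 <= k <= 6:
        raise ValueError(f"k must be in 1..6, got {k}")
    classes = {
        canonical_motif("".join(unit))
        for unit in itertools.product("ACGT", repeat=k)
        if is_primitive("".join(unit))
    }
    return len(classes)


def _match_runs(mask: np.ndarray):
    """Yield (start, stop) of maximal True runs in a boolean array."""
    if mask.size == 0:
        return
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    yield from zip(starts, stops)


def detect_ssrs(
    sequence: str,
    min_repeats: int = 5,
    k_range: tuple[int, int] = (2, 6),
    unigene_id: str = "",
) -> list[SSRLocus]:
    """All maximal perfect tandem repeats meeting the thresholds.

    An ``N`` breaks any repeat. Overlaps are resolved deterministically:
    the longer span wins, ties go to the leftmost locus, then to the
    smaller unit size. The reported unit is the phase starting at the
    locus start, and is always primitive (a region that is periodic with
    a composite unit is reported at its primitive period).
    """
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    candidates: list[SSRLocus] = []
    for k in range(k_range[0], k_range[1] + 1):
        if arr.size < 2 * k:
            continue
        mask = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
        for a, b in _match_runs(mask):
            a, b = int(a), int(b)
            total = (b - a) + k  # periodic segment s[a : b+k]
            n_rep = total // k
            if n_rep < min_repeats:
                continue
            unit = seq[a : a + k]
            if not is_primitive(unit):
                continue  # covered at its primitive period
            candidates.append(
                SSRLocus(unigene_id, a, a + n_rep * k, unit, canonical_motif(unit), n_rep)
            )
    # overlap resolution: longest span, then leftmost, then smallest unit
    candidates.sort(key=lambda c: (-c.span_bp, c.start, len(c.unit)))
    accepted: list[SSRLocus] = []
    for cand in candidates:
        if all(cand.end <= acc.start or cand.start >= acc.end for acc in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda c: c.start)
    return accepted


def summarize_ssrs(loci: Sequence[SSRLocus], total_non_ambiguous_bp: int) -> pd.DataFrame:
    """Table-style distribution summary of detected loci.

    One row per unit length k (2..6) plus a ``total`` row, with the locus
    count, bp occupied, percentage of the non-ambiguous sequence (2
    decimals, half-up) and the number of distinct canonical motif classes
    observed.
    """
    from denovotx.io import percent_of

    if total_non_ambiguous_bp <= 0:
        raise ValueError("total_non_ambiguous_bp must be positive")
    rows = {}
    for k in range(2, 7):
        sub = [l for l in loci if len(l.unit) == k]
        bp = sum(l.span_bp for l in sub)
        rows[k] = {
            "n_loci": len(sub),
            "bp": bp,
            "percent": percent_of(bp, total_non_ambiguous_bp),
            "n_classes": len({l.canonical for l in sub}),
        }
    total_bp = sum(l.span_bp for l in loci)
    rows["total"] = {
        "n_loci": len(loci),
        "bp": total_bp,
        "percent": percent_of(total_bp, total_non_ambiguous_bp),
        "n_classes": len({l.canonical for l in loci}),
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "unit_length"
    return df


def _masked_windows(seq: str, masked: list[tuple[int, int]], w: int):
    """Start positions of length-w windows not overlapping any masked span."""
    for s in range(len(seq) - w + 1):
        if all(s + w <= a or s >= b for a, b in masked):
            yield s


def select_marker_loci(
    loci: Sequence[SSRLocus],
    unigenes: Mapping[str, str],
    min_flank_bp: int = 50,
    min_product_bp: int = 150,
    uniqueness_window_bp: int = 60,
) -> list[MarkerCandidate]:
    """Apply the primer-design eligibility filters to detected loci.

    A locus is eligible iff (a) its unigene shares no exact
    ``uniqueness_window_bp`` window (outside SSR-masked spans) with any
    other unigene, (b) the ``min_flank_bp`` regions on both sides contain
    no repeat of 3+ units, and (c) the flanks are at least
    ``min_flank_bp`` long and allow a PCR product of
    ``min_product_bp`` spanning the locus.
    """
    for locus in loci:
        if locus.unigene_id not in unigenes:
            raise KeyError(f"locus refers to unknown unigene {locus.unigene_id!r}")
    by_uid: dict[str, list[SSRLocus]] = {}
    for locus in loci:
        by_uid.setdefault(locus.unigene_id, []).append(locus)

    # uniqueness proxy: exact shared windows on SSR-masked sequence
    window_owners: dict[str, set[str]] = {}
    for uid, seq in unigenes.items():
        masked = [(l.start, l.end) for l in by_uid.get(uid, [])]
        for s in _masked_windows(seq.upper(), masked, uniqueness_window_bp):
            window_owners.setdefault(seq.upper()[s : s + uniqueness_window_bp], set()).add(uid)
    non_unique = {
        uid for owners in window_owners.values() if len(owners) > 1 for uid in owners
    }

    out = []
    for locus in loci:
        seq = unigenes[locus.unigene_id].upper()
        left = locus.start
        right = len(seq) - locus.end
        lflank = seq[max(0, locus.start - min_flank_bp) : locus.start]
        rflank = seq[locus.end : locus.end + min_flank_bp]
        flank_free = not detect_ssrs(lflank, min_repeats=3) and not detect_ssrs(
            rflank, min_repeats=3
        )
        cand = MarkerCandidate(
            locus=locus,
            left_flank_bp=left,
            right_flank_bp=right,
            unique=locus.unigene_id not in non_unique,
            flank_repeat_free=flank_free,
            _min_flank_bp=min_flank_bp,
            _min_product_bp=min_product_bp,
        )
        out.append(cand)
    return out


def summarize_table1(fixture: pd.DataFrame) -> dict:
    """Status and motif-length breakdown of a validated-marker table.

    Expects columns ``motif`` (repeat unit string) and ``status``
    (YES = polymorphic, NO = monomorphic, NULL = null alleles).
    """
    required = {"motif", "status"}
    if not required <= set(fixture.columns):
        raise ValueError(f"fixture missing columns: {sorted(required - set(fixture.columns))}")
    bad = set(fixture["status"]) - {"YES", "NO", "NULL"}
    if bad:
        raise ValueError(f"malformed status values: {sorted(bad)}")
    status = fixture["status"].value_counts()
    by_len = fixture["motif"].str.len().value_counts().sort_index()
    return {
        "polymorphic": int(status.get("YES", 0)),
        "monomorphic": int(status.get("NO", 0)),
        "null_alleles": int(status.get("NULL", 0)),
        "by_motif_length": {int(k): int(v) for k, v in by_len.items()},
        "n_loci": int(len(fixture)),
    }
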