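"""Independent reference implementations used only by the test suite.

Each oracle takes a deliberately different route from the library code:
exact rational arithmetic for the two-library test, integer-combinatorics
enumeration for the hypergeometric tail, a per-position scan for SSR
detection, translated-peptide scanning for ORFs, a Mobius-function
necklace count for motif classes, and an exhaustive numpy Hamming scan
for read assignment.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from Bio.Seq import Seq, reverse_complement
from sympy import divisors, mobius


# --- two-library exact test (rational arithmetic) -------------------------

def ac_term_exact(x: int, y: int, N1: int, N2: int) -> Fraction:
    r = Fraction(N2, N1)
    num = r**y * comb(x + y, y)
    return num / (1 + r) ** (x + y + 1)


def ac_pvalue_exact(x: int, y: int, N1: int, N2: int) -> Fraction:
    lower = sum(ac_term_exact(x, yy, N1, N2) for yy in range(y + 1))
    upper = 1 - sum(ac_term_exact(x, yy, N1, N2) for yy in range(y))
    return min(Fraction(1), 2 * min(lower, upper))


def ac_pvalue_exact_series(x: int, max_y: int, N1: int, N2: int) -> list[Fraction]:
    """p-values for y = 0..max_y at fixed x, via one cumulative term sweep."""
    r = Fraction(N2, N1)
    term = Fraction(1) / (1 + r) ** (x + 1)  # y = 0
    cum = []
    running = Fraction(0)
    for y in range(max_y + 1):
        running += term
        cum.append(running)
        term = term * r * (x + y + 1) / ((y + 1) * (1 + r))
    out = []
    for y in range(max_y + 1):
        lower = cum[y]
        upper = 1 - (cum[y - 1] if y else Fraction(0))
        out.append(min(Fraction(1), 2 * min(lower, upper)))
    return out


# --- hypergeometric upper tail (integer combinatorics) ---------------------

def hypergeom_sf_exact(N: int, n: int, M: int, m: int) -> Fraction:
    hi = min(n, M)
    total = comb(N, n)
    return Fraction(sum(comb(M, i) * comb(N - M, n - i) for i in range(m, hi + 1)), total)


# --- motif classes (aperiodic necklaces over 4 letters) ---------------------

def necklace_count(k: int) -> int:
    return sum(int(mobius(d)) * 4 ** (k // d) for d in divisors(k)) // k


# --- SSR detection (per-position scan) --------------------------------------

def _primitive(unit: str) -> bool:
    return (unit + unit).find(unit, 1) == len(unit)


def ssr_oracle(seq: str, min_repeats: int = 5, k_range=(2, 6)):
    """Maximal perfect tandem repeats via per-start extension, then the
    same deterministic overlap policy (longest span, leftmost, smallest
    unit). Returns (start, end, unit, n_repeats) tuples."""
    seq = seq.upper()
    L = len(seq)
    dna = set("ACGT")
    cands = []
    for k in range(k_range[0], k_range[1] + 1):
        for start in range(L - k * min_repeats + 1):
            # leftmost phase of its run only
            if start > 0 and seq[start - 1] in dna and seq[start - 1] == seq[start - 1 + k]:
                continue
            unit = seq[start : start + k]
            if set(unit) - dna or not _primitive(unit):
                continue
            n = 1
            while seq[start + n * k : start + (n + 1) * k] == unit:
                n += 1
            if n >= min_repeats:
                cands.append((start, start + n * k, unit, n))
    cands.sort(key=lambda c: (-(c[1] - c[0]), c[0], len(c[2])))
    accepted = []
    for c in cands:
        if all(c[1] <= a[0] or c[0] >= a[1] for a in accepted):
            accepted.append(c)
    return sorted(accepted)


# --- ORF scan (translated-peptide route) -------------------------------------

def longest_orf_bp_oracle(seq: str) -> int:
    """Longest stop-free codon span over six frames, in bp, via Biopython
    translation and splitting the peptide on stop symbols."""
    best = 0
    for s in (seq.upper(), reverse_complement(seq.upper())):
        for off in range(3):
            frame = s[off : off + 3 * ((len(s) - off) // 3)]
            if not frame:
                continue
            peptide = str(Seq(frame).translate())
            longest = max((len(run) for run in peptide.split("*")), default=0)
            best = max(best, 3 * longest)
    return best


# --- read assignment (exhaustive Hamming scan) --------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def brute_assign(read: str, unigenes: dict[str, str], max_mismatch: int = 2):
    """Best full-length ungapped placement over every offset of every
    unigene, both strands; N never matches. Returns the unigene id, or
    None on a cross-unigene tie or no qualifying placement."""
    best = max_mismatch + 1
    best_uids: set[str] = set()
    queries = [read.upper(), reverse_complement(read.upper())]
    for uid, seq in unigenes.items():
        s = _encode(seq.upper())
        if len(seq) < len(read):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(s, len(read))
        for q in queries:
            qa = _encode(q)
            mm = (windows != qa).sum(axis=1) + np.isin(
                windows, _encode("N")
            ).sum(axis=1) * 0  # N in reference already mismatches unless read has N too
            # correct N handling: positions where both are N counted as mismatch
            both_n = ((windows == ord("N")) & (qa == ord("N"))).sum(axis=1)
            mm = mm + both_n
            lo = int(mm.min())
            if lo < best:
                best = lo
                best_uids = {uid}
            elif lo == best:
                best_uids.add(uid)
    if best <= max_mismatch and len(best_uids) == 1:
        return next(iter(best_uids))
    return None
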