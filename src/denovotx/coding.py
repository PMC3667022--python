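"""Six-frame ORF scan and coding-gene triage.

A unigene is triaged as putative protein coding when its best open
reading frame across the six frames is strictly longer than 300 bp of
coding sequence. The default ORF definition is getORF-like: the longest
stop-free codon span per frame (a start codon is not required); a
start-anchored mode restricts spans to begin at the first in-frame ATG.
Codons containing N are treated as neither stop nor start. Reverse-strand
ORFs are reported in forward-strand coordinates with a negative frame.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import reverse_complement

__all__ = ["OrfCall", "find_orfs", "classify_coding"]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfCall:
    """Best open span in one reading frame, forward-strand coordinates."""

    unigene_id: str
    frame: int  # +1,+2,+3 forward; -1,-2,-3 reverse
    start: int
    end: int
    length: int  # == end - start, multiple of 3
    has_start: bool  # span begins with ATG
    has_stop: bool   # span is immediately followed by an in-frame stop


def _best_span_in_frame(seq: str, offset: int, require_start: bool):
    """Longest stop-free codon span at frame ``offset`` of ``seq``.

    Returns (start, end, has_start, has_stop) in local coordinates, or
    None if no span exists.
    """
    n_codons = (len(seq) - offset) // 3
    best = None
    run_start = 0  # codon index where the current open run began
    i = 0
    while i <= n_codons:
        at_stop = i == n_codons or seq[offset + 3 * i : offset + 3 * i + 3] in _STOPS
        if at_stop:
            s, e = run_start, i
            if require_start:
                while s < e and seq[offset + 3 * s : offset + 3 * s + 3] != "ATG":
                    s += 1
            if e > s and (best is None or e - s > best[1] - best[0]):
                best = (s, e, i < n_codons)
            run_start = i + 1
        i += 1
    if best is None:
        return None
    s, e, stopped = best
    start, end = offset + 3 * s, offset + 3 * e
    return start, end, seq[start : start + 3] == "ATG", stopped


def find_orfs(sequence: str, unigene_id: str = "", require_start: bool = False) -> list[OrfCall]:
    """Best open reading frame per frame, over all six frames.

    Frames +1..+3 scan the forward strand at offsets 0..2; frames -1..-3
    scan the reverse complement, with the resulting span mapped back to
    forward-strand coordinates.
    """
    seq = sequence.upper()
    L = len(seq)
    rc = reverse_complement(seq)
    calls = []
    for frame_idx in range(3):
        hit = _best_span_in_frame(seq, frame_idx, require_start)
        if hit:
            s, e, has_start, has_stop = hit
            calls.append(OrfCall(unigene_id, frame_idx + 1, s, e, e - s, has_start, has_stop))
        hit = _best_span_in_frame(rc, frame_idx, require_start)
        if hit:
            s, e, has_start, has_stop = hit
            calls.append(
                OrfCall(unigene_id, -(frame_idx + 1), L - e, L - s, e - s, has_start, has_stop)
            )
    return calls


def classify_coding(
    sequence: str,
    min_cds_bp: int = 300,
    unigene_id: str = "",
    require_start: bool = False,
):
    """Coding triage: (coding flag, best OrfCall or None, direction).

    Coding iff the best ORF is strictly longer than ``min_cds_bp``. Ties
    are broken toward the forward strand, then the lower frame number.
    Direction is "+" or "-" per the best ORF's strand.
    """
    calls = find_orfs(sequence, unigene_id, require_start)
    if not calls:
        return False, None, "+"
    best = max(calls, key=lambda c: (c.length, c.frame > 0, -abs(c.frame)))
    return best.length > min_cds_bp, best, "+" if best.frame > 0 else "-"
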