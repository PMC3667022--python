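"""Synthetic transcriptome generator with planted ground truth.

Emulates, at desk scale, the artifacts of a two-library de novo
transcriptome study: a unigene set with a log-normal length distribution
bounded to 100–3,000 bp, optional planted microsatellites and open
reading frames, two-library read counts with a planted fraction of
differentially expressed genes at a fixed symmetric log2 fold change, an
annotation map with one planted enriched term, and error-bearing
single-end reads with known origins.

Counts are drawn Poisson when ``dispersion`` is 0 and negative-binomial
(variance mu + dispersion*mu^2) otherwise; there is no replicate
structure, matching the one-library-per-condition design the exact test
assumes. Every generator is deterministic given the spec and its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from denovotx.enrichment import TermMap

__all__ = [
    "SyntheticSpec",
    "TruthTable",
    "Read",
    "generate_unigenes",
    "generate_counts",
    "generate_reads",
    "generate_annotation",
]

logger = logging.getLogger(__name__)

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults emulate a desk-scale two-tissue comparison: ~570 bp mean
    unigene length (log-normal, bounded 100–3,000 bp), 45% GC, two
    libraries of 500,000 mapped reads, 10% of unigenes differentially
    expressed at |log2 fold change| = 3 with Poisson counts, and one
    annotation term of 50 members enriched for DE genes at odds 8.
    """

    n_unigenes: int = 2000
    length_log_mean: float = 6.2   # exp(6.2) ~ 493 bp median
    length_log_sd: float = 0.55
    length_bounds: tuple[int, int] = (100, 3000)
    gc_fraction: float = 0.45
    planted_ssrs: list[tuple[int, str, int, int]] = field(default_factory=list)
    planted_orf_fraction: float = 0.0
    library_sizes: tuple[int, int] = (500_000, 500_000)
    de_fraction: float = 0.1
    de_log2fc: float = 3.0
    dispersion: float = 0.0
    enriched_term: tuple[str, int, float] = ("TERM_0001", 50, 8.0)
    n_terms: int = 50
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        if self.n_unigenes < 0:
            raise ValueError("n_unigenes must be >= 0")
        for name in ("gc_fraction", "planted_orf_fraction", "de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.de_log2fc <= 0:
            raise ValueError("de_log2fc must be > 0")
        if any(n <= 0 for n in self.library_sizes):
            raise ValueError("library sizes must be positive")
        lo, hi = self.length_bounds
        if not 1 <= lo <= hi:
            raise ValueError("invalid length bounds")
        for idx, unit, n_rep, offset in self.planted_ssrs:
            if not (0 <= idx < self.n_unigenes):
                raise ValueError(f"planted SSR refers to unigene {idx} out of range")
            if offset < 0 or n_rep < 1 or not unit:
                raise ValueError("invalid planted SSR")
            if offset + len(unit) * n_rep > hi:
                raise ValueError(
                    f"planted SSR at offset {offset} would exceed the length bound {hi}"
                )
        return self


@dataclass
class TruthTable:
    """Ground truth for one generated unigene set."""

    lengths: dict[str, int]
    de_status: dict[str, int]          # 0 null, +1 up in library 2, -1 up in library 1
    expression: pd.DataFrame           # columns expr1, expr2; relative units
    ssr_loci: list[tuple[str, int, int, str, int]]  # (uid, start, end, unit, n_repeats)
    orfs: dict[str, tuple[int, int, int]]           # uid -> (start, end, frame)
    enriched_terms: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class Read:
    """One simulated read with its true origin."""

    read_id: str
    sequence: str
    origin: str
    start: int
    strand: str = "+"


def _unigene_ids(n: int) -> list[str]:
    width = max(1, len(str(max(n - 1, 0))))
    return [f"UN{i:0{width}d}" for i in range(n)]


def generate_unigenes(spec: SyntheticSpec):
    """Draw the unigene set and its ground truth.

    Sequences are i.i.d. bases at the requested GC content; planted SSRs
    and ORFs are written in place at their offsets (lengths are never
    changed by planting). A planting that would run past its unigene's
    end rejects the spec. Returns ``(dict uid -> sequence, TruthTable)``.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_unigenes
    ids = _unigene_ids(n)
    lo, hi = spec.length_bounds
    lengths = np.clip(
        np.rint(rng.lognormal(spec.length_log_mean, spec.length_log_sd, size=n)),
        lo, hi,
    ).astype(int)

    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    seqs = {}
    for uid, L in zip(ids, lengths):
        seqs[uid] = rng.choice(bases, size=L, p=probs)

    ssr_truth = []
    ssr_spans: dict[str, list[tuple[int, int]]] = {}
    for idx, unit, n_rep, offset in spec.planted_ssrs:
        uid = ids[idx]
        span = len(unit) * n_rep
        if offset + span > lengths[idx]:
            raise ValueError(
                f"planted SSR ({unit} x{n_rep} at {offset}) exceeds unigene {uid} "
                f"of length {lengths[idx]}"
            )
        seqs[uid][offset : offset + span] = list(unit * n_rep)
        ssr_truth.append((uid, offset, offset + span, unit, n_rep))
        ssr_spans.setdefault(uid, []).append((offset, offset + span))

    orfs: dict[str, tuple[int, int, int]] = {}
    if spec.planted_orf_fraction > 0:
        carry = rng.random(n) < spec.planted_orf_fraction
        for i, uid in enumerate(ids):
            if not carry[i] or lengths[i] < 306:
                continue
            max_codons = min(lengths[i] // 3, 400)
            n_codons = int(rng.integers(102, max_codons + 1))  # 3*102 = 306 bp > 300
            span = 3 * n_codons
            placed = False
            for _ in range(20):
                start = int(rng.integers(0, lengths[i] - span + 1))
                if all(
                    start + span <= a or start >= b
                    for a, b in ssr_spans.get(uid, [])
                ):
                    placed = True
                    break
            if not placed:
                continue
            body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
            stop = rng.choice(["TAA", "TAG", "TGA"])
            orf_seq = "ATG" + "".join(body) + stop
            seqs[uid][start : start + span] = list(orf_seq)
            orfs[uid] = (start, start + span, start % 3 + 1)

    # replanting order means an ORF never overwrites a planted SSR, but a
    # planted SSR offset inside an ORF region is the caller's to avoid
    de = np.zeros(n, dtype=int)
    is_de = rng.random(n) < spec.de_fraction
    de[is_de] = rng.choice([-1, 1], size=int(is_de.sum()))
    base_expr = rng.lognormal(0.0, 1.0, size=n)
    fc = np.power(2.0, de * spec.de_log2fc)
    expression = pd.DataFrame(
        {"expr1": base_expr, "expr2": base_expr * fc}, index=ids
    )
    expression.index.name = "unigene_id"

    truth = TruthTable(
        lengths=dict(zip(ids, (int(x) for x in lengths))),
        de_status=dict(zip(ids, (int(x) for x in de))),
        expression=expression,
        ssr_loci=ssr_truth,
        orfs=orfs,
    )
    return {uid: "".join(s) for uid, s in seqs.items()}, truth


def generate_counts(
    spec: SyntheticSpec, unigenes, truth: TruthTable, seed: int | None = None
) -> pd.DataFrame:
    """Two-library raw count table from the planted expression truth.

    The expected count of unigene i in library j is proportional to
    length_i * expression_ij, scaled so the expectations sum to the
    spec's library size target; realized column sums are the library
    totals N1, N2. ``seed`` overrides the spec seed for the count draw
    only (replicate counts over one fixed truth). Returns a DataFrame
    with columns ``lib1``, ``lib2``.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed if seed is None else seed, 1])
    ids = list(unigenes)
    L = np.array([truth.lengths[u] for u in ids], dtype=float)
    out = {}
    for j, lib in enumerate(("lib1", "lib2")):
        expr = truth.expression[f"expr{j + 1}"].reindex(ids).to_numpy()
        weight = L * expr
        mu = spec.library_sizes[j] * weight / weight.sum()
        if spec.dispersion == 0:
            out[lib] = rng.poisson(mu)
        else:
            r = 1.0 / spec.dispersion
            out[lib] = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(out, index=pd.Index(ids, name="unigene_id"), dtype=np.int64)
    return df


def generate_reads(
    unigenes,
    depth: float | dict[str, float] = 10.0,
    read_length: int = 75,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[Read]:
    """Single-end reads drawn uniformly from each unigene.

    ``depth`` is the Poisson mean number of reads per unigene (scalar or
    per-unigene mapping). Each read is a forward- or reverse-strand
    substring of its origin with i.i.d. substitution errors at
    ``error_rate``; the true origin, position and strand are retained.
    Unigenes shorter than ``read_length`` are skipped with a warning.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    from Bio.Seq import reverse_complement

    rng = np.random.default_rng(seed)
    bases = "ACGT"
    reads: list[Read] = []
    for uid, seq in unigenes.items():
        if len(seq) < read_length:
            logger.warning("unigene %s shorter than read length %d: skipped", uid, read_length)
            continue
        mean = depth[uid] if isinstance(depth, dict) else depth
        n_reads = rng.poisson(mean)
        for r in range(n_reads):
            start = int(rng.integers(0, len(seq) - read_length + 1))
            frag = seq[start : start + read_length]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = reverse_complement(frag)
            if error_rate > 0:
                frag = list(frag)
                errs = np.flatnonzero(rng.random(read_length) < error_rate)
                for pos in errs:
                    frag[pos] = bases[(bases.index(frag[pos]) + int(rng.integers(1, 4))) % 4]
                frag = "".join(frag)
            reads.append(Read(f"{uid}_r{r}", frag, uid, start, strand))
    return reads


def generate_annotation(spec: SyntheticSpec, truth: TruthTable) -> TermMap:
    """Annotation map with one planted enriched term.

    Every unigene belongs to the annotated background. The planted term
    samples its members without replacement with the planted odds as the
    relative weight of truly DE unigenes; the remaining terms draw
    uniformly at random (sizes uniform in 10..60), giving a flat null.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 2])
    ids = np.array(list(truth.lengths))
    term_id, M, odds = spec.enriched_term
    if M > len(ids):
        raise ValueError("planted term larger than the unigene set")
    de = np.array([truth.de_status[u] != 0 for u in ids], dtype=float)
    weights = np.where(de, odds, 1.0)
    members = {term_id: set(rng.choice(ids, size=M, replace=False, p=weights / weights.sum()))}
    width = max(4, len(str(spec.n_terms)))
    for t in range(spec.n_terms - 1):
        tid = f"TERM_null_{t:0{width}d}"
        size = int(rng.integers(10, min(61, len(ids) + 1)))
        members[tid] = set(rng.choice(ids, size=size, replace=False))
    truth.enriched_terms = {term_id}
    return TermMap(members, background=ids)
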