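# Methods

## Setting and scope

`denovotx` targets the two-library, no-replicate design typical of early
de novo transcriptome studies: one sequencing library per tissue, reads
mapped back to the assembled unigene set, expression compared pairwise
between tissues, and the assembly mined for functional annotation
signals (enriched terms), microsatellite markers and coding potential.
Assembly itself, homology annotation against protein databases,
interspersed-repeat masking and primer design are out of scope; the
package starts from unigene sequences (or count tables) and ends at
statistics, marker candidates and coding calls.

## Read counting

Reads are placed by full-length ungapped alignment with a substitution
budget (default 2 mismatches; `N` matches nothing). Candidate placements
come from an exact k-mer index (default k = 21) queried at every k-mer
of the read and, by default, of its reverse complement — libraries are
treated as unstranded. For reads of length ≥ k·(m+1)+m (e.g. 75 bp at
k = 21, m = 2) the pigeonhole principle guarantees every qualifying
placement shares an exact k-mer with the read, so seeding loses nothing
relative to an exhaustive scan; the test suite asserts exact agreement
with an all-offsets Hamming oracle. A read whose best score ties across
distinct unigenes is discarded (deterministic, conservative counts);
ties among positions within one unigene count once. The library total
`N` counts assigned reads only. Indels, spliced alignment and
base-quality scores are not modeled. Paired-end insert-size filtering is
not implemented; the generator emits single-end reads.

## Expression and differential expression

RPKM is computed as `1e9·C/(N·L)` in double precision, zeros retained,
no pseudocounts. The two-library test is the Audic–Claverie conditional
statistic: given `x` reads in library 1, `y` in library 2 follows a
negative binomial with `r = x+1` and `p = N1/(N1+N2)`, and both tails
are evaluated through scipy's regularized-incomplete-beta negative
binomial, which is stable for `x+y` well beyond 1e5. The two-sided
p-value doubles the smaller tail (capped at 1): sidedness is a
convention choice, and doubling is the conservative standard for this
statistic. Note that the statistic conditions on `x`, so
`p(x,y,N1,N2)` and `p(y,x,N2,N1)` are *not* identical — the exact
identity that does hold is `N2·p(y|x;N1,N2) = N1·p(x|y;N2,N1)` for the
single term. The log2 ratio is oriented sample 2 over sample 1; one-
sided zeros give signed infinity (and can be significant), double zeros
give p = 1, ratio 0, never significant. Multiple testing uses
Benjamini–Hochberg step-up; a unigene is called differentially
expressed when `q ≤ 0.001` **and** `|log2(RPKM2/RPKM1)| ≥ 1` (both
inclusive). Replicate-aware models (NB-GLMs) are deliberately absent:
with one library per condition there is nothing to estimate a
within-condition dispersion from.

## Enrichment

Over-representation only: `P(X ≥ m)` for the hypergeometric law with
background `N` = annotated unigenes (not the full transcriptome), `n` =
DE genes inside that background, `M` = term members, `m` = DE term
members. Bonferroni multiplies by the number of terms actually tested
(at least one background member); BH-FDR is the alternative. The
default significance cutoff on the corrected value is 0.05. No
term-graph propagation and no term–term dependence correction.

## SSR mining

A locus is a maximal perfect tandem repeat of a primitive 2–6 bp unit
with ≥ 5 repetitions (both configurable); `N` breaks any repeat;
mononucleotide runs are excluded. Detection compares the sequence with
itself at lag k (vectorized), so a maximal run of matches of length `r`
is a periodic segment of `r+k` bp containing `⌊(r+k)/k⌋` repeats; the
reported unit is the phase at the locus start, and a segment whose unit
is non-primitive is reported at its primitive period instead.
Overlaps are resolved deterministically: longest span, then leftmost,
then smallest unit. Motif classes are equivalence classes under cyclic
rotation **only** — reverse complements are kept distinct, which yields
6 dinucleotide and 20 trinucleotide classes (60/204/670 for k = 4/5/6,
the aperiodic-necklace counts); merging complements would halve these.

Marker selection mirrors the filters applied before primer design:
(a) *uniqueness* — the host unigene shares no exact 60 bp window
(computed outside SSR-masked spans) with any other unigene, an
alignment-free proxy for an all-against-all BLAST of soft-masked
sequences at a stringent E-value; (b) *clean flanks* — no repeat of ≥ 3
units within the flanking window (default 50 bp) on either side;
(c) *room to amplify* — both flanks at least the flank minimum and
locus-plus-flanks at least the minimum product size (150 bp).
Window length, flank window and product size are configurable; the
window proxy is stricter than BLAST for diverged paralogs and more
lenient for short high-identity matches, which is acceptable for a
conservative marker shortlist.

## Coding triage

Six-frame scan; per frame the longest stop-free codon span
(getORF-like), with an optional start-anchored mode that trims each
span to its first in-frame ATG. Codons containing `N` count as neither
stop nor start. Reported spans exclude the terminating stop codon;
`has_stop` records whether one follows. A unigene is coding when its
best span is strictly longer than 300 bp; ties prefer the forward
strand, then the lower frame number. This is a length rule, not a
trained coding model — no hexamer or codon-usage scoring — so it
inherits the false-positive rate of long stop-free spans in long
untranslated sequence (negligible below ~1.5 kb, noticeable above).

## Synthetic data

The generator emulates a desk-scale version of such a study, and its
defaults are the study conditions used throughout the tests: unigene
lengths log-normal (log-mean 6.2, log-sd 0.55, ≈ 570 bp mean) truncated
to 100–3,000 bp; GC 45%, typical of crustacean transcriptomes; two
libraries of 500,000 mapped reads; 10% of unigenes differentially
expressed at |log2 fold change| = 3 with random direction; Poisson
counts (`dispersion = 0`; negative binomial with variance
`mu + dispersion·mu²` otherwise); expected counts proportional to
length × expression, normalized per library to the size target; one
annotation term of 50 members drawn with sampling odds 8 for truly DE
unigenes among 50 terms total. Planted SSRs and ORFs are written over
the background at their stated offsets (lengths never change; a
planting that would overrun the unigene rejects the spec). Planted ORFs
are ATG + ≥ 100 random non-stop codons + stop, so at least 306 bp.
Reads are single-end 75-mers, uniform start positions, random strand,
i.i.d. substitution errors that always change the base.

Everything is deterministic given the spec: unigenes, counts,
annotation and reads each derive an independent stream from the spec
seed, and `generate_counts` accepts a replicate seed so count noise can
be redrawn over one fixed truth. What the generator does **not**
emulate — and what green tests therefore do not certify about real
data: assembly artifacts (chimeras, fragmented and redundant isoforms),
coverage and GC bias, positional error profiles, strandedness, and
biological dispersion beyond the NB option.

## Validation choices

Oracles are implemented independently of the code paths they check:
exact rational arithmetic for the two-library test (agreement to 1e-10
relative for all x, y ≤ 50 at three library ratios), integer
combinatorics for every feasible hypergeometric quadruple with N ≤ 60,
Möbius-function necklace counts for motif classes, a per-position
extension scan for SSRs (500 random 1 kb sequences per seeded run), a
translated-peptide scan for ORFs, and an exhaustive Hamming scan for
read assignment (25 unigenes × 1,000 reads). Null FDR control is
checked over 50 replicate count draws of a 2,000-unigene null study
(≤ 0.5% calls at q ≤ 0.001 in ≥ 95% of replicates) and power over 20
replicate studies (≥ 80% recall of planted DE genes with mean expected
count ≥ 20; planted-term recovery under both corrections in ≥ 90%).
These problem sizes keep the suite fast while leaving Monte-Carlo
margins far from the pass thresholds.

## Known limitations

- The exact test is valid for the Poisson sampling model it assumes; on
  overdispersed data (dispersion > 0) its p-values are anti-conservative,
  which is a property of the method, not a defect of the implementation.
- The uniqueness proxy for marker selection is exact-match based; see
  above for how it diverges from a BLAST criterion.
- Percent bookkeeping uses half-up rounding to 2 decimals, pinned by
  the published summary figures it reproduces.
- Coordinates are 0-based half-open everywhere in code and TSV output;
  only free-text reports use 1-based display.
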