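# Methods

## Problem setting

A reporter construct carrying a distal-limb enhancer is knocked into a
chosen site of a large regulatory locus by homology-directed repair. Two
computational questions follow. First, *what actually integrated*: one copy
in the intended orientation, or a tandem array of several copies in mixed
orientations — answerable from Cas9-enriched nanopore long reads that span
the insertion. Second, once the construct duplicates an element that
already exists elsewhere in the locus, *which copy did a short read come
from* — a prerequisite for accessibility and factor-binding profiling of
either copy separately. `tgverify` treats both questions with one
primitive: exact matching against k-mers that are unique in a reference,
so that every accepted match is unambiguous by construction.

## Mutant genome construction and lift-over

An allele is an ordered list of non-overlapping edits (deletion,
insertion, replacement, inversion) with targets on *original* wild-type
coordinates; edits are never serially shifted, which keeps a spec
order-independent and matches how breakpoints are recorded. All intervals
are 0-based half-open (BED convention); a span printed as
`chr2:74075311-74075843` therefore measures 532 bp, reproducing the
printed length of the relocated enhancer.

Applying a spec walks the wild type left to right, emitting identity
blocks between edits, payloads at insertions/replacements and
reverse-complemented blocks at inversions. The emitted blocks form a
coordinate map: positions in untouched blocks lift bijectively in both
directions (inverted blocks reverse), positions in deleted segments lift
to `None` with reason `deleted`, and mutant positions inside inserted
payload lift back to `None` with reason `inserted-only`. The map exports
as a UCSC chain file, one chain per run of same-orientation blocks.

Knock-in semantics: the inter-arm host segment `[left_HA.end,
right_HA.start)` — 26 bp in the geometry mirrored by the fixtures — is
**replaced** by the construct payload by default, as expected when
homology-directed repair resects across the cut site. Whether those guide
site bases actually persist in a given allele is generally unknowable
without sequencing through the junction, so the alternative (retain the
host segment, insert the payload at the left arm's end) is available as
`mode="retain"`. Arm-bearing constructs are stripped after verifying the
arm sequences against the host; N bases never satisfy verification.

## Unique k-mer anchoring

The index stores every k-mer of the reference panel that occurs exactly
once across the whole panel counting both strands (defaults k = 20).
k-mers containing N and k-mers equal to their own reverse complement
(strand undecidable) are excluded. Reads are sampled every `step` bases
(default 5) starting at offset 0 — the stride phase is not principled, so
the deterministic choice of 0 is used — and a window anchors iff it, or
its reverse complement, is in the index.

Uniqueness scope is a genuine design fork. Global scoping (the default for
the index builder) makes anchors unambiguous across wild type, expected
mutant and vector simultaneously — but because wild type and mutant share
their entire flanks, a panel containing both cancels every flank k-mer,
leaving nothing to anchor reads with. The verification pipeline therefore
scores each panel entry independently (`scope="per-entry"`) and infers
structure against the expected single-insert mutant. Within that single
reference the only non-unique sequence is the duplicated enhancer element
itself, whose interior is deliberately unanchorable — exactly the property
the disambiguation stage relies on.

## Structure inference

Chaining mechanizes what one does by eye on a dot plot. Anchors are
chained greedily left to right; an anchor extends the open segment iff it
shares reference and strand, the read gap is ≤ `max_gap` (500 bp) and its
diagonal (ref − read for +, ref + read for −) drifts from the *previous
anchor's* by ≤ `max_diag_offset` (50 bp). Drift is measured locally rather
than from the segment start because nanopore indels (≈7%/base combined)
make a segment's diagonal walk slowly; a global bound would split long
segments spuriously. Segments with < `min_anchors` (3) anchors are
dropped. Junctions between read-consecutive segments are typed by the
reference jump: strand change → inversion; backward jump beyond
`junction_tol` (100 bp) → copy junction (a tandem-array restart);
otherwise collinear gap, deletion or insertion by comparing reference and
read gaps.

For copy counting, segments on the target reference are first re-merged
along diagonals with a gap-scaled tolerance (bridging the anchorless
element interior, ~530 bp, and rare error deserts) and then split at the
construct boundaries. Sub-k slivers are discarded — a segment's span can
overshoot a boundary by up to k−1 bp because its terminal anchor's k-mer
crosses it, and such slivers must not masquerade as flank evidence. A
piece inside the construct counts as a copy when its reference span
overlaps the construct by ≥ 50%; pieces shorter than 30% of the construct
are flagged truncated and not counted, which tolerates copies clipped by
read ends without overcounting.

The allele-level configuration is a *minimum*: the per-read copy count
gives a floor, refined upward by junction stitching. For n from the floor
to `n_max` = 8 (2^n patterns; brute force is fine at this scale), every
orientation pattern is tested against every read's evidence: the read's
ordered copy orientations — flipped into genome order when a flanking
segment orients the read, otherwise both readings are admissible — must
occur contiguously in the pattern, at position 0 when the read carries the
left flank and at the end when it carries the right flank. The smallest n
with a surviving pattern is reported; ties at that n are broken
lexicographically (+ < −) and all co-optimal patterns are reported. If no
pattern up to `n_max` explains all reads the allele is flagged
inconsistent. This "minimum copies consistent with all reads" framing is
what makes the answer honest when no single read spans the whole array.

Read classification: `ambiguous` when segments cover < 50% of the read
(`min_classify_fraction`); otherwise `WT` (no construct evidence,
collinear), `expected_knockin` (exactly one full copy, no structural
junctions), `multi_copy` (≥2 copies or inversion/copy-junction evidence),
or `unclassified` (e.g. a lone truncated construct piece).

## Duplicated-element disambiguation

A read (or pair) is assigned `unique` when it contains at least
`min_unique_kmers` (default 1) k-mers unique in the whole mutant genome
and all of them lie within one placement (span ≤ read length + 50 bp
slack); the locus is the nearest element copy. A read whose k-mers occur
in the genome but never uniquely is `ambiguous`; a read sharing no k-mer
with the genome is `unmapped`. This emulates the intent of an aligner's
MAPQ ≥ 30 filter — keep only uniquely placeable reads — without running an
aligner; the equivalence is asserted on synthetic data only, since real
MAPQ models are aligner-specific. Sequencing errors can only destroy
unique k-mers, so an assignment degrades to `ambiguous` but can never
flip to the wrong copy (the wrong copy, being byte-identical, offers no
unique k-mers at all): the zero-false-assignment property is structural.
The pair rule defaults to `either-mate`, mirroring how a paired aligner
rescues an element-internal mate through its uniquely mapped mate;
`both-mates` is available for stricter work. Coverage tracks sum the
placements of uniquely assigned reads; fragment filtering drops pairs
with an end contained in either element copy.

## Synthetic data: what it emulates and what it does not

The toy locus is 60 kb of i.i.d. sequence at GC 0.42 with the 532 bp
element planted at 15 kb and the insertion site at 40 kb — a ~25 kb
separation standing in for the real 1.2 Mb, far enough that no read or
fragment straddles both sites. The construct is the element plus 600 bp
promoter and 3,058 bp reporter (4,190 bp total, the real construct size);
homology arms are 1,035/1,048 bp around a 26 bp guide segment, mirroring
the published arm geometry. The four-copy fixture's orientation pattern
`++-+` is a stand-in chosen once: the published conclusion is the copy
count ("minimum of four, multiple orientations"), not a printed pattern,
so recovery is always tested against the fixture's own truth.

The long-read simulator draws normal lengths (default 8 kb ± 1 kb),
uniform or cut-site-anchored starts, equiprobable strands and base-wise
errors at 5%/3%/4% substitution/insertion/deletion — a nanopore-like error
budget. It does not model homopolymer-specific errors, quality-score
structure or chimeric reads; the short-read simulator produces error-free
inward-facing pairs (insert 200 ± 50 bp, clipped to twice the 50 bp read
length). Real data additionally contain repeats beyond the single
duplicated element, mappability structure and coverage biases; passing
tests on this generator therefore demonstrate the logic of the method —
anchoring, stitching, the impossibility of wrong-copy assignment — not its
error tolerance on arbitrary genomes.

Problem sizes were chosen for desk-scale runs: 200 reads suffice for ~20×
coverage of the toy locus, and the acceptance sweep uses 30 array-spanning
reads per replicate across array sizes 1–5.

## Numerical and degenerate-input choices

- Deterministic everywhere: one `numpy` Generator per operation, seeded
  explicitly; identical inputs give byte-identical outputs.
- Empty inputs are data, not errors: reads shorter than k anchor nowhere;
  an empty anchor list chains to an empty architecture; an empty FASTQ
  produces empty outputs and exit 0. An all-short panel yields an empty
  index plus a warning.
- Zero-length intervals are tolerated structurally (insertion points) but
  refused by `interval_length` and region parsing.
- Tie-breaks are total: co-optimal orientation patterns sort + before −;
  anchor rows sort by read offset.

## Known limitations

- Copy number is a lower bound by design; arrays longer than `n_max` = 8
  or with internal rearrangements beyond the modeled junction types are
  reported as inconsistent rather than guessed.
- No base-level consensus or assembly of the array is attempted.
- Uniqueness-based disambiguation says nothing when *neither* end of a
  fragment leaves the duplicated element; such data are unrecoverable
  without longer fragments.
- The coordinate map handles one host sequence per allele; multi-
  chromosome rearrangements are out of scope.
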