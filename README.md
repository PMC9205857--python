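# tgverify

Verification of targeted transgene insertions from sequencing reads.

When an enhancer–reporter construct is knocked into a chosen genomic site by
homology-directed repair, the resulting allele is not always what was
designed: the construct may integrate once and correctly, or as a tandem
array of several copies in mixed orientations. When the construct also
duplicates an element that already exists elsewhere in the genome (for
example, relocating an enhancer within its own locus), short sequencing
reads from the two identical copies become indistinguishable. `tgverify`
implements the computational side of verifying such alleles:

- **Mutant genome construction** (`tgverify.genome`) — build the expected
  mutant sequence from a wild-type sequence plus breakpoint-exact edits
  (deletion, insertion, replacement, inversion), with a block-wise
  coordinate map for lifting positions in both directions (chain-file
  export included). A knock-in between two homology arms reduces to a
  single replacement of the inter-arm segment.
- **Unique k-mer dot plots** (`tgverify.kmers`) — index every k-mer
  (default k = 20) that occurs exactly once in a reference panel, counting
  both strands, and test read windows sampled every 5 bp against it. Only
  windows exactly identical to a panel-unique k-mer anchor; the resulting
  (read offset, reference offset) pairs are dot plots in which diagonals
  are collinear blocks and anti-diagonals are inversions.
- **Structure inference** (`tgverify.structure`) — chain anchors into
  orientation-aware segments, type the junctions between them (collinear
  gap, deletion, insertion, inversion, copy junction), classify each read
  against the expected wild-type / single-insert architectures, and
  combine reads into the *minimum* construct copy number n and an
  orientation pattern over {+, −}^n whose adjacent pairs explain every
  read's observed junctions.
- **Duplicated-element disambiguation** (`tgverify.disambiguate`) — assign
  short reads or pairs to one of two identical element copies only when
  they contain genome-wide unique sequence (a k-mer emulation of a
  MAPQ ≥ 30 unique-mapping filter), and build coverage tracks from the
  uniquely assigned reads.
- **Synthetic data** (`tgverify.simulate`) — a 60 kb toy locus with a
  532 bp enhancer element, a 4,190 bp enhancer–promoter–reporter construct,
  single-copy and four-copy (`++-+`) knock-in fixtures, and seeded
  simulators for nanopore-like long reads and clean short read pairs, each
  with per-read ground truth.

The central API follows the statsmodels idiom: `AlleleStructureModel` is
built from reads and a reference panel; `fit()` returns an
`AlleleStructureResults` with the inferred configuration, per-read
evidence, `summary()` and `to_json()`.

## Worked example

```python
import tgverify as tg

# a 60 kb toy locus and its four-copy tandem-array knock-in allele
locus = tg.make_toy_locus(seed=7)
expected = tg.make_fixture_allele("allele542", locus)   # single-copy reference
actual = tg.make_fixture_allele("allele320", locus)     # what really integrated

# 200 nanopore-like reads (mean 8 kb, 5%/3%/4% sub/ins/del errors)
params = tg.ReadSimulatorParams(n_reads=200, mean_length=8000, length_sd=1000, seed=42)
reads, truth = tg.simulate_long_reads({"chrT": actual.genome["chrT"]}, params)

panel = tg.ReferencePanel((("chrT", expected.genome["chrT"]),))
model = tg.AlleleStructureModel([(r[0], r[1]) for r in reads], panel,
                                expected.construct_interval, target_ref="chrT")
results = model.fit()
print(results.summary())
```

prints

```
Allele structure inference
============================================
reads analysed        : 200
allele class          : multi_copy_tandem
minimum copy number   : 4
orientation pattern   : ++-+
co-optimal patterns   : ++-+
read classification   :
    WT                124
    expected_knockin  28
    multi_copy        38
    ambiguous         0
    unclassified      10
junction support      :
    colinear-gap      115
    deletion          0
    insertion         0
    inversion         35
    copy-junction     16
```

No single 8 kb read spans the whole 16.8 kb array, yet the junctions
observed across reads admit no orientation pattern shorter than four
copies: the allele is reported as a tandem array of minimum four copies
with orientations `++-+` — which is exactly how the fixture was built.
Reads classified `WT` lie entirely in flanking sequence; `ambiguous` reads
(none here) would be those too short or too error-dense to anchor.

The same pipeline is available from the shell:

```sh
tgverify simulate --fixture allele320 --seed 42 --out-dir sim
tgverify verify --reads sim/long_reads.fastq \
    --panel sim/expected_single_copy.fa --construct expected:40000-44190 \
    --out-dir out
tgverify disambiguate --genome sim/allele542.fa --element-bed element.bed \
    --reads pairs_R1.fastq --reads2 pairs_R2.fastq
```

(`expected_single_copy.fa` is the expected single-insert mutant the reads
are compared against; verifying reads against the wild type alone cannot
count construct copies.)

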