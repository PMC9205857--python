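"""Synthetic locus, allele fixtures and read simulators with ground truth.

Everything the pipeline consumes can be generated at desk scale: a toy
locus carrying one copy of a short enhancer element plus a distant
insertion site flanked by homology arms; knock-in allele fixtures (a
single-copy allele and a four-copy mixed-orientation tandem array); and
seeded simulators for nanopore-like noisy long reads and clean short read
pairs, each with a per-read truth record.

Default geometry scales the real locus down to 60 kb: the enhancer element
keeps its native 532 bp, the enhancer-promoter-reporter construct its
4,190 bp, and the homology arms their ~1 kb sizes; the two element copies
end up ~25 kb apart (the native separation, 1.2 Mb, scaled down).  Error
rates default to a contemporary nanopore-like profile (5% substitutions,
3% insertions, 4% deletions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    AlleleSpec,
    CoordinateMap,
    GenomicInterval,
    apply_edits,
    build_knockin_allele,
)
from .seqio import revcomp

FIXTURE_NAMES = ("wt", "allele542", "allele320")

#: stand-in orientation pattern for the four-copy tandem-array fixture
DEFAULT_ARRAY_PATTERN = "++-+"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class LocusBlueprint:
    """Layout of the toy locus (all offsets on the wild-type sequence)."""

    total_length: int = 60_000
    element_length: int = 532
    element_copy1_offset: int = 15_000
    insertion_site_offset: int = 40_000  # start of the inter-arm (guide) segment
    inter_arm_length: int = 26
    left_ha_length: int = 1_035
    right_ha_length: int = 1_048
    construct_parts: tuple[tuple[str, int], ...] = (
        ("enhancer", 532),
        ("promoter", 600),
        ("reporter", 3_058),
    )
    gc_content: float = 0.42

    def __post_init__(self):
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.element_copy1_offset + self.element_length > self.total_length:
            raise ValueError("element does not fit in the locus")
        end_of_arms = (
            self.insertion_site_offset + self.inter_arm_length + self.right_ha_length
        )
        if end_of_arms > self.total_length or self.insertion_site_offset < self.left_ha_length:
            raise ValueError("insertion site / homology arms outside the locus")
        gap = abs(self.insertion_site_offset - self.element_copy1_offset)
        if gap < 10_000:
            raise ValueError("element copies must be separated by >= 10 kb")
        if self.construct_parts[0][1] != self.element_length:
            raise ValueError("first construct part must be the enhancer element")

    @property
    def construct_length(self) -> int:
        return sum(n for _, n in self.construct_parts)

    @property
    def chrom(self) -> str:
        return "chrT"


@dataclass
class ToyLocus:
    """A generated wild-type locus plus its feature annotation."""

    blueprint: LocusBlueprint
    genome: dict[str, str]
    features: dict[str, GenomicInterval]
    element_seq: str
    construct_seq: str

    @property
    def chrom(self) -> str:
        return self.blueprint.chrom

    def features_to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for name, iv in self.features.items():
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t+\n")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=probs)])


def make_toy_locus(blueprint: LocusBlueprint | None = None, seed: int = 7) -> ToyLocus:
    """Deterministically generate the wild-type locus and its construct.

    The enhancer element is planted at its copy-1 offset; the construct is
    the element followed by random promoter and reporter sequence, so that
    the element is duplicated once the construct is knocked in.
    """
    bp = blueprint or LocusBlueprint()
    rng = np.random.default_rng(seed)
    backbone = list(_random_seq(rng, bp.total_length, bp.gc_content))
    element = _random_seq(rng, bp.element_length, bp.gc_content)
    backbone[bp.element_copy1_offset : bp.element_copy1_offset + bp.element_length] = element
    seq = "".join(backbone)

    construct = element
    for part_name, part_len in bp.construct_parts[1:]:
        construct += _random_seq(rng, part_len, bp.gc_content)

    site = bp.insertion_site_offset
    features = {
        "element_copy1": GenomicInterval(bp.chrom, bp.element_copy1_offset,
                                         bp.element_copy1_offset + bp.element_length),
        "left_HA": GenomicInterval(bp.chrom, site - bp.left_ha_length, site),
        "guide_site": GenomicInterval(bp.chrom, site, site + bp.inter_arm_length),
        "right_HA": GenomicInterval(bp.chrom, site + bp.inter_arm_length,
                                    site + bp.inter_arm_length + bp.right_ha_length),
        "left_flank": GenomicInterval(bp.chrom, 0, site),
        "right_flank": GenomicInterval(bp.chrom, site + bp.inter_arm_length, bp.total_length),
    }
    return ToyLocus(bp, {bp.chrom: seq}, features, element, construct)


@dataclass
class FixtureAllele:
    """A fixture allele: its spec, realized mutant genome and truth."""

    name: str
    spec: AlleleSpec
    genome: dict[str, str]
    coord_map: CoordinateMap
    construct_interval: GenomicInterval | None  # one copy, on the mutant genome
    array_interval: GenomicInterval | None      # whole insertion, on the mutant genome
    copy_count: int
    orientation_pattern: str


def make_fixture_allele(
    name: str,
    locus: ToyLocus,
    orientation_pattern: str = DEFAULT_ARRAY_PATTERN,
) -> FixtureAllele:
    """Build one of the three study-condition fixtures.

    wt         no edits.
    allele542  single inter-arm replacement by one construct copy.
    allele320  the same replacement by a tandem concatenation of four
               construct copies with a mixed orientation pattern (default
               "++-+"; the real allele's printed conclusion is the copy
               count, the pattern itself is this fixture's ground truth).
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    bp = locus.blueprint
    left_ha = locus.features["left_HA"]
    right_ha = locus.features["right_HA"]
    site = bp.insertion_site_offset

    if name == "wt":
        spec = AlleleSpec(name="wt", host=locus.chrom, edits=())
        genome, cmap = apply_edits(locus.genome, spec)
        return FixtureAllele(name, spec, genome, cmap, None, None, 0, "")

    if name == "allele542":
        payload = locus.construct_seq
        pattern = "+"
    else:
        pattern = orientation_pattern
        payload = "".join(
            locus.construct_seq if o == "+" else revcomp(locus.construct_seq)
            for o in pattern
        )
    spec = build_knockin_allele(
        locus.genome, payload, left_ha, right_ha, name=name, mode="replace"
    )
    genome, cmap = apply_edits(locus.genome, spec)
    clen = bp.construct_length
    construct_iv = GenomicInterval(locus.chrom, site, site + clen)
    array_iv = GenomicInterval(locus.chrom, site, site + clen * len(pattern))
    return FixtureAllele(
        name, spec, genome, cmap, construct_iv, array_iv, len(pattern), pattern
    )


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class ReadSimulatorParams:
    """Knobs of the long-read simulator (rates are per base)."""

    n_reads: int = 200
    mean_length: int = 8_000
    length_sd: int = 1_000
    substitution_rate: float = 0.05
    insertion_rate: float = 0.03
    deletion_rate: float = 0.04
    cut_sites: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= r <= 0.2:
                raise ValueError("error rates must lie in [0, 0.2]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


def mutate_sequence(seq: str, rng: np.random.Generator,
                    sub: float, ins: float, dele: float) -> str:
    """Inject base-wise substitutions, insertions and deletions."""
    if sub == ins == dele == 0:
        return seq
    out = []
    n = len(seq)
    rolls = rng.random(n)
    for i, base in enumerate(seq):
        r = rolls[i]
        if r < dele:
            continue
        if r < dele + sub:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(3)])
        else:
            out.append(base)
        if rng.random() < ins:
            out.append("ACGT"[rng.integers(4)])
    return "".join(out)


def _single_sequence(genome: dict[str, str] | str) -> tuple[str, str]:
    if isinstance(genome, str):
        return "genome", genome
    if len(genome) != 1:
        raise ValueError("read simulation expects a single-sequence genome")
    ((name, seq),) = genome.items()
    return name, seq


def simulate_long_reads(
    genome: dict[str, str] | str,
    params: ReadSimulatorParams,
    copy_intervals: list[GenomicInterval] | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate nanopore-like long reads with per-read truth records.

    Read lengths are normal (truncated to [50, genome length]); start
    positions are uniform, or anchored within +-500 bp of the given cut
    sites (Cas9-enrichment style).  Strands are equiprobable; errors are
    injected base-wise.  Returns (reads, truth) where reads are
    (id, sequence, quality) tuples and truth records origin interval,
    strand and the number of construct copies fully spanned.
    """
    name, seq = _single_sequence(genome)
    glen = len(seq)
    if params.mean_length > glen:
        raise ValueError("mean_length exceeds genome length")
    rng = np.random.default_rng(params.seed)
    reads = []
    truth_rows = []
    for i in range(params.n_reads):
        length = int(np.clip(rng.normal(params.mean_length, params.length_sd), 50, glen))
        strand = "+" if rng.random() < 0.5 else "-"
        if params.cut_sites:
            site = int(params.cut_sites[rng.integers(len(params.cut_sites))])
            pos = site + int(rng.integers(-500, 501))
            start = pos if strand == "+" else pos - length
        else:
            start = int(rng.integers(0, max(1, glen - length + 1)))
        start = max(0, min(start, glen - 1))
        end = min(glen, start + length)
        fragment = seq[start:end]
        if strand == "-":
            fragment = revcomp(fragment)
        read_seq = mutate_sequence(
            fragment, rng,
            params.substitution_rate, params.insertion_rate, params.deletion_rate,
        )
        if not read_seq:
            read_seq = "N"
        read_id = f"read_{i:05d}"
        reads.append((read_id, read_seq, "5" * len(read_seq)))
        spanned = 0
        if copy_intervals:
            spanned = sum(
                1 for iv in copy_intervals if start <= iv.start and iv.end <= end
            )
        truth_rows.append(
            dict(read_id=read_id, origin=name, start=start, end=end,
                 strand=strand, copies_spanned=spanned)
        )
    truth = pd.DataFrame(truth_rows)
    return reads, truth


@dataclass(frozen=True)
class PairSimulatorParams:
    """Knobs of the paired short-read simulator."""

    n_pairs: int = 1_000
    read_length: int = 50
    insert_mean: int = 200
    insert_sd: int = 50
    substitution_rate: float = 0.0
    seed: int = 0
    region: GenomicInterval | None = None

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


def simulate_short_pairs(
    genome: dict[str, str] | str, params: PairSimulatorParams
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate inward-facing read pairs; truth carries the fragment interval."""
    name, seq = _single_sequence(genome)
    glen = len(seq)
    lo, hi = 0, glen
    if params.region is not None:
        lo, hi = params.region.start, params.region.end
    rng = np.random.default_rng(params.seed)
    min_insert = 2 * params.read_length
    r1, r2, rows = [], [], []
    for i in range(params.n_pairs):
        insert = int(rng.normal(params.insert_mean, params.insert_sd))
        if insert < min_insert:
            insert = min_insert
        insert = min(insert, hi - lo)
        start = int(rng.integers(lo, max(lo + 1, hi - insert + 1)))
        end = start + insert
        frag = seq[start:end]
        mate1 = frag[: params.read_length]
        mate2 = revcomp(frag)[: params.read_length]
        if params.substitution_rate:
            mate1 = mutate_sequence(mate1, rng, params.substitution_rate, 0, 0)
            mate2 = mutate_sequence(mate2, rng, params.substitution_rate, 0, 0)
        pid = f"pair_{i:06d}"
        qual = "5" * params.read_length
        r1.append((pid, mate1, qual[: len(mate1)]))
        r2.append((pid, mate2, qual[: len(mate2)]))
        rows.append(dict(read_id=pid, origin=name, start=start, end=end, strand="+"))
    return r1, r2, pd.DataFrame(rows)
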