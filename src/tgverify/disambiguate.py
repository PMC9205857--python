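"""Read disambiguation at duplicated elements via genome-wide unique k-mers.

After a knock-in, the enhancer element exists at two loci with byte-identical
sequence.  Short reads falling wholly inside either copy cannot be placed;
reads carrying at least `min_unique_kmers` k-mers that are unique in the
whole mutant genome are assigned to the copy their unique sequence belongs
to.  This emulates the MAPQ>=30 unique-mapping filter of a short-read
aligner without running one: uniqueness of placement is decided directly
from genome-wide unique k-mers, so an assignment can degrade to ambiguous
(e.g. when errors destroy the unique k-mers) but never flip to the wrong
copy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomicInterval, IntervalError
from .kmers import ReferencePanel, ScanParams, build_unique_index, scan_read
from .seqio import revcomp


class ElementError(ValueError):
    """Raised when a duplicated element is inconsistent with the genome."""


@dataclass(frozen=True)
class DuplicatedElement:
    """Two disjoint intervals on the mutant genome with identical sequence."""

    element_name: str
    copy_intervals: tuple[GenomicInterval, GenomicInterval]

    def __post_init__(self):
        a, b = self.copy_intervals
        if a.overlaps(b):
            raise ElementError("element copies overlap")

    def validate(self, genome: dict[str, str]) -> None:
        a, b = self.copy_intervals
        sa = genome[a.chrom][a.start : a.end]
        sb = genome[b.chrom][b.start : b.end]
        if sa != sb:
            raise ElementError(
                f"element copies {a} and {b} have different sequences"
            )


@dataclass(frozen=True)
class AssignmentParams:
    k_unique: int = 20
    pair_mode: str = "either-mate"
    min_unique_kmers: int = 1

    def __post_init__(self):
        if self.k_unique < 8:
            raise ValueError("k_unique must be >= 8")
        if self.min_unique_kmers < 1:
            raise ValueError("min_unique_kmers must be >= 1")
        if self.pair_mode not in ("either-mate", "both-mates"):
            raise ValueError(f"unknown pair_mode {self.pair_mode!r}")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str  # unique | ambiguous | unmapped
    locus: int | None = None  # copy index (0/1) when unique
    n_unique_kmers: int = 0

    def __post_init__(self):
        if (self.locus is not None) != (self.status == "unique"):
            raise ValueError("locus must be present iff status == unique")


class Disambiguator:
    """Pre-indexed assigner of reads/pairs to one of two element copies.

    Builds the genome-wide unique k-mer index and the full k-mer membership
    set once; `assign_read` / `assign_pair` then run in O(read length).
    """

    def __init__(
        self,
        genome: dict[str, str],
        element: DuplicatedElement,
        params: AssignmentParams | None = None,
        placement_slack: int = 50,
    ):
        self.genome = genome
        self.element = element
        self.params = params or AssignmentParams()
        self.placement_slack = placement_slack
        element.validate(genome)
        panel = ReferencePanel.from_dict(genome)
        self.index = build_unique_index(panel, self.params.k_unique)
        # membership set of all genome k-mers (canonical), for unmapped calls
        k = self.params.k_unique
        self._all_kmers: set[str] = set()
        for _, seq in panel.entries:
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                if "N" not in km:
                    rc = revcomp(km)
                    self._all_kmers.add(km if km < rc else rc)

    def _occurs_in_genome(self, seq: str) -> bool:
        k = self.params.k_unique
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            rc = revcomp(km)
            if (km if km < rc else rc) in self._all_kmers:
                return True
        return False

    def _nearest_copy(self, chrom: str, lo: int, hi: int) -> int:
        def dist(iv: GenomicInterval) -> int:
            if iv.chrom != chrom:
                return 10**12
            if lo < iv.end and iv.start < hi:
                return 0
            return iv.start - hi if iv.start >= hi else lo - iv.end

        d = [dist(iv) for iv in self.element.copy_intervals]
        return int(np.argmin(d))

    def assign_read(self, read_id: str, seq: str) -> ReadAssignment:
        """Assign one read: unique iff it has enough genome-wide unique
        k-mers, all consistent with a single placement."""
        seq = seq.upper()
        anchors = scan_read(seq, read_id, self.index, ScanParams(step=1))
        n_unique = len(anchors)
        if n_unique >= self.params.min_unique_kmers:
            chroms = {a.ref_name for a in anchors}
            lo = min(a.ref_offset for a in anchors)
            hi = max(a.ref_offset for a in anchors) + self.index.k
            if len(chroms) == 1 and hi - lo <= len(seq) + self.placement_slack:
                locus = self._nearest_copy(next(iter(chroms)), lo, hi)
                return ReadAssignment(read_id, "unique", locus, n_unique)
            return ReadAssignment(read_id, "ambiguous", None, n_unique)
        if self._occurs_in_genome(seq):
            return ReadAssignment(read_id, "ambiguous", None, n_unique)
        return ReadAssignment(read_id, "unmapped", None, 0)

    def assign_pair(self, read_id: str, seq1: str, seq2: str) -> ReadAssignment:
        """Assign a read pair under the configured pair rule.

        either-mate: a single uniquely-placed mate rescues the pair (the
        aligner analogue: the element-internal mate inherits its mate's
        placement).  both-mates: both must be unique and agree.
        """
        a1 = self.assign_read(read_id + "/1", seq1)
        a2 = self.assign_read(read_id + "/2", seq2)
        n = a1.n_unique_kmers + a2.n_unique_kmers
        uniques = [a for a in (a1, a2) if a.status == "unique"]
        if self.params.pair_mode == "either-mate":
            if len(uniques) == 2 and uniques[0].locus != uniques[1].locus:
                return ReadAssignment(read_id, "ambiguous", None, n)
            if uniques:
                return ReadAssignment(read_id, "unique", uniques[0].locus, n)
        else:
            if len(uniques) == 2 and uniques[0].locus == uniques[1].locus:
                return ReadAssignment(read_id, "unique", uniques[0].locus, n)
        if a1.status == a2.status == "unmapped":
            return ReadAssignment(read_id, "unmapped", None, 0)
        return ReadAssignment(read_id, "ambiguous", None, n)


def assign_read(
    read,
    mutant_genome: dict[str, str],
    element: DuplicatedElement,
    params: AssignmentParams | None = None,
) -> ReadAssignment:
    """One-shot functional form of `Disambiguator.assign_read`/`assign_pair`.

    `read` is (id, seq) for a single read or (id, seq1, seq2) for a pair.
    Builds the index on every call; use the Disambiguator class for batches.
    """
    d = Disambiguator(mutant_genome, element, params)
    if len(read) == 2:
        return d.assign_read(read[0], read[1])
    return d.assign_pair(read[0], read[1], read[2])


def coverage_track(
    assignments: list[ReadAssignment],
    placements: dict[str, GenomicInterval],
    genome: dict[str, str],
    region: GenomicInterval,
) -> np.ndarray:
    """Per-base coverage over `region` from uniquely assigned reads.

    `placements` gives each read's genomic interval (e.g. from simulation
    truth or from the unique-anchor span); only status == unique reads
    contribute, clipped to the region.
    """
    if region.chrom not in genome or region.end > len(genome[region.chrom]):
        raise IntervalError(f"region {region} outside genome")
    track = np.zeros(region.end - region.start, dtype=np.int64)
    for a in assignments:
        if a.status != "unique":
            continue
        iv = placements.get(a.read_id)
        if iv is None or iv.chrom != region.chrom:
            continue
        lo = max(iv.start, region.start) - region.start
        hi = min(iv.end, region.end) - region.start
        if hi > lo:
            track[lo:hi] += 1
    return track


def write_bedgraph(track: np.ndarray, region: GenomicInterval, path) -> None:
    """Write a coverage track as bedGraph (runs of equal coverage merged)."""
    with open(path, "w") as fh:
        if len(track) == 0:
            return
        run_start = 0
        for i in range(1, len(track) + 1):
            if i == len(track) or track[i] != track[run_start]:
                fh.write(
                    f"{region.chrom}\t{region.start + run_start}"
                    f"\t{region.start + i}\t{int(track[run_start])}\n"
                )
                run_start = i


def fragment_pair_filter(
    pairs: list[tuple[str, GenomicInterval, GenomicInterval]],
    element: DuplicatedElement,
) -> list[tuple[str, GenomicInterval, GenomicInterval]]:
    """Drop fragment pairs with an end fully inside the duplicated element.

    An end interval contained in either element copy carries no unique
    flanking sequence and cannot be attributed to one copy; such pairs are
    removed, all others pass unchanged.
    """
    kept = []
    for pair in pairs:
        _, end1, end2 = pair
        bad = any(
            copy.contains(end)
            for end in (end1, end2)
            for copy in element.copy_intervals
        )
        if not bad:
            kept.append(pair)
    return kept
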