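"""Mutant genome construction from exact breakpoints, and coordinate lift-over.

An engineered allele is described as a list of edits (deletion, insertion,
replacement, inversion) against wild-type coordinates.  Applying the edits
yields the mutant sequence together with a block-wise coordinate map that
lifts positions in either direction.  A knock-in allele specified by two
homology arms reduces to a single replacement of the inter-arm segment.

All intervals are 0-based half-open (BED convention), so a span printed as
``chr2:74075311-74075843`` has length 74075843 - 74075311 = 532 bp.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import yaml

from .seqio import revcomp

_PAYLOAD_ALPHABET = frozenset("ACGTN")

EDIT_KINDS = ("deletion", "insertion", "replacement", "inversion")


class IntervalError(ValueError):
    """Raised for malformed or out-of-bounds genomic intervals."""


class EditError(ValueError):
    """Raised for invalid edits or edit lists (overlap, bad payload...)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence.

    A zero-length interval (start == end) is tolerated structurally so that
    insertion points can be expressed, but `length` refuses it.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise IntervalError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return interval_length(self)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (0-based half-open, no thousands separators)."""
    chrom, _, span = text.partition(":")
    start_s, _, end_s = span.partition("-")
    try:
        iv = GenomicInterval(chrom, int(start_s), int(end_s))
    except ValueError as exc:
        raise IntervalError(f"cannot parse region {text!r}") from exc
    if iv.start == iv.end:
        raise IntervalError(f"empty interval {text!r}")
    return iv


def interval_length(interval: GenomicInterval) -> int:
    """Length in bp of a half-open interval; empty intervals are an error."""
    if interval.start >= interval.end:
        raise IntervalError(f"empty or inverted interval {interval}")
    return interval.end - interval.start


@dataclass(frozen=True)
class GenomeEdit:
    """One breakpoint-exact edit against wild-type (host) coordinates.

    kind      one of deletion / insertion / replacement / inversion
    target    host interval; zero-length only for insertion (point)
    payload   inserted sequence (insertion / replacement only)
    label     free-text name carried into BED exports
    """

    kind: str
    target: GenomicInterval
    payload: str | None = None
    label: str = ""

    def __post_init__(self):
        if self.kind not in EDIT_KINDS:
            raise EditError(f"unknown edit kind {self.kind!r}")
        needs_payload = self.kind in ("insertion", "replacement")
        if needs_payload:
            if not self.payload:
                raise EditError(f"{self.kind} edit requires a non-empty payload")
            bad = set(self.payload.upper()) - _PAYLOAD_ALPHABET
            if bad:
                raise EditError(f"payload contains invalid characters {sorted(bad)}")
            object.__setattr__(self, "payload", self.payload.upper())
        elif self.payload:
            raise EditError(f"{self.kind} edit takes no payload")
        if self.target.start == self.target.end and self.kind != "insertion":
            raise EditError("zero-length target only legal for insertion")
        if self.kind in ("deletion", "replacement", "inversion") and (
            self.target.end <= self.target.start
        ):
            raise EditError(f"{self.kind} target must be non-empty")

    @property
    def removed(self) -> int:
        """Host bp removed by this edit."""
        return self.target.end - self.target.start if self.kind in ("deletion", "replacement") else 0

    @property
    def added(self) -> int:
        """bp contributed by the payload."""
        return len(self.payload) if self.payload else 0


@dataclass(frozen=True)
class AlleleSpec:
    """A named allele: an ordered, non-overlapping edit list on one host sequence."""

    name: str
    host: str
    edits: tuple[GenomeEdit, ...] = ()

    def __post_init__(self):
        edits = tuple(sorted(self.edits, key=lambda e: (e.target.start, e.target.end)))
        object.__setattr__(self, "edits", edits)
        prev_end = -1
        for e in edits:
            if e.target.chrom != self.host:
                raise EditError(
                    f"edit target {e.target} not on host sequence {self.host}"
                )
            if e.target.start < prev_end:
                raise EditError(f"overlapping edits at {e.target}")
            prev_end = max(prev_end, e.target.end)

    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "host": self.host,
            "edits": [
                {
                    "kind": e.kind,
                    "start": e.target.start,
                    "end": e.target.end,
                    **({"payload": e.payload} if e.payload else {}),
                    **({"label": e.label} if e.label else {}),
                }
                for e in self.edits
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AlleleSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        edits = tuple(
            GenomeEdit(
                kind=e["kind"],
                target=GenomicInterval(doc["host"], int(e["start"]), int(e["end"])),
                payload=e.get("payload"),
                label=e.get("label", ""),
            )
            for e in doc.get("edits", [])
        )
        return cls(name=doc["name"], host=doc["host"], edits=edits)

    def targets_to_bed(self, path) -> None:
        """BED6 of edit targets; the strand column marks inversions."""
        with open(path, "w") as fh:
            for i, e in enumerate(self.edits):
                strand = "-" if e.kind == "inversion" else "+"
                label = e.label or f"{e.kind}_{i}"
                fh.write(
                    f"{e.target.chrom}\t{e.target.start}\t{e.target.end}"
                    f"\t{label}\t0\t{strand}\n"
                )


@dataclass(frozen=True)
class LiftedPosition:
    """Result of a lift: a mapped offset, or None with a reason."""

    position: int | None
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.position is not None


@dataclass(frozen=True)
class _Block:
    wt_start: int
    wt_end: int
    mut_start: int
    mut_end: int
    orientation: str  # '+' collinear, '-' inverted


@dataclass
class CoordinateMap:
    """Monotone block map between a wild-type sequence and its mutant.

    Positions inside deleted wild-type segments lift to None ("deleted");
    positions inside inserted payload lift back to None ("inserted-only").
    """

    host: str
    wt_length: int
    mut_length: int
    blocks: list[_Block] = field(default_factory=list)

    def lift(self, position: int, direction: str = "wt->mutant") -> LiftedPosition:
        if direction not in ("wt->mutant", "mutant->wt"):
            raise ValueError(f"unknown lift direction {direction!r}")
        forward = direction == "wt->mutant"
        size = self.wt_length if forward else self.mut_length
        if not 0 <= position < size:
            raise IntervalError(f"position {position} outside [0, {size})")
        if forward:
            starts = [b.wt_start for b in self.blocks]
            i = bisect.bisect_right(starts, position) - 1
            if i >= 0:
                b = self.blocks[i]
                if position < b.wt_end:
                    off = position - b.wt_start
                    if b.orientation == "+":
                        return LiftedPosition(b.mut_start + off)
                    return LiftedPosition(b.mut_end - 1 - off)
            return LiftedPosition(None, "deleted")
        starts = sorted(b.mut_start for b in self.blocks)
        by_mut = sorted(self.blocks, key=lambda b: b.mut_start)
        i = bisect.bisect_right(starts, position) - 1
        if i >= 0:
            b = by_mut[i]
            if position < b.mut_end:
                off = position - b.mut_start
                if b.orientation == "+":
                    return LiftedPosition(b.wt_start + off)
                return LiftedPosition(b.wt_end - 1 - off)
        return LiftedPosition(None, "inserted-only")

    def to_chain(self, path, wt_name: str | None = None, mut_name: str | None = None) -> None:
        """Export as UCSC chain file, one chain per run of same-orientation blocks.

        Target is the wild-type sequence, query the mutant.  Inverted blocks
        are emitted as separate minus-strand chains (query coordinates given
        on the reverse strand, per the chain spec).
        """
        wt_name = wt_name or self.host
        mut_name = mut_name or f"{self.host}_mut"
        chain_id = 0
        with open(path, "w") as fh:
            runs: list[list[_Block]] = []
            for b in self.blocks:
                if runs and runs[-1][-1].orientation == b.orientation == "+":
                    runs[-1].append(b)
                else:
                    runs.append([b])
            for run in runs:
                chain_id += 1
                orient = run[0].orientation
                t_start, t_end = run[0].wt_start, run[-1].wt_end
                if orient == "+":
                    q_start, q_end = run[0].mut_start, run[-1].mut_end
                    q_strand = "+"
                else:
                    # chain format: minus-strand query coords count from the 3' end
                    q_start = self.mut_length - run[-1].mut_end
                    q_end = self.mut_length - run[0].mut_start
                    q_strand = "-"
                fh.write(
                    f"chain 1000 {wt_name} {self.wt_length} + {t_start} {t_end} "
                    f"{mut_name} {self.mut_length} {q_strand} {q_start} {q_end} {chain_id}\n"
                )
                for j, b in enumerate(run):
                    size = b.wt_end - b.wt_start
                    if j + 1 < len(run):
                        nb = run[j + 1]
                        dt = nb.wt_start - b.wt_end
                        dq = nb.mut_start - b.mut_end
                        fh.write(f"{size} {dt} {dq}\n")
                    else:
                        fh.write(f"{size}\n")
                fh.write("\n")


def apply_edits(
    wt_genome: dict[str, str], spec: AlleleSpec
) -> tuple[dict[str, str], CoordinateMap]:
    """Apply an AlleleSpec to a wild-type genome.

    Edits are interpreted against original wild-type coordinates (no serial
    shifting).  Untouched sequences are passed through unchanged.  Returns the
    mutant genome and the CoordinateMap for the host sequence.
    """
    if spec.host not in wt_genome:
        raise EditError(f"host sequence {spec.host!r} not in genome")
    wt = wt_genome[spec.host]
    n = len(wt)
    for e in spec.edits:
        if e.target.end > n:
            raise EditError(f"edit target {e.target} outside host bounds (len {n})")

    parts: list[str] = []
    blocks: list[_Block] = []
    cursor = 0
    mut_pos = 0

    def emit_identity(upto: int):
        nonlocal cursor, mut_pos
        if upto > cursor:
            parts.append(wt[cursor:upto])
            blocks.append(_Block(cursor, upto, mut_pos, mut_pos + (upto - cursor), "+"))
            mut_pos += upto - cursor
            cursor = upto

    for e in spec.edits:
        emit_identity(e.target.start)
        span = e.target.end - e.target.start
        if e.kind == "deletion":
            pass
        elif e.kind == "insertion":
            parts.append(e.payload)
            mut_pos += len(e.payload)
        elif e.kind == "replacement":
            parts.append(e.payload)
            mut_pos += len(e.payload)
        elif e.kind == "inversion":
            parts.append(revcomp(wt[e.target.start : e.target.end]))
            blocks.append(
                _Block(e.target.start, e.target.end, mut_pos, mut_pos + span, "-")
            )
            mut_pos += span
        cursor = e.target.end
    emit_identity(n)

    mutant_seq = "".join(parts)
    cmap = CoordinateMap(spec.host, n, len(mutant_seq), blocks)
    mutant = dict(wt_genome)
    mutant[spec.host] = mutant_seq
    return mutant, cmap


def build_knockin_allele(
    wt: dict[str, str],
    construct: str,
    left_ha: GenomicInterval,
    right_ha: GenomicInterval,
    name: str,
    construct_includes_arms: bool = False,
    mode: str = "replace",
    verify_arms: bool = True,
) -> AlleleSpec:
    """AlleleSpec for a homology-directed knock-in between two arms.

    The inter-arm host segment [left_ha.end, right_ha.start) is replaced by
    the inter-arm payload of the construct (mode="replace", the default, as
    expected from homology-directed repair across the cut site), or the
    payload is inserted at left_ha.end with the host segment retained
    (mode="retain").

    When `construct_includes_arms` is true the construct string must begin
    with the left-arm sequence and end with the right-arm sequence, which are
    stripped to obtain the payload; arm identity is checked against the host
    unless `verify_arms` is disabled.  N bases never satisfy arm verification.
    """
    if mode not in ("replace", "retain"):
        raise EditError(f"unknown knock-in mode {mode!r}")
    if left_ha.chrom != right_ha.chrom:
        raise EditError("homology arms must be on the same sequence")
    if left_ha.end > right_ha.start:
        raise EditError(
            f"homology arms overlap or are out of order: {left_ha} vs {right_ha}"
        )
    host = left_ha.chrom
    if host not in wt:
        raise EditError(f"host sequence {host!r} not in genome")
    seq = wt[host]
    construct = construct.upper()

    if construct_includes_arms:
        l_seq = seq[left_ha.start : left_ha.end]
        r_seq = seq[right_ha.start : right_ha.end]
        if verify_arms:
            if "N" in l_seq or "N" in r_seq:
                raise EditError("homology arm contains N; cannot verify")
            if not construct.startswith(l_seq):
                raise EditError("construct does not begin with the left homology arm")
            if not construct.endswith(r_seq):
                raise EditError("construct does not end with the right homology arm")
        payload = construct[left_ha.length : len(construct) - right_ha.length]
    else:
        payload = construct
    if not payload:
        raise EditError("empty inter-arm payload")

    if mode == "replace" and left_ha.end < right_ha.start:
        edit = GenomeEdit(
            kind="replacement",
            target=GenomicInterval(host, left_ha.end, right_ha.start),
            payload=payload,
            label=name,
        )
    else:
        point = left_ha.end
        edit = GenomeEdit(
            kind="insertion",
            target=GenomicInterval(host, point, point),
            payload=payload,
            label=name,
        )
    return AlleleSpec(name=name, host=host, edits=(edit,))
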