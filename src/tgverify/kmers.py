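"""Unique k-mer anchoring of long reads against a reference panel.

The verification core: every k-mer of a reference panel that occurs exactly
once across the panel (counting both strands) is indexed; read windows
sampled every `step` bases anchor wherever the window, or its reverse
complement, hits the index exactly.  The resulting (read offset, reference
offset) pairs are the dots of a dot plot: collinear runs are diagonals,
inverted blocks anti-diagonals.

Defaults k=20, step=5.  k-mers containing N, and k-mers equal to their own
reverse complement (strand undecidable), are never indexed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .seqio import read_fasta, revcomp


class KmerParameterError(ValueError):
    """Raised for invalid k / step choices."""


@dataclass(frozen=True)
class ReferencePanel:
    """Ordered set of named reference sequences (e.g. wild type, expected
    mutant, cloning vector)."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("panel sequence names must be unique")
        for n, s in self.entries:
            if not s:
                raise ValueError(f"panel sequence {n!r} is empty")
        object.__setattr__(
            self, "entries", tuple((n, s.upper()) for n, s in self.entries)
        )

    @classmethod
    def from_fasta(cls, path) -> "ReferencePanel":
        return cls(tuple(read_fasta(path).items()))

    @classmethod
    def from_dict(cls, genome: dict[str, str]) -> "ReferencePanel":
        return cls(tuple(genome.items()))

    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def sequence(self, name: str) -> str:
        for n, s in self.entries:
            if n == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class ScanParams:
    """Read scanning stride; k is carried by the index."""

    step: int = 5

    def __post_init__(self):
        if self.step < 1:
            raise KmerParameterError("step must be >= 1")


@dataclass(frozen=True)
class Anchor:
    """An exact, panel-unique match of one read window."""

    read_id: str
    read_offset: int
    ref_name: str
    ref_offset: int
    strand: str  # '+' window matches forward, '-' its reverse complement does


@dataclass
class UniqueKmerIndex:
    """Mapping from k-mer string to its single panel location.

    Both orientations of each unique k-mer are keyed, so one dict lookup per
    window resolves position and strand at once.
    """

    k: int
    table: dict[str, tuple[str, int, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return sum(1 for v in self.table.values() if v[2] == "+")

    def lookup(self, kmer: str):
        return self.table.get(kmer)


def build_unique_index(
    panel: ReferencePanel, k: int = 20, scope: str = "global"
) -> UniqueKmerIndex | dict[str, UniqueKmerIndex]:
    """Index the k-mers occurring exactly once in the panel (both strands).

    scope="global" (default): uniqueness across all panel entries together —
    a k-mer shared by two entries is dropped, which makes every anchor
    unambiguous across the whole panel.  scope="per-entry": one independent
    index per entry is returned as a dict, for comparing a read against each
    reference separately (e.g. wild type vs expected mutant, whose flanks are
    identical and would cancel each other under global scoping).
    """
    if k < 8:
        raise KmerParameterError("k must be >= 8")
    if scope == "per-entry":
        return {
            name: build_unique_index(ReferencePanel(((name, seq),)), k)
            for name, seq in panel.entries
        }
    if scope != "global":
        raise KmerParameterError(f"unknown uniqueness scope {scope!r}")

    counts: dict[str, int] = {}
    first_loc: dict[str, tuple[str, int, str]] = {}
    for name, seq in panel.entries:
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            rc = revcomp(km)
            if rc == km:  # palindromic: strand undecidable
                counts[km] = counts.get(km, 0) + 2
                continue
            canon = km if km < rc else rc
            c = counts.get(canon, 0)
            counts[canon] = c + 1
            if c == 0:
                first_loc[canon] = (name, i, "+" if canon == km else "-")

    table: dict[str, tuple[str, int, str]] = {}
    for canon, c in counts.items():
        if c != 1:
            continue
        name, i, orient = first_loc[canon]
        fwd = canon if orient == "+" else revcomp(canon)
        table[fwd] = (name, i, "+")
        table[revcomp(fwd)] = (name, i, "-")
    index = UniqueKmerIndex(k=k, table=table)
    if not table:
        warnings.warn("unique k-mer index is empty", stacklevel=2)
    return index


def scan_read(
    seq: str,
    read_id: str,
    index: UniqueKmerIndex,
    params: ScanParams | None = None,
) -> list[Anchor]:
    """Anchor read windows sampled at offsets 0, step, 2*step, ...

    A window yields an anchor iff it (strand +) or its reverse complement
    (strand -) is a panel-unique k-mer.  Reads shorter than k yield no
    anchors.  Anchors are returned in read order.
    """
    params = params or ScanParams()
    k = index.k
    seq = seq.upper()
    anchors: list[Anchor] = []
    for off in range(0, len(seq) - k + 1, params.step):
        hit = index.table.get(seq[off : off + k])
        if hit is not None:
            name, pos, strand = hit
            anchors.append(Anchor(read_id, off, name, pos, strand))
    return anchors


_DOTPLOT_COLUMNS = ["read_id", "read_offset", "ref_name", "ref_offset", "strand"]


def anchors_to_frame(anchors: list[Anchor]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(a.read_id, a.read_offset, a.ref_name, a.ref_offset, a.strand) for a in anchors],
        columns=_DOTPLOT_COLUMNS,
    )
    return df.sort_values(["read_id", "read_offset"], kind="stable").reset_index(drop=True)


def export_dotplot(anchors: list[Anchor], destination, image=None) -> pd.DataFrame:
    """Write anchors as a TSV dot plot table (one row per anchor, read_offset
    ascending); optionally also render a raster dot plot."""
    df = anchors_to_frame(anchors)
    df.to_csv(destination, sep="\t", index=False)
    if image is not None:
        plot_dotplot(anchors, image)
    return df


def load_anchors(path) -> list[Anchor]:
    """Re-read a dot plot TSV into Anchor records."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "ref_name": str, "strand": str})
    return [
        Anchor(r.read_id, int(r.read_offset), r.ref_name, int(r.ref_offset), r.strand)
        for r in df.itertuples(index=False)
    ]


def plot_dotplot(anchors: list[Anchor], image, ax=None):
    """Scatter of read offset vs reference offset, strands colour-coded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    created = ax is None
    if created:
        _, ax = plt.subplots(figsize=(6, 5))
    for strand, colour in (("+", "tab:blue"), ("-", "tab:red")):
        xs = [a.read_offset for a in anchors if a.strand == strand]
        ys = [a.ref_offset for a in anchors if a.strand == strand]
        ax.scatter(xs, ys, s=4, c=colour, label=strand)
    ax.set_xlabel("read offset (bp)")
    ax.set_ylabel("reference offset (bp)")
    if anchors:
        ax.set_title(anchors[0].read_id)
    ax.legend(title="strand", loc="best", fontsize=8)
    if created:
        plt.tight_layout()
        plt.savefig(image, dpi=120)
        plt.close()
    return ax
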