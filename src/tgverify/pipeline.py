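"""Composed, file-level pipeline stages behind the command-line interface.

Each `run_*` function ties library stages together with deterministic
outputs: FASTA/FASTQ/BED/TSV in, TSV/JSON/bedGraph/chain out.  The
machine-readable verification report echoes parameters and input checksums
so a run can be reproduced byte-for-byte from its report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .disambiguate import (
    AssignmentParams,
    Disambiguator,
    DuplicatedElement,
    coverage_track,
    write_bedgraph,
)
from .genome import AlleleSpec, GenomicInterval, apply_edits
from .kmers import anchors_to_frame
from .seqio import read_fasta, read_fastq, write_fasta
from .structure import AlleleStructureModel, ChainParams

def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class VerifyConfig:
    """Inputs and parameters of a verification run."""

    reads: str
    panel: str
    construct_interval: GenomicInterval
    target_ref: str | None = None
    out_dir: str = "tgverify_out"
    k: int = 20
    step: int = 5
    chain_params: ChainParams = field(default_factory=ChainParams)
    n_max: int = 8


def run_verify(config: VerifyConfig) -> dict:
    """Full long-read verification: index, scan, chain, classify, infer.

    Writes anchors.tsv, architectures.tsv and report.json under the output
    directory and returns the report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = AlleleStructureModel.from_files(
        config.reads,
        config.panel,
        config.construct_interval,
        target_ref=config.target_ref,
        k=config.k,
        step=config.step,
        chain_params=config.chain_params,
    )
    results = model.fit(n_max=config.n_max)

    all_anchors = [a for anchors in results.anchors.values() for a in anchors]
    anchors_to_frame(all_anchors).to_csv(out / "anchors.tsv", sep="\t", index=False)
    results.architectures_frame().to_csv(out / "architectures.tsv", sep="\t", index=False)

    report = results.to_dict()
    report["tool_version"] = __version__
    report["inputs"] = {
        "reads": {"path": str(config.reads), "sha256_16": _checksum(config.reads)},
        "panel": {"path": str(config.panel), "sha256_16": _checksum(config.panel)},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "report.txt", "w") as fh:
        fh.write(results.summary() + "\n")
    return report


@dataclass
class DisambiguateConfig:
    genome: str
    element_bed: str
    reads1: str
    reads2: str | None = None
    out_dir: str = "tgverify_out"
    params: AssignmentParams = field(default_factory=AssignmentParams)
    region: GenomicInterval | None = None


def load_element_bed(path, name: str = "element") -> DuplicatedElement:
    """Read the two element-copy intervals from a BED file."""
    copies = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED line")
            copies.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            if len(fields) >= 4:
                name = fields[3]
    if len(copies) != 2:
        raise ValueError(f"element BED must contain exactly 2 intervals, got {len(copies)}")
    return DuplicatedElement(name, (copies[0], copies[1]))


def run_disambiguate(config: DisambiguateConfig) -> dict:
    """Assign reads or pairs to element copies; write TSV and bedGraph."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(config.genome)
    element = load_element_bed(config.element_bed)
    d = Disambiguator(genome, element, config.params)

    assignments = []
    placements: dict[str, GenomicInterval] = {}
    reads1 = list(read_fastq(config.reads1))
    if config.reads2 is not None:
        reads2 = dict(read_fastq(config.reads2))
        for rid, seq1 in reads1:
            assignments.append(d.assign_pair(rid, seq1, reads2[rid]))
    else:
        for rid, seq in reads1:
            assignments.append(d.assign_read(rid, seq))

    with open(out / "assignments.tsv", "w") as fh:
        fh.write("read_id\tstatus\tlocus\tn_unique_kmers\n")
        for a in assignments:
            locus = "" if a.locus is None else a.locus
            fh.write(f"{a.read_id}\t{a.status}\t{locus}\t{a.n_unique_kmers}\n")

    chrom = next(iter(genome))
    region = config.region or GenomicInterval(chrom, 0, len(genome[chrom]))
    # place reads by their unique-anchor span (exact for clean reads)
    from .kmers import ScanParams, scan_read

    for rid, seq in reads1:
        anchors = scan_read(seq, rid, d.index, ScanParams(step=1))
        if anchors:
            lo = min(a.ref_offset for a in anchors)
            hi = max(a.ref_offset for a in anchors) + d.index.k
            placements[rid] = GenomicInterval(anchors[0].ref_name, lo, hi)
    track = coverage_track(assignments, placements, genome, region)
    write_bedgraph(track, region, out / "coverage.bedGraph")

    tally = {"unique": 0, "ambiguous": 0, "unmapped": 0}
    for a in assignments:
        tally[a.status] += 1
    report = {"n_reads": len(assignments), "status_tally": tally,
              "element": element.element_name}
    with open(out / "disambiguate.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def run_build_genome(wt_fasta, edits_yaml, out_prefix) -> dict:
    """Apply an AlleleSpec to a wild-type FASTA; write mutant FASTA + chain."""
    wt = read_fasta(wt_fasta)
    spec = AlleleSpec.from_yaml(edits_yaml)
    mutant, cmap = apply_edits(wt, spec)
    out_prefix = str(out_prefix)
    write_fasta(mutant, out_prefix + ".fa")
    cmap.to_chain(out_prefix + ".chain", wt_name=spec.host, mut_name=spec.host)
    return {
        "allele": spec.name,
        "host": spec.host,
        "wt_length": cmap.wt_length,
        "mutant_length": cmap.mut_length,
        "n_edits": len(spec.edits),
        "fasta": out_prefix + ".fa",
        "chain": out_prefix + ".chain",
    }
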