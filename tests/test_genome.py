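"""Genome construction: intervals, edits, lift-over and knock-in assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tgverify as tg
from tgverify.genome import EditError, IntervalError, GenomeEdit, _Block
from tgverify.seqio import revcomp

from conftest import random_seq


# ---------------------------------------------------------------------------
# oracle: serial right-to-left string splicing (independent of apply_edits,
# which walks left-to-right building blocks)


def splice_oracle(seq: str, edits) -> str:
    out = seq
    for e in sorted(edits, key=lambda e: e.target.start, reverse=True):
        s, t = e.target.start, e.target.end
        if e.kind == "deletion":
            out = out[:s] + out[t:]
        elif e.kind == "insertion":
            out = out[:s] + e.payload + out[s:]
        elif e.kind == "replacement":
            out = out[:s] + e.payload + out[t:]
        elif e.kind == "inversion":
            out = out[:s] + revcomp(out[s:t]) + out[t:]
    return out


def random_edits(rng, host_len, max_edits=5, chrom="chr"):
    """Non-overlapping random edits of all four kinds."""
    n = int(rng.integers(1, max_edits + 1))
    cuts = np.sort(rng.choice(host_len, size=2 * n, replace=False))
    edits = []
    for i in range(n):
        s, t = int(cuts[2 * i]), int(cuts[2 * i + 1])
        kind = ["deletion", "insertion", "replacement", "inversion"][int(rng.integers(4))]
        if s == t and kind != "insertion":
            kind = "insertion"
        if kind == "insertion":
            edits.append(GenomeEdit("insertion", tg.GenomicInterval(chrom, s, s),
                                    random_seq(rng, int(rng.integers(1, 300)))))
        elif kind in ("replacement",):
            edits.append(GenomeEdit(kind, tg.GenomicInterval(chrom, s, t),
                                    random_seq(rng, int(rng.integers(1, 300)))))
        else:
            edits.append(GenomeEdit(kind, tg.GenomicInterval(chrom, s, t)))
    return edits


class TestIntervals:
    def test_printed_enhancer_span_is_532_bp(self):
        iv = tg.parse_region("chr2:74075311-74075843")
        assert tg.interval_length(iv) == 532

    def test_single_base_interval(self):
        assert tg.interval_length(tg.GenomicInterval("chrX", 100, 101)) == 1

    def test_empty_interval_rejected(self):
        iv = tg.GenomicInterval("chrX", 100, 100)  # structurally ok (insertion point)
        with pytest.raises(IntervalError):
            tg.interval_length(iv)
        with pytest.raises(IntervalError):
            tg.parse_region("chrX:100-100")

    def test_inverted_interval_rejected(self):
        with pytest.raises(IntervalError):
            tg.GenomicInterval("chrX", 10, 5)


class TestApplyEdits:
    def test_single_deletion_length(self, rng):
        wt = {"chr": random_seq(rng, 10_000)}
        spec = tg.AlleleSpec("del", "chr",
                             (GenomeEdit("deletion", tg.GenomicInterval("chr", 1000, 1532)),))
        mut, cmap = tg.apply_edits(wt, spec)
        assert len(mut["chr"]) == 9_468
        assert cmap.mut_length == 9_468

    def test_empty_edit_list_identity(self, rng):
        wt = {"chr": random_seq(rng, 2_000)}
        mut, cmap = tg.apply_edits(wt, tg.AlleleSpec("wt", "chr", ()))
        assert mut == wt
        assert all(cmap.lift(p).position == p for p in (0, 999, 1999))

    def test_construct_insertion_length(self, rng):
        wt = {"chr": random_seq(rng, 10_000)}
        payload = random_seq(rng, 4_190)
        spec = tg.AlleleSpec("ins", "chr",
                             (GenomeEdit("insertion", tg.GenomicInterval("chr", 5_000, 5_000),
                                         payload),))
        mut, _ = tg.apply_edits(wt, spec)
        assert len(mut["chr"]) == 10_000 + 4_190

    def test_matches_splice_oracle_on_random_edit_sets(self, rng):
        for _ in range(25):
            wt = {"chr": random_seq(rng, int(rng.integers(500, 5_000)))}
            edits = random_edits(rng, len(wt["chr"]))
            spec = tg.AlleleSpec("rand", "chr", tuple(edits))
            mut, cmap = tg.apply_edits(wt, spec)
            assert mut["chr"] == splice_oracle(wt["chr"], edits)
            removed = sum(e.removed for e in edits)
            added = sum(e.added for e in edits)
            assert len(mut["chr"]) == len(wt["chr"]) - removed + added
            assert cmap.mut_length == len(mut["chr"])

    def test_inversion_involution(self, rng):
        wt = {"chr": random_seq(rng, 3_000)}
        inv = GenomeEdit("inversion", tg.GenomicInterval("chr", 500, 1_700))
        spec = tg.AlleleSpec("inv", "chr", (inv,))
        once, _ = tg.apply_edits(wt, spec)
        twice, _ = tg.apply_edits(once, spec)
        assert twice == wt

    def test_overlapping_edits_rejected(self):
        with pytest.raises(EditError):
            tg.AlleleSpec("bad", "chr", (
                GenomeEdit("deletion", tg.GenomicInterval("chr", 100, 300)),
                GenomeEdit("deletion", tg.GenomicInterval("chr", 200, 400)),
            ))

    def test_out_of_bounds_edit_rejected(self, rng):
        wt = {"chr": random_seq(rng, 100)}
        spec = tg.AlleleSpec("oob", "chr",
                             (GenomeEdit("deletion", tg.GenomicInterval("chr", 50, 200)),))
        with pytest.raises(EditError):
            tg.apply_edits(wt, spec)


class TestLift:
    def test_positions_around_a_deletion(self, rng):
        wt = {"chr": random_seq(rng, 5_000)}
        spec = tg.AlleleSpec("del", "chr",
                             (GenomeEdit("deletion", tg.GenomicInterval("chr", 1_000, 1_532)),))
        _, cmap = tg.apply_edits(wt, spec)
        assert cmap.lift(0).position == 0
        assert cmap.lift(2_000).position == 2_000 - 532
        inside = cmap.lift(1_200)
        assert inside.position is None and inside.reason == "deleted"

    def test_inserted_only_positions(self, rng):
        wt = {"chr": random_seq(rng, 2_000)}
        spec = tg.AlleleSpec("ins", "chr",
                             (GenomeEdit("insertion", tg.GenomicInterval("chr", 500, 500),
                                         random_seq(rng, 100)),))
        _, cmap = tg.apply_edits(wt, spec)
        hit = cmap.lift(550, "mutant->wt")
        assert hit.position is None and hit.reason == "inserted-only"

    def test_out_of_bounds_raises(self, rng):
        wt = {"chr": random_seq(rng, 100)}
        _, cmap = tg.apply_edits(wt, tg.AlleleSpec("wt", "chr", ()))
        with pytest.raises(IntervalError):
            cmap.lift(100)
        with pytest.raises(IntervalError):
            cmap.lift(-1, "mutant->wt")

    def test_round_trip_outside_edits(self, rng):
        for _ in range(20):
            wt = {"chr": random_seq(rng, 3_000)}
            edits = random_edits(rng, 3_000)
            _, cmap = tg.apply_edits(wt, tg.AlleleSpec("r", "chr", tuple(edits)))
            for p in rng.integers(0, 3_000, size=50):
                fwd = cmap.lift(int(p))
                if fwd.position is None:
                    continue
                back = cmap.lift(fwd.position, "mutant->wt")
                assert back.position == int(p)

    def test_inverted_block_maps_reversed(self, rng):
        wt = {"chr": random_seq(rng, 1_000)}
        spec = tg.AlleleSpec("inv", "chr",
                             (GenomeEdit("inversion", tg.GenomicInterval("chr", 100, 200)),))
        mut, cmap = tg.apply_edits(wt, spec)
        assert cmap.lift(100).position == 199
        assert cmap.lift(199).position == 100
        assert mut["chr"][100:200] == revcomp(wt["chr"][100:200])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_length_conservation_property(seed):
    """|mutant| = |WT| - sum(removed) + sum(payload) for arbitrary edit sets."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(200, 2_000))
    wt = {"chr": random_seq(rng, n)}
    edits = random_edits(rng, n)
    mut, _ = tg.apply_edits(wt, tg.AlleleSpec("p", "chr", tuple(edits)))
    removed = sum(e.removed for e in edits)
    added = sum(e.added for e in edits)
    assert len(mut["chr"]) == n - removed + added


class TestKnockin:
    def test_abutting_arms_become_pure_insertion(self, rng):
        wt = {"chr": random_seq(rng, 5_000)}
        left = tg.GenomicInterval("chr", 1_000, 2_000)
        right = tg.GenomicInterval("chr", 2_000, 3_000)
        payload = random_seq(rng, 500)
        spec = tg.build_knockin_allele(wt, payload, left, right, "ki")
        (edit,) = spec.edits
        assert edit.kind == "insertion" and edit.target.start == edit.target.end == 2_000
        mut, _ = tg.apply_edits(wt, spec)
        assert mut["chr"] == wt["chr"][:2_000] + payload + wt["chr"][2_000:]

    def test_printed_arm_geometry_replaces_26_bp(self, rng):
        # homology arms at their published offsets, shifted into a toy host
        shift = 75_268_000
        left = tg.GenomicInterval("chr", 75_268_556 - shift, 75_269_591 - shift)
        right = tg.GenomicInterval("chr", 75_269_617 - shift, 75_270_665 - shift)
        assert right.start - left.end == 26
        wt = {"chr": random_seq(rng, 3_000)}
        payload = random_seq(rng, 4_190)
        spec = tg.build_knockin_allele(wt, payload, left, right, "ki")
        (edit,) = spec.edits
        assert edit.kind == "replacement"
        assert (edit.target.start, edit.target.end) == (left.end, right.start)
        mut, _ = tg.apply_edits(wt, spec)
        # brute-force assembly oracle
        assert mut["chr"] == wt["chr"][: left.end] + payload + wt["chr"][right.start :]
        assert len(mut["chr"]) == 3_000 - 26 + 4_190

    def test_retain_mode_keeps_guide_segment(self, rng):
        wt = {"chr": random_seq(rng, 3_000)}
        left = tg.GenomicInterval("chr", 500, 1_000)
        right = tg.GenomicInterval("chr", 1_026, 1_500)
        payload = random_seq(rng, 200)
        spec = tg.build_knockin_allele(wt, payload, left, right, "ki", mode="retain")
        mut, _ = tg.apply_edits(wt, spec)
        assert mut["chr"] == wt["chr"][:1_000] + payload + wt["chr"][1_000:]

    def test_arms_out_of_order_rejected(self, rng):
        wt = {"chr": random_seq(rng, 2_000)}
        with pytest.raises(EditError):
            tg.build_knockin_allele(
                wt, "ACGT",
                tg.GenomicInterval("chr", 500, 1_100),
                tg.GenomicInterval("chr", 1_000, 1_500),
                "bad",
            )

    def test_arm_bearing_construct_is_stripped_and_verified(self, rng):
        wt = {"chr": random_seq(rng, 2_000)}
        left = tg.GenomicInterval("chr", 200, 400)
        right = tg.GenomicInterval("chr", 420, 600)
        payload = random_seq(rng, 300)
        construct = wt["chr"][200:400] + payload + wt["chr"][420:600]
        spec = tg.build_knockin_allele(wt, construct, left, right, "ki",
                                       construct_includes_arms=True)
        assert spec.edits[0].payload == payload
        with pytest.raises(EditError):
            tg.build_knockin_allele(wt, "AAAA" + construct, left, right, "ki",
                                    construct_includes_arms=True)


class TestSerialization:
    def test_allele_spec_yaml_round_trip(self, rng, tmp_path):
        edits = random_edits(rng, 2_000)
        spec = tg.AlleleSpec("a", "chr", tuple(edits))
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        assert tg.AlleleSpec.from_yaml(path) == spec

    def test_bed_export_marks_inversions(self, tmp_path):
        spec = tg.AlleleSpec("a", "chr", (
            GenomeEdit("inversion", tg.GenomicInterval("chr", 10, 60), label="flip"),
            GenomeEdit("deletion", tg.GenomicInterval("chr", 100, 150), label="gone"),
        ))
        path = tmp_path / "targets.bed"
        spec.targets_to_bed(path)
        lines = [l.split("\t") for l in path.read_text().splitlines()]
        assert [l[3] for l in lines] == ["flip", "gone"]
        assert [l[5] for l in lines] == ["-", "+"]

    def test_chain_export_block_sizes_tile_wt(self, rng, tmp_path):
        wt = {"chr": random_seq(rng, 4_000)}
        edits = random_edits(rng, 4_000)
        spec = tg.AlleleSpec("c", "chr", tuple(edits))
        _, cmap = tg.apply_edits(wt, spec)
        path = tmp_path / "map.chain"
        cmap.to_chain(path)
        text = path.read_text()
        assert text.startswith("chain ")
        aligned = 0
        for line in text.splitlines():
            if line and not line.startswith("chain"):
                aligned += int(line.split()[0])
        deleted = sum(e.removed for e in edits)
        assert aligned == 4_000 - deleted
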