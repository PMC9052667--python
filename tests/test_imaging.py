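"""Image construction, alignment labeling, and training-set assembly."""

import numpy as np
import pysam
import pytest

from squigstr import events, imaging, simulate
from squigstr.imaging import (
    AlignedBaseMap,
    BaseStatus,
    Label,
    aligned_base_map,
    build_image,
    build_read_images,
    generate_training_set,
    label_anchor,
    load_training_set,
    save_training_set,
)
from squigstr.motifs import STRRegion, canonical_group

from conftest import bin_dataset, maps_of


def _bins(L, seed=0):
    return np.random.default_rng(seed).integers(0, 256, size=(L, 50), dtype=np.uint8)


class TestBuildImage:
    def test_channel_layout(self):
        bins = _bins(30)
        img = build_image(bins, j=10, unit_len=3)
        assert img.shape == (50, 3, 3)
        np.testing.assert_array_equal(img[:, :, 0], bins[7:10].T)
        np.testing.assert_array_equal(img[:, :, 1], bins[10:13].T)
        np.testing.assert_array_equal(img[:, :, 2], bins[13:16].T)

    def test_boundary_anchors_yield_no_image(self):
        bins = _bins(30)
        assert build_image(bins, j=0, unit_len=3) is None       # upstream window absent
        assert build_image(bins, j=2, unit_len=3) is None
        assert build_image(bins, j=25, unit_len=3) is None      # downstream window absent
        assert build_image(bins, j=24, unit_len=3) is not None

    def test_identical_unit_profiles_give_equal_channels(self):
        unit_bins = _bins(3, seed=5)
        bins = np.tile(unit_bins, (5, 1))
        img = build_image(bins, j=6, unit_len=3)
        np.testing.assert_array_equal(img[:, :, 0], img[:, :, 1])
        np.testing.assert_array_equal(img[:, :, 1], img[:, :, 2])

    def test_vectorized_equals_per_anchor(self):
        bins = _bins(60, seed=2)
        tensor, anchors = build_read_images(bins, 4)
        assert anchors[0] == 4 and anchors[-1] == 60 - 8
        for t, j in zip(tensor[::7], anchors[::7]):
            np.testing.assert_array_equal(t, build_image(bins, int(j), 4))

    def test_unit_len_below_two_rejected(self):
        with pytest.raises(ValueError):
            build_image(_bins(30), j=10, unit_len=1)

    def test_repeat_images_have_more_channel_overlap_than_nonrepeat(self, het_dataset, het_binned):
        """Over simulator draws, all-channel-active pixels are commoner in
        repeat-interior images than in flank images."""
        region = het_dataset.region
        rates = {"rep": [], "non": []}
        for (raw, table) in het_dataset.reads[:40]:
            bins = het_binned[raw.read_id]
            truth = het_dataset.truth_labels[raw.read_id]
            rep_anchors = np.flatnonzero(truth == Label.REPEAT)[3:-3][::5]
            non_anchors = np.arange(5, 40, 5)  # well inside the left flank
            for key, anchors in (("rep", rep_anchors), ("non", non_anchors)):
                tensor, kept = build_read_images(bins, 3, anchors)
                if kept.size:
                    active = (tensor > 0).all(axis=3)
                    rates[key].append(active.mean())
        assert len(rates["rep"]) * len(rates["non"]) > 0
        assert np.mean(rates["rep"]) > np.mean(rates["non"])


def _map_from_cigar(cigar, chrom="chr1", start=0, read_id="r"):
    header = pysam.AlignmentHeader.from_references([chrom], [100000])
    a = pysam.AlignedSegment(header)
    a.query_name = read_id
    n = sum(l for op, l in cigar if op in (0, 1, 4, 7, 8))
    a.query_sequence = "A" * n
    a.reference_id = 0
    a.reference_start = start
    a.cigartuples = cigar
    a.mapping_quality = 60
    return aligned_base_map(a)


class TestAlignedBaseMap:
    def test_match_insertion_deletion_clip(self):
        # 5M 1I 3M 1D 2M 2I 2M 3S starting at ref 100
        m = _map_from_cigar([(0, 5), (1, 1), (0, 3), (2, 1), (0, 2), (1, 2), (0, 2), (4, 3)], start=100)
        assert list(m.status[:5]) == [BaseStatus.MATCH] * 5
        assert m.status[5] == BaseStatus.INS_1BP
        assert m.status[9] == BaseStatus.DEL_1BP and m.ref_pos[9] == 108
        assert list(m.status[11:13]) == [BaseStatus.LARGE_INS] * 2
        assert list(m.status[-3:]) == [BaseStatus.CLIPPED] * 3
        assert m.ref_pos[0] == 100 and m.ref_pos[6] == 105

    def test_secondary_alignment_rejected(self):
        header = pysam.AlignmentHeader.from_references(["c"], [100])
        a = pysam.AlignedSegment(header)
        a.query_name = "r"
        a.query_sequence = "AAAA"
        a.flag = 256
        a.reference_id = 0
        a.reference_start = 0
        a.cigartuples = [(0, 4)]
        with pytest.raises(ValueError):
            aligned_base_map(a)


class TestLabelAnchor:
    # one 60 bp CAG region at 1000-1060 (M = 60, 1.5 M = 90)
    region = STRRegion("chr1", 1000, 1060, canonical_group("CAG"))

    def test_aligned_inside_region_is_repeat(self):
        m = _map_from_cigar([(0, 200)], start=950)
        assert label_anchor(m, [self.region], 60) == Label.REPEAT

    def test_one_bp_insertion_between_in_region_matches(self):
        m = _map_from_cigar([(0, 60), (1, 1), (0, 100)], start=950)
        # read base 60 is the insertion; neighbors align at 1009 and 1010
        assert label_anchor(m, [self.region], 60) == Label.INS_IN_REPEAT

    def test_one_bp_deletion_inside_region(self):
        m = _map_from_cigar([(0, 60), (2, 1), (0, 100)], start=950)
        assert label_anchor(m, [self.region], 60) == Label.DEL_IN_REPEAT

    def test_margin_rule(self):
        m = _map_from_cigar([(0, 3000)], start=0)
        # aligned at 1060 + 72 = 1132: 1.2*M away -> unlabeled
        assert label_anchor(m, [self.region], 1132) == Label.NO_LABEL
        # aligned at 1060 + 120 - 1: exactly 2*M away -> not-in-repeat
        assert label_anchor(m, [self.region], 1179) == Label.NOT_REPEAT

    def test_clipped_and_large_insertion_unlabeled(self):
        m = _map_from_cigar([(4, 10), (0, 50), (1, 5), (0, 100)], start=995)
        assert label_anchor(m, [self.region], 3) == Label.NO_LABEL     # clipped
        assert label_anchor(m, [self.region], 62) == Label.NO_LABEL    # large insertion

    def test_other_group_region_silences(self):
        other = STRRegion("chr1", 5000, 5060, canonical_group("AGAT"))
        m = _map_from_cigar([(0, 200)], start=4990)
        assert label_anchor(m, [self.region], 50, other_regions=[other]) == Label.NO_LABEL

    def test_out_of_range_anchor_unlabeled(self):
        m = _map_from_cigar([(0, 10)], start=0)
        assert label_anchor(m, [self.region], 99) == Label.NO_LABEL


class TestGenerateTrainingSet:
    def test_chunk_partition_sizes(self, het_training_set):
        ts = het_training_set
        n_rep, n_non = ts.repeat_idx.size, sum(c.size for c in ts.chunks)
        assert len(ts.chunks) == -(-n_non // n_rep)
        assert all(c.size == n_rep for c in ts.chunks[:-1])
        assert 0 < ts.chunks[-1].size <= n_rep
        # chunks are disjoint
        all_idx = np.concatenate(ts.chunks)
        assert np.unique(all_idx).size == all_idx.size

    def test_epoch_plan_cycles_chunks(self, het_training_set):
        ts = het_training_set
        e0 = ts.epoch_indices(0)
        again = ts.epoch_indices(len(ts.chunks))
        np.testing.assert_array_equal(e0, again)

    def test_no_label_images_dropped(self, het_training_set):
        assert np.all(het_training_set.labels != Label.NO_LABEL)

    def test_determinism(self, het_dataset, het_binned):
        import hashlib

        ds = het_dataset
        hashes = []
        for _ in range(2):
            ts = generate_training_set(
                het_binned, maps_of(ds), [ds.region], ds.region.group,
                max_images=800, seed=9,
            )
            h = hashlib.sha256(ts.images.tobytes() + ts.labels.tobytes()).hexdigest()
            hashes.append(h)
        assert hashes[0] == hashes[1]

    def test_region_sampling_cap_is_reproducible(self):
        """250 single-chromosome regions, cap 100: exactly 100 sampled, stable."""
        g = canonical_group("CAG")
        regions = [
            STRRegion("chr1", 10_000 * i, 10_000 * i + 30, g) for i in range(250)
        ]
        runs = []
        for _ in range(2):
            sampled, left_out = imaging.sample_regions(
                regions, 100, np.random.default_rng(1)
            )
            assert len(sampled) == 100 and len(left_out) == 150
            runs.append([r.start for r in sampled])
        assert runs[0] == runs[1]
        other = imaging.sample_regions(regions, 100, np.random.default_rng(2))[0]
        assert [r.start for r in other] != runs[0]

    def test_wrong_group_raises(self, het_dataset, het_binned):
        ds = het_dataset
        with pytest.raises(ValueError, match="AAGG"):
            generate_training_set(
                het_binned, maps_of(ds), [ds.region], canonical_group("AAGG"), seed=1
            )

    def test_channels_rederive_from_bin_event(self, het_dataset, het_binned, het_training_set):
        """Spot-check: stored image columns equal bin_event of the underlying events."""
        ts = het_training_set
        rng = np.random.default_rng(123)
        reads = {raw.read_id: (raw, table) for raw, table in het_dataset.reads}
        for i in rng.choice(ts.labels.size, size=100, replace=False):
            rid, j = ts.read_ids[int(i)], int(ts.anchors[int(i)])
            raw, table = reads[rid]
            samples = np.clip(raw.samples, -5, 5)
            for c, off in ((0, -3), (1, 0), (2, 3)):
                for col in range(3):
                    ev = table.events[j + off + col]
                    expect = events.bin_event(samples[ev.start : ev.end])
                    np.testing.assert_array_equal(ts.images[i][:, col, c], expect)

    def test_shuffled_regions_yield_no_repeat_labels(self, het_dataset, het_binned):
        """Regions placed where no repeat lies produce ~no in-repeat labels."""
        ds = het_dataset
        g = ds.region.group
        bogus = STRRegion(ds.region.chrom, 10, 40, g)  # inside the left flank
        maps = maps_of(ds)
        n_inrep = 0
        for rid in list(het_binned)[:20]:
            labels = imaging.label_read(maps[rid], [bogus])
            n_inrep += int(np.isin(labels, imaging.IN_REPEAT_CLASSES).sum())
        # only the 30 flank bases per read can be labeled in-repeat
        assert n_inrep <= 20 * 30

    def test_save_load_round_trip(self, tmp_path, small_training_set):
        path = str(tmp_path / "ts.npz")
        save_training_set(path, small_training_set)
        back = load_training_set(path)
        np.testing.assert_array_equal(back.images, small_training_set.images)
        np.testing.assert_array_equal(back.labels, small_training_set.labels)
        assert back.group_id == small_training_set.group_id
        assert len(back.chunks) == len(small_training_set.chunks)


def test_reverse_strand_read_maps_to_same_group():
    """A reverse-strand alignment of a CTG read labels against the same motif
    group as its forward CAG mate (groups close under reverse complement)."""
    fwd = canonical_group("CAG")
    rev = canonical_group("CTG")
    assert fwd == rev
    assert "CTG" in fwd and "CAG" in fwd
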