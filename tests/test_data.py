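import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seq2track import (
    HomologyTable,
    Region,
    TrackDataset,
    audit_leakage,
    extract_targets,
    homology_reassign,
    make_regions,
    one_hot_decode,
    one_hot_encode,
    partition_regions,
    subsample_examples,
)
from seq2track.data import read_bed, read_bedgraph_coverage, write_bed, write_bedgraph
from seq2track.errors import DataError, EncodingError, PartitionError


class TestOneHot:
    def test_canonical_mapping(self):
        np.testing.assert_array_equal(
            one_hot_encode("ACGT"),
            [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])

    def test_n_is_all_zero(self):
        np.testing.assert_array_equal(one_hot_encode("N"), [[0, 0, 0, 0]])

    def test_empty_sequence(self):
        assert one_hot_encode("").shape == (0, 4)

    def test_case_folding(self):
        np.testing.assert_array_equal(one_hot_encode("acgtn"),
                                      one_hot_encode("ACGTN"))

    def test_invalid_character_reports_position(self):
        with pytest.raises(EncodingError, match="position 2"):
            one_hot_encode("ACXGT")

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGTN", max_size=200))
    def test_decode_inverts_encode(self, seq):
        assert one_hot_decode(one_hot_encode(seq)) == seq


class TestRegions:
    def test_exact_tiling(self):
        regions = make_regions({"chr1": 1000}, window=300, stride=300)
        assert [(r.start, r.end) for r in regions] == [(0, 300), (300, 600), (600, 900)]

    def test_overlapping_stride(self):
        # valid starts s satisfy s + 300 <= 500, i.e. s in {0, 100, 200}
        regions = make_regions({"chr1": 500}, window=300, stride=100)
        assert [r.start for r in regions] == [0, 100, 200]

    def test_empty_map(self):
        assert make_regions({}, 100, 100) == []

    def test_short_chromosome_contributes_nothing(self):
        regions = make_regions({"tiny": 50, "chr1": 400}, window=100, stride=100)
        assert all(r.chromosome == "chr1" for r in regions)

    def test_invalid_region_rejected(self):
        with pytest.raises(DataError):
            Region("chr1", 100, 100)

    def test_bed_round_trip(self, tmp_path):
        regions = make_regions({"chr1": 900, "chr2": 600}, 300, 300)
        p = tmp_path / "r.bed"
        write_bed(regions, p)
        assert read_bed(p) == regions


class TestPartition:
    def _regions(self, n):
        return make_regions({"chr1": n * 100}, 100, 100)

    def test_exact_fraction_sizes(self):
        split = partition_regions(self._regions(100), (0.8, 0.1, 0.1), seed=0)
        assert split.sizes() == {"train": 80, "validation": 10, "test": 10}

    def test_largest_remainder_tie_goes_to_earlier_group(self):
        split = partition_regions(self._regions(10), (0.75, 0.25, 0.0), seed=0)
        assert split.sizes() == {"train": 8, "validation": 2, "test": 0}

    def test_seed_determinism(self):
        r = self._regions(50)
        a = partition_regions(r, (0.6, 0.2, 0.2), seed=5)
        b = partition_regions(r, (0.6, 0.2, 0.2), seed=5)
        assert a.labels == b.labels
        c = partition_regions(r, (0.6, 0.2, 0.2), seed=6)
        assert a.labels != c.labels

    def test_membership_conserved(self):
        r = self._regions(30)
        split = partition_regions(r, (0.5, 0.3, 0.2), seed=1)
        assert set(split.labels) == set(r)

    def test_too_few_regions(self):
        with pytest.raises(PartitionError):
            partition_regions(self._regions(2), (0.4, 0.3, 0.3), seed=0)

    def test_bad_fractions(self):
        with pytest.raises(PartitionError):
            partition_regions(self._regions(10), (0.5, 0.4, 0.2), seed=0)


class TestHomologyReassign:
    def _worked_example(self):
        regions = [Region("chr1", i * 1000, (i + 1) * 1000) for i in range(10)]
        labels = {r: ("train" if i < 6 else "validation")
                  for i, r in enumerate(regions)}
        from seq2track.data import SplitAssignment
        split = SplitAssignment(labels=labels,
                                provenance={r: "originally_assigned" for r in regions},
                                seed=0)
        table = HomologyTable(pairs=[(regions[7], "ext:a"), (regions[8], "ext:b")])
        return regions, split, table

    def test_worked_example_sizes_and_leakage(self):
        regions, split, table = self._worked_example()
        out = homology_reassign(split, table, seed=3)
        assert out.labels[regions[7]] == "train"
        assert out.labels[regions[8]] == "train"
        assert out.sizes() == {"train": 6, "validation": 4, "test": 0}
        assert audit_leakage(out, table) == 0
        moved_out = [r for r, p in out.provenance.items() if p == "reassigned_out"]
        assert len(moved_out) == 2
        assert all(split.labels[r] == "train" for r in moved_out)
        assert all(out.labels[r] == "validation" for r in moved_out)

    def test_membership_conserved(self):
        regions, split, table = self._worked_example()
        out = homology_reassign(split, table, seed=1)
        assert set(out.labels) == set(split.labels)

    def test_empty_homology_is_identity(self):
        _, split, _ = self._worked_example()
        out = homology_reassign(split, HomologyTable(pairs=[]), seed=0)
        assert out.labels == split.labels

    def test_all_homologous_shortfall_logged_not_fatal(self, caplog):
        regions, split, _ = self._worked_example()
        table = HomologyTable(pairs=[(r, "ext") for r in regions])
        with caplog.at_level("WARNING"):
            out = homology_reassign(split, table, seed=0)
        assert all(l == "train" for l in out.labels.values())
        assert "shortfall" in caplog.text

    def test_unknown_region_rejected(self):
        _, split, _ = self._worked_example()
        table = HomologyTable(pairs=[(Region("chrX", 0, 10), "ext")])
        with pytest.raises(DataError, match="unknown region"):
            homology_reassign(split, table, seed=0)

    def test_tsv_round_trip(self, tmp_path):
        _, _, table = self._worked_example()
        p = tmp_path / "hom.tsv"
        table.write_tsv(p)
        assert HomologyTable.read_tsv(p).pairs == table.pairs


class TestExtractTargets:
    def test_sum_of_ones(self):
        np.testing.assert_array_equal(
            extract_targets(np.ones(256), 128), [128.0, 128.0])

    def test_zeros(self):
        np.testing.assert_array_equal(extract_targets(np.zeros(256), 128), [0, 0])

    def test_single_spike_lands_in_second_bin(self):
        cov = np.zeros(256)
        cov[130] = 1.0
        np.testing.assert_array_equal(extract_targets(cov, 128), [0.0, 1.0])

    def test_negative_signal_rejected(self):
        with pytest.raises(DataError, match="negative"):
            extract_targets(np.array([1.0, -0.5] * 64), 64)

    def test_indivisible_length_rejected(self):
        with pytest.raises(DataError, match="not divisible"):
            extract_targets(np.ones(100), 64)

    def test_bedgraph_round_trip(self, tmp_path):
        region = Region("chr3", 1000, 1256)
        per_bin = np.array([3.0, 7.0])
        p = tmp_path / "cov.bedgraph"
        write_bedgraph(p, region, per_bin, bin_size=128)
        cov = read_bedgraph_coverage(p, region)
        np.testing.assert_array_equal(extract_targets(cov, 128), [3 * 128, 7 * 128])


class TestTrackDataset:
    def test_container_round_trip(self, tmp_path, tiny_dataset):
        p = tmp_path / "data.npz"
        tiny_dataset.save(p)
        back = TrackDataset.load(p)
        np.testing.assert_array_equal(back.seq_codes, tiny_dataset.seq_codes)
        np.testing.assert_array_equal(back.targets, tiny_dataset.targets)
        pd.testing.assert_frame_equal(back.tracks, tiny_dataset.tracks)
        assert back.fingerprint == tiny_dataset.fingerprint
        assert back.split == tiny_dataset.split

    def test_load_rejects_non_container(self, tmp_path):
        p = tmp_path / "junk.npz"
        np.savez(p, a=np.arange(3))
        with pytest.raises(DataError, match="container"):
            TrackDataset.load(p)

    def test_negative_targets_rejected(self, tiny_dataset):
        with pytest.raises(DataError, match="negative"):
            TrackDataset(seq_codes=tiny_dataset.seq_codes,
                         targets=-tiny_dataset.targets - 1,
                         tracks=tiny_dataset.tracks,
                         bin_size=tiny_dataset.bin_size)

    def test_select_tracks(self, tiny_dataset):
        sub = tiny_dataset.select_tracks([2, 0])
        assert sub.num_tracks == 2
        np.testing.assert_array_equal(sub.targets[:, :, 0],
                                      tiny_dataset.targets[:, :, 2])
        assert list(sub.tracks["name"]) == [tiny_dataset.tracks["name"][2],
                                            tiny_dataset.tracks["name"][0]]


class TestSubsample:
    def test_full_subsample_is_identity(self, tiny_dataset):
        out = subsample_examples(tiny_dataset, len(tiny_dataset), seed=0)
        np.testing.assert_array_equal(out.seq_codes, tiny_dataset.seq_codes)
        np.testing.assert_array_equal(out.targets, tiny_dataset.targets)

    def test_empty_subsample_keeps_metadata(self, tiny_dataset):
        out = subsample_examples(tiny_dataset, 0, seed=0)
        assert len(out) == 0
        pd.testing.assert_frame_equal(out.tracks, tiny_dataset.tracks)

    def test_seed_determinism_and_order_preservation(self, tiny_dataset):
        a = subsample_examples(tiny_dataset, 3, seed=4)
        b = subsample_examples(tiny_dataset, 3, seed=4)
        np.testing.assert_array_equal(a.seq_codes, b.seq_codes)
        # order preserved relative to the source: indices are sorted
        src = [tiny_dataset.sequence(i) for i in range(len(tiny_dataset))]
        picked = [src.index(a.sequence(i)) for i in range(3)]
        assert picked == sorted(picked)

    def test_oversample_rejected(self, tiny_dataset):
        with pytest.raises(DataError):
            subsample_examples(tiny_dataset, len(tiny_dataset) + 1, seed=0)
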