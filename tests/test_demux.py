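"""Segment extraction, barcode assignment and UMI counting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scidseq import (
    AssignedRead,
    assign_reads,
    count_umis,
    default_layout,
    extract_segments,
    match_barcode,
    merge_replicate_barcodes,
    simulate_reads,
    truth_count_matrix,
)
from scidseq.demux import BarcodeMatcher, DemuxConfigError
from scidseq.panel import ReadLayout

from conftest import toy_panel

LAYOUT = ReadLayout(well_bc=(0, 8), ab_bc=(8, 10), umi=(18, 15))

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestExtractSegments:
    def test_identity_on_constructed_read(self):
        w, a, u = "AAAACCCC", "ACGTACGTAC", "T" * 15
        assert extract_segments(w + a + u, LAYOUT) == (w, a, u)

    def test_too_short_flagged_at_boundary(self):
        read = "A" * (LAYOUT.min_read_length - 1)
        assert extract_segments(read, LAYOUT) is None
        assert extract_segments("A" * LAYOUT.min_read_length, LAYOUT) is not None

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(seq=dna)
    def test_matches_slicing_oracle(self, seq):
        result = extract_segments(seq, LAYOUT)
        if len(seq) < LAYOUT.min_read_length:
            assert result is None
        else:
            off, ln = LAYOUT.ab_bc
            assert result[1] == seq[off : off + ln]
            assert result[0] == seq[0:8] and result[2] == seq[18:33]


class TestMatchBarcode:
    WHITELIST = ["AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG"]  # pairwise distance 10

    def test_exact_match_distance_zero(self):
        assert match_barcode("CCCCCCCCCC", self.WHITELIST, 1) == ("CCCCCCCCCC", 0)

    def test_single_substitution_corrected(self):
        assert match_barcode("ACCCCCCCCC", self.WHITELIST, 1) == ("CCCCCCCCCC", 1)

    def test_equidistant_observation_rejected(self):
        # two entries differ at exactly 2 positions; observed is midway
        wl = ["AAAAAAAAAA", "CCAAAAAAAA"]
        observed = "CAAAAAAAAA"
        assert match_barcode(observed, wl, 1) is None

    def test_beyond_tolerance_is_no_match(self):
        assert match_barcode("AATTTAAAAA", self.WHITELIST, 1) is None

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            match_barcode("AAAA", self.WHITELIST, 1)

    def test_neighbor_table_agrees_with_bruteforce_scan(self, rng):
        wl = ["".join("ACGT"[b] for b in rng.integers(0, 4, 10)) for _ in range(30)]
        wl = list(dict.fromkeys(wl))
        fast = BarcodeMatcher(wl, 1)
        slow = BarcodeMatcher(wl, 1)
        slow._neighbors = None  # force the Hamming-scan path
        for _ in range(500):
            obs = "".join("ACGT"[b] for b in rng.integers(0, 4, 10))
            assert fast.match(obs) == slow.match(obs)


class TestAssignReads:
    def test_clean_reads_all_assigned_none_corrected(self, small_truth):
        reads, molecules = simulate_reads(small_truth)
        layout = default_layout(small_truth.config.well_bc_len)
        assigned, report = assign_reads(
            reads, layout, small_truth.panel, small_truth.plate
        )
        assert report.n_assigned == report.n_reads_total == len(reads)
        assert report.n_ab_corrected == 0 and report.n_well_corrected == 0

    def test_forced_single_mismatch_all_corrected(self, small_truth):
        reads, _ = simulate_reads(small_truth, force_ab_mismatches=1)
        layout = default_layout(small_truth.config.well_bc_len)
        assigned, report = assign_reads(
            reads, layout, small_truth.panel, small_truth.plate
        )
        assert report.n_assigned == report.n_reads_total
        assert report.n_ab_corrected == report.n_reads_total

    def test_unknown_well_counted_unassigned(self, small_truth):
        layout = default_layout(small_truth.config.well_bc_len)
        tag = small_truth.panel.tags[0]
        foreign_well = "N" * 0 + "TTTTTTTT"
        assert foreign_well not in small_truth.plate.wells
        reads = [foreign_well + tag.barcode + "A" * 15]
        _, report = assign_reads(reads, layout, small_truth.panel, small_truth.plate,
                                 max_mismatch_well=0)
        assert report.n_well_unassigned == 1 and report.n_assigned == 0

    def test_tallies_partition_reads(self, small_truth):
        layout = default_layout(small_truth.config.well_bc_len)
        reads, _ = simulate_reads(small_truth)
        reads += ["ACGT"]  # too short
        _, report = assign_reads(reads, layout, small_truth.panel, small_truth.plate)
        assert report.n_too_short == 1
        total = (report.n_too_short + report.n_ab_unassigned
                 + report.n_well_unassigned + report.n_assigned)
        assert total == report.n_reads_total == len(reads)

    def test_incompatible_mismatch_config_rejected_upfront(self):
        panel = toy_panel(["AAAAAAAAAA", "CAAAAAAAAA"])  # distance 1
        from scidseq import PlateLayout, Well

        plate = PlateLayout({"ACGTACGT": Well("C1", "cell")})
        with pytest.raises(DemuxConfigError, match="min pairwise distance"):
            assign_reads([], LAYOUT, panel, plate, max_mismatch_ab=1)


class TestCountUmis:
    def test_duplicates_collapse_to_one(self, small_truth):
        reads = [AssignedRead("C001", small_truth.panel.names[0], "A" * 15)] * 5
        m = count_umis(reads, small_truth.panel, small_truth.plate)
        assert m.values.loc["C001", small_truth.panel.names[0]] == 1

    def test_matrix_shape_fixed_by_design(self, small_truth):
        m = count_umis([], small_truth.panel, small_truth.plate)
        assert m.shape == (
            small_truth.config.n_cell_wells + small_truth.config.n_empty_wells,
            small_truth.config.panel_size,
        )
        assert (m.values.to_numpy() == 0).all()

    def test_counts_match_distinct_set_oracle(self, small_truth, rng):
        wells = small_truth.plate.well_ids()[:4]
        abs_ = small_truth.panel.names[:3]
        reads = [
            AssignedRead(
                rng.choice(wells),
                rng.choice(abs_),
                "".join("ACGT"[b] for b in rng.integers(0, 4, 15)[:3]) * 5,
            )
            for _ in range(800)
        ]
        m = count_umis(reads, small_truth.panel, small_truth.plate)
        oracle = {}
        for r in reads:
            oracle.setdefault((r.well_id, r.antibody_name), set()).add(r.umi)
        for (w, a), umis in oracle.items():
            assert m.values.loc[w, a] == len(umis)

    def test_order_invariance(self, small_truth):
        reads, _ = simulate_reads(small_truth)
        layout = default_layout(small_truth.config.well_bc_len)
        a1, _ = assign_reads(reads, layout, small_truth.panel, small_truth.plate)
        a2 = list(reversed(a1))
        m1 = count_umis(a1, small_truth.panel, small_truth.plate)
        m2 = count_umis(a2, small_truth.panel, small_truth.plate)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_roundtrip_reproduces_simulator_truth(self, small_truth):
        reads, _ = simulate_reads(small_truth)
        layout = default_layout(small_truth.config.well_bc_len)
        assigned, _ = assign_reads(reads, layout, small_truth.panel, small_truth.plate)
        m = count_umis(assigned, small_truth.panel, small_truth.plate)
        pd.testing.assert_frame_equal(m.values, small_truth.true_counts)

    def test_directional_collapse_merges_single_mismatch_umis(self, small_truth):
        name = small_truth.panel.names[0]
        reads = [
            AssignedRead("C001", name, "A" * 15),
            AssignedRead("C001", name, "C" + "A" * 14),  # 1 mismatch away
            AssignedRead("C001", name, "C" * 15),
        ]
        exact = count_umis(reads, small_truth.panel, small_truth.plate, "exact")
        directional = count_umis(reads, small_truth.panel, small_truth.plate, "directional")
        assert exact.values.loc["C001", name] == 3
        assert directional.values.loc["C001", name] == 2


class TestReplicateBarcodes:
    def test_identical_columns_correlate_perfectly(self, small_truth):
        panel = toy_panel(
            ["AAAAAAAAAA", "CCCCCCCCCC"], replicate_group="g"
        )
        values = pd.DataFrame(
            {"Ab0": [1, 5, 9, 2], "Ab1": [1, 5, 9, 2]},
            index=pd.Index([f"C{i}" for i in range(4)], name="well_id"),
        )
        row_meta = pd.DataFrame(
            {"well_type": "cell", "gate_label": "none", "total_umis": values.sum(axis=1)},
            index=values.index,
        )
        from scidseq import CountMatrix

        m = CountMatrix(values, row_meta, panel.to_frame().set_index("antibody_name"), "raw")
        corr, merged = merge_replicate_barcodes(m, panel, merge=True)
        assert corr["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert (merged.values["g"] == values["Ab0"] + values["Ab1"]).all()

    def test_correlations_match_direct_oracle(self, default_truth):
        from scidseq import simulate_replicate_barcodes

        panel, original, reps = simulate_replicate_barcodes(default_truth)
        row_meta = pd.DataFrame(
            {"well_type": "cell", "gate_label": "none", "total_umis": reps.sum(axis=1)},
            index=reps.index,
        )
        from scidseq import CountMatrix

        m = CountMatrix(reps, row_meta, panel.to_frame().set_index("antibody_name"), "raw")
        corr, _ = merge_replicate_barcodes(m, panel)
        assert len(corr) == 5 * (9 * 8 // 2)
        for _, row in corr.sample(20, random_state=0).iterrows():
            x = reps[row["member_a"]].to_numpy(dtype=float)
            y = reps[row["member_b"]].to_numpy(dtype=float)
            mx, my = x.mean(), y.mean()
            oracle = float(
                np.sum((x - mx) * (y - my))
                / np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
            )
            assert row["pearson_r"] == pytest.approx(oracle, abs=1e-12)
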