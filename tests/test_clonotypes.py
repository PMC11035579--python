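"""Clonotype construction, pairing taxonomy and diversity statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dogtcr.clonotypes import (build_clonotypes, classify_pairing,
                               clonotype_bin_proportions, diversity,
                               downsample_diversity, inverse_simpson,
                               length_distributions, pairing_summary,
                               segment_usage, subset_diversity, summary_metrics)


def _ann_row(barcode, chain, cdr3_nt, productive=True, **kw):
    base = {
        "barcode": barcode, "contig_id": f"{barcode}_{chain}_{cdr3_nt[:6]}",
        "chain": chain, "v_call": kw.get("v_call", f"{chain}V1*01"),
        "j_call": kw.get("j_call", f"{chain}J1*01"), "v_identity": 1.0,
        "j_identity": 1.0, "cdr3_nt": cdr3_nt,
        "cdr3_aa": kw.get("cdr3_aa", "CASF"), "frame_offset": 0,
        "has_stop": False, "full_length": True, "productive": productive,
        "contig_length": 500, "umi_count": kw.get("umi_count", 5),
        "flags": kw.get("flags", ""), "reason": None,
    }
    return base


class TestBuildClonotypes:
    def test_identical_cdr3_sets_group(self):
        ann = pd.DataFrame([
            _ann_row("bc1", "TRA", "TGTGCATTT"), _ann_row("bc1", "TRB", "TGTGCCTTT"),
            _ann_row("bc2", "TRA", "TGTGCATTT"), _ann_row("bc2", "TRB", "TGTGCCTTT"),
        ])
        cts, cell_map = build_clonotypes(ann)
        assert len(cts) == 1
        assert cts.iloc[0]["n_cells"] == 2
        assert set(cell_map["barcode"]) == {"bc1", "bc2"}

    def test_silent_nt_difference_splits(self):
        ann = pd.DataFrame([
            _ann_row("bc1", "TRA", "TGTGCATTT"),
            _ann_row("bc2", "TRA", "TGTGCGTTT"),  # same aa, one nt apart
        ])
        cts, _ = build_clonotypes(ann)
        assert len(cts) == 2

    def test_unproductive_cells_excluded_and_counted(self):
        ann = pd.DataFrame([
            _ann_row("bc1", "TRA", "TGTGCATTT"),
            _ann_row("bc2", "TRA", "TGTGCATTT", productive=False),
        ])
        cts, cell_map = build_clonotypes(ann)
        assert cts["n_cells"].sum() == 1
        assert cts.attrs["n_cells_excluded"] == 1

    def test_recovers_truth_partition(self, small_repertoire, small_annotations):
        _, truth = small_repertoire
        cts, cell_map = build_clonotypes(small_annotations)
        recovered = cell_map.merge(truth.cells, on="barcode")
        # identical partitions: clonotype ids and clone ids are bijective
        pairs = recovered.groupby(["clonotype_id", "clone_id"]).size().reset_index()
        assert pairs["clonotype_id"].is_unique
        assert pairs["clone_id"].is_unique


class TestPairing:
    @pytest.mark.parametrize("chains,expected", [
        ((("TRA", "x"), ("TRB", "y")), "single_pair"),
        ((("TRA", "x"),), "tra_only"),
        ((("TRB", "y"),), "trb_only"),
        ((("TRA", "x"), ("TRA", "z"), ("TRB", "y")), "extra_tra"),
        ((("TRA", "x"), ("TRB", "y"), ("TRB", "z")), "extra_trb"),
        ((("TRA", "x"), ("TRA", "w"), ("TRB", "y"), ("TRB", "z")), "extra_both"),
        ((("TRA", "x"), ("TRA", "w"), ("TRA", "v"), ("TRB", "y")), "gt2_chains"),
    ])
    def test_category_table(self, chains, expected):
        assert classify_pairing(chains) == expected

    def test_no_chain_clonotype_is_internal_error(self):
        with pytest.raises(ValueError):
            classify_pairing(())

    def test_fractions_sum_to_one(self, small_annotations):
        cts, _ = build_clonotypes(small_annotations)
        summary = pairing_summary(cts)
        assert abs(sum(summary.values()) - 1.0) < 1e-12

    def test_all_single_pair(self):
        ann = pd.DataFrame([
            _ann_row("bc1", "TRA", "TGTGCATTT"), _ann_row("bc1", "TRB", "TGTGCCTTT"),
        ])
        cts, _ = build_clonotypes(ann)
        summary = pairing_summary(cts)
        assert summary["single_pair"] == 1.0
        assert all(v == 0.0 for k, v in summary.items() if k != "single_pair")


class TestInverseSimpson:
    def test_boundaries(self):
        assert inverse_simpson([1.0]) == 1.0
        n = 100
        assert inverse_simpson([1 / n] * n) == pytest.approx(n)

    def test_hand_computed_example(self):
        assert inverse_simpson([0.5, 0.25, 0.25]) == pytest.approx(1 / 0.375)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            inverse_simpson([])
        with pytest.raises(ValueError):
            inverse_simpson([0.4, 0.4])
        with pytest.raises(ValueError):
            inverse_simpson([1.5, -0.5])

    @given(st.lists(st.integers(1, 500), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds_and_concentration_monotonicity(self, counts):
        c = np.array(sorted(counts, reverse=True), dtype=float)
        p = c / c.sum()
        isi = inverse_simpson(p)
        assert 1.0 - 1e-9 <= isi <= len(c) + 1e-9
        if len(c) > 1 and c[-1] > 0:
            # move one cell from the smallest clone to the largest
            c2 = c.copy()
            c2[0] += 1
            c2[-1] -= 1
            c2 = c2[c2 > 0]
            assert inverse_simpson(c2 / c2.sum()) <= isi + 1e-9


class TestRankBins:
    def test_monoclonal_mass_in_first_bin(self):
        assert clonotype_bin_proportions([50])["1"] == 1.0

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bin_fractions_sum_to_one(self, counts):
        fr = clonotype_bin_proportions(counts)
        assert abs(sum(fr.values()) - 1.0) < 1e-12


class TestDownsampling:
    def test_single_clonotype_diversity_is_one(self):
        res = downsample_diversity(["A"] * 500, n_target=500, n_perm=10, seed=0)
        assert res["inverse_simpson"] == pytest.approx(1.0)
        assert res["bin_fractions"]["1"] == pytest.approx(1.0)

    def test_defaults_match_study_protocol(self):
        res = downsample_diversity(["A", "B"] * 50, seed=0)
        assert res["n_target"] == 1850
        assert res["n_perm"] == 100

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            downsample_diversity([], n_target=10)
        with pytest.raises(ValueError):
            downsample_diversity(["A"], n_perm=0)


class TestSubsetDiversity:
    def test_single_label_equals_whole_sample(self):
        cell_map = pd.DataFrame({
            "barcode": [f"b{i}" for i in range(10)],
            "clonotype_id": ["c1"] * 6 + ["c2"] * 4,
        })
        types = pd.DataFrame({"barcode": cell_map["barcode"], "cell_type": "CD8"})
        res = subset_diversity(cell_map, types)
        assert len(res) == 1
        counts = np.array([6, 4], float)
        assert res.iloc[0]["inverse_simpson"] == pytest.approx(
            inverse_simpson(counts / counts.sum())
        )
        assert res.iloc[0]["top_clone_proportion"] == pytest.approx(0.6)

    def test_restricted_dominant_clone(self):
        rows = []
        for i in range(100):
            rows.append({"barcode": f"cd8_{i}", "clonotype_id": "dom" if i < 92 else f"c{i}"})
        for i in range(100):
            rows.append({"barcode": f"cd4_{i}", "clonotype_id": f"d{i}"})
        cell_map = pd.DataFrame(rows)
        types = pd.DataFrame({
            "barcode": cell_map["barcode"],
            "cell_type": ["CD8"] * 100 + ["CD4"] * 100,
        })
        res = subset_diversity(cell_map, types).set_index("cell_type")
        assert res.loc["CD8", "top_clone_proportion"] == pytest.approx(0.92)
        assert res.loc["CD4", "inverse_simpson"] == pytest.approx(100.0)
        assert res["n_cells"].sum() == 200

    def test_unlabeled_excluded_and_counted(self):
        cell_map = pd.DataFrame({"barcode": ["a", "b"], "clonotype_id": ["c1", "c1"]})
        types = pd.DataFrame({"barcode": ["a"], "cell_type": ["CD4"]})
        res = subset_diversity(cell_map, types)
        assert res.attrs["n_unlabeled"] == 1


class TestUsageAndLengths:
    def test_full_functional_coverage_at_scale(self, default_ref, small_annotations):
        cts, cell_map = build_clonotypes(small_annotations)
        usage = segment_usage(small_annotations, default_ref, cell_map=cell_map)
        census = usage["coverage_census"]
        functional = census[census["functional_class"] == "functional"]
        assert (functional["coverage"] == 1.0).all()
        assert usage["unknown_segments"] == []

    def test_zero_weight_segment_unobserved(self, default_ref, small_annotations):
        usage = segment_usage(small_annotations, default_ref)
        census = usage["coverage_census"]
        pseudo = census[census["functional_class"] == "pseudogene"]
        assert (pseudo["n_observed"] == 0).all()

    def test_matrix_total_counts_chain_observations(self, small_annotations):
        from dogtcr.refdata import default_reference

        usage = segment_usage(small_annotations, default_reference())
        n_productive = int(small_annotations["productive"].sum())
        assert usage["usage_matrix"]["n_cells"].sum() == n_productive

    def test_reference_combination_lengths(self, default_ref, small_annotations):
        res = length_distributions(small_annotations, default_ref)
        combos = res["reference_combinations"]
        tra = combos[combos["chain"] == "TRA"]
        vs = default_ref.select("TRA", "V")
        js = default_ref.select("TRA", "J")
        assert len(tra) == len(vs) * len(js)
        v0, j0 = vs[0], js[0]
        row = tra[(tra["v"] == v0.key) & (tra["j"] == j0.key)]
        assert int(row["length"].iloc[0]) == len(v0) + len(j0)

    def test_single_contig_median(self):
        ann = pd.DataFrame([_ann_row("bc1", "TRA", "TGTGCATTT")])
        res = length_distributions(ann)
        assert res["observed"]["TRA"]["contig_nt"]["median"] == 500.0


class TestSummaryMetrics:
    def test_hand_checked_five_cell_fixture(self):
        rows = [
            _ann_row("c1", "TRA", "TGTGCATTT"), _ann_row("c1", "TRB", "TGTGCCTTT"),
            _ann_row("c2", "TRA", "TGTGAATTT"), _ann_row("c2", "TRB", "TGTGCCTTT"),
            _ann_row("c3", "TRB", "TGTGGCTTT"),
            _ann_row("c4", "TRA", "TGTACATTT", productive=False),
            _ann_row("c5", "TRA", "TGTGCATTT"), _ann_row("c5", "TRB", "TGTGCCTTT"),
        ]
        ann = pd.DataFrame(rows)
        cts, _ = build_clonotypes(ann)
        m = summary_metrics(ann, cts)
        assert m["estimated_cells"] == 5
        assert m["cells_with_tra_contig"] == pytest.approx(4 / 5)
        assert m["cells_with_productive_tra"] == pytest.approx(3 / 5)
        assert m["cells_with_productive_pair"] == pytest.approx(3 / 5)
        # clonotypes: {c1,c5} identical, c2, c3 -> 3; diversity over (2,1,1)
        assert m["unique_clonotypes"] == 3
        p = np.array([2, 1, 1]) / 4
        assert m["paired_clonotype_diversity"] == pytest.approx(
            inverse_simpson(p)
        )

    def test_all_productive_paired_sample(self, small_annotations):
        cts, _ = build_clonotypes(small_annotations)
        m = summary_metrics(small_annotations, cts)
        assert m["cells_with_productive_pair"] == 1.0
        assert m["unique_clonotypes"] == len(cts)
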