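"""Repertoire simulator: rearrangement bookkeeping, profiles, pairing,
defect planting, export round trips."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dogtcr._seq import STOP_CODONS, has_stop, translate
from dogtcr.clonotypes import inverse_simpson
from dogtcr.io import read_airr
from dogtcr.simulate import (PAIRING_PERFECT, PAIRING_V2, ClonalityProfile,
                             InsertionModel, PlantedRescue, SimulationConfig,
                             TrimModel, export_simulation,
                             plant_defect_and_rescue, simulate_rearrangement,
                             simulate_repertoire, simulate_rescue_study)

NO_TRIM = TrimModel(max_trim=0)
NO_INS = InsertionModel(max_ins=0)


def _productivity_oracle(ct, refset):
    """Brute-force: rebuild the coding region from the truth components and
    translate-and-scan it, independent of the simulator's own logic."""
    v = refset.get(ct.v_key)
    j = refset.get(ct.j_key)
    d_part = ""
    if ct.d_key is not None:
        d = refset.get(ct.d_key)
        d_part = d.nt_sequence[ct.d_trim5 : len(d) - ct.d_trim3]
    coding = (
        v.nt_sequence[: len(v) - ct.v_trim] + ct.ins1 + d_part + ct.ins2
        + j.nt_sequence[ct.j_trim :]
    )
    anchor_pos = len(coding) - (len(j) - ct.j_trim) + (j.jmotif_anchor - ct.j_trim)
    aa = translate(coding)
    cys_idx = v.cys_anchor // 3
    if anchor_pos % 3 != 0:
        return False
    if "*" in aa:
        return False
    if cys_idx >= len(aa) or aa[cys_idx] != "C":
        return False
    return aa[anchor_pos // 3] in "FW"


class TestSimulateRearrangement:
    def test_identity_case_is_exact_concatenation(self, default_ref):
        rng = np.random.default_rng(0)
        ct = simulate_rearrangement(default_ref, "TRA", rng, trim=NO_TRIM,
                                    insertion=NO_INS)
        v = default_ref.get(ct.v_key)
        j = default_ref.get(ct.j_key)
        c = default_ref.get(ct.c_key)
        assert ct.contig_nt == v.nt_sequence + j.nt_sequence + c.nt_sequence

    def test_fixed_seed_reproducible(self, default_ref):
        draws = [
            simulate_rearrangement(default_ref, "TRB", np.random.default_rng(42))
            for _ in range(2)
        ]
        assert draws[0] == draws[1]

    def test_unknown_chain_rejected(self, default_ref):
        with pytest.raises(ValueError, match="chain"):
            simulate_rearrangement(default_ref, "TRG", np.random.default_rng(0))

    @pytest.mark.parametrize("chain", ["TRA", "TRB"])
    def test_truth_matches_translate_and_scan_oracle(self, default_ref, chain):
        rng = np.random.default_rng(7)
        for _ in range(500):
            ct = simulate_rearrangement(default_ref, chain, rng)
            assert ct.truth_productive == _productivity_oracle(ct, default_ref)

    def test_productive_implies_in_frame_junction(self, default_ref):
        rng = np.random.default_rng(3)
        for _ in range(300):
            ct = simulate_rearrangement(default_ref, "TRA", rng)
            if ct.truth_productive:
                assert len(ct.truth_cdr3_nt) % 3 == 0
                assert ct.truth_cdr3_aa == translate(ct.truth_cdr3_nt)
                assert ct.truth_cdr3_aa[0] == "C"
                assert ct.truth_cdr3_aa[-1] in "FW"


class TestSimulateRepertoire:
    def test_single_cell(self, default_ref):
        cfg = SimulationConfig(seed=1, n_cells=1, pairing=dict(PAIRING_PERFECT))
        cells, truth = simulate_repertoire(default_ref, cfg)
        assert len(cells) == 1
        assert len(truth.cells) == 1
        assert truth.cells["clone_id"].nunique() == 1

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError, match="n_cells"):
            SimulationConfig(seed=1, n_cells=0)

    def test_cell_count_conserved_and_barcodes_unique(self, small_repertoire):
        cells, truth = small_repertoire
        assert len(cells) == 200
        barcodes = [c.barcode for c in cells]
        assert len(set(barcodes)) == len(barcodes)

    def test_contig_reassembles_from_components(self, default_ref, small_repertoire):
        cells, _ = small_repertoire
        for cell in cells:
            for ct in cell.contigs:
                v = default_ref.get(ct.v_key)
                j = default_ref.get(ct.j_key)
                c = default_ref.get(ct.c_key)
                d_part = ""
                if ct.d_key is not None:
                    d = default_ref.get(ct.d_key)
                    d_part = d.nt_sequence[ct.d_trim5 : len(d) - ct.d_trim3]
                rebuilt = (
                    v.nt_sequence[: len(v) - ct.v_trim] + ct.ins1 + d_part
                    + ct.ins2 + j.nt_sequence[ct.j_trim :] + c.nt_sequence
                )
                assert ct.contig_nt == rebuilt

    def test_clone_members_share_cdr3s(self, small_repertoire):
        cells, truth = small_repertoire
        by_clone = {}
        for c in cells:
            key = tuple(sorted((ct.chain, ct.truth_cdr3_nt) for ct in c.contigs))
            by_clone.setdefault(c.clone_id, set()).add(key)
        assert all(len(v) == 1 for v in by_clone.values())
        for clone_id, keys in by_clone.items():
            assert keys == {truth.clone_cdr3[clone_id]}

    def test_monoclonal_dominant_fraction(self, default_ref):
        cfg = SimulationConfig(
            seed=9, n_cells=4000, profile=ClonalityProfile.monoclonal(0.88),
            pairing=dict(PAIRING_PERFECT),
        )
        _, truth = simulate_repertoire(default_ref, cfg)
        top = truth.cells["clone_id"].value_counts().iloc[0] / 4000
        sigma = (0.88 * 0.12 / 4000) ** 0.5
        assert abs(top - 0.88) <= 3 * sigma

    def test_polyclonal_diversity_scales_with_clones(self, default_ref):
        # default study conditions (v2 pairing noise included): realized
        # clonotype frequencies stay at least half as diverse as the
        # configured clone count
        cfg = SimulationConfig(
            seed=12, n_cells=2000, profile=ClonalityProfile.polyclonal(2000),
        )
        cells, _ = simulate_repertoire(default_ref, cfg)
        keys = Counter(
            tuple(sorted((ct.chain, ct.truth_cdr3_nt) for ct in c.contigs))
            for c in cells
        )
        counts = np.array(list(keys.values()), float)
        isi = inverse_simpson(counts / counts.sum())
        assert isi >= 0.5 * 2000

    def test_determinism_end_to_end(self, default_ref):
        cfg = SimulationConfig(seed=33, n_cells=50)
        a_cells, a_truth = simulate_repertoire(default_ref, cfg)
        b_cells, b_truth = simulate_repertoire(default_ref, cfg)
        assert [c.barcode for c in a_cells] == [c.barcode for c in b_cells]
        assert all(
            x.contigs[i].contig_nt == y.contigs[i].contig_nt
            for x, y in zip(a_cells, b_cells)
            for i in range(len(x.contigs))
        )
        assert a_truth.contigs.equals(b_truth.contigs)


class TestPairingModel:
    def test_degenerate_preset_keeps_one_pair(self, small_repertoire):
        cells, _ = small_repertoire
        for c in cells:
            chains = Counter(ct.chain for ct in c.contigs)
            assert chains == {"TRA": 1, "TRB": 1}

    def test_probabilities_must_sum_to_one(self):
        bad = dict(PAIRING_V2)
        bad["single_pair"] -= 0.1
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(seed=0, n_cells=10, pairing=bad)

    def test_categories_shape_chain_counts(self, default_ref):
        cfg = SimulationConfig(seed=21, n_cells=400)
        cells, _ = simulate_repertoire(default_ref, cfg)
        expected = {
            "single_pair": (1, 1), "tra_only": (1, 0), "trb_only": (0, 1),
            "extra_tra": (2, 1), "extra_trb": (1, 2), "extra_both": (2, 2),
        }
        for c in cells:
            chains = Counter(ct.chain for ct in c.contigs)
            assert (chains.get("TRA", 0), chains.get("TRB", 0)) == expected[
                c.pairing_category
            ]

    def test_extra_chains_are_productive_and_distinct(self, default_ref):
        cfg = SimulationConfig(seed=22, n_cells=300)
        cells, _ = simulate_repertoire(default_ref, cfg)
        for c in cells:
            if c.pairing_category.startswith("extra"):
                for chain in ("TRA", "TRB"):
                    cdr3s = [ct.truth_cdr3_nt for ct in c.contigs if ct.chain == chain]
                    assert len(set(cdr3s)) == len(cdr3s)
                assert all(ct.truth_productive for ct in c.contigs)


class TestDefectPlanting:
    def test_no_plan_leaves_reference_untouched(self, default_ref):
        overrides, j_min, truth = plant_defect_and_rescue(default_ref, [])
        assert overrides == {}
        assert j_min == {}

    def test_germline_snv_only_in_carrier(self, default_ref):
        plan = [PlantedRescue("TRBV19*01", "germline_snv", donors=("dA",))]
        overrides, _, truth = plant_defect_and_rescue(default_ref, plan)
        base = default_ref.get("TRBV19*01").nt_sequence
        fixed = overrides["dA"].get("TRBV19*01").nt_sequence
        assert fixed != base
        diff = [i for i, (a, b) in enumerate(zip(base, fixed)) if a != b]
        assert diff == [309]  # TAG -> CAG at amino-acid position 104
        assert base[309:312] == "TAG" and fixed[309:312] == "CAG"

    def test_junctional_rescue_outside_window_rejected(self, default_ref):
        with pytest.raises(ValueError, match="junction"):
            plant_defect_and_rescue(
                default_ref,
                [PlantedRescue("TRBV19*01", "junctional")],
            )

    def test_carrier_restriction_of_germline_rescue(self, default_ref, rescue_edits):
        plan = [PlantedRescue("TRBV19*01", "germline_snv", donors=("dB",))]
        cells, truth = simulate_rescue_study(
            default_ref, plan, donors=("dA", "dB"), cells_per_donor=60, seed=5
        )
        users = {
            cell.donor_id
            for cell in cells
            for ct in cell.contigs
            if ct.v_key == "TRBV19*01" and ct.truth_productive
        }
        assert users == {"dB"}

    def test_junctional_rescue_in_all_donors(self, default_ref):
        plan = [PlantedRescue("TRBJ1-3*01", "junctional")]
        cells, truth = simulate_rescue_study(
            default_ref, plan, donors=("dA", "dB", "dC"), cells_per_donor=60, seed=6
        )
        seg = default_ref.get("TRBJ1-3*01")
        users = {}
        for cell in cells:
            for ct in cell.contigs:
                if ct.j_key == "TRBJ1-3*01" and ct.truth_productive:
                    users.setdefault(cell.donor_id, 0)
                    users[cell.donor_id] += 1
                    assert ct.j_trim >= 6  # the 5' stop codon is trimmed away
        assert set(users) == {"dA", "dB", "dC"}


class TestExport:
    def test_round_trip_and_determinism(self, default_ref, tmp_path):
        cfg = SimulationConfig(seed=8, n_cells=30)
        cells, truth = simulate_repertoire(default_ref, cfg)
        paths1 = export_simulation(cells, truth, tmp_path / "a")
        airr = read_airr(paths1["airr"])
        n_contigs = sum(len(c.contigs) for c in cells)
        assert len(airr) == n_contigs
        assert set(airr["cell_id"]) == {c.barcode for c in cells}
        cells2, truth2 = simulate_repertoire(default_ref, cfg)
        paths2 = export_simulation(cells2, truth2, tmp_path / "b")
        for key in paths1:
            assert paths1[key].read_bytes() == paths2[key].read_bytes()


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_trim_and_insertion_respect_bounds(seed):
    rng = np.random.default_rng(seed)
    trim = TrimModel()
    ins = InsertionModel()
    k = trim.sample(rng)
    s = ins.sample(rng)
    assert 0 <= k <= trim.max_trim
    assert 0 <= len(s) <= ins.max_ins
    assert set(s) <= set("ACGT")
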