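"""Pseudogene rescue: diff enumeration, donor-reference inference, defect
assessment and re-annotation proposals."""

import numpy as np
import pandas as pd
import pytest

from dogtcr.refdata import apply_edits, build_default_reference
from dogtcr.reference import Defect, GeneSegment
from dogtcr.rescue import (DefectAssessment, SequenceDiff,
                           align_consensus_to_segment, assess_defects,
                           collect_segment_consensus, infer_donor_reference,
                           propose_reannotation)


def _segment(seq, sid="VX", seg_class="V", defects=()):
    return GeneSegment(sid, "01", "TRB", seg_class, seq, defects=list(defects))


class TestDiffEnumeration:
    def test_identical_sequences_no_diffs(self):
        seg = _segment("ACGTAGGTCCATTGCA" * 8)
        assert align_consensus_to_segment(seg.nt_sequence, seg) == []

    def test_single_planted_snv(self):
        seq = "ACGTAGGTCCATTGCA" * 8
        seg = _segment(seq)
        obs = seq[:37] + "C" + seq[38:]
        assert seq[37] != "C"
        diffs = align_consensus_to_segment(obs, seg)
        assert len(diffs) == 1
        d = diffs[0]
        assert (d.kind, d.segment_position, d.ref_allele, d.obs_allele) == (
            "SNV", 37, seq[37], "C")

    # a non-repetitive 120-nt segment; planted edits below are chosen so no
    # equal-cost alternative placement exists (neighbors differ everywhere)
    BASE = ("ATCAGTCGATCGTAGCTAGCATGCACGTGACTGATCGATGCTAGCTACGATCGTACGTAGC"
            "TAGCATCGATGCACTGACGTAGCTAGCATCGTACGATGCTAGCACGATCGTAGCATCGA")

    @pytest.mark.parametrize("planted", [
        [("SNV", 20, "C"), ("SNV", 50, "A")],
        [("insertion", 30, "T")],
        [("deletion", 40, "")],
        [("SNV", 10, "G"), ("insertion", 60, "T"), ("deletion", 100, "")],
    ])
    def test_brute_force_oracle_small_instances(self, planted):
        """Planted-edit oracle: the observed sequence is built by direct
        string surgery; the aligner must report exactly the planted edits."""
        seq = self.BASE
        seg = _segment(seq)
        obs = seq
        expected = set()
        for kind, pos, allele in sorted(planted, key=lambda x: -x[1]):
            if kind == "SNV":
                assert seq[pos] != allele
                expected.add(("SNV", pos, seq[pos], allele))
                obs = obs[:pos] + allele + obs[pos + 1 :]
            elif kind == "insertion":
                assert seq[pos - 1] != allele and seq[pos] != allele
                expected.add(("insertion", pos, "", allele))
                obs = obs[:pos] + allele + obs[pos:]
            else:
                assert seq[pos - 1] != seq[pos]
                expected.add(("deletion", pos, seq[pos], ""))
                obs = obs[:pos] + obs[pos + 1 :]
        diffs = align_consensus_to_segment(obs, seg)
        got = {(d.kind, d.segment_position, d.ref_allele, d.obs_allele) for d in diffs}
        assert got == expected

    def test_indels_left_normalized(self):
        # insertion of A inside an AAA homopolymer must report the leftmost slot
        seq = "CGTCGTAAACGTCGTCGCCGGCGATTACCGGTTAACCGGATCG" * 3
        seg = _segment(seq)
        pos = seq.index("AAA")
        obs = seq[: pos + 2] + "A" + seq[pos + 2 :]
        diffs = align_consensus_to_segment(obs, seg)
        assert len(diffs) == 1
        assert diffs[0].kind == "insertion"
        assert diffs[0].segment_position == pos

    def test_low_identity_not_covered(self):
        seg = _segment("ACGT" * 40)
        assert align_consensus_to_segment("TTTTGGGG" * 20, seg) is None

    def test_trav92_donor_consensus_has_nine_diffs(self, default_ref, rescue_edits):
        seg = default_ref.get("TRAV9-2*01")
        donor = apply_edits(seg.nt_sequence, rescue_edits["TRAV9-2*01"])
        diffs = align_consensus_to_segment(donor, seg)
        kinds = sorted(d.kind for d in diffs)
        assert len(diffs) == 9
        assert kinds.count("SNV") == 8
        assert kinds.count("insertion") == 1


class TestDonorReference:
    def _mk(self, pos, shared_in, total, kind="SNV", window=False):
        table = {}
        for i in range(total):
            diffs = []
            if i < shared_in:
                diffs.append(SequenceDiff(kind, pos, "A", "G",
                                          in_junction_window=window))
            table[f"ct{i}"] = diffs
        return table

    def test_fully_shared_variant_recovered(self):
        shared = infer_donor_reference(self._mk(50, 20, 20))
        assert shared == {("SNV", 50, "A", "G")}

    def test_rare_variant_excluded(self):
        assert infer_donor_reference(self._mk(50, 1, 20)) == set()

    def test_junction_window_variant_excluded(self):
        assert infer_donor_reference(self._mk(2, 20, 20, window=True)) == set()

    def test_single_clonotype_unresolved(self):
        assert infer_donor_reference(self._mk(50, 1, 1)) == set()


class TestAssessment:
    def test_retained_defect(self, default_ref):
        seg = default_ref.get("TRBV19*01")
        table = pd.DataFrame([
            {"donor": "dA", "clonotype_id": f"ct{i}",
             "consensus_nt": seg.nt_sequence + "ACGTACGTACGT"}
            for i in range(3)
        ])
        (a,) = assess_defects(seg, table)
        assert a.status == "retained"

    def test_not_covered_without_usage(self, default_ref):
        seg = default_ref.get("TRBV19*01")
        table = pd.DataFrame(columns=["donor", "clonotype_id", "consensus_nt"])
        (a,) = assess_defects(seg, table)
        assert a.status == "not_covered"
        assert a.mechanism == "unresolved"

    def test_germline_corrected_stop(self, default_ref, rescue_edits):
        seg = default_ref.get("TRBV19*01")
        fixed = seg.nt_sequence[:309] + "C" + seg.nt_sequence[310:]
        table = pd.DataFrame([
            {"donor": "dA", "clonotype_id": f"ct{i}",
             "consensus_nt": fixed + "ACGATT"}
            for i in range(4)
        ])
        (a,) = assess_defects(seg, table)
        assert a.status == "corrected"
        assert a.mechanism == "germline_shared"
        assert a.evidence[0].key() == ("SNV", 309, "T", "C")

    def test_order_invariance(self, default_ref, rescue_edits):
        refset, edits = build_default_reference()
        seg = refset.get("TRAV9-2*01")
        donor = apply_edits(seg.nt_sequence, edits["TRAV9-2*01"])
        rows = [
            {"donor": d, "clonotype_id": f"ct{i}", "consensus_nt": donor + tail}
            for d in ("dA", "dB")
            for i, tail in enumerate(["ACG", "TTA", "GGC"])
        ]
        fwd = assess_defects(seg, pd.DataFrame(rows))
        rev = assess_defects(seg, pd.DataFrame(rows[::-1]))
        assert [(a.status, a.mechanism) for a in fwd] == [
            (a.status, a.mechanism) for a in rev
        ]
        assert all(a.status == "corrected" and a.mechanism == "germline_shared"
                   for a in fwd)


class TestEndToEnd:
    def test_planted_mechanisms_recovered(self, default_ref, rescue_edits):
        from dogtcr.analysis_helpers import run_rescue_assessment
        from dogtcr.simulate import default_rescue_plan

        res = run_rescue_assessment(
            default_ref, default_rescue_plan(rescue_edits), seed=123
        )
        by_seg = {(a.segment_key, a.defect.kind): a for a in res.assessments}
        a = by_seg[("TRBV19*01", "in_frame_stop")]
        assert (a.status, a.mechanism) == ("corrected", "germline_shared")
        assert a.n_donors_with_usage == 1
        for kind in ("in_frame_stop", "frameshift"):
            a = by_seg[("TRAV9-2*01", kind)]
            assert (a.status, a.mechanism) == ("corrected", "germline_shared")
        a = by_seg[("TRBJ1-3*01", "in_frame_stop")]
        assert (a.status, a.mechanism) == ("corrected", "junctional")

        rec = res.proposals.set_index("segment_key")["recommendation"]
        assert rec["TRBJ1-3*01"] == "functional"
        assert rec["TRAV9-2*01"] == "functional"
        assert rec["TRBV19*01"] == "donor_specific_note"


class TestReannotation:
    def _assessment(self, key, status, donors):
        return DefectAssessment(
            segment_key=key, defect=Defect("in_frame_stop"), status=status,
            mechanism="germline_shared", n_donors_with_usage=donors,
        )

    def test_unused_pseudogene_unchanged(self):
        out = propose_reannotation(
            [self._assessment("X*01", "not_covered", 0)], {}, {})
        assert out.iloc[0]["recommendation"] == "no_change"

    def test_usage_thresholds(self):
        a = [self._assessment("X*01", "corrected", 3)]
        hi = propose_reannotation(a, {"X*01": 150}, {"X*01": 10})
        lo = propose_reannotation(a, {"X*01": 10}, {"X*01": 10})
        assert hi.iloc[0]["recommendation"] == "functional"
        assert lo.iloc[0]["recommendation"] == "no_change"
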