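"""Pseudogene/ORF rescue analysis: why do defective segments appear in
productive clonotypes?

Clonotype consensus sequences are aligned back to the defective reference
segment, the differences are enumerated (SNVs and left-normalized
indels), differences shared by nearly all of a donor's clonotypes outside
the junction-proximal window are classified as germline (Donor Reference)
variants, and each annotated defect is then assessed as corrected or
retained with a mechanism: ``germline_shared`` (a corrective variant in
the donor's germline, as in a stop-removing SNV), or ``junctional``
(per-clonotype sequence changes at the V(D)J joining boundary that
eliminate a junction-proximal stop while preserving frame). Segments
whose defects are consistently corrected at meaningful usage levels are
proposed for re-annotation as functional.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib
import pandas as pd

from ._seq import STOP_CODONS
from .reference import Defect, GeneSegment

#: nt window at the V 3' end / J 5' end attributed to V(D)J joining
JUNCTION_WINDOW_NT = 12
#: a difference is donor-germline if shared by at least this fraction of
#: the donor's clonotypes using the segment (with >= 2 clonotypes)
DONOR_SHARED_FRACTION = 0.9
MIN_CLONOTYPES_FOR_GERMLINE = 2
#: minimum alignment identity for the consensus to cover the segment
MIN_COVER_IDENTITY = 0.6

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class SequenceDiff:
    """One difference of an observed consensus vs. a reference segment.

    ``segment_position`` is a 0-based nt offset on the segment; insertions
    are placed before that offset. Indels are left-normalized so the same
    physical variant is reported identically across clonotypes.
    """

    kind: str  # SNV | insertion | deletion
    segment_position: int
    ref_allele: str = ""
    obs_allele: str = ""
    in_junction_window: bool = False
    donor_shared: bool = False

    def key(self) -> tuple:
        return (self.kind, self.segment_position, self.ref_allele, self.obs_allele)


@dataclass
class DefectAssessment:
    segment_key: str
    defect: Defect
    status: str  # corrected | retained | not_covered
    mechanism: str  # germline_shared | junctional | unresolved
    evidence: list[SequenceDiff] = field(default_factory=list)
    n_clonotypes_examined: int = 0
    n_donors_with_usage: int = 0
    fraction_corrected: float = 0.0


def _junction_window(seg: GeneSegment, pos: int, window: int = JUNCTION_WINDOW_NT) -> bool:
    if seg.segment_class == "V":
        return pos >= len(seg) - window
    if seg.segment_class == "J":
        return pos < window
    return False


def align_consensus_to_segment(
    consensus_nt: str, segment: GeneSegment, window: int = JUNCTION_WINDOW_NT
) -> Optional[list[SequenceDiff]]:
    """Enumerate differences of ``consensus_nt`` against the segment.

    The segment is aligned as a whole into the consensus (glocal,
    unit-cost edit alignment); differences are emitted in segment
    coordinates with indels normalized to their leftmost equivalent
    position. Returns None when identity falls below
    ``MIN_COVER_IDENTITY`` (segment region not covered).
    """
    res = edlib.align(segment.nt_sequence, consensus_nt, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    identity = 1.0 - res["editDistance"] / len(segment)
    if identity < MIN_COVER_IDENTITY:
        return None
    tstart = res["locations"][0][0]
    qpos, tpos = 0, tstart
    seg_nt = segment.nt_sequence
    diffs: list[SequenceDiff] = []
    for n_str, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n_str)
        if op == "=":
            qpos += n
            tpos += n
        elif op == "X":
            for k in range(n):
                diffs.append(SequenceDiff(
                    "SNV", qpos + k, ref_allele=seg_nt[qpos + k],
                    obs_allele=consensus_nt[tpos + k],
                ))
            qpos += n
            tpos += n
        elif op == "I":  # segment bases absent from the consensus: deletion
            diffs.append(SequenceDiff(
                "deletion", qpos, ref_allele=seg_nt[qpos : qpos + n]
            ))
            qpos += n
        elif op == "D":  # extra consensus bases: insertion
            diffs.append(SequenceDiff(
                "insertion", qpos, obs_allele=consensus_nt[tpos : tpos + n]
            ))
            tpos += n
    diffs = [_left_normalize(d, seg_nt) for d in diffs]
    return [
        SequenceDiff(d.kind, d.segment_position, d.ref_allele, d.obs_allele,
                     in_junction_window=_junction_window(segment, d.segment_position, window))
        for d in sorted(diffs, key=lambda d: (d.segment_position, d.kind))
    ]


def _left_normalize(d: SequenceDiff, seg_nt: str) -> SequenceDiff:
    if d.kind == "SNV":
        return d
    pos, allele = d.segment_position, (d.obs_allele or d.ref_allele)
    while pos > 0 and allele and seg_nt[pos - 1] == allele[-1]:
        allele = allele[-1] + allele[:-1]
        pos -= 1
    if d.kind == "insertion":
        return SequenceDiff("insertion", pos, obs_allele=allele)
    return SequenceDiff("deletion", pos, ref_allele=allele)


def infer_donor_reference(
    diffs_by_clonotype: dict[str, list[SequenceDiff]],
    min_fraction: float = DONOR_SHARED_FRACTION,
) -> set[tuple]:
    """Donor-germline variant set from one donor's per-clonotype diffs.

    A diff is germline (donor-shared) if present in at least
    ``min_fraction`` of the donor's clonotypes using the segment and it
    lies outside the junction window; fewer than two clonotypes cannot
    resolve germline from junctional variation, so the set is empty.
    """
    n = len(diffs_by_clonotype)
    if n < MIN_CLONOTYPES_FOR_GERMLINE:
        return set()
    counts: Counter = Counter()
    window_keys: set = set()
    for diffs in diffs_by_clonotype.values():
        for d in diffs:
            counts[d.key()] += 1
            if d.in_junction_window:
                window_keys.add(d.key())
    return {
        k for k, c in counts.items()
        if c / n >= min_fraction and k not in window_keys
    }


def _defect_present(
    segment: GeneSegment, defect: Defect, diffs: list[SequenceDiff]
) -> bool:
    """Is the annotated defect still present in the observed sequence?"""
    if defect.kind == "in_frame_stop":
        lo, hi = defect.nt_position, defect.nt_position + 3
        obs = _observed_codon(segment, lo, diffs)
        return obs in STOP_CODONS
    if defect.kind == "frameshift":
        # the reference frame is broken; it is restored only by a net
        # non-zero (mod 3) indel balance in the segment body. Indels in
        # the junction window are trimming artifacts, not frame-relevant.
        net = sum(
            len(d.obs_allele) - len(d.ref_allele)
            for d in diffs
            if d.kind != "SNV" and not d.in_junction_window
        )
        return net % 3 == 0
    return True  # RSS / motif defects are not assessable from transcripts


def _observed_codon(
    segment: GeneSegment, pos: int, diffs: list[SequenceDiff]
) -> Optional[str]:
    """The observed bases at segment codon ``pos``; None if indel-disrupted."""
    codon = list(segment.nt_sequence[pos : pos + 3])
    for d in diffs:
        if d.kind == "SNV" and pos <= d.segment_position < pos + 3:
            codon[d.segment_position - pos] = d.obs_allele
        elif d.kind == "deletion":
            if d.segment_position < pos + 3 and d.segment_position + len(d.ref_allele) > pos:
                return None
        elif d.kind == "insertion":
            if pos < d.segment_position < pos + 3:
                return None
    return "".join(codon)


def _correcting_diffs(
    segment: GeneSegment, defect: Defect, diffs: list[SequenceDiff]
) -> list[SequenceDiff]:
    """Diffs that plausibly remove the defect from the observed sequence."""
    if defect.kind == "in_frame_stop":
        lo, hi = defect.nt_position, defect.nt_position + 3
        out = []
        for d in diffs:
            if d.kind == "SNV" and lo <= d.segment_position < hi:
                out.append(d)
            elif d.kind == "deletion" and d.segment_position < hi and \
                    d.segment_position + len(d.ref_allele) > lo:
                out.append(d)
            elif d.kind == "insertion" and lo < d.segment_position < hi:
                out.append(d)
        return out
    if defect.kind == "frameshift":
        return [d for d in diffs if d.kind != "SNV" and not d.in_junction_window]
    return []


def assess_defects(
    segment: GeneSegment,
    consensus_table: pd.DataFrame,
    window: int = JUNCTION_WINDOW_NT,
) -> list[DefectAssessment]:
    """Assess every annotated defect of ``segment`` against observed usage.

    ``consensus_table`` needs columns donor, clonotype_id, consensus_nt:
    one clonotype consensus per row, from clonotypes using the segment.
    Status is ``corrected`` when at least 90% of examined clonotypes lack
    the defect, ``retained`` otherwise, ``not_covered`` when no consensus
    covers the segment. The mechanism is ``germline_shared`` when every
    correcting diff is a donor-shared germline variant in every donor with
    usage, ``junctional`` when the correcting diffs sit inside the
    junction window and vary between clonotypes, else ``unresolved``.
    The result is invariant to the row order of the table.
    """
    table = consensus_table.sort_values(["donor", "clonotype_id"]).reset_index(drop=True)
    diffs_by_ct: dict[tuple, list[SequenceDiff]] = {}
    for row in table.itertuples(index=False):
        diffs = align_consensus_to_segment(row.consensus_nt, segment, window)
        if diffs is not None:
            diffs_by_ct[(row.donor, row.clonotype_id)] = diffs

    donors = sorted({donor for donor, _ in diffs_by_ct})
    shared_by_donor = {
        donor: infer_donor_reference(
            {ct: d for (dn, ct), d in diffs_by_ct.items() if dn == donor}
        )
        for donor in donors
    }
    # mark donor_shared on the stored diffs
    for (donor, ct), diffs in diffs_by_ct.items():
        diffs_by_ct[(donor, ct)] = [
            SequenceDiff(d.kind, d.segment_position, d.ref_allele, d.obs_allele,
                         d.in_junction_window,
                         donor_shared=d.key() in shared_by_donor[donor])
            for d in diffs
        ]

    out = []
    for defect in segment.defects:
        if defect.kind in ("noncanonical_RSS",):
            continue  # not assessable from transcript sequence
        if not diffs_by_ct:
            out.append(DefectAssessment(
                segment_key=segment.key, defect=defect, status="not_covered",
                mechanism="unresolved",
            ))
            continue
        corrected_flags = []
        evidence_sets = []
        for key, diffs in sorted(diffs_by_ct.items()):
            corrected_flags.append(not _defect_present(segment, defect, diffs))
            evidence_sets.append(tuple(d.key() for d in
                                       _correcting_diffs(segment, defect, diffs)))
        frac = sum(corrected_flags) / len(corrected_flags)
        status = "corrected" if frac >= 0.9 else "retained"

        all_correcting: list[SequenceDiff] = []
        seen = set()
        for key, diffs in sorted(diffs_by_ct.items()):
            for d in _correcting_diffs(segment, defect, diffs):
                if d.key() not in seen:
                    seen.add(d.key())
                    all_correcting.append(d)
        mechanism = "unresolved"
        if status == "corrected" and all_correcting:
            if all(d.donor_shared for d in all_correcting):
                mechanism = "germline_shared"
            elif all(d.in_junction_window for d in all_correcting) and (
                len(set(evidence_sets)) > 1
            ):
                mechanism = "junctional"
        out.append(DefectAssessment(
            segment_key=segment.key, defect=defect, status=status,
            mechanism=mechanism, evidence=all_correcting,
            n_clonotypes_examined=len(diffs_by_ct),
            n_donors_with_usage=len(donors),
            fraction_corrected=frac,
        ))
    return out


def collect_segment_consensus(
    annotations: pd.DataFrame,
    sequences: dict[str, str],
    cell_map: pd.DataFrame,
    donor_by_barcode: dict[str, str],
    segment_key: str,
) -> pd.DataFrame:
    """Per-clonotype consensus sequences for contigs calling ``segment_key``.

    With error-free contigs the members of a clonotype are identical and
    the consensus is simply the (majority) member sequence; ties break to
    the lexicographically smallest sequence.
    """
    used = annotations[
        annotations["productive"]
        & ((annotations["v_call"] == segment_key) | (annotations["j_call"] == segment_key))
    ].merge(cell_map, on="barcode", how="inner")
    rows = []
    for cid, grp in used.groupby("clonotype_id", sort=True):
        seqs = [sequences[c] for c in grp["contig_id"] if c in sequences]
        if not seqs:
            continue
        counts = Counter(seqs)
        top = max(counts.values())
        consensus = sorted(s for s, n in counts.items() if n == top)[0]
        donors = sorted({donor_by_barcode[b] for b in grp["barcode"]})
        rows.append({
            "donor": donors[0], "clonotype_id": cid,
            "consensus_nt": consensus, "n_cells": grp["barcode"].nunique(),
        })
    return pd.DataFrame(rows, columns=["donor", "clonotype_id", "consensus_nt", "n_cells"])


#: declared re-annotation policy thresholds
REANNOTATION_MIN_DONORS = 2
REANNOTATION_MIN_CELLS = 100
REANNOTATION_MIN_CLONOTYPES = 50


def propose_reannotation(
    assessments: Iterable[DefectAssessment],
    segment_cells: dict[str, int],
    segment_clonotypes: dict[str, int],
) -> pd.DataFrame:
    """Re-annotation recommendations from defect assessments and usage.

    ``functional``: every defect corrected in >= 2 donors and the segment
    is used in >= 100 productive cells or >= 50 unique clonotypes.
    ``donor_specific_note``: corrected but observed in a single donor only
    (more individuals needed). Otherwise ``no_change``.
    """
    by_seg: dict[str, list[DefectAssessment]] = {}
    for a in assessments:
        by_seg.setdefault(a.segment_key, []).append(a)
    rows = []
    for seg_key in sorted(by_seg):
        segs = by_seg[seg_key]
        all_corrected = all(a.status == "corrected" for a in segs)
        n_donors = max(a.n_donors_with_usage for a in segs)
        cells = segment_cells.get(seg_key, 0)
        cts = segment_clonotypes.get(seg_key, 0)
        if all_corrected and n_donors >= REANNOTATION_MIN_DONORS and (
            cells >= REANNOTATION_MIN_CELLS or cts >= REANNOTATION_MIN_CLONOTYPES
        ):
            rec = "functional"
        elif all_corrected and n_donors == 1:
            rec = "donor_specific_note"
        else:
            rec = "no_change"
        rows.append({
            "segment_key": seg_key, "recommendation": rec,
            "n_donors_with_usage": n_donors, "n_cells": cells,
            "n_clonotypes": cts,
            "mechanisms": ";".join(sorted({a.mechanism for a in segs})),
        })
    return pd.DataFrame(rows)
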