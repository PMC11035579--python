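"""Alignment-based contig annotation: segment assignment, CDR3, productivity.

This is the definitional layer a 10x-style pipeline delegates to its
V(D)J annotator: each contig is aligned against every V and J segment,
the CDR3 is extracted between the conserved V cysteine and the J
[FW]-G-X-G phenylalanine/tryptophan (both anchors inclusive, so printed
CDR3s read C...F/W), and productivity is called from the V reading frame.
D segments are deliberately not assigned: their short, heavily trimmed
remnants do not support reliable calls from contig sequence alone.

Candidate segments are short-listed with a fast infix edit-distance
screen (edlib), then scored with local Smith-Waterman (match +2,
mismatch -2, gap open -4, gap extend -1; score floor 40). Ties are broken
by higher identity, then lexicographically smaller segment key, and are
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from ._seq import CYS_CODONS, PHE_CODONS, TRP_CODONS, has_stop, translate
from .reference import GeneSegment, ReferenceSet

SCORE_FLOOR = 40
MIN_CONTIG_LENGTH = 100
SCREEN_MARGIN = 10  # edit-distance slack kept for rescoring with SW
SCREEN_TOP = 3


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


@dataclass
class SegmentHit:
    """Best-scoring alignment of one segment against a contig."""

    segment: GeneSegment
    score: float
    identity: float
    target_blocks: Sequence[tuple[int, int]]  # contig coordinates
    query_blocks: Sequence[tuple[int, int]]  # segment coordinates
    tie: bool = False

    def map_to_contig(self, q: int) -> Optional[int]:
        """Map a segment coordinate onto the contig; None if gapped/unaligned."""
        for (ts, te), (qs, qe) in zip(self.target_blocks, self.query_blocks):
            if qs <= q < qe:
                return ts + (q - qs)
        return None

    @property
    def query_start(self) -> int:
        return self.query_blocks[0][0]

    @property
    def query_end(self) -> int:
        return self.query_blocks[-1][1]

    @property
    def target_start(self) -> int:
        return self.target_blocks[0][0]


@dataclass
class ContigAnnotation:
    barcode: str
    contig_id: str
    contig_length: int
    chain: Optional[str] = None
    v_call: Optional[str] = None
    j_call: Optional[str] = None
    v_identity: Optional[float] = None
    j_identity: Optional[float] = None
    cdr3_nt: Optional[str] = None
    cdr3_aa: Optional[str] = None
    frame_offset: Optional[int] = None
    has_stop: bool = False
    full_length: bool = False
    productive: bool = False
    umi_count: Optional[int] = None
    flags: list[str] = field(default_factory=list)
    reason: Optional[str] = None
    # contig coordinates of the two CDR3 anchors (internal bookkeeping)
    cys_pos: Optional[int] = None
    jm_pos: Optional[int] = None


class ContigAnnotator:
    """Reusable annotator bound to an anchored reference set."""

    def __init__(self, refset: ReferenceSet):
        self.refset = refset
        self.v_segments = sorted(
            (s for s in refset if s.segment_class == "V"), key=lambda s: s.key
        )
        self.j_segments = sorted(
            (s for s in refset if s.segment_class == "J"), key=lambda s: s.key
        )
        if not self.v_segments or not self.j_segments:
            raise ValueError("reference must contain V and J segments")
        self.aligner = _make_aligner()

    # -- segment assignment ------------------------------------------------

    def _screen(self, contig: str, segments: list[GeneSegment]) -> list[GeneSegment]:
        dists = []
        for seg in segments:
            d = edlib.align(seg.nt_sequence, contig, mode="HW", task="distance")
            dists.append(d["editDistance"])
        order = np.argsort(dists, kind="stable")
        best = dists[order[0]]
        out = [segments[i] for i in order[:SCREEN_TOP] if dists[i] <= best + SCREEN_MARGIN]
        return out

    def _best_hit(self, contig: str, segments: list[GeneSegment]) -> Optional[SegmentHit]:
        candidates = self._screen(contig, segments)
        hits: list[SegmentHit] = []
        for seg in candidates:
            alns = self.aligner.align(contig, seg.nt_sequence)
            if len(alns) == 0:
                continue
            aln = alns[0]
            tb, qb = aln.aligned
            matches = sum(
                1
                for (ts, te), (qs, qe) in zip(tb, qb)
                for k in range(te - ts)
                if contig[ts + k] == seg.nt_sequence[qs + k]
            )
            cols = aln.length
            hits.append(
                SegmentHit(
                    segment=seg, score=aln.score,
                    identity=matches / cols if cols else 0.0,
                    target_blocks=[tuple(b) for b in tb],
                    query_blocks=[tuple(b) for b in qb],
                )
            )
        hits = [h for h in hits if h.score >= SCORE_FLOOR]
        if not hits:
            return None
        hits.sort(key=lambda h: (-h.score, -h.identity, h.segment.key))
        best = hits[0]
        if len(hits) > 1 and hits[1].score == best.score and hits[1].identity == best.identity:
            best.tie = True
        return best

    def assign_segments(
        self, contig: str
    ) -> tuple[Optional[SegmentHit], Optional[SegmentHit]]:
        """Best V and best J hit (chain inferred downstream from the V)."""
        return self._best_hit(contig, self.v_segments), self._best_hit(
            contig, self.j_segments
        )

    # -- CDR3 and productivity ---------------------------------------------

    def annotate(
        self,
        contig: str,
        barcode: str = "",
        contig_id: str = "",
        umi_count: Optional[int] = None,
    ) -> ContigAnnotation:
        ann = ContigAnnotation(
            barcode=barcode, contig_id=contig_id, contig_length=len(contig),
            umi_count=umi_count,
        )
        if len(contig) < MIN_CONTIG_LENGTH:
            ann.flags.append("short_contig")
            ann.reason = "short_contig"
            return ann
        v_hit, j_hit = self.assign_segments(contig)
        if v_hit is None:
            ann.flags.append("unannotated")
            ann.reason = "no_v_alignment"
            return ann
        ann.chain = v_hit.segment.chain
        ann.v_call = v_hit.segment.key
        ann.v_identity = round(v_hit.identity, 6)
        if v_hit.tie:
            ann.flags.append("v_tie")
        if j_hit is not None and j_hit.segment.chain != v_hit.segment.chain:
            ann.j_call = j_hit.segment.key
            ann.flags.append("chain_conflict")
            ann.reason = "chain_conflict"
            return ann
        if j_hit is None:
            ann.reason = "no_j_alignment"
            return ann
        ann.j_call = j_hit.segment.key
        ann.j_identity = round(j_hit.identity, 6)
        if j_hit.tie:
            ann.flags.append("j_tie")

        ann.full_length = v_hit.query_start == 0 and j_hit.query_end == len(
            j_hit.segment
        )

        extract_cdr3(contig, v_hit, j_hit, ann)
        call_productivity(contig, v_hit, j_hit, ann)
        return ann


def _cys_anchor_on_contig(contig: str, v_hit: SegmentHit) -> Optional[int]:
    """Contig-frame cysteine anchor for frame-broken V references.

    When the reference V carries an annotated frameshift (or lacks a
    usable Cys anchor altogether), mapping its anchor through the
    alignment is meaningless. Instead, scan the V-aligned contig span for
    the 3'-most TGT/TGC codon in the contig's V reading frame — the same
    convention production annotators fall back on.
    """
    v0 = v_hit.target_start - v_hit.query_start
    v_end = v_hit.target_blocks[-1][1]
    lo = max(v0, v_end - 45)
    best = None
    for p in range(lo + ((v0 - lo) % 3), v_end - 2, 3):
        if contig[p : p + 3] in CYS_CODONS:
            best = p
    return best


def extract_cdr3(
    contig: str, v_hit: SegmentHit, j_hit: SegmentHit, ann: ContigAnnotation
) -> ContigAnnotation:
    """CDR3 between the mapped V-Cys codon and J-[FW] codon, both inclusive.

    The CDR3 is absent (with a recorded reason) when either anchor fails
    to map through its alignment onto the contig.
    """
    v_seg, j_seg = v_hit.segment, j_hit.segment
    if j_seg.jmotif_anchor is None:
        ann.reason = "anchor_missing_in_reference"
        return ann
    v_frame_broken = v_seg.cys_anchor is None or any(
        d.kind == "frameshift" for d in v_seg.defects
    )
    if v_frame_broken:
        cys_pos = _cys_anchor_on_contig(contig, v_hit)
    else:
        cys_pos = v_hit.map_to_contig(v_seg.cys_anchor)
    jm_pos = j_hit.map_to_contig(j_seg.jmotif_anchor)
    if cys_pos is None or jm_pos is None:
        ann.reason = "anchor_unmapped"
        return ann
    if jm_pos + 3 <= cys_pos:
        ann.reason = "anchor_order"
        return ann
    ann.cys_pos, ann.jm_pos = cys_pos, jm_pos
    ann.cdr3_nt = contig[cys_pos : jm_pos + 3]
    if len(ann.cdr3_nt) % 3 == 0:
        ann.cdr3_aa = translate(ann.cdr3_nt)
    return ann


def call_productivity(
    contig: str, v_hit: SegmentHit, j_hit: SegmentHit, ann: ContigAnnotation
) -> ContigAnnotation:
    """Productive iff the CDR3 exists, the V frame runs unbroken through the
    junction into the J, no stop codon occurs from V start through J end,
    and the anchors are canonical (C ... F/W)."""
    if ann.cdr3_nt is None:
        ann.productive = False
        if ann.reason is None:
            ann.reason = "no_cdr3"
        return ann
    v_seg, j_seg = v_hit.segment, j_hit.segment
    # contig coordinate of V codon 0, extrapolated if the alignment clips it
    v0 = v_hit.target_start - v_hit.query_start
    ann.frame_offset = v0 % 3
    cys_pos, jm_pos = ann.cys_pos, ann.jm_pos
    j_end = j_hit.target_blocks[-1][1] + (len(j_seg) - j_hit.query_blocks[-1][1])

    if (cys_pos - v0) % 3 != 0 or (jm_pos - v0) % 3 != 0:
        ann.productive = False
        ann.reason = "out_of_frame"
        return ann
    region = contig[max(v0, 0) : j_end]
    ann.has_stop = has_stop(region)
    if ann.has_stop:
        ann.productive = False
        ann.reason = "stop_codon"
        return ann
    cys_codon = contig[cys_pos : cys_pos + 3]
    anchor_codon = contig[jm_pos : jm_pos + 3]
    if cys_codon not in CYS_CODONS or not (
        anchor_codon in PHE_CODONS or anchor_codon in TRP_CODONS
    ):
        ann.productive = False
        ann.reason = "noncanonical_anchor"
        return ann
    ann.productive = True
    ann.reason = None
    return ann


ANNOTATION_COLUMNS = [
    "barcode", "contig_id", "chain", "v_call", "j_call", "v_identity",
    "j_identity", "cdr3_nt", "cdr3_aa", "frame_offset", "has_stop",
    "full_length", "productive", "contig_length", "umi_count", "flags", "reason",
]


def annotate_contigs(contigs: Iterable, refset: ReferenceSet) -> pd.DataFrame:
    """Annotate a batch of contigs into a tidy table.

    ``contigs`` may be a list of :class:`~dogtcr.simulate.SimulatedCell`
    or an iterable of ``(barcode, contig_id, sequence)`` /
    ``(barcode, contig_id, sequence, umi_count)`` tuples. An empty input
    yields an empty, correctly-typed table.
    """
    annotator = ContigAnnotator(refset)
    rows = []
    for item in _iter_contigs(contigs):
        barcode, contig_id, seq, umi = item
        ann = annotator.annotate(seq, barcode=barcode, contig_id=contig_id, umi_count=umi)
        row = {c: getattr(ann, c) for c in ANNOTATION_COLUMNS if c != "flags"}
        row["flags"] = ";".join(ann.flags)
        rows.append(row)
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def _iter_contigs(contigs: Iterable):
    from .simulate import SimulatedCell

    for item in contigs:
        if isinstance(item, SimulatedCell):
            for ct in item.contigs:
                yield item.barcode, ct.contig_id, ct.contig_nt, ct.umi_count
        else:
            barcode, contig_id, seq, *rest = item
            yield barcode, contig_id, seq, (rest[0] if rest else None)


def barcode_summary(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-barcode chain flags (the per-cell rollup behind Table-style metrics)."""
    if annotations.empty:
        return pd.DataFrame(
            columns=["barcode", "has_tra", "has_trb", "cdr3_tra", "cdr3_trb",
                     "productive_tra", "productive_trb", "productive_pair"]
        )
    g = annotations.assign(
        is_tra=annotations["chain"] == "TRA",
        is_trb=annotations["chain"] == "TRB",
        cdr3_ok=annotations["cdr3_nt"].notna(),
    ).groupby("barcode", sort=True)
    out = pd.DataFrame({
        "has_tra": g["is_tra"].any(),
        "has_trb": g["is_trb"].any(),
        "cdr3_tra": g.apply(lambda d: bool((d["is_tra"] & d["cdr3_ok"]).any()),
                            include_groups=False),
        "cdr3_trb": g.apply(lambda d: bool((d["is_trb"] & d["cdr3_ok"]).any()),
                            include_groups=False),
        "productive_tra": g.apply(lambda d: bool((d["is_tra"] & d["productive"]).any()),
                                  include_groups=False),
        "productive_trb": g.apply(lambda d: bool((d["is_trb"] & d["productive"]).any()),
                                  include_groups=False),
    })
    out["productive_pair"] = out["productive_tra"] & out["productive_trb"]
    return out.reset_index()
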