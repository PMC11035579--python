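"""Synthetic default TRA/TRB segment reference.

A deterministic, programmatically generated stand-in for a curated canine
IMGT V(D)JC reference. It carries the locus structure the analyses need:

* functional V segments with a conserved cysteine anchor near the 3' end,
* functional J segments with the [FW]-G-X-G motif,
* three defective segments modeled on the documented canine cases:

  - ``TRBV19``: pseudogene with an in-frame stop (TAG) at amino-acid
    position 104 in FR3, correctable by a single germline T->C change
    (TAG -> CAG, glutamine) carried by some donors;
  - ``TRAV9-2``: pseudogene with an in-frame stop (TGA) at position 45
    and a 1-nt deletion at position 57 causing a frameshift; the donor
    consensus differs from the reference by 8 SNVs plus a single
    frame-restoring C-like insertion (9 differences in total);
  - ``TRBJ1-3``: pseudogene with an in-frame stop in its second codon,
    removable only by junctional trimming during V(D)J joining;

* one ORF J segment (``TRAJ52``) lacking a conserved [FW]GXG motif.

Everything here is synthetic sequence: only the defect architecture, not
the actual canine nucleotide content, is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import STOP_CODONS
from .reference import (
    Defect,
    GeneSegment,
    ReferenceSet,
    annotate_anchors,
    locate_cys_anchor,
    locate_jmotif_anchor,
)

DEFAULT_REFERENCE_SEED = 20251

_SENSE_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - STOP_CODONS
)
_SENSE_NONCYS = [c for c in _SENSE_CODONS if c not in ("TGT", "TGC")]

#: V segment geometry (codons); the cysteine anchor sits 3 codons from the end
V_CODONS = 108
V_CYS_CODON = 104
#: J segment geometry; the [FW]GXG anchor starts at codon 8
J_CODONS = 17
J_ANCHOR_CODON = 8


@dataclass(frozen=True)
class GermlineEdit:
    """A single donor-germline difference relative to the universal reference.

    ``position`` is a 0-based offset on the *reference* segment sequence.
    For SNVs ``ref``/``obs`` are single bases; insertions carry the inserted
    base(s) in ``obs`` (placed before ``position``); deletions carry the
    removed base(s) in ``ref``.
    """

    kind: str  # SNV | insertion | deletion
    position: int
    ref: str = ""
    obs: str = ""


def apply_edits(sequence: str, edits: list[GermlineEdit]) -> str:
    """Apply reference-coordinate edits (right-to-left, so offsets hold)."""
    s = sequence
    for e in sorted(edits, key=lambda e: e.position, reverse=True):
        if e.kind == "SNV":
            if s[e.position] != e.ref:
                raise ValueError(f"SNV ref mismatch at {e.position}")
            s = s[: e.position] + e.obs + s[e.position + 1 :]
        elif e.kind == "insertion":
            s = s[: e.position] + e.obs + s[e.position :]
        elif e.kind == "deletion":
            if s[e.position : e.position + len(e.ref)] != e.ref:
                raise ValueError(f"deletion ref mismatch at {e.position}")
            s = s[: e.position] + s[e.position + len(e.ref) :]
        else:
            raise ValueError(f"unknown edit kind {e.kind!r}")
    return s


def _random_v(rng: np.random.Generator) -> str:
    """Random in-frame, stop-free V-REGION with a unique 3' Cys anchor."""
    codons = [str(rng.choice(_SENSE_NONCYS)) for _ in range(V_CODONS)]
    codons[V_CYS_CODON] = "TGT"
    seq = "".join(codons)
    assert locate_cys_anchor(seq) == 3 * V_CYS_CODON
    return seq


def _random_j(rng: np.random.Generator) -> str:
    """Random stop-free J-REGION whose only [FW]GXG motif starts at codon 8."""
    while True:
        codons = [str(rng.choice(_SENSE_CODONS)) for _ in range(J_CODONS)]
        codons[J_ANCHOR_CODON] = "TTT" if rng.random() < 0.7 else "TGG"
        codons[J_ANCHOR_CODON + 1] = "GGA"
        codons[J_ANCHOR_CODON + 3] = "GGC"
        seq = "".join(codons)
        if locate_jmotif_anchor(seq) == 3 * J_ANCHOR_CODON:
            return seq


def _random_orf_j(rng: np.random.Generator) -> str:
    """Random J-REGION with no [FW]GXG motif in any frame (ORF class)."""
    while True:
        seq = "".join(str(rng.choice(_SENSE_CODONS)) for _ in range(J_CODONS))
        if locate_jmotif_anchor(seq) is None:
            return seq


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT")) for _ in range(n))


def build_default_reference(
    seed: int = DEFAULT_REFERENCE_SEED,
) -> tuple[ReferenceSet, dict[str, list[GermlineEdit]]]:
    """Build the default anchored reference plus donor-rescue edit catalog.

    Returns ``(refset, rescue_edits)`` where ``rescue_edits`` maps the keys
    of the germline-rescuable pseudogenes (``TRBV19*01``, ``TRAV9-2*01``)
    to the edits that turn the reference allele into the corrected donor
    germline.
    """
    rng = np.random.default_rng(seed)
    refset = ReferenceSet()

    def add(segment_id, chain, seg_class, seq, functional_class="functional", defects=()):
        refset.add(
            GeneSegment(
                segment_id=segment_id,
                allele="01",
                chain=chain,
                segment_class=seg_class,
                nt_sequence=seq,
                functional_class=functional_class,
                defects=list(defects),
            )
        )

    # --- TRA locus -------------------------------------------------------
    for i in range(1, 13):
        add(f"TRAV{i}", "TRA", "V", _random_v(rng))
    for i in range(1, 11):
        add(f"TRAJ{i}", "TRA", "J", _random_j(rng))
    add("TRAJ52", "TRA", "J", _random_orf_j(rng), functional_class="ORF",
        defects=[Defect("nonconserved_motif", region="J-region", nt_position=0,
                        note="no conserved FGXG")])
    add("TRAC", "TRA", "C", _random_nt(rng, 150))

    # --- TRB locus -------------------------------------------------------
    for i in range(1, 13):
        add(f"TRBV{i}", "TRB", "V", _random_v(rng))
    add("TRBD1", "TRB", "D", _random_nt(rng, 13))
    add("TRBD2", "TRB", "D", _random_nt(rng, 14))
    for name in ("TRBJ1-1", "TRBJ1-2", "TRBJ1-4", "TRBJ1-5",
                 "TRBJ2-1", "TRBJ2-2", "TRBJ2-5", "TRBJ2-6"):
        add(name, "TRB", "J", _random_j(rng))
    add("TRBC1", "TRB", "C", _random_nt(rng, 150))

    rescue_edits: dict[str, list[GermlineEdit]] = {}

    # --- TRBV19: in-frame stop in FR3, single-SNV germline rescue --------
    v19_functional = _random_v(rng)
    # plant TAG at codon 103 (amino-acid position 104); donor carries T->C
    pos = 3 * 103
    v19_ref = v19_functional[:pos] + "TAG" + v19_functional[pos + 3 :]
    add("TRBV19", "TRB", "V", v19_ref, functional_class="pseudogene",
        defects=[Defect("in_frame_stop", region="FR3", nt_position=pos,
                        note="TAG at aa position 104")])
    rescue_edits["TRBV19*01"] = [GermlineEdit("SNV", pos, ref="T", obs="C")]

    # --- TRAV9-2: stop at aa45 + frameshift, multi-variant germline rescue
    while True:
        av92_functional = _random_v(rng)
        # codon 44 must be TCA so a single G<->C change toggles TGA (stop)
        av92_functional = av92_functional[: 3 * 44] + "TCA" + av92_functional[3 * 44 + 3 :]
        del_pos = 3 * 56 + 1  # inside codon 56 (amino-acid position 57)
        # avoid homopolymer ambiguity so the insertion left-normalizes here
        if av92_functional[del_pos] != av92_functional[del_pos - 1]:
            break
    snv_positions = [30, 60, 90, 200, 230, 260, 290]
    av92_ref = av92_functional
    edits: list[GermlineEdit] = []
    for p in snv_positions:
        ref_base = av92_ref[p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        av92_ref = av92_ref[:p] + alt + av92_ref[p + 1 :]
        edits.append(GermlineEdit("SNV", p, ref=alt, obs=ref_base))
    av92_ref = av92_ref[: 3 * 44] + "TGA" + av92_ref[3 * 44 + 3 :]
    edits.append(GermlineEdit("SNV", 3 * 44 + 1, ref="G", obs="C"))
    inserted_base = av92_ref[del_pos]
    av92_ref = av92_ref[:del_pos] + av92_ref[del_pos + 1 :]
    # positions after the deletion shift down by one on the reference
    edits = [
        GermlineEdit(e.kind, e.position - 1 if e.position > del_pos else e.position,
                     ref=e.ref, obs=e.obs)
        for e in edits
    ]
    edits.append(GermlineEdit("insertion", del_pos, obs=inserted_base))
    add("TRAV9-2", "TRA", "V", av92_ref, functional_class="pseudogene",
        defects=[
            Defect("in_frame_stop", region="FR1", nt_position=3 * 44,
                   note="TGA at aa position 45"),
            Defect("frameshift", region="FR2", nt_position=del_pos,
                   note="1-nt deletion at aa position 57"),
        ])
    assert apply_edits(av92_ref, edits) == av92_functional
    rescue_edits["TRAV9-2*01"] = sorted(edits, key=lambda e: e.position)

    # --- TRBJ1-3: stop in the second 5' codon, junctional rescue only ----
    j13 = _random_j(rng)
    j13_ref = j13[:3] + "TAG" + j13[6:]
    if locate_jmotif_anchor(j13_ref) != 3 * J_ANCHOR_CODON:  # pragma: no cover
        raise RuntimeError("TRBJ1-3 construction lost its anchor")
    add("TRBJ1-3", "TRB", "J", j13_ref, functional_class="pseudogene",
        defects=[Defect("in_frame_stop", region="J-region", nt_position=3,
                        note="stop codon in the second 5' codon")])

    annotate_anchors(refset)
    return refset, rescue_edits


def default_reference(seed: int = DEFAULT_REFERENCE_SEED) -> ReferenceSet:
    """The anchored default reference (fresh object on every call)."""
    return build_default_reference(seed)[0]
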