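"""TRA/TRB gene-segment reference model.

Loads IMGT-style V/D/J/C segment references with functional-class
annotations (functional | ORF | pseudogene), locates the CDR3 anchor
motifs (the conserved V cysteine and the J [FW]-G-X-G), and builds the
in-silico 10x 5' V(D)JC cDNA template used for C-region primer design.

FASTA header dialect (pipe-delimited, documented here and in the README):

    >SEGMENT_ID|ALLELE|CHAIN|CLASS|FUNCTIONAL_CLASS
    e.g. >TRBV20|01|TRB|V|functional

Defect side table: TSV with columns
``segment_id  allele  kind  region  nt_position  note``.

Coordinates are 0-based half-open; sequences are stored 5'->3' in
transcript orientation (the genomic strand of the locus is a loader
concern only).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import CYS_CODONS, translate, validate_nt

CHAINS = ("TRA", "TRB")
SEGMENT_CLASSES = ("V", "D", "J", "C")
FUNCTIONAL_CLASSES = ("functional", "ORF", "pseudogene")
DEFECT_KINDS = ("in_frame_stop", "frameshift", "noncanonical_RSS", "nonconserved_motif")

#: codons searched for the V cysteine anchor, counted from the 3' end
CYS_SEARCH_CODONS = 15


@dataclass(frozen=True)
class Defect:
    """An annotated sequence defect on a gene segment."""

    kind: str
    region: str = ""
    nt_position: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in DEFECT_KINDS:
            raise ValueError(f"unknown defect kind {self.kind!r}")
        if self.nt_position < 0:
            raise ValueError("defect nt_position must be >= 0")


@dataclass
class GeneSegment:
    """One V, D, J or C gene segment allele.

    ``cys_anchor`` (V only) is the 0-based nt offset of the conserved
    cysteine codon; ``jmotif_anchor`` (J only) is the offset of the first
    codon ([FW]) of the J-region [FW]-G-X-G motif. Both are codon-aligned
    in the segment's reading frame.
    """

    segment_id: str
    allele: str
    chain: str
    segment_class: str
    nt_sequence: str
    functional_class: str = "functional"
    defects: list[Defect] = field(default_factory=list)
    cys_anchor: Optional[int] = None
    jmotif_anchor: Optional[int] = None

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValueError(f"{self.segment_id}: unknown chain {self.chain!r}")
        if self.segment_class not in SEGMENT_CLASSES:
            raise ValueError(f"{self.segment_id}: unknown class {self.segment_class!r}")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"{self.segment_id}: unknown functional_class {self.functional_class!r}"
            )
        self.nt_sequence = validate_nt(self.nt_sequence, self.segment_id)
        for d in self.defects:
            if d.nt_position >= len(self.nt_sequence):
                raise ValueError(f"{self.segment_id}: defect position out of bounds")

    @property
    def key(self) -> str:
        return f"{self.segment_id}*{self.allele}"

    def __len__(self) -> int:
        return len(self.nt_sequence)


@dataclass
class ReferenceSet:
    """A keyed collection of gene segments with census helpers."""

    segments: dict[str, GeneSegment] = field(default_factory=dict)

    def add(self, seg: GeneSegment) -> None:
        if seg.key in self.segments:
            raise ValueError(f"duplicate segment {seg.key}")
        self.segments[seg.key] = seg

    def get(self, key: str) -> GeneSegment:
        if key in self.segments:
            return self.segments[key]
        # allow bare segment_id lookups when unambiguous
        hits = [s for s in self.segments.values() if s.segment_id == key]
        if len(hits) == 1:
            return hits[0]
        raise KeyError(key)

    def __iter__(self):
        return iter(self.segments.values())

    def __len__(self) -> int:
        return len(self.segments)

    def select(
        self,
        chain: Optional[str] = None,
        segment_class: Optional[str] = None,
        functional_only: bool = False,
    ) -> list[GeneSegment]:
        out = []
        for s in self.segments.values():
            if chain is not None and s.chain != chain:
                continue
            if segment_class is not None and s.segment_class != segment_class:
                continue
            if functional_only and s.functional_class != "functional":
                continue
            out.append(s)
        return sorted(out, key=lambda s: s.key)

    def census(self) -> dict:
        """Counts per chain x segment class x functional class."""
        out: dict = {}
        for s in self.segments.values():
            out.setdefault(s.chain, {}).setdefault(s.segment_class, {})
            cls = out[s.chain][s.segment_class]
            cls[s.functional_class] = cls.get(s.functional_class, 0) + 1
        return out


def read_segment_fasta(
    path: str | Path, annotations: str | Path | None = None
) -> ReferenceSet:
    """Read a pipe-delimited segment FASTA (and optional defect TSV).

    Raises on duplicate (segment_id, allele), unknown functional-class
    tokens, empty sequences, or malformed headers.
    """
    refset = ReferenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        if len(fields) != 5:
            raise ValueError(f"malformed header {rec.description!r}: expected 5 fields")
        segment_id, allele, chain, seg_class, func = (f.strip() for f in fields)
        refset.add(
            GeneSegment(
                segment_id=segment_id,
                allele=allele,
                chain=chain,
                segment_class=seg_class,
                nt_sequence=str(rec.seq),
                functional_class=func,
            )
        )
    if annotations is not None:
        for seg_key, defect in _read_defect_table(annotations):
            refset.get(seg_key).defects.append(defect)
    return refset


def _read_defect_table(path: str | Path) -> Iterable[tuple[str, Defect]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"segment_id", "allele", "kind", "region", "nt_position", "note"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"defect table missing columns: {sorted(missing)}")
        for row in reader:
            yield (
                f"{row['segment_id']}*{row['allele']}",
                Defect(
                    kind=row["kind"],
                    region=row["region"],
                    nt_position=int(row["nt_position"]),
                    note=row["note"],
                ),
            )


def write_segment_fasta(
    refset: ReferenceSet, path: str | Path, annotations: str | Path | None = None
) -> None:
    """Inverse of :func:`read_segment_fasta` (anchors are recomputable)."""
    records = []
    for seg in sorted(refset, key=lambda s: s.key):
        header = "|".join(
            [seg.segment_id, seg.allele, seg.chain, seg.segment_class, seg.functional_class]
        )
        records.append(SeqRecord(Seq(seg.nt_sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")
    if annotations is not None:
        with open(annotations, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["segment_id", "allele", "kind", "region", "nt_position", "note"])
            for seg in sorted(refset, key=lambda s: s.key):
                for d in seg.defects:
                    w.writerow([seg.segment_id, seg.allele, d.kind, d.region, d.nt_position, d.note])


def locate_cys_anchor(nt: str, search_codons: int = CYS_SEARCH_CODONS) -> Optional[int]:
    """3'-most in-frame TGT/TGC within the last ``search_codons`` codons.

    The V reading frame is frame 0 (V-REGION convention, no leader).
    """
    n_codons = len(nt) // 3
    for codon_idx in range(n_codons - 1, max(-1, n_codons - 1 - search_codons), -1):
        if nt[3 * codon_idx : 3 * codon_idx + 3] in CYS_CODONS:
            return 3 * codon_idx
    return None


def locate_jmotif_anchor(nt: str) -> Optional[int]:
    """Last [FW]-G-X-G occurrence in any J reading frame; returns nt offset.

    The J frame is whichever frame contains the rightmost motif.
    """
    best: Optional[int] = None
    for frame in range(3):
        aa = translate(nt[frame:])
        for i in range(len(aa) - 3):
            if aa[i] in "FW" and aa[i + 1] == "G" and aa[i + 3] == "G":
                pos = frame + 3 * i
                if best is None or pos > best:
                    best = pos
    return best


def annotate_anchors(refset: ReferenceSet) -> ReferenceSet:
    """Locate CDR3 anchors on every V and J segment, in place.

    Missing motifs are flagged as ``nonconserved_motif`` defects rather
    than raised: the field's ORF category includes exactly such segments.
    """
    for seg in refset:
        if seg.segment_class == "V":
            seg.cys_anchor = locate_cys_anchor(seg.nt_sequence)
            if seg.cys_anchor is None and not any(
                d.kind == "nonconserved_motif" for d in seg.defects
            ):
                seg.defects.append(
                    Defect("nonconserved_motif", region="FR3", nt_position=0,
                           note="no conserved Cys codon near 3' end")
                )
        elif seg.segment_class == "J":
            seg.jmotif_anchor = locate_jmotif_anchor(seg.nt_sequence)
            if seg.jmotif_anchor is None and not any(
                d.kind == "nonconserved_motif" for d in seg.defects
            ):
                seg.defects.append(
                    Defect("nonconserved_motif", region="J-region", nt_position=0,
                           note="no [FW]GXG motif")
                )
    return refset


@dataclass(frozen=True)
class AdapterConfig:
    """5' adapter layout of a 10x 5' GEX/V(D)J cDNA molecule."""

    r1_adapter: str = "CTACACGACGCTCTTCCGATCT"  # Illumina TruSeq Read 1 primer site
    barcode_len: int = 16
    umi_len: int = 10
    tso: str = "TTTCTTATATGGG"  # 13-nt template-switch oligo 3' end

    def __post_init__(self) -> None:
        if len(self.tso) != 13:
            raise ValueError("TSO must be exactly 13 nt")
        if self.barcode_len != 16 or self.umi_len != 10:
            raise ValueError("10x layout requires a 16-nt barcode and 10-nt UMI")


@dataclass(frozen=True)
class TemplateConstruct:
    """In-silico full-length V(D)JC cDNA with 10x adapters, 5'->3'."""

    r1_adapter: str
    barcode_placeholder: str
    umi_placeholder: str
    tso: str
    v_nt: str
    j_nt: str
    c_nt: str
    d_nt: Optional[str] = None

    @property
    def parts(self) -> list[str]:
        parts = [self.r1_adapter, self.barcode_placeholder, self.umi_placeholder,
                 self.tso, self.v_nt]
        if self.d_nt is not None:
            parts.append(self.d_nt)
        parts.extend([self.j_nt, self.c_nt])
        return parts

    @property
    def full_sequence(self) -> str:
        return "".join(self.parts)

    @property
    def component_offsets(self) -> dict[str, tuple[int, int]]:
        """Half-open [start, end) of every component on full_sequence."""
        names = ["r1_adapter", "barcode", "umi", "tso", "v"]
        if self.d_nt is not None:
            names.append("d")
        names.extend(["j", "c"])
        out, pos = {}, 0
        for name, part in zip(names, self.parts):
            out[name] = (pos, pos + len(part))
            pos += len(part)
        return out


def build_template(
    v: GeneSegment,
    j: GeneSegment,
    c: GeneSegment,
    d: Optional[GeneSegment] = None,
    adapters: AdapterConfig = AdapterConfig(),
) -> TemplateConstruct:
    """Assemble the reference cDNA template used for C-region primer design.

    ``d`` is supplied only for TRB; all segments must share a chain.
    """
    segs = [v, j, c] + ([d] if d is not None else [])
    chains = {s.chain for s in segs}
    if len(chains) != 1:
        raise ValueError(f"chain mismatch among segments: {sorted(chains)}")
    if d is not None and v.chain != "TRB":
        raise ValueError("D segment supplied for a non-TRB construct")
    if c.segment_class != "C":
        raise ValueError("missing C segment")
    return TemplateConstruct(
        r1_adapter=adapters.r1_adapter,
        barcode_placeholder="N" * adapters.barcode_len,
        umi_placeholder="N" * adapters.umi_len,
        tso=adapters.tso,
        v_nt=v.nt_sequence,
        d_nt=d.nt_sequence if d is not None else None,
        j_nt=j.nt_sequence,
        c_nt=c.nt_sequence,
    )
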