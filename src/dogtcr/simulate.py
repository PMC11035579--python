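"""Synthetic single-cell TRA/TRB repertoire generator with known truth.

Emulates the generative process behind 10x 5' V(D)J libraries at the
contig level: clonal structure (polyclonal, oligoclonal, monoclonal),
V(D)J segment choice with usage weights, junctional trimming and
nontemplated insertion, per-donor germline V variants (including variants
that rescue annotated pseudogene defects), TRA/TRB chain dropout and
extra-chain noise, and per-chain UMI counts. Every emitted contig carries
definitional ground truth (segments, trims, CDR3, productivity) computed
by direct bookkeeping, independent of the alignment-based annotator.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import CYS_CODONS, PHE_CODONS, STOP_CODONS, TRP_CODONS, has_stop, translate
from .reference import GeneSegment, ReferenceSet
from .refdata import GermlineEdit, apply_edits

PAIRING_CATEGORIES = (
    "single_pair", "tra_only", "trb_only", "extra_tra", "extra_trb", "extra_both",
)

#: chain-pairing category frequencies observed with the 10x v2 5' protocol
PAIRING_V2 = {
    "single_pair": 0.698, "tra_only": 0.025, "trb_only": 0.157,
    "extra_tra": 0.066, "extra_trb": 0.033, "extra_both": 0.021,
}
#: and with the earlier v1 protocol (far more chain dropout)
PAIRING_V1 = {
    "single_pair": 0.309, "tra_only": 0.202, "trb_only": 0.409,
    "extra_tra": 0.023, "extra_trb": 0.054, "extra_both": 0.003,
}
#: degenerate preset: every cell keeps exactly one TRA and one TRB
PAIRING_PERFECT = {
    "single_pair": 1.0, "tra_only": 0.0, "trb_only": 0.0,
    "extra_tra": 0.0, "extra_trb": 0.0, "extra_both": 0.0,
}


def _trunc_geom_cdf(p: float, hi: int) -> np.ndarray:
    probs = np.array([(1 - p) ** k for k in range(hi + 1)])
    return np.cumsum(probs / probs.sum())


@dataclass(frozen=True)
class TrimModel:
    """Truncated-geometric exonuclease trimming, per segment end (nt)."""

    p: float = 0.25
    max_trim: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "_cdf", _trunc_geom_cdf(self.p, self.max_trim))

    def sample(self, rng: np.random.Generator, upper: Optional[int] = None) -> int:
        hi = self.max_trim if upper is None else min(self.max_trim, upper)
        cdf = self._cdf if hi == self.max_trim else _trunc_geom_cdf(self.p, hi)
        return int(np.searchsorted(cdf, rng.random()))


@dataclass(frozen=True)
class InsertionModel:
    """Truncated-geometric N-insertion length, uniform ACGT composition."""

    p: float = 0.25
    max_ins: int = 12

    def __post_init__(self) -> None:
        object.__setattr__(self, "_cdf", _trunc_geom_cdf(self.p, self.max_ins))

    def sample(self, rng: np.random.Generator) -> str:
        n = int(np.searchsorted(self._cdf, rng.random()))
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@dataclass(frozen=True)
class ClonalityProfile:
    """Clone-mass profile for a sample.

    ``polyclonal``: near-uniform masses over ``n_clones`` (default: one
    clone per cell, so most observed clones are singletons).
    ``oligoclonal``: a few expanded clones over a polyclonal background
    (default top fractions 0.10/0.05/0.03, the melanoma-like regime).
    ``monoclonal``: one dominant clone (default 0.88 of cells, the
    T-cell-lymphoma-like regime) over a thin background.
    """

    name: str = "polyclonal"
    dominant_fractions: tuple[float, ...] = ()
    n_background: Optional[int] = None
    #: power-law decay exponent of background clone masses (0 = uniform);
    #: real repertoires have decaying clone-size spectra
    background_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ("polyclonal", "oligoclonal", "monoclonal"):
            raise ValueError(f"unknown clonality profile {self.name!r}")
        for f in self.dominant_fractions:
            if not 0 < f <= 1:
                raise ValueError("dominant-clone fractions must lie in (0, 1]")
        if sum(self.dominant_fractions) > 1:
            raise ValueError("dominant-clone fractions sum to more than 1")

    @classmethod
    def polyclonal(cls, n_clones: Optional[int] = None) -> "ClonalityProfile":
        return cls("polyclonal", (), n_clones)

    @classmethod
    def oligoclonal(
        cls,
        dominant_fractions: tuple[float, ...] = (0.10, 0.05, 0.03),
        n_background: Optional[int] = None,
        background_decay: float = 0.0,
    ) -> "ClonalityProfile":
        return cls("oligoclonal", tuple(dominant_fractions), n_background,
                   background_decay)

    @classmethod
    def monoclonal(
        cls, dominant_fraction: float = 0.88, n_background: Optional[int] = None,
        background_decay: float = 0.0,
    ) -> "ClonalityProfile":
        return cls("monoclonal", (dominant_fraction,), n_background, background_decay)

    def clone_masses(self, n_cells: int) -> np.ndarray:
        n_bg = self.n_background if self.n_background is not None else n_cells
        dom = np.array(self.dominant_fractions, dtype=float)
        bg_mass = 1.0 - dom.sum()
        bg = np.arange(1, n_bg + 1, dtype=float) ** (-self.background_decay)
        masses = np.concatenate([dom, bg_mass * bg / bg.sum()])
        return masses / masses.sum()


@dataclass
class SimulationConfig:
    """Full parameterization of one simulated sample; ``seed`` fixes all draws."""

    seed: int = 0
    n_cells: int = 5000
    profile: ClonalityProfile = field(default_factory=ClonalityProfile.polyclonal)
    usage_weights: Optional[dict[str, float]] = None  # default: uniform, functional only
    trim: TrimModel = field(default_factory=TrimModel)
    insertion: InsertionModel = field(default_factory=InsertionModel)
    pairing: dict[str, float] = field(default_factory=lambda: dict(PAIRING_V2))
    umi_lambda: dict[str, float] = field(default_factory=lambda: {"TRA": 6.6, "TRB": 12.5})
    donor_id: str = "donor1"
    max_retries: int = 200
    #: per-base substitution rate applied to emitted contigs (truth fields
    #: keep the error-free values); 0 disables the error model
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        validate_pairing(self.pairing)


def validate_pairing(pairing: dict[str, float]) -> None:
    unknown = set(pairing) - set(PAIRING_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown pairing categories: {sorted(unknown)}")
    total = sum(pairing.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"pairing probabilities sum to {total}, not 1")


@dataclass
class SimulatedContig:
    """One emitted contig with full generative ground truth."""

    chain: str
    v_key: str
    j_key: str
    c_key: str
    v_trim: int
    j_trim: int
    contig_nt: str
    d_key: Optional[str] = None
    d_trim5: int = 0
    d_trim3: int = 0
    ins1: str = ""
    ins2: str = ""
    umi_count: int = 1
    truth_cdr3_nt: Optional[str] = None
    truth_cdr3_aa: Optional[str] = None
    truth_productive: bool = False
    contig_id: str = ""


@dataclass
class SimulatedCell:
    barcode: str
    contigs: list[SimulatedContig]
    clone_id: int
    donor_id: str
    pairing_category: str = "single_pair"


@dataclass
class TruthTable:
    """Ground truth covering every emitted cell and contig."""

    cells: pd.DataFrame
    contigs: pd.DataFrame
    clone_cdr3: dict[int, tuple[tuple[str, str], ...]]
    germline_edits: dict[str, dict[str, list[GermlineEdit]]] = field(default_factory=dict)
    rescue_mechanisms: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)


def _frame0_stop_before(seg: GeneSegment, end: int) -> bool:
    """Any in-frame stop codon entirely within seg[0:end]? (cached per segment)"""
    stops = getattr(seg, "_frame0_stops", None)
    if stops is None:
        s = seg.nt_sequence
        stops = [i for i in range(0, len(s) - 2, 3) if s[i : i + 3] in STOP_CODONS]
        seg._frame0_stops = stops  # type: ignore[attr-defined]
    return any(p + 3 <= end for p in stops)


def _segment_weights(
    segs: list[GeneSegment], usage_weights: Optional[dict[str, float]]
) -> tuple[list[GeneSegment], np.ndarray]:
    if usage_weights is None:
        chosen = [s for s in segs if s.functional_class == "functional"]
        w = np.ones(len(chosen))
    else:
        chosen = [s for s in segs if usage_weights.get(s.key, 0.0) > 0]
        w = np.array([usage_weights[s.key] for s in chosen], dtype=float)
    if not chosen:
        raise ValueError("no eligible segments after applying usage weights")
    return chosen, w / w.sum()


class _ChainSampler:
    """Precomputed segment lists and sampling CDFs for one chain."""

    def __init__(self, refset: ReferenceSet, chain: str,
                 usage_weights: Optional[dict[str, float]]):
        self.vs, vw = _segment_weights(refset.select(chain, "V"), usage_weights)
        self.js, jw = _segment_weights(refset.select(chain, "J"), usage_weights)
        self.v_cdf = np.cumsum(vw)
        self.j_cdf = np.cumsum(jw)
        cs = refset.select(chain, "C")
        if not cs:
            raise ValueError(f"no C segment for chain {chain}")
        self.c = cs[0]
        self.ds = refset.select(chain, "D") if chain == "TRB" else []

    def pick_v(self, rng: np.random.Generator) -> GeneSegment:
        return self.vs[int(np.searchsorted(self.v_cdf, rng.random()))]

    def pick_j(self, rng: np.random.Generator) -> GeneSegment:
        return self.js[int(np.searchsorted(self.j_cdf, rng.random()))]


def _get_sampler(
    refset: ReferenceSet, chain: str, usage_weights: Optional[dict[str, float]]
) -> _ChainSampler:
    cache = refset.__dict__.setdefault("_samplers", {})
    key = (chain, tuple(sorted(usage_weights.items())) if usage_weights else None)
    if key not in cache:
        cache[key] = _ChainSampler(refset, chain, usage_weights)
    return cache[key]


def simulate_rearrangement(
    refset: ReferenceSet,
    chain: str,
    rng: np.random.Generator,
    trim: TrimModel = TrimModel(),
    insertion: InsertionModel = InsertionModel(),
    usage_weights: Optional[dict[str, float]] = None,
    j_min_trim: Optional[dict[str, int]] = None,
    max_retries: int = 200,
) -> SimulatedContig:
    """Simulate one V(D)J(C) rearrangement; TRB inserts a trimmed D segment.

    The contig is ``V[:len-v_trim] + ins1 (+ D' + ins2) + J[j_trim:] + C``.
    Truth CDR3 and productivity are computed by positional bookkeeping.
    """
    if chain not in ("TRA", "TRB"):
        raise ValueError(f"unknown chain {chain!r}")
    sampler = _get_sampler(refset, chain, usage_weights)
    c = sampler.c

    for _ in range(max_retries):
        v = sampler.pick_v(rng)
        j = sampler.pick_j(rng)
        v_trim = trim.sample(rng)
        lo = (j_min_trim or {}).get(j.key, 0)
        if lo > trim.max_trim:
            j_trim = lo
        elif lo > 0:
            j_trim = int(rng.integers(lo, trim.max_trim + 1))
        else:
            j_trim = trim.sample(rng)
        if v_trim >= len(v) or j_trim >= len(j):
            continue  # trim exceeds the segment: reject and resample

        ins1 = insertion.sample(rng)
        d_key, d_trim5, d_trim3, d_part, ins2 = None, 0, 0, "", ""
        if chain == "TRB":
            ds = sampler.ds
            if ds:
                d = ds[int(rng.integers(0, len(ds)))]
                d_key = d.key
                d_trim5 = trim.sample(rng, upper=len(d))
                d_trim3 = trim.sample(rng, upper=len(d) - d_trim5)
                d_part = d.nt_sequence[d_trim5 : len(d) - d_trim3]
                ins2 = insertion.sample(rng)

        v_part = v.nt_sequence[: len(v) - v_trim]
        j_part = j.nt_sequence[j_trim:]
        contig = v_part + ins1 + d_part + ins2 + j_part + c.nt_sequence
        j_start = len(v_part) + len(ins1) + len(d_part) + len(ins2)
        j_end = j_start + len(j_part)

        contig_obj = SimulatedContig(
            chain=chain, v_key=v.key, j_key=j.key, c_key=c.key,
            v_trim=v_trim, j_trim=j_trim, contig_nt=contig,
            d_key=d_key, d_trim5=d_trim5, d_trim3=d_trim3, ins1=ins1, ins2=ins2,
        )
        _fill_truth(contig_obj, v, j, j_start, j_end)
        return contig_obj
    raise RuntimeError(f"could not simulate a valid {chain} rearrangement "
                       f"after {max_retries} attempts")


def _fill_truth(
    ct: SimulatedContig, v: GeneSegment, j: GeneSegment, j_start: int, j_end: int
) -> None:
    """Definitional CDR3/productivity from the generative bookkeeping."""
    contig = ct.contig_nt
    vp_len = len(v) - ct.v_trim
    cys = v.cys_anchor
    cys_ok = cys is not None and cys + 3 <= vp_len
    jm = j.jmotif_anchor
    jm_ok = jm is not None and jm >= ct.j_trim
    if cys_ok and jm_ok:
        anchor_pos = j_start + (jm - ct.j_trim)
        ct.truth_cdr3_nt = contig[cys : anchor_pos + 3]
    else:
        ct.truth_productive = False
        return

    in_frame = anchor_pos % 3 == 0 and cys % 3 == 0
    if not in_frame:
        return
    # V prefix stops (precomputed per segment), then the junction-through-J scan
    if _frame0_stop_before(v, vp_len):
        return
    scan_from = max(0, 3 * (vp_len // 3 - 1))
    window = contig[scan_from:j_end]
    if has_stop(window):
        return
    cys_codon = contig[cys : cys + 3]
    anchor_codon = contig[anchor_pos : anchor_pos + 3]
    if cys_codon in CYS_CODONS and (anchor_codon in PHE_CODONS or anchor_codon in TRP_CODONS):
        ct.truth_productive = True
        ct.truth_cdr3_aa = translate(ct.truth_cdr3_nt)


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    s = list(seq)
    for i in hits:
        s[i] = "ACGT"[(("ACGT".index(s[i]) + int(rng.integers(1, 4))) % 4)]
    return "".join(s)


def _barcode(i: int) -> str:
    """Deterministic distinct 16-mers: index in base 4 over ACGT, plus '-1'."""
    digits = []
    for _ in range(16):
        digits.append("ACGT"[i % 4])
        i //= 4
    return "".join(reversed(digits)) + "-1"


def _simulate_founder_pair(
    refset: ReferenceSet, cfg: SimulationConfig, rng: np.random.Generator,
    j_min_trim: Optional[dict[str, int]] = None,
) -> list[SimulatedContig]:
    pair = []
    for chain in ("TRA", "TRB"):
        for _ in range(cfg.max_retries):
            ct = simulate_rearrangement(
                refset, chain, rng, cfg.trim, cfg.insertion,
                cfg.usage_weights, j_min_trim, cfg.max_retries,
            )
            if ct.truth_productive:
                pair.append(ct)
                break
        else:
            raise RuntimeError(f"no productive {chain} rearrangement found")
    return pair


def simulate_repertoire(
    refset: ReferenceSet,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    j_min_trim: Optional[dict[str, int]] = None,
    barcode_offset: int = 0,
) -> tuple[list[SimulatedCell], TruthTable]:
    """Simulate one sample: clones, cells, pairing noise, UMIs, truth.

    Every clone founder carries one productive TRA and one productive TRB
    rearrangement; all cells of a clone share those chains before pairing
    noise is applied. ``(cfg, seed)`` fully determines the output.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    masses = cfg.profile.clone_masses(cfg.n_cells)
    counts = rng.multinomial(cfg.n_cells, masses)

    founders: dict[int, list[SimulatedContig]] = {}
    for clone_id in np.nonzero(counts)[0]:
        founders[int(clone_id)] = _simulate_founder_pair(refset, cfg, rng, j_min_trim)

    cells: list[SimulatedCell] = []
    idx = barcode_offset
    for clone_id, pair in founders.items():
        for _ in range(counts[clone_id]):
            contigs = [replace(ct) for ct in pair]
            cells.append(
                SimulatedCell(
                    barcode=_barcode(idx), contigs=contigs,
                    clone_id=clone_id, donor_id=cfg.donor_id,
                )
            )
            idx += 1

    apply_pairing_model(cells, cfg.pairing, refset, cfg, rng, j_min_trim)

    for cell in cells:
        for k, ct in enumerate(cell.contigs):
            lam = cfg.umi_lambda.get(ct.chain, 5.0)
            ct.umi_count = 1 + int(rng.poisson(max(lam - 1.0, 0.0)))
            ct.contig_id = f"{cell.barcode}_contig_{k + 1}"
            if cfg.error_rate > 0:
                ct.contig_nt = _substitute(ct.contig_nt, cfg.error_rate, rng)

    truth = _build_truth(cells, founders)
    return cells, truth


def apply_pairing_model(
    cells: list[SimulatedCell],
    pairing: dict[str, float],
    refset: ReferenceSet,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    j_min_trim: Optional[dict[str, int]] = None,
) -> list[SimulatedCell]:
    """Drop or duplicate chains per cell, i.i.d. over pairing categories.

    Pre-condition: each cell carries exactly one TRA and one TRB. An
    "extra" chain reuses the founder's segments but re-draws the junction
    (resampled until productive), emulating a second rearranged allele.
    """
    validate_pairing(pairing)
    cats = list(PAIRING_CATEGORIES)
    probs = np.array([pairing.get(c, 0.0) for c in cats])
    draws = rng.choice(len(cats), size=len(cells), p=probs)

    def redraw(template: SimulatedContig) -> SimulatedContig:
        v = refset.get(template.v_key)
        j = refset.get(template.j_key)
        weights = {v.key: 1.0, j.key: 1.0}
        for _ in range(cfg.max_retries):
            ct = simulate_rearrangement(
                refset, template.chain, rng, cfg.trim, cfg.insertion,
                usage_weights=weights, j_min_trim=j_min_trim,
                max_retries=cfg.max_retries,
            )
            if ct.truth_productive and ct.truth_cdr3_nt != template.truth_cdr3_nt:
                return ct
        raise RuntimeError("could not re-draw a productive extra chain")

    for cell, di in zip(cells, draws):
        cat = cats[int(di)]
        cell.pairing_category = cat
        tra = [c for c in cell.contigs if c.chain == "TRA"]
        trb = [c for c in cell.contigs if c.chain == "TRB"]
        if len(tra) != 1 or len(trb) != 1:
            raise ValueError("pairing model requires cells with exactly 1 TRA + 1 TRB")
        if cat == "tra_only":
            cell.contigs = tra
        elif cat == "trb_only":
            cell.contigs = trb
        elif cat == "extra_tra":
            cell.contigs = tra + [redraw(tra[0])] + trb
        elif cat == "extra_trb":
            cell.contigs = tra + trb + [redraw(trb[0])]
        elif cat == "extra_both":
            cell.contigs = tra + [redraw(tra[0])] + trb + [redraw(trb[0])]
    return cells


def _build_truth(
    cells: list[SimulatedCell], founders: dict[int, list[SimulatedContig]]
) -> TruthTable:
    cell_rows = [
        {"barcode": c.barcode, "donor_id": c.donor_id, "clone_id": c.clone_id,
         "pairing_category": c.pairing_category}
        for c in cells
    ]
    contig_rows = []
    for c in cells:
        for ct in c.contigs:
            contig_rows.append({
                "barcode": c.barcode, "contig_id": ct.contig_id, "chain": ct.chain,
                "v_key": ct.v_key, "d_key": ct.d_key, "j_key": ct.j_key,
                "v_trim": ct.v_trim, "j_trim": ct.j_trim,
                "inserted_nt": ct.ins1 + ct.ins2,
                "cdr3_nt": ct.truth_cdr3_nt, "cdr3_aa": ct.truth_cdr3_aa,
                "productive": ct.truth_productive, "umi_count": ct.umi_count,
                "contig_length": len(ct.contig_nt),
            })
    clone_cdr3 = {
        cid: tuple(sorted((ct.chain, ct.truth_cdr3_nt) for ct in pair))
        for cid, pair in founders.items()
    }
    return TruthTable(
        cells=pd.DataFrame(cell_rows),
        contigs=pd.DataFrame(contig_rows),
        clone_cdr3=clone_cdr3,
    )


# ---------------------------------------------------------------------------
# Defect planting and rescue scenarios
# ---------------------------------------------------------------------------

RESCUE_MECHANISMS = ("germline_snv", "germline_consensus", "junctional")

#: width of the junction-proximal window (nt) inside which sequence changes
#: are attributed to V(D)J joining rather than germline variation
JUNCTION_WINDOW_NT = 12


@dataclass(frozen=True)
class PlantedRescue:
    """One defect-rescue scenario to plant in the simulation."""

    segment_key: str
    mechanism: str  # germline_snv | germline_consensus | junctional
    donors: tuple[str, ...] = ()
    edits: Optional[tuple[GermlineEdit, ...]] = None

    def __post_init__(self) -> None:
        if self.mechanism not in RESCUE_MECHANISMS:
            raise ValueError(f"unknown rescue mechanism {self.mechanism!r}")


def _auto_stop_fix(seg: GeneSegment) -> GermlineEdit:
    stops = [d for d in seg.defects if d.kind == "in_frame_stop"]
    if not stops:
        raise ValueError(f"{seg.key} has no in_frame_stop defect to fix")
    pos = stops[0].nt_position
    codon = seg.nt_sequence[pos : pos + 3]
    fixes = {"TAG": (0, "C"), "TAA": (0, "C"), "TGA": (1, "C")}  # ->CAG/CAA/TCA
    if codon not in fixes:
        raise ValueError(f"{seg.key}: no stop codon at defect position {pos}")
    off, base = fixes[codon]
    return GermlineEdit("SNV", pos + off, ref=codon[off], obs=base)


def plant_defect_and_rescue(
    refset: ReferenceSet, plan: list[PlantedRescue]
) -> tuple[dict[str, ReferenceSet], dict[str, int], dict]:
    """Materialize planted rescue mechanisms.

    Returns ``(donor_overrides, j_min_trim, truth)`` where
    ``donor_overrides`` maps donor ids to modified reference sets (germline
    mechanisms), ``j_min_trim`` maps J keys to the minimum junctional trim
    that removes a 5'-J stop (junctional mechanism), and ``truth`` records
    the planted mechanism labels and germline edits.
    """
    donor_refsets: dict[str, ReferenceSet] = {}
    j_min_trim: dict[str, int] = {}
    truth_mech: dict[str, tuple[str, tuple[str, ...]]] = {}
    truth_edits: dict[str, dict[str, list[GermlineEdit]]] = {}

    for planted in plan:
        seg = refset.get(planted.segment_key)
        if planted.mechanism in ("germline_snv", "germline_consensus"):
            if planted.edits is not None:
                edits = list(planted.edits)
            elif planted.mechanism == "germline_snv":
                edits = [_auto_stop_fix(seg)]
            else:
                raise ValueError("germline_consensus rescue requires explicit edits")
            for donor in planted.donors:
                donor_rs = donor_refsets.setdefault(donor, copy.deepcopy(refset))
                donor_rs.__dict__.pop("_samplers", None)
                dseg = donor_rs.get(planted.segment_key)
                dseg.nt_sequence = apply_edits(seg.nt_sequence, edits)
                from .reference import locate_cys_anchor, locate_jmotif_anchor

                if dseg.segment_class == "V":
                    dseg.cys_anchor = locate_cys_anchor(dseg.nt_sequence)
                elif dseg.segment_class == "J":
                    dseg.jmotif_anchor = locate_jmotif_anchor(dseg.nt_sequence)
                dseg._frame0_stops = None  # type: ignore[attr-defined]
                truth_edits.setdefault(donor, {})[seg.key] = list(edits)
        else:  # junctional
            stops = [d for d in seg.defects if d.kind == "in_frame_stop"]
            if not stops:
                raise ValueError(f"{seg.key}: junctional rescue needs an in_frame_stop")
            end = stops[0].nt_position + 3
            if seg.segment_class != "J" or end > JUNCTION_WINDOW_NT:
                raise ValueError(
                    f"{seg.key}: defect lies outside the junction window; "
                    "junctional rescue impossible"
                )
            min_trim = 3 * ((end + 2) // 3)
            j_min_trim[seg.key] = min_trim
        truth_mech[seg.key] = (planted.mechanism, tuple(planted.donors))

    return donor_refsets, j_min_trim, {"mechanisms": truth_mech, "edits": truth_edits}


DEFAULT_RESCUE_DONORS = ("donorA", "donorB", "donorC", "donorD", "donorE")


def default_rescue_plan(
    rescue_edits: dict[str, list[GermlineEdit]],
    carrier_donor: str = "donorE",
    consensus_donors: tuple[str, ...] = DEFAULT_RESCUE_DONORS,
) -> list[PlantedRescue]:
    """The three canonical rescue scenarios on the default reference:

    a single-donor stop-correcting germline SNV (TRBV19-like), a
    multi-donor multi-variant germline consensus (TRAV9-2-like), and an
    all-donor junctional correction (TRBJ1-3-like).
    """
    return [
        PlantedRescue("TRBV19*01", "germline_snv", donors=(carrier_donor,)),
        PlantedRescue("TRAV9-2*01", "germline_consensus", donors=consensus_donors,
                      edits=tuple(rescue_edits["TRAV9-2*01"])),
        PlantedRescue("TRBJ1-3*01", "junctional"),
    ]


def simulate_rescue_study(
    refset: ReferenceSet,
    plan: list[PlantedRescue],
    donors: tuple[str, ...],
    cells_per_donor: int,
    seed: int,
    defective_weight: float = 4.0,
) -> tuple[list[SimulatedCell], TruthTable]:
    """Multi-donor study exercising the planted rescue mechanisms.

    Every donor contributes ``cells_per_donor`` polyclonal cells. Usage
    weights include the planted defective segments (boosted so enough
    clonotypes use them); donors lacking a corrective germline variant
    simply never yield productive rearrangements of that segment.
    """
    donor_overrides, j_min_trim, truth_info = plant_defect_and_rescue(refset, plan)
    planted_keys = {p.segment_key for p in plan}
    rng = np.random.default_rng(seed)

    weights: dict[str, float] = {}
    for s in refset:
        if s.segment_class in ("V", "J"):
            if s.key in planted_keys:
                weights[s.key] = defective_weight
            elif s.functional_class == "functional":
                weights[s.key] = 1.0

    all_cells: list[SimulatedCell] = []
    cell_frames, contig_frames = [], []
    clone_cdr3: dict[int, tuple] = {}
    offset = 0
    for d_idx, donor in enumerate(donors):
        cfg = SimulationConfig(
            seed=seed, n_cells=cells_per_donor,
            profile=ClonalityProfile.polyclonal(),
            usage_weights=weights, pairing=dict(PAIRING_PERFECT),
            donor_id=donor,
        )
        donor_rs = donor_overrides.get(donor, refset)
        cells, truth = simulate_repertoire(
            donor_rs, cfg, rng=rng, j_min_trim=j_min_trim, barcode_offset=offset
        )
        offset += len(cells)
        # clone ids are per-donor; make them globally unique
        shift = 10_000_000 * d_idx
        for c in cells:
            c.clone_id += shift
        truth.cells["clone_id"] += shift
        clone_cdr3.update({cid + shift: v for cid, v in truth.clone_cdr3.items()})
        all_cells.extend(cells)
        cell_frames.append(truth.cells)
        contig_frames.append(truth.contigs)

    truth = TruthTable(
        cells=pd.concat(cell_frames, ignore_index=True),
        contigs=pd.concat(contig_frames, ignore_index=True),
        clone_cdr3=clone_cdr3,
        germline_edits=truth_info["edits"],
        rescue_mechanisms=truth_info["mechanisms"],
    )
    return all_cells, truth


def export_simulation(cells: list[SimulatedCell], truth: TruthTable, outdir) -> dict:
    """Write contig FASTA, AIRR TSV and truth CSVs; returns the paths."""
    from pathlib import Path

    from .io import cells_to_airr, write_airr

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "contigs.fasta"
    with open(fasta, "w") as fh:
        for cell in cells:
            for ct in cell.contigs:
                fh.write(f">{ct.contig_id} {cell.barcode}|{ct.chain}\n{ct.contig_nt}\n")
    airr = out / "rearrangements.airr.tsv"
    write_airr(cells_to_airr(cells), airr)
    truth_cells = out / "truth_cells.csv"
    truth_contigs = out / "truth_contigs.csv"
    truth.cells.to_csv(truth_cells, index=False, lineterminator="\n")
    truth.contigs.to_csv(truth_contigs, index=False, lineterminator="\n")
    return {"fasta": fasta, "airr": airr, "truth_cells": truth_cells,
            "truth_contigs": truth_contigs}
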