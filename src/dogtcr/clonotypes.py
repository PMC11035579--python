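"""Clonotype construction, chain pairing and repertoire diversity statistics.

A clonotype is one or more TRA and/or one or more TRB resolved productive
CDR3 nucleotide sequences expressed in one or more cells: cells are
grouped by the exact sorted multiset of their productive (chain, cdr3_nt)
pairs. On top of that partition this module computes the repertoire
statistics a clinical TCR study reports: Inverse Simpson diversity,
rank-binned clonotype distributions with permutation downsampling,
chain-pairing taxonomy, per-subset diversity, V x J usage with a
functional-class coverage census, length distributions and a per-sample
summary record.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .reference import ReferenceSet

PAIRING_BINS = (
    "single_pair", "tra_only", "trb_only", "extra_tra", "extra_trb",
    "extra_both", "gt2_chains",
)

#: rank bins of the clonotype distribution (1-based ranks, inclusive)
DEFAULT_RANK_BINS = ((1, 1), (2, 5), (6, 10), (11, 100), (101, 1000), (1001, None))


@dataclass(frozen=True)
class DiversityResult:
    inverse_simpson: float
    n_cells: int
    n_clonotypes: int


def build_clonotypes(annotations: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group cells into clonotypes by their productive CDR3 nt multiset.

    Returns ``(clonotypes, cell_map)``. ``clonotypes`` has one row per
    clonotype (id, n_cells, proportion, cdr3s_nt, cdr3s_aa); ``cell_map``
    maps each clonotyped barcode to its clonotype_id. Cells without any
    productive chain (or flagged chain_conflict) are excluded and counted
    in ``clonotypes.attrs["n_cells_excluded"]``.
    """
    ann = annotations
    usable = ann[
        ann["productive"]
        & ann["cdr3_nt"].notna()
        & ~ann["flags"].fillna("").str.contains("chain_conflict")
    ]
    all_barcodes = set(ann["barcode"])
    keys: dict[str, tuple] = {}
    aa_keys: dict[str, tuple] = {}
    for barcode, grp in usable.groupby("barcode", sort=True):
        pairs = sorted(zip(grp["chain"], grp["cdr3_nt"]))
        keys[barcode] = tuple(pairs)
        aa_keys[barcode] = tuple(
            sorted(zip(grp["chain"], grp["cdr3_aa"].fillna("")))
        )
    n_excluded = len(all_barcodes) - len(keys)

    by_key: dict[tuple, list[str]] = {}
    for barcode, key in keys.items():
        by_key.setdefault(key, []).append(barcode)

    ordered = sorted(by_key.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    total = sum(len(v) for _, v in ordered)
    rows, mapping = [], []
    for rank, (key, barcodes) in enumerate(ordered, start=1):
        cid = f"clonotype{rank}"
        rows.append({
            "clonotype_id": cid,
            "n_cells": len(barcodes),
            "proportion": len(barcodes) / total,
            "cdr3s_nt": ";".join(f"{ch}:{nt}" for ch, nt in key),
            "cdr3s_aa": ";".join(
                f"{ch}:{aa}" for ch, aa in aa_keys[barcodes[0]]
            ),
        })
        mapping.extend({"barcode": b, "clonotype_id": cid} for b in sorted(barcodes))
    clonotypes = pd.DataFrame(
        rows, columns=["clonotype_id", "n_cells", "proportion", "cdr3s_nt", "cdr3s_aa"]
    )
    clonotypes.attrs["n_cells_excluded"] = n_excluded
    cell_map = pd.DataFrame(mapping, columns=["barcode", "clonotype_id"])
    return clonotypes, cell_map


def classify_pairing(cdr3s_nt: str | Iterable[tuple[str, str]]) -> str:
    """Pairing category from TRA/TRB chain counts of one clonotype.

    (1,1) single_pair; (1,0) tra_only; (0,1) trb_only; (2,1) extra_tra;
    (1,2) extra_trb; (2,2) extra_both; anything above 2 of either chain
    is gt2_chains (duplicate/artifact territory).
    """
    if isinstance(cdr3s_nt, str):
        chains = [part.split(":", 1)[0] for part in cdr3s_nt.split(";") if part]
    else:
        chains = [ch for ch, _ in cdr3s_nt]
    a = chains.count("TRA")
    b = chains.count("TRB")
    if a == 0 and b == 0:
        raise ValueError("clonotype with no chains should not exist")
    if a > 2 or b > 2:
        return "gt2_chains"
    table = {
        (1, 1): "single_pair", (1, 0): "tra_only", (0, 1): "trb_only",
        (2, 1): "extra_tra", (1, 2): "extra_trb", (2, 2): "extra_both",
        (2, 0): "gt2_chains", (0, 2): "gt2_chains",
    }
    return table[(a, b)]


def pairing_summary(
    clonotypes: pd.DataFrame,
    cell_map: Optional[pd.DataFrame] = None,
    by: str = "clonotype",
) -> dict[str, float]:
    """Fraction of clonotypes (or cells) in each pairing category.

    ``by="clonotype"`` weights each distinct clonotype once (the reported
    taxonomy); ``by="cell"`` weights by member cells, which recovers an
    i.i.d. per-cell pairing process exactly.
    """
    if clonotypes.empty:
        raise ValueError("pairing summary of an empty clonotype table")
    cats = clonotypes["cdr3s_nt"].map(classify_pairing)
    if by == "clonotype":
        weights = np.ones(len(clonotypes))
    elif by == "cell":
        weights = clonotypes["n_cells"].to_numpy(dtype=float)
    else:
        raise ValueError("by must be 'clonotype' or 'cell'")
    total = weights.sum()
    out = {c: 0.0 for c in PAIRING_BINS}
    for cat, w in zip(cats, weights):
        out[cat] += float(w / total)
    return out


def inverse_simpson(proportions: Iterable[float]) -> float:
    """Inverse Simpson index 1 / sum(p_i^2) of a frequency vector.

    1 means a single clonotype (minimally diverse); n means n equally
    frequent clonotypes (maximally diverse).
    """
    p = np.asarray(list(proportions), dtype=float)
    if p.size == 0:
        raise ValueError("empty proportion vector")
    if (p < 0).any():
        raise ValueError("negative proportions")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()}, not 1")
    return float(1.0 / np.square(p).sum())


def diversity(clonotypes: pd.DataFrame, paired_only: bool = False) -> DiversityResult:
    """Inverse Simpson over clonotype frequencies.

    By default every clonotyped cell counts (paired and unpaired
    clonotypes); ``paired_only`` restricts the frequency vector to
    clonotypes with at least one TRA and one TRB.
    """
    df = clonotypes
    if paired_only:
        cats = df["cdr3s_nt"].map(classify_pairing)
        df = df[cats.isin(["single_pair", "extra_tra", "extra_trb", "extra_both"])]
    if df.empty:
        raise ValueError("no clonotypes to compute diversity over")
    counts = df["n_cells"].to_numpy(dtype=float)
    p = counts / counts.sum()
    return DiversityResult(
        inverse_simpson=inverse_simpson(p),
        n_cells=int(counts.sum()),
        n_clonotypes=len(df),
    )


def clonotype_bin_proportions(
    counts: Iterable[int], bins=DEFAULT_RANK_BINS
) -> dict[str, float]:
    """Fraction of cells per clonotype rank bin (ranks sorted by descending
    cell count, ties broken by the caller's stable order)."""
    c = np.asarray(sorted(counts, reverse=True), dtype=float)
    total = c.sum()
    out = {}
    for lo, hi in bins:
        hi_idx = len(c) if hi is None else min(hi, len(c))
        label = _bin_label(lo, hi)
        out[label] = float(c[lo - 1 : hi_idx].sum() / total) if lo - 1 < len(c) else 0.0
    return out


def _bin_label(lo: int, hi: Optional[int]) -> str:
    if hi is None:
        return f">{lo - 1}"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


def downsample_diversity(
    cell_labels: Iterable,
    n_target: int = 1850,
    n_perm: int = 100,
    seed: int = 0,
    bins=DEFAULT_RANK_BINS,
) -> dict:
    """Permutation downsampling of the clonotype distribution.

    Draws ``n_target`` cells with replacement from the per-cell clonotype
    labels, recomputes rank-bin cell fractions and Inverse Simpson
    diversity per permutation, and averages across ``n_perm`` permutations
    (defaults: 100 permutations, 1,850 cells).
    """
    raw = list(cell_labels)
    codes = {k: i for i, k in enumerate(dict.fromkeys(raw))}
    labels = np.array([codes[k] for k in raw], dtype=np.int64)
    if labels.size == 0:
        raise ValueError("no cell labels to downsample")
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n_lab = labels.max() + 1
    bin_acc: dict[str, float] = {}
    div_acc = 0.0
    for _ in range(n_perm):
        draw = rng.integers(0, labels.size, size=n_target)
        counts = np.bincount(labels[draw], minlength=n_lab)
        counts = counts[counts > 0]
        fr = clonotype_bin_proportions(counts, bins=bins)
        for k, v in fr.items():
            bin_acc[k] = bin_acc.get(k, 0.0) + v
        p = counts / counts.sum()
        div_acc += inverse_simpson(p)
    return {
        "bin_fractions": {k: v / n_perm for k, v in bin_acc.items()},
        "inverse_simpson": div_acc / n_perm,
        "n_target": n_target,
        "n_perm": n_perm,
    }


def subset_diversity(
    cell_map: pd.DataFrame, cell_types: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell-type diversity and top-clone proportion.

    ``cell_types`` needs columns barcode, cell_type; unlabeled clonotyped
    cells are excluded and counted in ``result.attrs["n_unlabeled"]``.
    """
    merged = cell_map.merge(cell_types[["barcode", "cell_type"]], on="barcode", how="left")
    n_unlabeled = int(merged["cell_type"].isna().sum())
    labeled = merged.dropna(subset=["cell_type"])
    if labeled.empty:
        raise ValueError("no labeled cells")
    rows = []
    for cell_type, grp in labeled.groupby("cell_type", sort=True):
        counts = grp["clonotype_id"].value_counts().to_numpy(dtype=float)
        p = counts / counts.sum()
        rows.append({
            "cell_type": cell_type,
            "n_cells": int(counts.sum()),
            "n_clonotypes": len(counts),
            "inverse_simpson": inverse_simpson(p),
            "top_clone_proportion": float(p.max()),
        })
    out = pd.DataFrame(rows)
    out.attrs["n_unlabeled"] = n_unlabeled
    return out


def segment_usage(
    annotations: pd.DataFrame,
    refset: ReferenceSet,
    productive_only: bool = True,
    cell_map: Optional[pd.DataFrame] = None,
) -> dict:
    """V x J usage counts per chain plus a functional-class coverage census.

    Counts unique cell barcodes per segment and per V x J combination; a
    cell with several annotated chains counts toward every segment it
    uses. Segment calls absent from the reference are flagged.
    """
    ann = annotations[annotations["v_call"].notna() & annotations["j_call"].notna()]
    if productive_only:
        ann = ann[ann["productive"]]
    known = {s.key for s in refset}
    unknown = sorted(
        (set(ann["v_call"]) | set(ann["j_call"])) - known
    )
    usage = (
        ann.groupby(["chain", "v_call", "j_call"])["barcode"]
        .nunique()
        .rename("n_cells")
        .reset_index()
    )
    seg_cells: dict[str, int] = {}
    for col in ("v_call", "j_call"):
        for key, n in ann.groupby(col)["barcode"].nunique().items():
            seg_cells[key] = seg_cells.get(key, 0) + int(n)
    seg_clonotypes: dict[str, int] = {}
    if cell_map is not None:
        ann_ct = ann.merge(cell_map, on="barcode", how="inner")
        for col in ("v_call", "j_call"):
            for key, n in ann_ct.groupby(col)["clonotype_id"].nunique().items():
                seg_clonotypes[key] = seg_clonotypes.get(key, 0) + int(n)

    observed = set(seg_cells)
    census_rows = []
    for chain in ("TRA", "TRB"):
        for seg_class in ("V", "J"):
            for func in ("functional", "ORF", "pseudogene"):
                segs = [
                    s for s in refset
                    if s.chain == chain and s.segment_class == seg_class
                    and s.functional_class == func
                ]
                if not segs:
                    continue
                n_obs = sum(1 for s in segs if s.key in observed)
                census_rows.append({
                    "chain": chain, "segment_class": seg_class,
                    "functional_class": func, "n_known": len(segs),
                    "n_observed": n_obs, "coverage": n_obs / len(segs),
                })
    return {
        "usage_matrix": usage,
        "segment_cells": seg_cells,
        "segment_clonotypes": seg_clonotypes,
        "coverage_census": pd.DataFrame(census_rows),
        "unknown_segments": unknown,
    }


def length_distributions(
    annotations: pd.DataFrame, refset: Optional[ReferenceSet] = None
) -> dict:
    """Contig and CDR3 length summaries per chain; optionally the reference
    V-J (TRA) / V-D-J (TRB) combination length table by exhaustive pairing."""
    out: dict = {"observed": {}}
    for chain, grp in annotations.groupby("chain"):
        lengths = grp["contig_length"].dropna()
        cdr3nt = grp["cdr3_nt"].dropna().str.len()
        cdr3aa = grp["cdr3_aa"].dropna().str.len()
        out["observed"][chain] = {
            "contig_nt": _summary(lengths),
            "cdr3_nt": _summary(cdr3nt),
            "cdr3_aa": _summary(cdr3aa),
        }
    if refset is not None:
        ref_rows = []
        for chain in ("TRA", "TRB"):
            vs = refset.select(chain, "V")
            js = refset.select(chain, "J")
            ds = refset.select(chain, "D") if chain == "TRB" else [None]
            for v, j, d in itertools.product(vs, js, ds):
                total = len(v) + len(j) + (len(d) if d is not None else 0)
                ref_rows.append({
                    "chain": chain, "v": v.key, "j": j.key,
                    "d": d.key if d is not None else None, "length": total,
                })
        ref_df = pd.DataFrame(ref_rows)
        out["reference_combinations"] = ref_df
        out["reference_summary"] = {
            chain: _summary(ref_df[ref_df["chain"] == chain]["length"])
            for chain in ("TRA", "TRB")
        }
    return out


def _summary(values) -> dict:
    v = pd.Series(values, dtype=float)
    if v.empty:
        return {"median": None, "min": None, "max": None, "n": 0}
    return {"median": float(v.median()), "min": float(v.min()),
            "max": float(v.max()), "n": int(v.size)}


def summary_metrics(
    annotations: pd.DataFrame,
    clonotypes: pd.DataFrame,
    paired_only_diversity: bool = False,
) -> dict:
    """Per-sample summary record in the style of a sequencing-metrics table."""
    from .annotate import barcode_summary

    bc = barcode_summary(annotations)
    n_cells = len(bc)
    if n_cells == 0:
        raise ValueError("no cells to summarize")

    def frac(col):
        return float(bc[col].mean())

    div = diversity(clonotypes, paired_only=paired_only_diversity)
    metrics = {
        "estimated_cells": n_cells,
        "cells_with_tra_contig": frac("has_tra"),
        "cells_with_trb_contig": frac("has_trb"),
        "cells_with_cdr3_tra": frac("cdr3_tra"),
        "cells_with_cdr3_trb": frac("cdr3_trb"),
        "cells_with_productive_tra": frac("productive_tra"),
        "cells_with_productive_trb": frac("productive_trb"),
        "cells_with_productive_pair": frac("productive_pair"),
        "unique_clonotypes": int(len(clonotypes)),
        "paired_clonotype_diversity": div.inverse_simpson,
    }
    if "umi_count" in annotations.columns and annotations["umi_count"].notna().any():
        per_cell = annotations.groupby("barcode")["umi_count"].sum()
        metrics["median_umis_per_cell"] = float(per_cell.median())
    return metrics
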