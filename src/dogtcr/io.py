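"""Readers/writers for the formats around the pipeline, plus the pipeline
driver.

Supported formats: AIRR Rearrangement TSV (the community standard for
rearrangement records), cellranger-style ``filtered_contig_annotations.csv``
and ``clonotypes.csv`` dialects, and a YAML pipeline configuration. All
tables are written UTF-8 with LF line endings and explicit headers;
summary floats are rounded to 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

AIRR_COLUMNS = [
    "cell_id", "locus", "v_call", "j_call", "junction", "junction_aa",
    "productive", "consensus_count",
]

CONTIG_CSV_COLUMNS = [
    "barcode", "contig_id", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt",
    "productive", "full_length", "length",
]

CLONOTYPE_CSV_COLUMNS = ["clonotype_id", "frequency", "proportion", "cdr3s_aa", "cdr3s_nt"]


# ---------------------------------------------------------------------------
# AIRR Rearrangement TSV
# ---------------------------------------------------------------------------

def write_airr(records: pd.DataFrame, path) -> None:
    """Write rearrangement records as AIRR TSV (productive as T/F)."""
    missing = [c for c in AIRR_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"missing mandatory AIRR column: {missing[0]}")
    df = records[AIRR_COLUMNS].copy()
    df["productive"] = df["productive"].map(lambda b: "T" if b else "F")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_airr(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory AIRR column: {missing[0]}")
    df["productive"] = df["productive"].map({"T": True, "F": False})
    df["consensus_count"] = pd.to_numeric(df["consensus_count"], errors="coerce")
    df = df.replace({"": None})
    return df


def cells_to_airr(cells) -> pd.DataFrame:
    """AIRR records from simulated cells (truth CDR3s as junctions)."""
    rows = []
    for cell in cells:
        for ct in cell.contigs:
            rows.append({
                "cell_id": cell.barcode, "locus": ct.chain,
                "v_call": ct.v_key, "j_call": ct.j_key,
                "junction": ct.truth_cdr3_nt or "",
                "junction_aa": ct.truth_cdr3_aa or "",
                "productive": ct.truth_productive,
                "consensus_count": ct.umi_count,
            })
    return pd.DataFrame(rows, columns=AIRR_COLUMNS)


def annotations_to_airr(annotations: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame({
        "cell_id": annotations["barcode"],
        "locus": annotations["chain"].fillna(""),
        "v_call": annotations["v_call"].fillna(""),
        "j_call": annotations["j_call"].fillna(""),
        "junction": annotations["cdr3_nt"].fillna(""),
        "junction_aa": annotations["cdr3_aa"].fillna(""),
        "productive": annotations["productive"].fillna(False),
        "consensus_count": annotations["umi_count"],
    })
    return out


# ---------------------------------------------------------------------------
# cellranger-style CSV dialects
# ---------------------------------------------------------------------------

def write_cellranger_contigs(annotations: pd.DataFrame, path) -> None:
    """Write annotations in the filtered_contig_annotations.csv dialect."""
    df = pd.DataFrame({
        "barcode": annotations["barcode"],
        "contig_id": annotations["contig_id"],
        "chain": annotations["chain"],
        "v_gene": annotations["v_call"],
        "j_gene": annotations["j_call"],
        "cdr3": annotations["cdr3_aa"],
        "cdr3_nt": annotations["cdr3_nt"],
        "productive": annotations["productive"],
        "full_length": annotations["full_length"],
        "length": annotations["contig_length"],
    })
    df.to_csv(path, index=False, lineterminator="\n")


def read_cellranger_contigs(path) -> pd.DataFrame:
    """Read the contig CSV dialect into the internal annotation layout.

    Unknown extra columns are preserved; malformed rows raise with the
    offending line number.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV in {path}: {exc}") from exc
    missing = [c for c in CONTIG_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"contig CSV missing columns: {missing}")
    rename = {"v_gene": "v_call", "j_gene": "j_call", "cdr3": "cdr3_aa",
              "length": "contig_length"}
    out = df.rename(columns=rename)
    for col in ("productive", "full_length"):
        out[col] = out[col].astype(bool)
    if "flags" not in out.columns:
        out["flags"] = ""
    return out


def write_clonotypes_csv(clonotypes: pd.DataFrame, path) -> None:
    df = pd.DataFrame({
        "clonotype_id": clonotypes["clonotype_id"],
        "frequency": clonotypes["n_cells"],
        "proportion": clonotypes["proportion"].map(lambda x: float(f"{x:.6g}")),
        "cdr3s_aa": clonotypes["cdr3s_aa"],
        "cdr3s_nt": clonotypes["cdr3s_nt"],
    })
    df.to_csv(path, index=False, lineterminator="\n")


def read_clonotypes_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV in {path}: {exc}") from exc
    missing = [c for c in CLONOTYPE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clonotype CSV missing columns: {missing}")
    out = df.rename(columns={"frequency": "n_cells"})
    return out


def parse_cdr3s(field: str) -> list[tuple[str, str]]:
    """Parse a 'TRA:CAX...;TRB:CAS...' field into (chain, sequence) pairs."""
    if not isinstance(field, str) or not field:
        return []
    out = []
    for part in field.split(";"):
        chain, _, seq = part.partition(":")
        out.append((chain, seq))
    return out


# ---------------------------------------------------------------------------
# Pipeline configuration and driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration; round-trips losslessly through YAML."""

    seed: int = 0
    n_cells: int = 500
    profile: str = "polyclonal"
    dominant_fractions: list[float] = field(default_factory=list)
    pairing_preset: str = "v2"  # v2 | v1 | perfect
    expanded_threshold: float = 0.01
    downsample_n_target: int = 1850
    downsample_n_perm: int = 100
    paired_only_diversity: bool = False
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "annotate": True, "clonotype": True,
        "rescue": False, "phenotype": False,
    })

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _make_profile(cfg: PipelineConfig):
    from .simulate import ClonalityProfile

    if cfg.profile == "polyclonal":
        return ClonalityProfile.polyclonal()
    if cfg.profile == "oligoclonal":
        fr = tuple(cfg.dominant_fractions) or (0.10, 0.05, 0.03)
        return ClonalityProfile.oligoclonal(fr)
    if cfg.profile == "monoclonal":
        fr = cfg.dominant_fractions[0] if cfg.dominant_fractions else 0.88
        return ClonalityProfile.monoclonal(fr)
    raise ValueError(f"unknown profile {cfg.profile!r}")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the toggled stages end to end; returns the summary dict.

    Writes contig annotations (cellranger CSV dialect + AIRR TSV),
    clonotypes.csv, summary.json and run.log under ``outdir``. Identical
    (config, seed) pairs produce byte-identical outputs.
    """
    from . import __version__
    from .annotate import annotate_contigs
    from .clonotypes import (build_clonotypes, clonotype_bin_proportions, diversity,
                             downsample_diversity, pairing_summary, summary_metrics)
    from .phenotype import label_expanded, simulate_expression, test_markers
    from .refdata import build_default_reference
    from .simulate import (PAIRING_PERFECT, PAIRING_V1, PAIRING_V2, SimulationConfig,
                           default_rescue_plan, simulate_repertoire,
                           simulate_rescue_study)

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("dogtcr.pipeline")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("dogtcr %s", __version__)
    log.info("config: %s", dataclasses.asdict(config))

    summary: dict = {"seed": config.seed, "version": __version__}
    try:
        refset, rescue_edits = build_default_reference()
        presets = {"v2": PAIRING_V2, "v1": PAIRING_V1, "perfect": PAIRING_PERFECT}
        sim_cfg = SimulationConfig(
            seed=config.seed, n_cells=config.n_cells, profile=_make_profile(config),
            pairing=dict(presets[config.pairing_preset]),
        )
        cells = truth = None
        if config.stages.get("simulate", True):
            log.info("stage simulate: n_cells=%d profile=%s", config.n_cells, config.profile)
            cells, truth = simulate_repertoire(refset, sim_cfg)
            from .simulate import export_simulation

            export_simulation(cells, truth, out)
        annotations = None
        if config.stages.get("annotate", True) and cells is not None:
            log.info("stage annotate")
            annotations = annotate_contigs(cells, refset)
            write_cellranger_contigs(annotations, out / "filtered_contig_annotations.csv")
            write_airr(annotations_to_airr(annotations), out / "annotations.airr.tsv")
        if config.stages.get("clonotype", True) and annotations is not None:
            log.info("stage clonotype")
            clonotypes, cell_map = build_clonotypes(annotations)
            write_clonotypes_csv(clonotypes, out / "clonotypes.csv")
            cell_map.to_csv(out / "cell_clonotypes.csv", index=False, lineterminator="\n")
            div = diversity(clonotypes, paired_only=config.paired_only_diversity)
            labels = cell_map["clonotype_id"]
            ds = downsample_diversity(
                labels, n_target=config.downsample_n_target,
                n_perm=config.downsample_n_perm, seed=config.seed,
            )
            summary.update({
                "metrics": _round(summary_metrics(annotations, clonotypes)),
                "pairing": _round(pairing_summary(clonotypes)),
                "diversity": _round({
                    "inverse_simpson": div.inverse_simpson,
                    "n_cells": div.n_cells, "n_clonotypes": div.n_clonotypes,
                }),
                "bin_fractions": _round(
                    clonotype_bin_proportions(clonotypes["n_cells"])
                ),
                "downsampled": _round(ds["bin_fractions"]),
            })
        if config.stages.get("rescue", False):
            log.info("stage rescue")
            from .analysis_helpers import run_rescue_assessment

            plan = default_rescue_plan(rescue_edits)
            res = run_rescue_assessment(refset, plan, seed=config.seed)
            res.proposals.to_csv(out / "reannotation_proposals.csv", index=False,
                                 lineterminator="\n")
            summary["rescue"] = [
                {"segment": a.segment_key, "defect": a.defect.kind,
                 "status": a.status, "mechanism": a.mechanism}
                for a in res.assessments
            ]
        if config.stages.get("phenotype", False):
            log.info("stage phenotype")
            expr, expanded = simulate_expression(
                500, 500, shifts={"GZMA": 1.0}, seed=config.seed
            )
            res = test_markers(expr, expanded)
            res.to_csv(out / "marker_tests.csv", index=False, lineterminator="\n")
            summary["phenotype"] = {
                "n_significant": int((res["direction"].isin(
                    ["up_in_expanded", "down_in_expanded"])).sum()),
            }
    except Exception as exc:  # pragma: no cover - exercised via CLI
        log.error("pipeline failed: %s", exc)
        raise
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.removeHandler(handler)
    handler.close()
    return summary


def _round(d: dict) -> dict:
    return {k: (float(f"{v:.6g}") if isinstance(v, float) else v) for k, v in d.items()}
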