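"""Expanded vs non-expanded T-cell phenotype testing.

Cells are labeled *expanded* when their clonotype accounts for more than
a threshold fraction (default 1%, strict) of all cells in the sample.
Activation/exhaustion (and memory/naive) marker genes are then compared
between expanded and non-expanded cells with a two-sided Wilcoxon
rank-sum test, Bonferroni-corrected over the number of markers actually
tested (16 for the default activation + exhaustion panel).

Expression values are log-scale normalized per-cell counts (log_e(x+1) of
library-size-scaled counts); per-gene z-scaling is a display concern and
is not applied before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

MARKER_PANELS: dict[str, tuple[str, ...]] = {
    "activation": ("CD38", "GZMA", "GZMK", "MKI67"),
    "exhaustion": ("CTLA4", "HAVCR2", "NFATC1", "NR4A1", "NR4A2", "NR4A3",
                   "PDCD1", "PRDM1", "TCF7", "TIGIT", "TOX", "TOX2"),
    "effector_memory": ("CCL5", "ZEB2", "GZMK"),
    "naive": ("LEF1", "TCF7", "CCR7"),
}

#: the default differential-expression panel: 16 activation + exhaustion markers
DEFAULT_PANEL = ("activation", "exhaustion")
EXPANDED_THRESHOLD = 0.01
ALPHA = 0.05


@dataclass(frozen=True)
class MarkerTestResult:
    gene: str
    panel: str
    statistic: Optional[float]
    p_value: Optional[float]
    p_adjusted: Optional[float]
    direction: str  # up_in_expanded | down_in_expanded | ns | missing


def label_expanded(
    cell_map: pd.DataFrame,
    clonotypes: pd.DataFrame,
    threshold: float = EXPANDED_THRESHOLD,
    cell_types: Optional[pd.DataFrame] = None,
    cell_type: Optional[str] = None,
) -> pd.DataFrame:
    """Per-cell expansion flag: clonotype proportion strictly above threshold.

    Proportions are taken over all clonotyped cells in the sample. When
    ``cell_types`` and ``cell_type`` are given (e.g. ``"CD8"``), the
    output is restricted to that subset *after* labeling, so the
    expansion threshold still refers to the whole sample.
    """
    if not 0 < threshold < 1:
        raise ValueError("expansion threshold must lie in (0, 1)")
    merged = cell_map.merge(
        clonotypes[["clonotype_id", "proportion"]], on="clonotype_id", how="left"
    )
    merged["expanded"] = merged["proportion"] > threshold
    if cell_type is not None:
        if cell_types is None:
            raise ValueError("cell_type restriction requires a cell_types table")
        merged = merged.merge(cell_types[["barcode", "cell_type"]], on="barcode")
        merged = merged[merged["cell_type"] == cell_type]
    return merged[["barcode", "clonotype_id", "expanded"]].reset_index(drop=True)


def test_markers(
    expression: pd.DataFrame,
    expanded: pd.Series | pd.DataFrame,
    panels: Iterable[str] = DEFAULT_PANEL,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Wilcoxon rank-sum tests of marker genes, expanded vs non-expanded.

    ``expression`` is a cells x genes table indexed by barcode;
    ``expanded`` is a boolean Series indexed by barcode (or the output of
    :func:`label_expanded`). The Bonferroni factor is the number of
    markers actually tested in this run; markers absent from the table
    are reported as missing and do not enter the correction.
    """
    if isinstance(expanded, pd.DataFrame):
        expanded = expanded.set_index("barcode")["expanded"]
    common = expression.index.intersection(expanded.index)
    expr = expression.loc[common]
    mask = expanded.loc[common].astype(bool)
    if mask.all() or (~mask).all():
        raise ValueError("both expanded and non-expanded groups must be nonempty")

    markers = []
    for panel in panels:
        if panel not in MARKER_PANELS:
            raise ValueError(f"unknown marker panel {panel!r}")
        for gene in MARKER_PANELS[panel]:
            if (gene, panel) not in [(m[0], m[1]) for m in markers]:
                markers.append((gene, panel))
    present = [(g, p) for g, p in markers if g in expr.columns]
    n_tested = len(present)

    rows = []
    for gene, panel in markers:
        if gene not in expr.columns:
            rows.append(MarkerTestResult(gene, panel, None, None, None, "missing"))
            continue
        x = expr.loc[mask, gene].to_numpy()
        y = expr.loc[~mask, gene].to_numpy()
        stat, p = stats.ranksums(x, y)
        p_adj = min(1.0, p * n_tested)
        if p_adj < alpha:
            direction = "up_in_expanded" if x.mean() > y.mean() else "down_in_expanded"
        else:
            direction = "ns"
        rows.append(MarkerTestResult(gene, panel, float(stat), float(p), p_adj, direction))
    return pd.DataFrame([r.__dict__ for r in rows])


def simulate_expression(
    n_expanded: int,
    n_non_expanded: int,
    shifts: Optional[dict[str, float]] = None,
    panels: Iterable[str] = DEFAULT_PANEL,
    seed: int = 0,
    extra_genes: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic log-normalized expression with optional planted shifts.

    Baseline marker expression is drawn per gene as N(mu_g, 1) with
    mu_g ~ U(0.5, 2) (log_e(x+1)-scale magnitudes), identical between
    groups; ``shifts`` adds the given log-scale offset to the expanded
    group. Returns (cells x genes table, expanded flags), both indexed by
    synthetic barcodes.
    """
    rng = np.random.default_rng(seed)
    genes: list[str] = []
    for panel in panels:
        for g in MARKER_PANELS[panel]:
            if g not in genes:
                genes.append(g)
    genes += [f"GENE{i}" for i in range(extra_genes)]
    n = n_expanded + n_non_expanded
    barcodes = [f"cell{i:06d}" for i in range(n)]
    expanded = pd.Series([True] * n_expanded + [False] * n_non_expanded,
                         index=barcodes, name="expanded")
    data = {}
    for g in genes:
        mu = rng.uniform(0.5, 2.0)
        vals = rng.normal(mu, 1.0, size=n)
        if shifts and g in shifts:
            vals[:n_expanded] += shifts[g]
        data[g] = np.clip(vals, 0.0, None)
    return pd.DataFrame(data, index=barcodes), expanded
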