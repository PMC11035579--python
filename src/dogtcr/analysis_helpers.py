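"""End-to-end composites shared by the analysis drivers, the pipeline and
the acceptance checks."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotate import annotate_contigs
from .clonotypes import build_clonotypes, segment_usage
from .refdata import build_default_reference
from .reference import ReferenceSet
from .rescue import (DefectAssessment, assess_defects, collect_segment_consensus,
                     propose_reannotation)
from .simulate import (DEFAULT_RESCUE_DONORS, PlantedRescue, TruthTable,
                       simulate_rescue_study)


@dataclass
class RescueStudyResult:
    """Assessments plus the intermediates they were computed from."""

    assessments: list[DefectAssessment]
    proposals: pd.DataFrame
    annotations: pd.DataFrame
    clonotypes: pd.DataFrame
    cell_map: pd.DataFrame
    consensus_tables: dict[str, pd.DataFrame]
    donor_by_barcode: dict[str, str]
    truth: TruthTable


def run_rescue_assessment(
    refset: ReferenceSet,
    plan: list[PlantedRescue],
    seed: int,
    donors: tuple[str, ...] = DEFAULT_RESCUE_DONORS,
    cells_per_donor: int = 120,
) -> RescueStudyResult:
    """Simulate a multi-donor rescue study, annotate it against the
    universal reference, and assess every planted defective segment.

    Note the annotation step deliberately uses the *universal* reference
    (not the donor germlines): discovering donor variants from the data is
    the point of the analysis.
    """
    cells, truth = simulate_rescue_study(refset, plan, donors, cells_per_donor, seed)
    annotations = annotate_contigs(cells, refset)
    clonotypes, cell_map = build_clonotypes(annotations)
    sequences = {ct.contig_id: ct.contig_nt for cell in cells for ct in cell.contigs}
    donor_by_barcode = dict(zip(truth.cells["barcode"], truth.cells["donor_id"]))

    assessments: list[DefectAssessment] = []
    consensus_tables: dict[str, pd.DataFrame] = {}
    for planted in plan:
        segment = refset.get(planted.segment_key)
        consensus = collect_segment_consensus(
            annotations, sequences, cell_map, donor_by_barcode, planted.segment_key
        )
        consensus_tables[planted.segment_key] = consensus
        assessments.extend(assess_defects(segment, consensus))

    usage = segment_usage(annotations, refset, cell_map=cell_map)
    proposals = propose_reannotation(
        assessments, usage["segment_cells"], usage["segment_clonotypes"]
    )
    return RescueStudyResult(
        assessments=assessments, proposals=proposals, annotations=annotations,
        clonotypes=clonotypes, cell_map=cell_map,
        consensus_tables=consensus_tables, donor_by_barcode=donor_by_barcode,
        truth=truth,
    )
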