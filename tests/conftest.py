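import pytest

from dogtcr.annotate import annotate_contigs
from dogtcr.refdata import build_default_reference
from dogtcr.simulate import (PAIRING_PERFECT, ClonalityProfile, SimulationConfig,
                             simulate_repertoire)


@pytest.fixture(scope="session")
def default_ref():
    refset, _ = build_default_reference()
    return refset


@pytest.fixture(scope="session")
def rescue_edits():
    _, edits = build_default_reference()
    return edits


@pytest.fixture(scope="session")
def small_repertoire(default_ref):
    """200-cell error-free polyclonal sample with clean pairing + truth."""
    cfg = SimulationConfig(
        seed=101, n_cells=200, profile=ClonalityProfile.polyclonal(),
        pairing=dict(PAIRING_PERFECT),
    )
    return simulate_repertoire(default_ref, cfg)


@pytest.fixture(scope="session")
def small_annotations(default_ref, small_repertoire):
    cells, _ = small_repertoire
    return annotate_contigs(cells, default_ref)
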