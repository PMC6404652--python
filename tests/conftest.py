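from __future__ import annotations

import numpy as np
import pytest

from tastrain.align import build_kmer_index, map_read
from tastrain.markerdb import build_database
from tastrain.profiler import ReportThresholds, profile
from tastrain.simdata import (
    CommunitySpec,
    StrainPanelSpec,
    simulate_reads,
    simulate_strain_panel,
)


def map_all(reads, index, **kwargs):
    alignments = []
    for r in reads:
        alignments.extend(map_read(r.read_id, r.sequence, index, **kwargs))
    return alignments


def run_pipeline(
    panel,
    planted: list[str],
    mean_depth: float = 20.0,
    error_rate: float = 0.0,
    min_support: int = 1,
    seed: int = 0,
    db=None,
    thresholds: ReportThresholds | None = None,
    reads=None,
):
    """Panel -> database -> simulated reads -> mapping -> profile."""
    if db is None:
        db = build_database(panel.genes)
    if reads is None:
        community = CommunitySpec(
            planted=tuple((s, 1.0) for s in planted),
            mean_depth=mean_depth,
            error_rate=error_rate,
            seed=seed,
        )
        reads = simulate_reads(panel, community)
    index = build_kmer_index({g.gene_id: g.sequence for g in db.genes})
    alignments = map_all(reads, index)
    report, evidence, detections, G, St, sets = profile(
        alignments, db, min_support=min_support, thresholds=thresholds
    )
    return {
        "db": db,
        "reads": reads,
        "alignments": alignments,
        "report": report,
        "evidence": evidence,
        "detections": detections,
        "G": G,
        "St": St,
        "sets": sets,
    }


def performance_of(strain: str, sets, db) -> int:
    """Size of the indiscernible set containing the strain; worst case
    (total number of reference strains) when the strain is undetected."""
    for s in sets:
        if strain in s.members:
            return s.performance
    return len(db.repertoires)


@pytest.fixture(scope="session")
def small_panel():
    return simulate_strain_panel(StrainPanelSpec(n_species=2, strains_per_species=3, seed=11))


@pytest.fixture(scope="session")
def small_db(small_panel):
    return build_database(small_panel.genes)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
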