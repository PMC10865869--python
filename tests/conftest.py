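"""Shared fixtures: one ancestor world + one exemplar genome per session.

Profile calibration is the slow step, so the ancestor world (seed 3) is
built once and reused; tests that need different worlds build their own.
"""

import pytest

from hicascan.classify import classify_genome
from hicascan.simulate import build_genome, exemplar_specs, make_ancestors

WORLD_SEED = 3


@pytest.fixture(scope="session")
def ancestors():
    return make_ancestors(WORLD_SEED)


@pytest.fixture(scope="session")
def profiles(ancestors):
    return {label: entry.profile for label, entry in ancestors.items()}


@pytest.fixture(scope="session")
def exemplar_genome(ancestors):
    """One locus per class at 10% divergence, mixed strands."""
    specs = exemplar_specs(WORLD_SEED, per_class=1, divergence=0.1)
    for i, spec in enumerate(specs):
        if i % 3 == 2:
            spec.strand = "-"
    record, truth = build_genome(specs, rng_seed=WORLD_SEED, ancestors=ancestors)
    return record, truth


@pytest.fixture(scope="session")
def exemplar_classified(exemplar_genome, profiles):
    record, truth = exemplar_genome
    table, assignments, contexts = classify_genome([record], profiles)
    return record, truth, table, assignments, contexts


def truth_locus(gene_id: str) -> str:
    """Map a focal gene id (L003_hicA) to its truth-table locus id (L003)."""
    return gene_id.split("_")[0]
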