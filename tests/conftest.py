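"""Shared fixtures: the standard synthetic benchmark, searched once per session."""

from __future__ import annotations

import pytest

from orthoprof.orthology import best_hits, classify_proteins, reciprocal_best_hits
from orthoprof.seqsim import ScoringScheme, search_all
from orthoprof.synthetic import generate_dataset, standard_fixture_config

FIXTURE_SEED = 11
E_CUTOFF = 1e-10


@pytest.fixture(scope="session")
def standard_dataset():
    """Four organisms, one family per non-empty organism subset (all 15
    presence categories), three partial-homolog families, five decoys per
    organism."""
    return generate_dataset(standard_fixture_config(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def org_of(standard_dataset):
    return {
        pid: org
        for org, prot in standard_dataset.proteomes.items()
        for pid, _ in prot
    }


@pytest.fixture(scope="session")
def standard_hits(standard_dataset):
    return search_all(
        list(standard_dataset.proteomes.values()),
        ScoringScheme(),
        e_cutoff=E_CUTOFF,
        prefilter=True,
    )


@pytest.fixture(scope="session")
def standard_best(standard_hits, org_of):
    return best_hits(standard_hits, E_CUTOFF, org_of)


@pytest.fixture(scope="session")
def standard_assignments(standard_best, org_of):
    pairs = reciprocal_best_hits(standard_best, org_of)
    return classify_proteins(pairs, org_of)
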