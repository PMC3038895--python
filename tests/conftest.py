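"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from raibin.io_formats import ProfileDatabase
from raibin.rai_core import build_profile
from raibin.synthetic import (
    make_taxonomy_fixture,
    perturb_source,
    sample_fragments,
    simulate_genome,
)

STANDARD_SEED = 1


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard 8-species mixture: references, taxonomy, leaf sources."""
    refs, tax, sources = make_taxonomy_fixture(seed=STANDARD_SEED, return_sources=True)
    return refs, tax, sources


@pytest.fixture(scope="session")
def standard_db(standard_fixture):
    refs, tax, _ = standard_fixture
    return ProfileDatabase(
        k=7, profiles=[build_profile(r, 7) for r in refs], lineages=tax
    )


@pytest.fixture(scope="session")
def standard_fragments(standard_fixture):
    """1000 fragments of 400 bp per species, truth lineages attached."""
    refs, _, _ = standard_fixture
    frags = []
    for i, r in enumerate(refs):
        frags.extend(sample_fragments(r, 1000, 400, seed=100 + i))
    return frags


@pytest.fixture(scope="session")
def perturbed_seed_db(standard_fixture):
    """Seed profiles trained on perturbed relatives of each species' source."""
    refs, tax, sources = standard_fixture
    profiles = []
    for i, r in enumerate(refs):
        rel = perturb_source(sources[r.ref_id], 0.35, seed=500 + i)
        rel.seed = 900 + i
        profiles.append(build_profile(simulate_genome(rel, 500_000), 7, ref_id=r.ref_id))
    return ProfileDatabase(k=7, profiles=profiles, lineages=tax)


@pytest.fixture(scope="session")
def mini_fixture():
    """A fast, small mixture for I/O and plumbing tests (k=4-friendly)."""
    refs, tax = make_taxonomy_fixture(seed=5, genome_length=30_000, order=1)
    return refs, tax


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
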