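"""Shared fixtures: synthetic genomes and digestions reused across tests."""

import numpy as np
import pytest

import trichrom as tc

TRIPLE = ("DpnII", "Csp6I", "NlaIII")


@pytest.fixture(scope="session")
def genome_2mb():
    return {"sim": tc.make_genome(2_000_000, 0.5, seed=1)}


@pytest.fixture(scope="session")
def fmap_2mb(genome_2mb):
    return tc.digest_genome(genome_2mb, tc.get_enzymes(TRIPLE))


@pytest.fixture(scope="session")
def genome_300kb():
    return {"sim": tc.make_genome(300_000, 0.5, seed=2)}


@pytest.fixture(scope="session")
def fmap_300kb(genome_300kb):
    return tc.digest_genome(genome_300kb, tc.get_enzymes(("DpnII", "Csp6I", "CviAII")))


@pytest.fixture(scope="session")
def regular_fmap_1mb():
    """Evenly spaced cuts: no restriction-site structure, clean backgrounds."""
    cuts = list(range(85, 1_000_000, 85))
    return tc.build_fragment_map({"sim": cuts}, {"sim": 1_000_000})


VIEWPOINT = ("sim", 1_000_000, 1_001_000)
REGION_2MB = (0, 2_000_000)


def tri4c_profile(fmap, seed, loops=(), n=100_000, dup=0.0, alpha=1.0):
    """One simulated, deduplicated viewpoint profile on the 2 Mb genome."""
    spec = tc.SimulationSpec(
        mode="4c", seed=seed, n_molecules=n, viewpoint=VIEWPOINT[1:],
        loops=list(loops), duplication_rate=dup, alpha=alpha,
    )
    table, truth = tc.simulate_tri4c(spec, fmap)
    prof = tc.bin_profile(
        tc.dedup_contacts(table), VIEWPOINT, region=REGION_2MB
    )
    return prof, truth
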