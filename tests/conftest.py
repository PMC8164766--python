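"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from antarscan.io import make_seed_alignment
from antarscan.motif import MotifConstraints, build_profile
from antarscan.simulate import make_synthetic_seed

# Analytic background of a 65% GC genome, the simulator's default composition.
GC65_BACKGROUND = {"A": 0.175, "C": 0.325, "G": 0.325, "U": 0.175}


def identical_row_seed(n_rows: int = 10):
    """A seed of identical rows: 3-bp stems, canonical loops, 4-nt linker."""
    row = "GGG" + "ACUGUU" + "CCC" + "AAAA" + "CCC" + "AGCGCA" + "GGG"
    ss = "(((......)))....(((......)))"
    rows = [(f"r{i}", row) for i in range(n_rows)]
    return make_seed_alignment(rows, ss)


@pytest.fixture(scope="session")
def tiny_seed():
    return identical_row_seed(10)


@pytest.fixture(scope="session")
def tiny_profile(tiny_seed):
    # max_stem_bp pinned to the seed's architecture so the seed row itself is
    # the profile's argmax candidate
    constraints = MotifConstraints(max_stem_bp=3)
    return build_profile(tiny_seed, background=None, constraints=constraints)


@pytest.fixture(scope="session")
def family_seed():
    return make_synthetic_seed(30, seed=1)


@pytest.fixture(scope="session")
def family_profile(family_seed):
    return build_profile(family_seed, background=GC65_BACKGROUND)


def random_rna(rng: np.random.Generator, length: int, p=None) -> str:
    return "".join(rng.choice(list("ACGU"), size=length, p=p))


def random_dna(rng: np.random.Generator, length: int, p=None) -> str:
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
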