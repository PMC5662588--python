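import numpy as np
import pytest

from pedherit.pedigree import Individual, Pedigree
from pedherit.simulate import preset, simulate_dataset


def make_pedigree(rows, phenotyped=()):
    """rows: (id, father|None, mother|None[, adopted]) tuples."""
    inds = {}
    for row in rows:
        iid, f, m = row[:3]
        adopted = len(row) > 3 and row[3]
        inds[iid] = Individual(
            id=iid, father=f, mother=m, adopted=bool(adopted),
            phenotyped=iid in phenotyped,
        )
    return Pedigree(inds)


@pytest.fixture
def trio():
    return make_pedigree(
        [("F1", None, None), ("M1", None, None), ("C1", "F1", "M1")],
        phenotyped={"C1"},
    )


@pytest.fixture
def sibship3():
    return make_pedigree(
        [("F", None, None), ("M", None, None),
         ("S1", "F", "M"), ("S2", "F", "M"), ("S3", "F", "M")],
        phenotyped={"S1", "S2", "S3"},
    )


@pytest.fixture
def half_sibs():
    return make_pedigree(
        [("F", None, None), ("M1", None, None), ("M2", None, None),
         ("H1", "F", "M1"), ("H2", "F", "M2")],
        phenotyped={"H1", "H2"},
    )


@pytest.fixture
def full_cousins():
    # grandparents -> two full-sib parents -> cousins C1, C2
    return make_pedigree(
        [("GF", None, None), ("GM", None, None),
         ("P1", "GF", "GM"), ("P2", "GF", "GM"),
         ("S1", None, None), ("S2", None, None),
         ("C1", "P1", "S1"), ("C2", "P2", "S2")],
        phenotyped={"C1", "C2"},
    )


@pytest.fixture
def half_cousins():
    # shared grandfather, different grandmothers -> half-sib parents
    return make_pedigree(
        [("GF", None, None), ("GM1", None, None), ("GM2", None, None),
         ("P1", "GF", "GM1"), ("P2", "GF", "GM2"),
         ("S1", None, None), ("S2", None, None),
         ("C1", "P1", "S1"), ("C2", "P2", "S2")],
        phenotyped={"C1", "C2"},
    )


@pytest.fixture(scope="session")
def tiny_sim():
    """One small synthetic census shared across tests (~200 phenotyped)."""
    return simulate_dataset(preset("tiny", seed=11))


@pytest.fixture(scope="session")
def oracle_sim():
    """Single-relation-path pedigree (all partners from outside the clans) of
    ~1,000 phenotyped children for kinship cross-checks."""
    return simulate_dataset(preset("tiny", n_families=210, immigrant_rate=1.0, seed=5))
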