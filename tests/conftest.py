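import numpy as np
import pytest

from exped.pedigree import Individual, Pedigree
from exped.phenotype_scoring import load_activity_table


@pytest.fixture(scope="session")
def activity_table():
    return load_activity_table()


def make_pedigree(family_id, rows):
    """Build a pedigree from (id, father, mother, sex, birth_year, mz, spouse)."""
    inds = {}
    for iid, f, m, sex, by, mz, sp in rows:
        inds[iid] = Individual(
            individual_id=iid, family_id=family_id,
            father_id=f, mother_id=m, sex=sex,
            birth_year=by, mz_group_id=mz, spouse_id=sp,
        )
    return Pedigree(family_id, inds)


@pytest.fixture
def extended_family():
    """Parents, MZ twin pair, non-twin sister, spouse of twin 1, their child."""
    return make_pedigree("fam1", [
        ("F", None, None, "male", 1950, None, "M"),
        ("M", None, None, "female", 1952, None, "F"),
        ("T1", "F", "M", "male", 1978, "mz1", "S1"),
        ("T2", "F", "M", "male", 1978, "mz1", None),
        ("B1", "F", "M", "female", 1980, None, None),
        ("S1", None, None, "female", 1979, None, "T1"),
        ("O1", "T1", "S1", "male", 2000, None, None),
    ])


@pytest.fixture
def three_generations():
    """Grandparents, their two children (one married in), grandchildren."""
    return make_pedigree("fam2", [
        ("GF", None, None, "male", 1930, None, "GM"),
        ("GM", None, None, "female", 1932, None, "GF"),
        ("P1", "GF", "GM", "male", 1955, None, "W1"),
        ("P2", "GF", "GM", "female", 1957, None, "H2"),
        ("W1", None, None, "female", 1956, None, "P1"),
        ("H2", None, None, "male", 1955, None, "P2"),
        ("C1", "P1", "W1", "male", 1980, None, None),
        ("C2", "H2", "P2", "female", 1982, None, None),
    ])
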