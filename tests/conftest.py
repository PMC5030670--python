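"""Shared fixtures: reference tables at desk scale, built once per session."""

import pytest

from metapopabc.experiments import build_reference_table

TABLE_LOCI = 120


@pytest.fixture(scope="session")
def fim_scd_table():
    return build_reference_table("FIM", "SCD", 4000, TABLE_LOCI, seed=101)


@pytest.fixture(scope="session")
def fim_sid_table():
    return build_reference_table("FIM", "SID", 3000, TABLE_LOCI, seed=102)


@pytest.fixture(scope="session")
def chg1_tables():
    return {
        "SID": build_reference_table("CHG1", "SID", 2500, TABLE_LOCI, seed=103),
        "SCD": build_reference_table("CHG1", "SCD", 2500, TABLE_LOCI, seed=104),
    }


@pytest.fixture(scope="session")
def cos_tables():
    return {
        "SID": build_reference_table("COS", "SID", 2000, TABLE_LOCI, seed=105),
        "SCD": build_reference_table("COS", "SCD", 2000, TABLE_LOCI, seed=106),
    }


@pytest.fixture(scope="session")
def chg2_scd_table():
    return build_reference_table("CHG2", "SCD", 2500, TABLE_LOCI, seed=107)
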