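import numpy as np
import pytest

from refugia.popgen import PopulationPartition, SequenceAlignment

# ~60-sequence design used for desk-scale ABC work, proportional to the
# study's 18/87/97 region split
DESK_REGION_SIZES = {"A": 6, "C": 26, "S": 28}
DESK_TABLE_SEED = 20240501
DESK_N_PER_SCENARIO = 10_000


@pytest.fixture
def toy_alignment():
    """{AAA, AAA, AAT, ATT}: k=3, counts [2,1,1]."""
    return SequenceAlignment(["s1", "s2", "s3", "s4"], ["AAA", "AAA", "AAT", "ATT"])


@pytest.fixture
def two_group_partition():
    ids = [f"s{i}" for i in range(8)]
    sites = ["x"] * 4 + ["y"] * 4
    return PopulationPartition(ids, sites, sites[:], ["r1"] * 4 + ["r2"] * 4)


def make_partition(labels, prefix="s"):
    ids = [f"{prefix}{i}" for i in range(len(labels))]
    labels = list(labels)
    return PopulationPartition(ids, labels, labels[:], ["all"] * len(labels))


@pytest.fixture(scope="session")
def desk_table():
    """Session-scoped 3x10^4-row reference table (the expensive fixture)."""
    from refugia.inference import build_reference_table

    return build_reference_table(
        (1, 2, 3),
        n_per_scenario=DESK_N_PER_SCENARIO,
        region_sizes=DESK_REGION_SIZES,
        seed=DESK_TABLE_SEED,
    )


@pytest.fixture(scope="session")
def three_region_partition_factory():
    def make(n_a, n_c, n_s):
        ids = [f"i{i}" for i in range(n_a + n_c + n_s)]
        regions = ["Aleutians"] * n_a + ["Central"] * n_c + ["South"] * n_s
        return PopulationPartition(ids, regions[:], regions[:], regions)

    return make
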