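import numpy as np
import pandas as pd
import pytest

from weaverkin.datamodel import (
    ChamberMap,
    ColonyDataset,
    GenotypeTable,
    Individual,
    ObservationLog,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_genotypes(rng, n=30, n_loci=5, n_alleles=6, missing_rate=0.0, prefix="b"):
    """A GenotypeTable of iid genotypes under locus-specific Dirichlet freqs."""
    freqs = [rng.dirichlet(np.ones(n_alleles)) for _ in range(n_loci)]
    codes = np.empty((n, n_loci, 2), dtype=np.int32)
    for j, p in enumerate(freqs):
        codes[:, j, :] = rng.choice(n_alleles, size=(n, 2), p=p)
    if missing_rate > 0:
        drop = rng.random((n, n_loci)) < missing_rate
        codes[drop] = -1
    ids = [f"{prefix}{i}" for i in range(n)]
    loci = [f"L{j}" for j in range(n_loci)]
    labels = [[str(a) for a in range(n_alleles)] for _ in range(n_loci)]
    return GenotypeTable(ids, loci, codes, labels), freqs


@pytest.fixture
def tiny_dataset():
    """Two colonies, hand-built: enough structure to exercise every stage."""
    individuals = [
        Individual("a1", "male", "X"),
        Individual("a2", "female", "X"),
        Individual("a3", "male", "X", is_builder=True),
        Individual("b1", "male", "Y"),
        Individual("b2", "female", "Y"),
    ]
    genotypes = GenotypeTable.from_calls(
        {
            "a1": {"L1": ("1", "2"), "L2": ("1", "1")},
            "a2": {"L1": ("2", "3"), "L2": ("1", "2")},
            "a3": {"L1": ("1", "2"), "L2": ("2", "2")},
            "b1": {"L1": ("3", "3"), "L2": ("1", "2")},
            "b2": {"L1": ("1", "3"), "L2": None},
        },
        loci=["L1", "L2"],
    )
    maps = {
        "X": ChamberMap("X", {"X-1": (0.0, 0.0), "X-2": (1.0, 0.0), "X-3": (5.0, 5.0)}),
        "Y": ChamberMap("Y", {"Y-1": (0.0, 0.0), "Y-2": (2.0, 0.0)}),
    }
    entries = pd.DataFrame(
        [
            ("a1", "X", "X-1", "s1", "roost"),
            ("a2", "X", "X-1", "s1", "roost"),
            ("a2", "X", "X-2", "s1", "chamber_build"),
            ("a3", "X", "X-2", "s1", "roost"),
            ("b1", "Y", "Y-1", "s1", "roost"),
            ("b2", "Y", "Y-1", "s1", "roost"),
        ],
        columns=ObservationLog.ENTRY_COLS,
    )
    building = pd.DataFrame(
        [("a3", "X", "X-2", 3), ("a3", "X", "X-3", 1)],
        columns=ObservationLog.BUILD_COLS,
    )
    return ColonyDataset(
        individuals, genotypes, maps, ObservationLog(entries, building),
        provenance={"source": "fixture"},
    )
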