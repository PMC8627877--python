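import random

import pytest
from hypothesis import HealthCheck, settings

from strmonitor.model import Genotype, GenotypeTable, LocusSpec, MISSING_GENOTYPE, SampleRecord

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_table(rows, loci):
    """Build a GenotypeTable from [(sample_id, cohort, [cell, ...]), ...].

    A cell is a 2-tuple of allele labels or None for missing.
    """
    panel = tuple(LocusSpec(name) for name in loci)
    samples = []
    for sid, cohort, cells in rows:
        genos = tuple(
            MISSING_GENOTYPE if cell is None else Genotype(*cell) for cell in cells
        )
        samples.append(SampleRecord(sid, cohort, genos))
    return GenotypeTable(panel=panel, samples=tuple(samples))


def random_table(rng: random.Random, n_samples=None, n_loci=None, cohorts=("c1", "c2"),
                 alphabet="KLMNOP", missing_rate=0.1):
    """Small random table for oracle-equivalence and round-trip tests."""
    n_samples = n_samples if n_samples is not None else rng.randint(1, 10)
    n_loci = n_loci if n_loci is not None else rng.randint(1, 4)
    loci = [f"L{i}" for i in range(n_loci)]
    rows = []
    for s in range(n_samples):
        cohort = rng.choice(cohorts)
        cells = []
        for _ in range(n_loci):
            if rng.random() < missing_rate:
                cells.append(None)
            else:
                cells.append((rng.choice(alphabet), rng.choice(alphabet)))
        rows.append((f"s{s}", cohort, cells))
    return make_table(rows, loci)


@pytest.fixture
def tiny_table():
    """Three animals, two loci; the hand-countable example cohort."""
    return make_table(
        [
            ("h1", "2000", [("K", "K"), ("A", "B")]),
            ("h2", "2000", [("K", "L"), ("A", "A")]),
            ("h3", "2000", [("L", "M"), ("B", "B")]),
        ],
        ["VHL20", "HTG4"],
    )
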