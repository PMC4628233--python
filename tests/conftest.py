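import numpy as np
import pytest

from strpopgen import (GenotypeTable, Pedigree, PedigreeRecord,
                       SimulationConfig, simulate_cohort)


def make_table(rows, loci, locus_class=None):
    """Build a GenotypeTable from {individual: [(a1, a2), ...]}."""
    individuals = list(rows)
    calls = np.array([rows[i] for i in individuals], dtype=np.int64)
    return GenotypeTable(individuals, list(loci), calls,
                         dict(locus_class or {}))


@pytest.fixture
def two_ind_one_locus():
    return make_table({"A": [(148, 148)], "B": [(148, 152)]}, ["FH1"])


@pytest.fixture
def full_sib_pedigree():
    """x is the offspring of full siblings S1 x S2; grandparents founders."""
    return Pedigree([
        PedigreeRecord("GS", None, None, "M"),
        PedigreeRecord("GD", None, None, "F"),
        PedigreeRecord("S1", "GS", "GD", "M"),
        PedigreeRecord("S2", "GS", "GD", "F"),
        PedigreeRecord("x", "S1", "S2", "F"),
    ])


@pytest.fixture(scope="session")
def small_cohort():
    """One moderately sized simulated cohort shared across tests."""
    cfg = SimulationConfig(seed=7, n_founders=60, n_generations=3,
                           pop_size=120, sire_concentration=1.0)
    return cfg, simulate_cohort(cfg)
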