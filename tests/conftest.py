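"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from phsgp.genotypes import GenotypeMatrix, vanraden_grm
from phsgp.synthetic import (
    PopulationSpec,
    TrialDesignSpec,
    make_qtl_architecture,
    simulate_phenotypes,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_population():
    """120 lines, 6 programs, 400 markers — mirrors the cohort layout at 30% scale."""
    spec = PopulationSpec(
        n_lines=120,
        programs=[("P1", 20), ("P2", 20), ("P3", 20), ("P4", 30), ("P5", 10), ("P6", 20)],
        season_split={"CS": 60, "VS15": 30, "VS16": 30},
        n_markers=400,
        seed=42,
    )
    return simulate_population(spec)


@pytest.fixture(scope="session")
def small_architecture(small_population):
    return make_qtl_architecture(small_population, n_polygenic=100, seed=7)


@pytest.fixture(scope="session")
def small_grm(small_population):
    return vanraden_grm(small_population)


@pytest.fixture(scope="session")
def small_trial(small_population, small_architecture):
    """One season of augmented-design records at target h2 = 0.85."""
    design = TrialDesignSpec(target_h2=0.85)
    pheno, true_g = simulate_phenotypes(
        small_population, small_architecture, design, seed=11
    )
    return pheno, true_g, design


@pytest.fixture()
def tiny_genotypes():
    """Hand-sized matrix for exact checks."""
    return GenotypeMatrix(
        dosages=np.array([[0.0, 2.0], [2.0, 0.0], [1.0, 1.0]]),
        marker_ids=np.array(["m1", "m2"]),
        line_ids=np.array(["a", "b", "c"]),
    )


def line_level_phenotypes(geno, arch, h2, seed):
    """Adjusted-mean-level phenotypes y = g + e at entry-mean heritability h2.

    ``h2 = 0`` gives pure noise (``arch`` may then be None).
    """
    rng = np.random.default_rng(seed)
    if h2 == 0 or arch is None:
        return pd.Series(rng.normal(size=geno.n_lines), index=geno.line_ids)
    g = arch.genetic_values(geno)
    s2g = float(np.var(g.to_numpy()))
    e = rng.normal(0.0, np.sqrt(s2g * (1 - h2) / h2), len(g))
    return g + e
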