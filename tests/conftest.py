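import numpy as np
import pytest

from igsa import (
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeTable,
    SimulationSpec,
    simulate_cohort,
)


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples = ["c1", "c2", "s1", "s2", "s3"]
    return ExpressionMatrix(genes, samples, rng.uniform(1.0, 10.0, size=(6, 5)))


@pytest.fixture
def tiny_sets() -> GeneSetCollection:
    return GeneSetCollection(
        sets={"up": frozenset({"g0", "g1"}), "dn": frozenset({"g2", "g3", "g4"})},
        descriptions={"up": "", "dn": ""},
    )


@pytest.fixture
def tiny_pheno() -> PhenotypeTable:
    return PhenotypeTable(
        group_of={"c1": "control", "c2": "control", "s1": "case", "s2": "case", "s3": "case"}
    )


@pytest.fixture
def small_cohort():
    """A compact planted cohort with strong signal, for fast pipeline tests."""
    spec = SimulationSpec(
        n_genes=400,
        n_controls=8,
        n_cases=10,
        n_sets=20,
        set_size=10,
        n_planted_up=4,
        n_planted_down=3,
        effect=2.5,
        noise_sd=0.25,
        seed=11,
    )
    return simulate_cohort(spec)
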