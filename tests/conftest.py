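import numpy as np
import pytest

from vitipop import (
    PopulationSpec,
    SimulationConfig,
    align_risk_alleles,
    make_risk_table,
    simulate_cohort,
)
from vitipop.simulate import kgp_like_populations


@pytest.fixture(scope="session")
def two_pop_cohort():
    """2 populations x 50 samples, 100 SNPs, F = 0.1."""
    cfg = SimulationConfig(
        populations=[PopulationSpec("A", "X", 50), PopulationSpec("B", "Y", 50)],
        n_snps=100,
        fst=0.1,
        seed=1,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def kgp_cohort():
    """7-super-population cohort (100 samples each), 200 SNPs, F = 0.05,
    with the first 64 SNPs designated as risk alleles (62 EUR + 2 EAS)."""
    cfg = SimulationConfig(
        populations=kgp_like_populations(100),
        n_snps=200,
        fst=0.05,
        seed=42,
    )
    gm, panel, truth = simulate_cohort(cfg)
    risk = make_risk_table(
        gm, list(range(64)), ["EAS"] * 2 + ["EUR"] * 62, seed=42
    )
    arm = align_risk_alleles(risk, gm)
    return gm, panel, truth, risk, arm
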