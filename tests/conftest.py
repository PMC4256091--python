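import logging

import numpy as np
import pandas as pd
import pytest

from survey_phewas.config import (
    CorrelationBlock,
    PhenotypeSpec,
    PlantedEffect,
    PopulationConfig,
    SnpSpec,
    default_config,
)
from survey_phewas.synthetic import generate_dataset

logging.getLogger("survey_phewas").setLevel(logging.ERROR)


def small_config(seed: int = 0, **overrides) -> PopulationConfig:
    """A fast single-stratum population with one pleiotropic planted SNP."""
    cfg = PopulationConfig(
        strata=("NHW",),
        n_per_stratum={"S1": {"NHW": 600}, "S2": {"NHW": 600}},
        snps=(
            SnpSpec("rs1", "1", 1000, "A", "G", {"NHW": 0.3}),
            SnpSpec("rs2", "2", 5000, "A", "G", {"NHW": 0.4}),
        ),
        phenotypes=(
            PhenotypeSpec("chol", "Cholesterol", baseline=200.0, noise_sd=35.0, shared=True),
            PhenotypeSpec("trig", "Triglycerides", baseline=130.0, noise_sd=30.0),
            PhenotypeSpec("urate", "Uric Acid", baseline=5.4, noise_sd=1.0, shared=True),
        ),
        planted_effects=(
            PlantedEffect("rs1", "Cholesterol", 0.5),
            PlantedEffect("rs1", "Triglycerides", 0.5),
        ),
        missing_rate=0.02,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(default_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_gene_table(rng, n_genes=15, n_chroms=3) -> pd.DataFrame:
    chroms = rng.integers(1, n_chroms + 1, size=n_genes).astype(str)
    starts = rng.integers(1, 1_000_000, size=n_genes)
    lengths = rng.integers(100, 50_000, size=n_genes)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "symbol": [f"G{i}" for i in range(n_genes)],
        }
    )
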