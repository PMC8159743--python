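import numpy as np
import pandas as pd
import pytest

from dietcross import synthpop
from dietcross.containers import GenotypeMatrix


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes, 30 markers, 150 cM total."""
    return synthpop.build_map(30, {"1": 100.0, "2": 50.0})


@pytest.fixture(scope="session")
def study_map():
    return synthpop.default_map()


def make_null_pheno(geno, seed, trait="y", sd=1.0):
    """Phenotype table with random sex/diet and a pure-noise trait."""
    rng = np.random.default_rng(seed)
    n = geno.n_individuals
    return pd.DataFrame({
        "id": geno.ids,
        "generation": "F2",
        "sex": np.where(rng.random(n) < 0.5, "M", "F"),
        "diet": np.where(rng.random(n) < 0.5, "ketogenic", "american"),
        trait: rng.normal(0.0, sd, size=n),
    })


@pytest.fixture(scope="session")
def small_cross(small_map):
    """469 F2s on the small map with a pure-noise trait."""
    geno = synthpop.simulate_f2(small_map, 469, seed=42)
    return make_null_pheno(geno, seed=43), geno
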