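import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import rilqtl as rq

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_map():
    return rq.simulate_genetic_map(n_chrom=2, markers_per_chrom=20,
                                   chrom_length_cM=100.0, seed=11)


@pytest.fixture(scope="session")
def small_geno(small_map):
    return rq.simulate_ril_genotypes(small_map, n_lines=80, seed=11)


@pytest.fixture(scope="session")
def small_design():
    return rq.TrialDesign(blocs_per_year={2013: 4, 2014: 3, 2015: 3})


@pytest.fixture(scope="session")
def quiet_components():
    """Low-noise components for deterministic-ish recovery checks."""
    return rq.TrueComponents(sigma2_g=1.0, sigma2_gy=0.1, sigma2_ge=0.1,
                             sigma2_bloc=0.5, sigma2_E=0.5)


@pytest.fixture(scope="session")
def small_trial(small_geno, small_design, quiet_components):
    qtl = rq.QTLEffectSpec("chr1_m0010", additive_effect=0.8,
                           interaction_effect=0.5)
    return rq.simulate_trial_phenotypes(small_geno, [qtl], small_design,
                                        quiet_components, seed=11)


def balanced_ril_table(n_lines=30, years=(2013, 2014), scenarios=("I", "NI"),
                       value=0.0, rng=None):
    """Fully balanced RIL-only phenotype table (one bloc per cell)."""
    rows = []
    for i in range(n_lines):
        for y in years:
            for s in scenarios:
                rows.append((f"RIL{i + 1:03d}", y, s, 1, False))
    t = pd.DataFrame(rows, columns=["line", "year", "scenario", "bloc",
                                    "is_check"])
    if rng is None:
        t["trait"] = value
    else:
        t["trait"] = rng.normal(size=len(t))
    return t
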