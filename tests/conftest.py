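import numpy as np
import pandas as pd
import pytest

import medipath as mp


@pytest.fixture(scope="session")
def tiny_cohort() -> mp.CohortData:
    """Small cohort with one planted mediated chain, reused across tests."""
    config = mp.SimConfig(
        n_individuals=400,
        n_markers=60,
        n_otus=30,
        rarefaction_depth=2000,
        n_pens=40,
        genetic_effects=[("snp00005", "otu0003", 0.8)],
        mediator_effects=[("otu0003", "FATg", 0.4)],
        direct_effects=[("snp00005", "FATg", 0.1)],
        seed=42,
    )
    return mp.simulate_cohort(config)


@pytest.fixture()
def mediation_dataset():
    """Factory for flat mediation tables with configurable path effects."""

    def make(seed=0, n=400, alpha=0.0, beta=0.0, gamma=0.0, maf=0.3):
        rng = np.random.default_rng(seed)
        G = rng.binomial(2, maf, n).astype(float)
        covm = rng.normal(size=(n, 3))
        covp = rng.normal(size=(n, 3))
        M = alpha * G + covm @ [0.2, 0.1, 0.2] + rng.normal(size=n)
        P = beta * M + gamma * G + covp @ [0.2, 0.1, 0.2] + rng.normal(size=n)
        return pd.DataFrame({
            "P": P, "M": M, "G": G,
            "CGbm": covm[:, 0], "damline": covm[:, 1], "Srm": covm[:, 2],
            "CGbp": covp[:, 0], "Srp": covp[:, 2],
        })

    return make
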