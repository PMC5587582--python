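import numpy as np
import pandas as pd
import pytest

import pleioscan as ps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_panel(dosages, sample_ids=None, info=None, mafs_for_ids=None):
    """Small DosagePanel from a raw matrix, with generated metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if sample_ids is None:
        sample_ids = [f"s{i+1}" for i in range(n)]
    if info is None:
        info = [np.nan] * m
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j+1}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 100,
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
            "info_score": info,
        }
    )
    return ps.DosagePanel(sample_ids=sample_ids, variants=variants, dosages=dosages)


@pytest.fixture
def tiny_panel():
    return make_panel([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0]])


@pytest.fixture
def sib_cohort():
    """200 sib-quartets, h2=0.5, correlated traits: the calibration scenario."""
    cfg = ps.SimulationConfig(
        n=800,
        m=600,
        k=5,
        families=[ps.FamilyBlock("sib", 4, 200)],
        h2=0.5,
        sigma_e_rho=0.5,
        seed=7,
    )
    return ps.simulate_cohort(cfg)
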