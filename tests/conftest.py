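import numpy as np
import pandas as pd
import pytest

import synmod as sm


@pytest.fixture(scope="session")
def one_gene_panel():
    """Aggregated panel with one synergistic and one additive allele."""
    cfg, labels = sm.make_screen_config(
        [
            sm.ModifierGeneSpec(
                "gA", ["a1", "a2"], beta_int=[0.5, 0.5], beta_tox=[0.0, 1.5]
            )
        ],
        seed=101,
    )
    panel, truth = sm.simulate_screen_trajectories(cfg)
    return sm.aggregate_technical(panel), truth, labels


@pytest.fixture
def flat_null_config():
    """Two genotypes with identical flat generating curves (calibration null)."""

    def make(seed, **kw):
        defaults = dict(
            replicate_intercept_sd=0.0, aging_slope=0.0, deficit_amplitude=0.0
        )
        defaults.update(kw)
        return sm.ScreenSimConfig(
            trays={"t": [sm.GenotypeSpec("g1"), sm.GenotypeSpec("g2")]},
            seed=seed,
            **defaults,
        )

    return make


@pytest.fixture
def hand_panel():
    """Tiny hand-built aggregated panel: 2 genotypes x 2 replicates x 3 ages."""
    rows = []
    speeds = {
        ("A", "r1"): [9.0, 8.0, 6.5],
        ("A", "r2"): [9.4, 7.6, 6.9],
        ("B", "r1"): [8.1, 6.9, 4.8],
        ("B", "r2"): [8.5, 7.3, 5.2],
    }
    for (g, r), vals in speeds.items():
        for age, v in zip([5.0, 15.0, 25.0], vals):
            rows.append((g, "tray1", r, age, v))
    return pd.DataFrame(rows, columns=["genotype", "tray", "replicate", "age_days", "speed"])


@pytest.fixture(scope="session")
def small_proteome():
    matrix, meta, truth = sm.simulate_proteome(
        60,
        sm.CrossSectionalDesign(n_per_genotype=8),
        {i: (1.0, 0.0) for i in range(10)},
        dispersion=0.05,
        seed=77,
    )
    return matrix, meta, truth
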