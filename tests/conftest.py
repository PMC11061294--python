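import numpy as np
import pandas as pd
import pytest

from ct5hmc import CohortConfig, make_truth_table, simulate_cohort


def two_group_config(**overrides):
    """Clean-regime two-group config: composition independent of group."""
    params = dict(
        n_probes=2000,
        n_genes=300,
        seed=11,
        groups={"NonTumor": 10, "TUM": 10},
        dirichlet_concentrations={
            "NonTumor": (5, 2, 2, 2, 2, 4),
            "TUM": (5, 2, 2, 2, 2, 4),
        },
        measurement_precision=200.0,
    )
    params.update(overrides)
    return CohortConfig(**params)


def plant_bulk_effects(config, n_planted, delta, assay="5hmC", group="TUM", seed=0,
                       headroom=None):
    """Truth table planting `delta` at probes with room for it in every cell type."""
    from ct5hmc import simulate_reference_profiles

    prof = simulate_reference_profiles(config)
    slack = 1.0 - prof["5mC"] - prof["5hmC"]
    need = headroom if headroom is not None else abs(delta) + 0.05
    eligible = slack.min(axis=1)[lambda s: s >= need].index
    rng = np.random.default_rng(seed)
    probes = list(rng.choice(eligible, size=n_planted, replace=False))
    key = "delta_5hmC" if assay == "5hmC" else "delta_5mC"
    other = "delta_5mC" if assay == "5hmC" else "delta_5hmC"
    truth = make_truth_table(
        [{"probe_id": p, "cell_type": "bulk", "group": group, key: delta, other: 0.0}
         for p in probes]
    )
    return truth, probes


@pytest.fixture(scope="session")
def small_cohort():
    """A 2000-probe clean-regime cohort shared by read-only tests."""
    return simulate_cohort(two_group_config())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_annotation():
    """Six-probe annotation with both design types and simple flags."""
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 6,
            "start": range(100, 700, 100),
            "end": range(102, 702, 100),
            "design_type": ["I", "I", "II", "II", "II", "II"],
            "island_relation": ["Island", "Shore", "OpenSea", "Island", "Shelf", "OpenSea"],
            "TSS200": [1, 0, 0, 1, 0, 0],
            "TSS1500": [0, 1, 0, 0, 0, 0],
            "gene_body": [0, 0, 1, 0, 1, 1],
            "genes": ["GA", "GA;GB", "", "GB", "GC", ""],
        },
        index=pd.Index([f"cg{i}" for i in range(6)], name="probe_id"),
    )
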