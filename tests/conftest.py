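import numpy as np
import pandas as pd
import pytest

from kosynergy import SimulationConfig


def make_cohort(rows):
    """Build a cohort table from (genotype, lesion_time, lesion_event,
    followup_time, death_event) tuples."""
    return pd.DataFrame(
        [
            {
                "subject_id": f"s{i:03d}",
                "genotype": g,
                "lesion_time": lt,
                "lesion_event": le,
                "followup_time": ft,
                "death_event": de,
            }
            for i, (g, lt, le, ft, de) in enumerate(rows)
        ]
    )


def binary_cohort(n_a, k_a, n_b, k_b, n_ab, k_ab, t=400):
    """Censor-free cohort in which k of n subjects per arm are lesioned by t."""
    rows = []
    for genotype, n, k in [
        ("SIRT2KO", n_a, k_a),
        ("SOD1KO", n_b, k_b),
        ("DKO", n_ab, k_ab),
    ]:
        for i in range(n):
            if i < k:
                rows.append((genotype, t // 2, 1, t, 0))
            else:
                rows.append((genotype, t, 0, t, 0))
    return make_cohort(rows)


@pytest.fixture
def small_config():
    """A fast generator configuration for unit tests."""
    return SimulationConfig(n_per_genotype=20, n_genes=500, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
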