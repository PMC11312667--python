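import numpy as np
import pandas as pd
import pytest

from survgwas.simulate import GeneSpec, SimConfig, VariantSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_study():
    """A seeded 2,000-subject study with one causal common variant and two
    gene architectures (one harmful LoF, one null missense)."""
    config = SimConfig(
        n_subjects=2_000,
        seed=11,
        variants=[VariantSpec(maf=0.3, log_hr=0.3), VariantSpec(maf=0.2)],
        genes=[
            GeneSpec("GENE1", n_variants=8, carrier_freq=0.01, variant_class="LoF", log_hr=0.8),
            GeneSpec("GENE2", n_variants=6, carrier_freq=0.01, variant_class="AlphaMissense",
                     log_hr=0.0, n_nonqualifying=2),
        ],
    )
    cohort, G, truth = simulate_cohort(config)
    return config, cohort, G, truth


def toy_cohort(n=200, seed=0, frac_events=0.6):
    """Small hand-rolled cohort table with sex/PC columns."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "event": (rng.random(n) < frac_events).astype(int),
            "age": rng.uniform(40, 90, n),
            "sex": rng.integers(0, 2, n),
            **{f"pc{k}": rng.standard_normal(n) for k in range(1, 6)},
        }
    )
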