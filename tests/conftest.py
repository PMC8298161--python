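import numpy as np
import pandas as pd
import pytest

from dlgwas.data import GenotypeDataset
from dlgwas.simulate import CausalVariant, SimulationConfig, simulate


@pytest.fixture
def tiny_ds() -> GenotypeDataset:
    """Hand-built 2-sample x 3-SNP dataset with one missing call."""
    samples = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "group": ["AD", "HC"],
            "sex": ["male", "female"],
        }
    )
    variants = pd.DataFrame(
        {
            "rsid": ["rs1", "rs2", "rs3"],
            "chromosome": ["1", "1", "2"],
            "position": [100, 200, 50],
            "allele_a": ["A", "C", "A"],
            "allele_b": ["G", "T", "T"],
        }
    )
    # codes: A=1, T=2, C=3, G=4; 0 = missing
    calls = np.array(
        [
            [[1, 4], [3, 3], [1, 2]],
            [[1, 1], [0, 0], [2, 2]],
        ],
        dtype=np.uint8,
    )
    return GenotypeDataset(samples=samples, variants=variants, calls=calls)


def make_random_ds(seed: int = 0, n_samples: int = 20, n_variants: int = 50):
    """Small clean simulated dataset (both alleles observed at every variant)."""
    cfg = SimulationConfig(
        n_cases=n_samples // 2,
        n_controls=n_samples - n_samples // 2,
        n_variants=n_variants,
        maf_range=(0.25, 0.5),
        missing_rate=0.05,
        seed=seed,
    )
    ds, _ = simulate(cfg)
    return ds


@pytest.fixture
def random_ds():
    return make_random_ds(seed=11)


def make_causal_config(**kw) -> SimulationConfig:
    defaults = dict(
        n_cases=250,
        n_controls=250,
        n_variants=500,
        maf_range=(0.1, 0.5),
        causal=[CausalVariant(3, 4.0, maf=0.3)],
        baseline_prevalence=0.1,
        missing_rate=0.01,
        seed=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)
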