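import numpy as np
import pytest

from agetrend import GeneratorConfig, generate_expression
from agetrend.datamodel import AGE_GROUPS, AgeGroup, SampleRecord, Sex


@pytest.fixture(scope="session")
def tiny_config():
    """A small, fast bundle configuration for structural tests."""
    return GeneratorConfig(
        n_genes=40,
        n_tissues=2,
        samples_per_bin=6,
        planted_increasing=5,
        planted_decreasing=5,
        planted_term_size=8,
        planted_term_overlap=6,
        n_decoy_terms=6,
        edge_prob=0.08,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return generate_expression(tiny_config)


def make_profile_dataset(bin_values):
    """Build a one-gene, one-tissue ExpressionDataset from six value lists."""
    from agetrend import ExpressionDataset

    samples, values = [], []
    k = 0
    for age, vals in zip(AGE_GROUPS, bin_values):
        for v in vals:
            k += 1
            samples.append(
                SampleRecord(f"S-{k:03d}-0001", f"S-{k:03d}", "liver", Sex.UNKNOWN, age)
            )
            values.append(v)
    return ExpressionDataset(["G1"], samples, np.array([values], dtype=float))
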