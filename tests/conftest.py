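import numpy as np
import pytest

from afsmqtl import RunConfig, SimConfig, simulate_cross
from afsmqtl.calling import CLASS_LABELS


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def all_class_frequencies():
    """Equal mass on all twelve heritability classes."""
    freqs = {label: 1.0 / 12.0 for label in CLASS_LABELS}
    freqs["D4"] = 1.0 - sum(v for k, v in freqs.items() if k != "D4")
    return freqs


@pytest.fixture
def small_truth(all_class_frequencies):
    """A small cross covering all twelve classes, deterministic."""
    sim = SimConfig(
        n_f1=20,
        n_sites=120,
        n_markers=40,
        scaffold_lengths={"scaffold_1": 20000},
        class_frequencies=all_class_frequencies,
        read_depth_mean=10.0,
        seed=42,
    )
    return simulate_cross(sim)
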