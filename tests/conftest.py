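import numpy as np
import pytest

from duincoder import (CategoricalPriorVAE, SimConfig, compute_stats,
                       simulate_dataset, windows_from_records)

TINY_MODEL_PARAMS = dict(
    n_categories=4, latent_dim=8, hidden_cat=(32,), hidden_en=(32,),
    hidden_de=(32,), epochs=8, batch_size=64, val_interval_epochs=4,
    k_val=4, random_state=0)


@pytest.fixture(scope="session")
def tiny_records():
    """12 short synthetic journeys (2 per route x status, 20 s each)."""
    return simulate_dataset(SimConfig(seed=3, records_per_cell=2,
                                      duration_override_s=20.0))


@pytest.fixture(scope="session")
def tiny_normal(tiny_records):
    return [r for r in tiny_records if r.status == "normal"]


@pytest.fixture(scope="session")
def tiny_trained(tiny_normal):
    """A small driver model trained briefly on normal windows (L=21)."""
    stats = compute_stats(tiny_normal)
    batch = windows_from_records(tiny_normal, 21, stats)
    model = CategoricalPriorVAE(window_frames=21, **TINY_MODEL_PARAMS)
    model.fit(batch.data[::4])
    return model, stats, batch


def build_untrained(window_frames=21, seed=0, **overrides):
    """Model with initialized (random) weights but no training."""
    params = {**TINY_MODEL_PARAMS, **overrides}
    params["random_state"] = seed
    m = CategoricalPriorVAE(window_frames=window_frames, **params)
    m._build(np.random.SeedSequence(seed))
    return m
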