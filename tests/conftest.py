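import pytest

from xlrip import (
    CSMSimSpec,
    RunConfig,
    prefilter_csms,
    simulate_csms,
    train_classifier,
)


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def scored_sim():
    """A medium synthetic CSM set with both channel classifiers trained.

    Returns (scored records, truth table, classifier specs, config).
    Shared across tests that only read from it.
    """
    run_cfg = RunConfig(rng_seed=11)
    records, truth = simulate_csms(CSMSimSpec(n_true=800, n_false=6000, rng_seed=11))
    kept = prefilter_csms(records, run_cfg)
    models = {ch: train_classifier(kept, ch, run_cfg) for ch in ("ETD", "HCD")}
    return kept, truth, models, run_cfg
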