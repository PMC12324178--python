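import numpy as np
import pytest

import seqgrammar as sg
from seqgrammar.simulate import simulate_reads


@pytest.fixture(scope="session")
def layout():
    return sg.builtin_layout()


@pytest.fixture(scope="session")
def whitelist():
    return sg.random_whitelist(200, rng=7)


@pytest.fixture(scope="session")
def clean_reads(layout, whitelist):
    """Error-free canonical reads with ground truth."""
    cfg = sg.SimulationConfig(
        layout=layout,
        n_reads=60,
        whitelist=whitelist,
        seed=5,
        error_rates=sg.ErrorRates.zero(),
    )
    return simulate_reads(cfg)


@pytest.fixture(scope="session")
def noisy_reads(layout, whitelist):
    """Default-error-rate canonical reads."""
    cfg = sg.SimulationConfig(layout=layout, n_reads=60, whitelist=whitelist, seed=6)
    return simulate_reads(cfg)


@pytest.fixture(scope="session")
def reference(layout):
    """Reference softmax + CRF models trained at the benchmark conditions.

    Expensive (trains on 50,000 simulated reads); shared by every test that
    needs realistic trained models.
    """
    from seqgrammar.benchmark import (
        evaluate_structural_accuracy,
        train_reference_models,
    )

    seed = 2024
    fast, crf, layout, whitelist = train_reference_models(layout=layout, seed=seed)
    evaluation = evaluate_structural_accuracy(fast, crf, layout, whitelist, seed)
    return {
        "fast": fast,
        "crf": crf,
        "layout": layout,
        "whitelist": whitelist,
        "evaluation": evaluation,
        "seed": seed,
    }
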