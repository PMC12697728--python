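"""Shared fixtures: a seeded small CNN adapter and synthesized image sets.

The expensive synthesis runs are session-scoped so that efficacy, recovery
and residual-method tests share one artifact each.
"""

import numpy as np
import pytest

from layerprint.adapters import SmallCNNAdapter
from layerprint.cnn_rsm import compute_rsm
from layerprint.synthesis import (
    SynthesisConfig,
    diversify_phase,
    init_noise,
    orthogonalize_phase,
)


@pytest.fixture(scope="session")
def adapter():
    """The seeded offline test CNN (3 tanh conv layers, 64 x 64 input)."""
    return SmallCNNAdapter.seeded(0, input_size=64)


@pytest.fixture(scope="session")
def tiny_adapter():
    """A faster 16 x 16 CNN for gradient and optimizer unit tests."""
    return SmallCNNAdapter.seeded(0, input_size=16, channels=(4, 6), stride=2)


@pytest.fixture(scope="session")
def desk_trace(adapter):
    """Desk-scale synthesis: 8 images at 64 x 64, 200 + 200 iterations."""
    cfg = SynthesisConfig(
        n_images=8, image_size=(64, 64), phase1_iters=200, phase2_iters=200,
        step_size=0.05, rgb_breadth_weight=0.1, seed=11, target_layer="conv3",
    )
    stimuli = diversify_phase(init_noise(cfg), adapter, cfg)
    return orthogonalize_phase(stimuli, adapter, cfg)


@pytest.fixture(scope="session")
def ortho_rsms(adapter):
    """Orthogonalized layer RSMs from a long-diversification synthesis.

    The longer, larger-step diversification phase gives the images enough
    representational variance for geometry embedded in synthetic brains to
    be recoverable (the desk 200-iteration profile leaves RSM triangles
    nearly constant).
    """
    cfg = SynthesisConfig(
        n_images=8, image_size=(64, 64), phase1_iters=2000, phase2_iters=300,
        step_size=0.5, rgb_breadth_weight=0.1, seed=3, target_layer="conv3",
    )
    stimuli = diversify_phase(init_noise(cfg), adapter, cfg)
    trace = orthogonalize_phase(stimuli, adapter, cfg)
    acts = adapter.activations(trace.final_images.pixels)
    return {lid: compute_rsm(acts[lid], layer_id=lid)
            for lid in adapter.layer_ids}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
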