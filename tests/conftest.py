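"""Shared fixtures: a trained punctum classifier and synapse-window helpers."""

import numpy as np
import pytest

from synapcount import pipeline, synthgen


@pytest.fixture(scope="session")
def classifier():
    """Punctum/background classifier trained once on a synthetic field."""
    return pipeline.train_default_classifier(7, n_fields=1)


@pytest.fixture(scope="session")
def default_field():
    """One default-condition field with ground truth (seed fixed)."""
    spec = synthgen.PunctaFieldSpec(seed=101)
    image, truth = synthgen.make_puncta_field(spec)
    return spec, image, truth


def render_synapse_window(rng, spec, syn_type):
    """Rasterize one synapse in its own minimal window.

    Returns ``(params, pre_mask, post_mask)``; used for desk-scale statistics
    over many synapses without building a full labeled volume.
    """
    p = synthgen.sample_synapse_params(rng, spec, syn_type)
    ext = synthgen.synapse_extent_nm(p)
    dx, dy, dz = spec.voxel_size
    shape = (int(2 * ext / dz) + 4, int(2 * ext / dy) + 4,
             int(2 * ext / dx) + 4)
    _, pre, post = synthgen.rasterize_synapse(p, (ext + 10,) * 3,
                                              spec.voxel_size, shape)
    return p, pre, post
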