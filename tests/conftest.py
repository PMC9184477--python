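import numpy as np
import pytest

from terralabel import synthetic as syn
from terralabel import training_prep as tp
from terralabel.inference import prepare_model_inputs
from terralabel.normalization import fit_norm_stats


@pytest.fixture(scope="session")
def small_world():
    """A 120 px truth world with all nine classes."""
    cfg = syn.WorldConfig(seed=7, tile_pixels=120, blob_scale=30)
    return cfg, syn.generate_truth(cfg)


@pytest.fixture(scope="session")
def rendered_scene(small_world):
    _, truth = small_world
    return syn.render_scene(truth, seed=11)


@pytest.fixture(scope="session")
def cloudy_package(small_world, rendered_scene):
    _, truth = small_world
    return syn.inject_clouds_shadows(rendered_scene, truth, 0.12,
                                     solar_azimuth_deg=135.0, seed=13,
                                     add_building=True)


def build_examples(n_tiles, size, seed0, n_stats=None):
    """Synthetic training examples paired with their truth grids."""
    scenes, truths = [], []
    for i in range(n_tiles):
        cfg = syn.WorldConfig(seed=seed0 + i, tile_pixels=size, blob_scale=30)
        t = syn.generate_truth(cfg)
        scenes.append(syn.render_scene(t, seed=seed0 + 1000 + i))
        truths.append(t)
    stats = fit_norm_stats(scenes[:n_stats or n_tiles])
    examples = []
    for s, t in zip(scenes, truths):
        inputs = prepare_model_inputs(s, stats)
        targets, labeled = tp.smooth_labels(t.values, "expert")
        counts = np.bincount(t.values.ravel(), minlength=10)
        w = tp.compute_weights(t.values, inputs, counts)
        examples.append(tp.TrainingExample(
            inputs=inputs, targets=targets, class_weight=w["classification"],
            synth_weight=w["high_freq"], labeled=labeled,
            clear=np.ones_like(labeled)))
    return examples, [t.values for t in truths], stats


@pytest.fixture(scope="session")
def toy_examples():
    return build_examples(10, 66, seed0=0, n_stats=8)
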