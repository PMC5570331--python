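import numpy as np
import pytest

from scenegaze.io_core import DEFAULT_GEOMETRY, TrialMeta
from scenegaze.roi_partition import build_roiset
from scenegaze.scene_saliency import compute_saliency
from scenegaze.synthetic_data import GazeSimSpec, SceneSpec, generate_scene


@pytest.fixture(scope="session")
def geom():
    """The reference screen geometry (24" panel at 50 cm)."""
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def small_scene():
    """A 240x180 synthetic scene with saliency and ROI partition.

    Session-scoped: saliency computation dominates test runtime.
    """
    spec = SceneSpec(size_px=(240, 180), n_heads=3, n_bodies=3,
                     n_distractors=5, seed=11)
    image, masks = generate_scene(spec)
    smap = compute_saliency(image)
    roiset = build_roiset(masks, smap, q=80.0)
    return {"spec": spec, "image": image, "masks": masks,
            "saliency": smap, "roiset": roiset}


@pytest.fixture
def free_meta():
    def make(trial_id="t0", presentation_ms=3000.0, onset_ms=2000.0,
             cross=(119.5, 89.5), task="free", click=None):
        return TrialMeta(
            subject_id="s0", trial_id=trial_id, stimulus_id="stim0",
            task=task, category="social", stimulus_onset_ms=onset_ms,
            presentation_ms=presentation_ms, click_time_ms=click,
            cross_position_px=cross,
        )
    return make


@pytest.fixture
def clean_sim():
    """Noiseless, driftless, blink-free simulation spec."""
    return GazeSimSpec(noise_sd_px=0.0, drift_sd_px=0.0, blink_rate_hz=0.0)
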