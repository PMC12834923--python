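import numpy as np
import pytest

from gazecad.design import CaseSpec, DesignConfig, Group
from gazecad.metrics import GazeRecording
from gazecad.simulate import (
    ConditionEffects,
    GeneratorConfig,
    ReaderProfile,
    make_lung_mask,
    sample_lesion_box,
)


def build_recording(
    points,
    valid=None,
    rate: float = 60.0,
    duration: float | None = None,
    width: int = 640,
    height: int = 480,
) -> GazeRecording:
    """Recording from an (n, 2) point array with implicit 1/rate spacing."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    t = np.arange(n) / rate
    if valid is None:
        valid = np.ones(n, dtype=bool)
    if duration is None:
        duration = n / rate
    return GazeRecording(
        t=t, x=pts[:, 0], y=pts[:, 1], valid=np.asarray(valid, dtype=bool),
        sampling_rate=rate, duration=duration, image_width=width, image_height=height,
    )


@pytest.fixture(scope="session")
def small_mask():
    return make_lung_mask(640, 480, seed=7)


@pytest.fixture(scope="session")
def tp_case(small_mask):
    rng = np.random.default_rng(11)
    box = sample_lesion_box(small_mask, (30, 50), rng)
    return CaseSpec(
        "tp000", True, Group.TP, lesion_box=box, displayed_box=box,
        image_width=640, image_height=480,
    )


def small_profiles():
    return [
        ReaderProfile("A", 6.0, 0.8, 1.2, 2000.0, 0.55,
                      dropout_rate=0.08, decision_sensitivity=0.7,
                      decision_specificity=0.9, prompt_adoption=0.7),
        ReaderProfile("B", 4.0, 0.5, 1.6, 1500.0, 0.45,
                      dropout_rate=0.05, decision_sensitivity=0.8,
                      decision_specificity=0.8, prompt_adoption=0.9),
    ]


@pytest.fixture()
def tiny_config():
    """A reduced crossover study: 2 readers x 10 cases on 640x480 frames."""
    return GeneratorConfig(
        readers=small_profiles(),
        effects=ConditionEffects(1.5, 0.4, -0.4, 500.0, 6.0),
        design=DesignConfig(4, 1, 0, 4, 1, target_sensitivity=0.8,
                            target_specificity=0.8),
        image_width=640,
        image_height=480,
        lesion_size_range=(25, 45),
        seed=5,
    )
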