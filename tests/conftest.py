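import numpy as np
import pytest

from arenatrack import AnimalSpec, ArenaSpec


@pytest.fixture
def small_arena() -> ArenaSpec:
    return ArenaSpec(width=160, height=160, polarity="bright_on_dark",
                     background_level=0.1, noise_sigma=0.01, fps=30.0)


@pytest.fixture
def quiet_arena() -> ArenaSpec:
    """Noise-free arena for exact segmentation checks."""
    return ArenaSpec(width=160, height=160, polarity="bright_on_dark",
                     background_level=0.1, noise_sigma=0.0, fps=30.0)


def make_animals(n: int, target_area: int = 60, speed: float = 2.0) -> list[AnimalSpec]:
    return [AnimalSpec(animal_id=i, target_area=target_area, axis_ratio=3.0,
                       contrast=0.5, speed=speed, heading_persistence=0.8)
            for i in range(n)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
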