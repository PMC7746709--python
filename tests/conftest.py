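import numpy as np
import pytest

from shapecorr import ClosedContour, PartSpec, ShapeSpec, generate_pair


@pytest.fixture
def unit_square():
    return ClosedContour([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def circle400():
    t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    return ClosedContour(np.column_stack([np.cos(t), np.sin(t)]))


@pytest.fixture
def animal_spec():
    return ShapeSpec(
        name="critter",
        parts={
            "Head": PartSpec(0.25, 0.28, 0.55),
            "Neck": PartSpec(1.45, 0.18, 0.5),
            "Front leg/s": PartSpec(-0.95, 0.26, 0.45),
            "Hind leg/s": PartSpec(-2.15, 0.26, 0.45),
            "Tail": PartSpec(np.pi, 0.26, 0.7),
        },
        aspect=1.7,
    )


@pytest.fixture
def self_pair(animal_spec):
    """A shape paired with itself: identity transforms, identity labels."""
    return generate_pair(animal_spec, {}, "different_geometry", pair_id="self")


@pytest.fixture
def stretched_pair(animal_spec):
    return generate_pair(
        animal_spec, {"Head": 2.0, "Tail": 0.5}, "different_geometry", pair_id="stretched"
    )
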