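import numpy as np
import pytest

from comorph.containers import layout_to_frame
from comorph.pipeline import default_moa_assignment
from comorph.synthetic import (
    CellSpec,
    EffectModel,
    SceneSpec,
    generate_plate_layout,
    render_well_image,
)


@pytest.fixture(scope="session")
def small_layout():
    """One plate: 4 compounds x 5 concentrations + 12+12 controls."""
    assignment = default_moa_assignment(4, 2)
    return generate_plate_layout(4, 5, assignment, seed=0, plate_id="P1")


@pytest.fixture(scope="session")
def small_layout_frame(small_layout):
    return layout_to_frame([small_layout])


@pytest.fixture(scope="session")
def null_effects():
    return EffectModel.null(["PARP", "MEK1/2"], n_features=6)


@pytest.fixture(scope="session")
def mixed_scene():
    """Three cancer cells and two fibroblasts, well separated."""
    return SceneSpec(
        cells=(
            CellSpec("cancer", (40.0, 40.0), size=7.0, eccentricity=0.2),
            CellSpec("cancer", (40.0, 120.0), size=6.0, eccentricity=0.1),
            CellSpec("cancer", (120.0, 60.0), size=8.0, eccentricity=0.3,
                     orientation=0.7),
            CellSpec("fibroblast", (120.0, 140.0), size=8.0, eccentricity=0.9,
                     orientation=1.2),
            CellSpec("fibroblast", (160.0, 40.0), size=7.0, eccentricity=0.95),
        )
    )


@pytest.fixture(scope="session")
def rendered(mixed_scene):
    image, mask = render_well_image(mixed_scene, image_size=(195, 195), seed=3)
    return image, mask
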