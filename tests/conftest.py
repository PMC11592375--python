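import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_rules():
    from osteosim import RegulationRuleSet

    return RegulationRuleSet()


@pytest.fixture(scope="session")
def tiny_gyroid_model():
    """One calibrated gyroid cell at coarse resolution with thin plates."""
    from osteosim import Structure, UnitCellSpec, build_scaffold_model

    spec = UnitCellSpec(
        structure=Structure.GYROID, cells_per_axis=1, voxels_per_cell=8
    )
    model, spec = build_scaffold_model(spec, plate_thickness=1, side_thickness=1)
    return model, spec
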