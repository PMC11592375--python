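"""Deterministic verification fixtures.

Small degenerate models with known analytic behaviour, used by the test
suite and handy for sanity-checking a new installation:

* ``homogeneous_block`` — an all-solid cube of one material; under top
  traction p with a frictionless base and symmetry side planes its axial
  strain is exactly -p/E.
* ``two_element_toy`` — two healing elements with prescribed tissue
  compositions for hand-checking the volume-fraction estimators.
* ``plate_sandwich`` — a healing column between two bone endplates for
  checking that ossification seeds from bone surfaces.
"""

from __future__ import annotations

import numpy as np

from .fem import MaterialField
from .geometry import RegionLabel, VoxelModel
from .regulation import TissueComposition


def make_fixture(kind: str, n: int = 4, spacing_um: float = 100.0):
    """Build a named fixture; returns (VoxelModel, MaterialField, extras)."""
    if kind == "homogeneous_block":
        labels = np.full((n, n, n), int(RegionLabel.SCAFFOLD), dtype=np.uint8)
        model = VoxelModel(
            labels=labels,
            spacing_um=spacing_um,
            quarter_symmetry=True,
            symmetry_planes=((0, 0), (1, 0)),
        )
        nelem = n**3
        materials = MaterialField(np.full(nelem, 1000.0), np.full(nelem, 0.325))
        return model, materials, {}

    if kind == "two_element_toy":
        labels = np.full((1, 1, 2), int(RegionLabel.HEALING), dtype=np.uint8)
        model = VoxelModel(
            labels=labels, spacing_um=spacing_um, quarter_symmetry=False,
            symmetry_planes=(),
        )
        comp = TissueComposition(
            np.array([[0.7, 0.0, 0.0, 0.3], [0.9, 0.0, 0.0, 0.1]])
        )
        from .regulation import homogenize_material

        E, nu = homogenize_material(comp.fractions)
        materials = MaterialField(E, nu)
        return model, materials, {"composition": comp}

    if kind == "plate_sandwich":
        nz = n + 2
        labels = np.full((n, n, nz), int(RegionLabel.HEALING), dtype=np.uint8)
        labels[:, :, 0] = RegionLabel.ENDPLATE_BOTTOM
        labels[:, :, -1] = RegionLabel.ENDPLATE_TOP
        model = VoxelModel(
            labels=labels,
            spacing_um=spacing_um,
            quarter_symmetry=True,
            symmetry_planes=((0, 0), (1, 0)),
        )
        nelem = int(model.active_mask.sum())
        E = np.full(nelem, 0.2)
        nu = np.full(nelem, 0.167)
        plates = model.labels[model.active_mask] != RegionLabel.HEALING
        E[plates], nu[plates] = 10000.0, 0.325
        materials = MaterialField(E, nu)
        return model, materials, {}

    raise ValueError(f"unknown fixture kind: {kind!r}")
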