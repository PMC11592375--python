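"""Run configuration: every tunable of a simulation in one auditable place.

The defaults reproduce the reference compression set-up: 1560 um cubic unit
cells at 80% porosity, a 2x2x2 mirrored lattice reduced to quarter symmetry,
0.5 MPa compression on a rigid top endplate, the standard tissue/region
material table and differentiation rule windows. Configurations round-trip
losslessly through YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fem import LoadCase
from .geometry import ConfigurationError, Structure, UnitCellSpec
from .regulation import RegulationRuleSet, TissueProperties


@dataclass
class RunConfig:
    """Complete, serializable description of one simulation run."""

    structure: str = "gyroid"
    cell_size_um: float = 1560.0
    target_porosity: float = 0.80
    cells_per_axis: int = 2
    voxels_per_cell: int = 20
    solid_side: int | None = None
    level_offset: float | None = None
    calibration_resolution: int = 64
    plate_thickness: int = 2
    side_thickness: int = 2
    pressure_mpa: float = 0.5
    rules: RegulationRuleSet = field(default_factory=RegulationRuleSet)
    output_dir: str = "runs"
    seed: int | None = None  # reserved: the algorithm itself is deterministic

    def unit_cell_spec(self) -> UnitCellSpec:
        return UnitCellSpec(
            structure=Structure(self.structure),
            cell_size_um=self.cell_size_um,
            target_porosity=self.target_porosity,
            level_offset=self.level_offset,
            cells_per_axis=self.cells_per_axis,
            voxels_per_cell=self.voxels_per_cell,
            solid_side=self.solid_side,
        )

    def load_case(self) -> LoadCase:
        return LoadCase(pressure_mpa=self.pressure_mpa)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}"
            )
        if "rules" in d and isinstance(d["rules"], dict):
            rd = dict(d["rules"])
            for key in ("tissue_properties", "region_properties"):
                if key in rd:
                    rd[key] = {
                        name: (
                            TissueProperties(**p) if isinstance(p, dict) else p
                        )
                        for name, p in rd[key].items()
                    }
            try:
                d["rules"] = RegulationRuleSet(**rd)
            except TypeError as exc:
                raise ConfigurationError(f"invalid rules section: {exc}") from exc
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
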