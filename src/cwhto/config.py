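"""Run configuration for the command-line pipeline.

Defaults encode the study conditions: a cohort of 11 knees, all four
techniques, correction angles 12°, 15° and 18°, zero saw kerf, and a
0.25 mm AP scanline step for the overhang decomposition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .analysis import DEFAULT_THETAS
from .errors import ParameterError, SchemaError
from .geometry import DEFAULT_SCANLINE_STEP
from .phantoms import CohortConfig, TruncNormal
from .planning import Technique


@dataclass
class RunConfig:
    n_knees: int = 11
    techniques: list[str] = field(
        default_factory=lambda: [t.value for t in Technique]
    )
    thetas: list[float] = field(default_factory=lambda: list(DEFAULT_THETAS))
    kerf: float = 0.0  # mm; saw-cut thickness (0 in the simulated protocol)
    scanline_step: float = DEFAULT_SCANLINE_STEP  # mm
    stat_test: str = "mann_whitney"
    mpta_vara_threshold: float = 83.0  # deg; MPTA <= threshold -> vara
    jlca_high_threshold: float = 7.0  # deg; JLCA >= threshold -> high
    cohort_dir: str | None = None  # read STL+landmarks instead of generating
    n_ring: int = 64  # phantom angular resolution
    ring_spacing: float = 2.0  # phantom axial resolution, mm
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def validate(self) -> "RunConfig":
        if self.n_knees < 1:
            raise ParameterError("n_knees: must be >= 1")
        for t in self.techniques:
            try:
                Technique(t)
            except ValueError:
                raise ParameterError(f"techniques: unknown technique {t!r}") from None
        for th in self.thetas:
            if not (0.0 < th < 45.0):
                raise ParameterError(f"thetas: {th} outside (0, 45) degrees")
        if self.kerf < 0:
            raise ParameterError("kerf: must be >= 0")
        if self.scanline_step <= 0:
            raise ParameterError("scanline_step: must be > 0")
        if self.stat_test not in ("mann_whitney", "student_t", "welch_t"):
            raise ParameterError(f"stat_test: unsupported test {self.stat_test!r}")
        self.cohort.validate()
        return self

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise SchemaError(f"{path}: top level must be a mapping")
        return RunConfig.from_dict(data, source=str(path))

    @staticmethod
    def from_dict(data: dict, source: str = "<config>") -> "RunConfig":
        data = dict(data)
        cohort_data = data.pop("cohort", None)
        known = {f.name for f in fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"{source}: unknown config keys {sorted(unknown)}")
        cfg = RunConfig(**data)
        if cohort_data is not None:
            cfg.cohort = _cohort_from_dict(cohort_data, source)
        return cfg.validate()


def _cohort_from_dict(data: dict, source: str) -> CohortConfig:
    data = dict(data)
    kwargs = {}
    for name in ("width", "mpta", "jlca", "hka", "age"):
        if name in data:
            spec = data.pop(name)
            try:
                kwargs[name] = TruncNormal(**spec)
            except TypeError as exc:
                raise SchemaError(f"{source}: cohort.{name}: {exc}") from None
    known = {f.name for f in fields(CohortConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"{source}: unknown cohort keys {sorted(unknown)}")
    kwargs.update(data)
    return CohortConfig(**kwargs)
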