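"""Validated run configuration (YAML or JSON; unknown keys rejected).

An empty config yields the full default sweep: sine and brachial waveforms,
0.1 and 1 Hz, maximal strains 2.5-17.5 % in 2.5 % increments, 10 cycles.
Mesh sizing defaults to the reference profile (h_max 0.99 um, refined
0.159 um); the ``ci`` profile swaps in the coarse desk-scale sizing.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .chromatin import ChromatinParams, INTERPHASE, MITOTIC
from .errors import ConfigurationError
from .fem import Material
from .geometry import CellGeometry, MeshSizing

__all__ = ["SweepConfig", "validate_config", "apply_profile", "DEFAULT_Y_TO_X_RATIO"]

#: Anisotropic-mode loading ratio calibrated so the long/short-axis nuclear
#: strain ratio for a 0.1 Hz sine at the desk-scale mesh profile is ~11.
DEFAULT_Y_TO_X_RATIO = 0.183


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MaterialConfig(_Model):
    E_pa: float = Field(gt=0)
    eta_pa_s: float = Field(ge=0)
    nu: float = Field(default=0.45, ge=0, lt=0.5)


class MaterialsConfig(_Model):
    membrane: MaterialConfig = MaterialConfig(E_pa=2980.0, eta_pa_s=4010.0)
    cytoplasm: MaterialConfig = MaterialConfig(E_pa=4000.0, eta_pa_s=5430.0)
    nucleus: MaterialConfig = MaterialConfig(E_pa=2010.0, eta_pa_s=970.0)

    def as_materials(self) -> dict[str, Material]:
        return {
            name: Material(name, m.E_pa, m.eta_pa_s, m.nu)
            for name, m in (
                ("membrane", self.membrane),
                ("cytoplasm", self.cytoplasm),
                ("nucleus", self.nucleus),
            )
        }


class MembraneConfig(_Model):
    thickness_um: float = Field(default=0.01, gt=0)


class GeometryConfig(_Model):
    cell_semi_axes_um: tuple[float, float, float] = (25.0, 15.0, 6.0)
    nucleus_semi_axes_um: tuple[float, float, float] = (8.0, 6.0, 3.0)
    nucleus_center_um: tuple[float, float, float] = (0.0, 0.0, 3.0)

    def as_geometry(self, membrane_thickness: float = 0.01) -> CellGeometry:
        return CellGeometry(
            cell_semi_axes=self.cell_semi_axes_um,
            nucleus_semi_axes=self.nucleus_semi_axes_um,
            nucleus_center=self.nucleus_center_um,
            membrane_thickness=membrane_thickness,
        )


class MeshConfig(_Model):
    h_max_um: float = Field(default=0.99, gt=0)
    growth_rate: float = Field(default=1.4, gt=1)
    h_refined_um: float = Field(default=0.159, gt=0)

    def as_sizing(self) -> MeshSizing:
        return MeshSizing(self.h_max_um, self.growth_rate, self.h_refined_um)


class SolverConfig(_Model):
    scheme: Literal["backward_euler", "generalized_alpha"] = "backward_euler"
    steps_per_cycle: int = Field(default=50, ge=50)


class LoadingConfig(_Model):
    mode: Literal["equibiaxial", "anisotropic"] = "equibiaxial"
    y_to_x_ratio: float = Field(default=DEFAULT_Y_TO_X_RATIO, ge=-0.5, le=1.0)
    n_cycles: int = Field(default=10, ge=1)


class WaveformConfig(_Model):
    """Single-run waveform block (sweeps use the top-level lists)."""

    kind: Literal["sine", "brachial"] = "sine"
    eps_max: float = Field(default=0.075, gt=0, lt=0.5)
    frequency_hz: float = Field(default=0.1, gt=0)
    shape_file: Optional[str] = None


class ChromatinConfig(_Model):
    phases: tuple[str, ...] = ("interphase", "mitotic")
    interphase_E_pa: float = Field(default=INTERPHASE.E, gt=0)
    interphase_eta: float = Field(default=INTERPHASE.eta, gt=0)
    mitotic_E_pa: float = Field(default=MITOTIC.E, gt=0)
    mitotic_eta: float = Field(default=MITOTIC.eta, gt=0)
    unfold_fold: float = Field(default=2.0, gt=1)
    damage_fold: float = Field(default=3.0, gt=1)
    stress_component: Literal["sigma_xx", "sigma_yy", "sigma_zz", "sigma_vm"] = (
        "sigma_xx"
    )

    def params(self) -> list[ChromatinParams]:
        table = {
            "interphase": ChromatinParams(
                self.interphase_E_pa, self.interphase_eta, "interphase"
            ),
            "mitotic": ChromatinParams(self.mitotic_E_pa, self.mitotic_eta, "mitotic"),
        }
        try:
            return [table[p] for p in self.phases]
        except KeyError as exc:
            raise ConfigurationError(f"unknown chromatin phase {exc}") from exc


def _default_eps_list() -> tuple[float, ...]:
    return tuple(np.round(np.arange(1, 8) * 0.025, 4))


class SweepConfig(_Model):
    """Top-level sweep: waveforms x frequencies x maximal strain amplitudes."""

    waveforms: tuple[Literal["sine", "brachial"], ...] = ("sine", "brachial")
    frequencies_hz: tuple[float, ...] = (0.1, 1.0)
    eps_max_list: tuple[float, ...] = Field(default_factory=_default_eps_list)
    waveform: WaveformConfig = WaveformConfig()
    geometry: GeometryConfig = GeometryConfig()
    mesh: MeshConfig = MeshConfig()
    materials: MaterialsConfig = MaterialsConfig()
    membrane: MembraneConfig = MembraneConfig()
    solver: SolverConfig = SolverConfig()
    loading: LoadingConfig = LoadingConfig()
    chromatin: ChromatinConfig = ChromatinConfig()
    output_dir: str = "cellstretch_out"
    log_level: str = "INFO"

    @field_validator("waveforms", "frequencies_hz", "eps_max_list")
    @classmethod
    def _nonempty(cls, v):
        if len(v) == 0:
            raise ValueError("list must be non-empty")
        return v

    @field_validator("frequencies_hz")
    @classmethod
    def _positive_freq(cls, v):
        if any(f <= 0 for f in v):
            raise ValueError("frequencies must be positive")
        return v

    @field_validator("eps_max_list")
    @classmethod
    def _eps_range(cls, v):
        if any(not (0 < e < 0.5) for e in v):
            raise ValueError("eps_max values must lie in (0, 0.5)")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(raw: str | dict | None) -> SweepConfig:
    """Parse and validate YAML/JSON config text (or a mapping) into a fully
    defaulted :class:`SweepConfig`; unknown keys are rejected with their path."""
    if raw is None or (isinstance(raw, str) and not raw.strip()):
        data = {}
    elif isinstance(raw, str):
        try:
            data = yaml.safe_load(raw) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"config is not valid YAML/JSON: {exc}") from exc
    else:
        data = raw
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    try:
        return SweepConfig.model_validate(data)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration ({paths})") from exc


_PROFILES = {
    "ci": {"mesh": {"h_max_um": 2.5, "growth_rate": 1.4, "h_refined_um": 1.0}},
    "fidelity": {"mesh": {"h_max_um": 0.99, "growth_rate": 1.4, "h_refined_um": 0.159}},
}


def apply_profile(cfg: SweepConfig, profile: str) -> SweepConfig:
    """Return a copy of ``cfg`` with the named profile's overrides applied."""
    if profile not in _PROFILES:
        raise ConfigurationError(
            f"unknown profile {profile!r}; choose from {sorted(_PROFILES)}"
        )
    data = cfg.model_dump(mode="json")
    for block, overrides in _PROFILES[profile].items():
        data[block].update(overrides)
    return SweepConfig.model_validate(data)
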