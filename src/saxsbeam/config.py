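"""Flat, typed run configuration shared by all CLI commands.

A run is fully described by one flat key-value document (YAML); every CLI
flag mirrors a config key and flags win over the file.  All physical values
carry their unit in the key name.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .forward_model import MediumProperties, QSettings
from .geometry import BeamGeometry, wavelength_from_energy

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration; the message names the field."""


@dataclass(frozen=True)
class RunConfig:
    # beam
    energy_kev: float | None = 60.0
    wavelength_nm: float | None = None
    L0_cm: float = 20.0
    q_center_nm_inv: float = 13.4
    n_q_samples: int = 2048
    span_factor: float = 1.5
    kernel_width_factor: float = 0.35
    # medium (reference grey/white matter + amyloid values)
    mu_cm_inv: float = 0.30
    rho_t_cm3: float = 5.5e5
    sigma_cm2: float = 5e-23
    # scan
    orientations: str = "row,column"
    stride: int = 1
    exclusion: str = "off"
    include_target_in_path: bool = True
    # io
    pixel_size_cm: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.energy_kev is None) == (self.wavelength_nm is None):
            raise ConfigError(
                "exactly one of energy_kev and wavelength_nm must be set"
            )
        for name in (
            "L0_cm",
            "q_center_nm_inv",
            "kernel_width_factor",
            "span_factor",
            "pixel_size_cm",
        ):
            value = getattr(self, name)
            if value is None or value <= 0:
                raise ConfigError(f"{name} must be a positive number, got {value}")
        for name in ("mu_cm_inv", "rho_t_cm3", "sigma_cm2"):
            value = getattr(self, name)
            if value is None or value < 0:
                raise ConfigError(
                    f"{name} must be a non-negative number, got {value}"
                )
        if self.energy_kev is not None and self.energy_kev <= 0:
            raise ConfigError(f"energy_kev must be positive, got {self.energy_kev}")
        if self.wavelength_nm is not None and self.wavelength_nm <= 0:
            raise ConfigError(
                f"wavelength_nm must be positive, got {self.wavelength_nm}"
            )
        if self.stride < 1:
            raise ConfigError(f"stride must be >= 1, got {self.stride}")
        if self.exclusion not in ("off", "drop"):
            raise ConfigError(
                f"exclusion must be 'off' or 'drop', got {self.exclusion!r}"
            )
        for orientation in self.orientation_list():
            if orientation not in ("row", "column"):
                raise ConfigError(f"unknown orientation {orientation!r} in orientations")

    # -- derived objects ----------------------------------------------------

    def wavelength(self) -> float:
        if self.wavelength_nm is not None:
            return self.wavelength_nm
        return wavelength_from_energy(self.energy_kev)

    def beam(self, incidence_angle: float = 0.0, impact_parameter: float = 0.0) -> BeamGeometry:
        return BeamGeometry(
            wavelength=self.wavelength(),
            L0=self.L0_cm,
            incidence_angle=incidence_angle,
            impact_parameter=impact_parameter,
        )

    def medium(self) -> MediumProperties:
        return MediumProperties(
            mu=self.mu_cm_inv, rho_t=self.rho_t_cm3, sigma=self.sigma_cm2
        )

    def qsettings(self) -> QSettings:
        return QSettings(
            q_center=self.q_center_nm_inv,
            n_samples=self.n_q_samples,
            span_factor=self.span_factor,
            kernel_width_factor=self.kernel_width_factor,
        )

    def orientation_list(self) -> list[str]:
        return [o.strip() for o in self.orientations.split(",") if o.strip()]


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    The file must be a flat mapping whose keys are RunConfig field names;
    unknown keys are an error.  ``overrides`` (CLI flags) win over the file.
    Setting ``wavelength_nm`` clears the default ``energy_kev`` and vice
    versa unless both are given explicitly.
    """
    known = {f.name for f in fields(RunConfig)}
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a flat key-value mapping")
        data.update(loaded)
    explicit = dict(data)
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
            explicit[key] = value
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    if "wavelength_nm" in explicit and "energy_kev" not in explicit:
        data["energy_kev"] = None
    if "energy_kev" in explicit and "wavelength_nm" not in explicit:
        data["wavelength_nm"] = None
    return RunConfig(**data)
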