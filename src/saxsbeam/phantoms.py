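"""Synthetic phantoms: labeled raster masks with known ground-truth
geometry, and analytic scene sweeps for the forward model.

The mask generator stands in for a manually segmented scout image: an
object outline (elliptical "head" or rectangular slab, the latter matching
the uniform-thickness PMMA slab phantoms used in benchtop scatter
experiments), one or more elliptical target lobes and optional excluded
(radiosensitive) zones, all rasterized by pixel-centre membership so labels
are unambiguous and reproducible.  Optional salt-and-pepper label noise on
the object/target boundary, behind a fixed seed, exercises the robustness
of pixel-counting path measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .forward_model import MediumProperties, SceneConfig
from .geometry import (
    BeamGeometry,
    EllipticalTarget,
    SphericalObject,
    SphericalTarget,
)
from .raster_paths import (
    LABEL_EXCLUDED,
    LABEL_OBJECT,
    LABEL_TARGET,
    LabeledMask,
)

__all__ = [
    "EllipseZone",
    "RectZone",
    "PhantomSpec",
    "make_embedded_disk_mask",
    "paper_sweep_configs",
    "default_medium",
    "default_beam",
    "SWEEP_NAMES",
]

#: Reference medium: differential cross-section per scatterer (cm^2),
#: amyloid number density in the target (cm^-3) and grey/white-matter
#: linear attenuation coefficient (cm^-1).
DEFAULT_SIGMA_CM2 = 5e-23
DEFAULT_RHO_T_CM3 = 5.5e5
DEFAULT_MU_CM_INV = 0.30

DEFAULT_ENERGY_KEV = 60.0
DEFAULT_L0_CM = 20.0


def default_medium() -> MediumProperties:
    return MediumProperties(
        mu=DEFAULT_MU_CM_INV, rho_t=DEFAULT_RHO_T_CM3, sigma=DEFAULT_SIGMA_CM2
    )


def default_beam(L0: float = DEFAULT_L0_CM, **kwargs) -> BeamGeometry:
    return BeamGeometry.from_energy(DEFAULT_ENERGY_KEV, L0, **kwargs)


@dataclass(frozen=True)
class EllipseZone:
    """Ellipse in physical cm coordinates (row axis down, column axis right).

    ``center`` is (row_cm, col_cm) from the top-left grid corner;
    ``semi_axes`` is (row semi-axis, column semi-axis); ``orientation``
    rotates the zone.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float = 0.0

    def contains(self, rows_cm: np.ndarray, cols_cm: np.ndarray) -> np.ndarray:
        dr = rows_cm - self.center[0]
        dc = cols_cm - self.center[1]
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        u = c * dr + s * dc
        v = -s * dr + c * dc
        ar, ac = self.semi_axes
        return (u / ar) ** 2 + (v / ac) ** 2 <= 1.0

    def bounds(self) -> tuple[float, float, float, float]:
        r = max(self.semi_axes)
        return (
            self.center[0] - r,
            self.center[0] + r,
            self.center[1] - r,
            self.center[1] + r,
        )


@dataclass(frozen=True)
class RectZone:
    """Axis-aligned rectangle in physical cm coordinates."""

    center: tuple[float, float]
    half_sizes: tuple[float, float]

    def contains(self, rows_cm: np.ndarray, cols_cm: np.ndarray) -> np.ndarray:
        dr = np.abs(rows_cm - self.center[0])
        dc = np.abs(cols_cm - self.center[1])
        return (dr <= self.half_sizes[0]) & (dc <= self.half_sizes[1])

    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.center[0] - self.half_sizes[0],
            self.center[0] + self.half_sizes[0],
            self.center[1] - self.half_sizes[1],
            self.center[1] + self.half_sizes[1],
        )


Zone = Union[EllipseZone, RectZone]


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of a synthetic mask.

    ``grid`` is (n_rows, n_cols); ``pixel_size`` in cm.  ``head`` is the
    object outline; ``lobes`` are target zones; ``excluded_zones`` mark
    radiosensitive structures.  ``boundary_noise`` flips that fraction of
    object/target boundary pixels (salt-and-pepper), seeded for
    reproducibility; default off.
    """

    grid: tuple[int, int]
    pixel_size: float
    head: Zone
    lobes: tuple[Zone, ...] = ()
    excluded_zones: tuple[Zone, ...] = ()
    boundary_noise: float = 0.0
    seed: int = 0
    name: str = "phantom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "lobes", tuple(self.lobes))
        object.__setattr__(self, "excluded_zones", tuple(self.excluded_zones))
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if not 0 <= self.boundary_noise <= 1:
            raise ValueError("boundary_noise must lie in [0, 1]")
        extent = (self.grid[0] * self.pixel_size, self.grid[1] * self.pixel_size)
        for zone in (self.head, *self.lobes, *self.excluded_zones):
            r0, r1, c0, c1 = zone.bounds()
            if r0 < 0 or c0 < 0 or r1 > extent[0] or c1 > extent[1]:
                raise ValueError(
                    f"zone {zone} extends outside the {extent[0]} x {extent[1]} cm grid"
                )


def make_embedded_disk_mask(spec: PhantomSpec) -> LabeledMask:
    """Rasterize a phantom spec into a labeled mask.

    Membership is tested at pixel centres (no anti-aliasing); identical
    specs always produce identical masks.  Lobes and excluded zones must
    fall inside the head.
    """
    n_rows, n_cols = spec.grid
    p = spec.pixel_size
    rows_cm = (np.arange(n_rows)[:, None] + 0.5) * p
    cols_cm = (np.arange(n_cols)[None, :] + 0.5) * p
    rows_cm, cols_cm = np.broadcast_arrays(rows_cm, cols_cm)

    head = spec.head.contains(rows_cm, cols_cm)
    labels = np.where(head, LABEL_OBJECT, 0).astype(np.int64)
    for lobe in spec.lobes:
        inside = lobe.contains(rows_cm, cols_cm)
        if np.any(inside & ~head):
            raise ValueError(f"target lobe {lobe} is not fully inside the head")
        labels[inside] = LABEL_TARGET
    for zone in spec.excluded_zones:
        inside = zone.contains(rows_cm, cols_cm)
        if np.any(inside & ~head):
            raise ValueError(f"excluded zone {zone} is not fully inside the head")
        labels[inside] = LABEL_EXCLUDED

    if spec.boundary_noise > 0:
        labels = _flip_boundary(labels, spec.boundary_noise, spec.seed)

    return LabeledMask(labels=labels, pixel_size=p, name=spec.name)


def _flip_boundary(labels: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Flip a fraction of object<->target boundary pixels (4-neighbourhood)."""
    out = labels.copy()
    is_t = labels == LABEL_TARGET
    is_o = labels == LABEL_OBJECT
    neighbor_t = np.zeros_like(is_t)
    neighbor_o = np.zeros_like(is_o)
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neighbor_t |= np.roll(is_t, shift, axis=(0, 1))
        neighbor_o |= np.roll(is_o, shift, axis=(0, 1))
    boundary = (is_t & neighbor_o) | (is_o & neighbor_t)
    idx = np.argwhere(boundary)
    rng = np.random.default_rng(seed)
    n_flip = int(round(fraction * len(idx)))
    if n_flip:
        chosen = idx[rng.choice(len(idx), size=n_flip, replace=False)]
        r, c = chosen[:, 0], chosen[:, 1]
        out[r, c] = np.where(
            labels[r, c] == LABEL_TARGET, LABEL_OBJECT, LABEL_TARGET
        )
    return out


# ---------------------------------------------------------------------------
# analytic scene sweeps

SWEEP_NAMES = ("fig1", "fig2", "fig3", "fig4", "fig6", "fig8")


def paper_sweep_configs(name: str) -> list[SceneConfig]:
    """Analytic scene sweeps over object size, target location, incidence
    angle, target shape and target size.

    * ``fig1`` — object radius R_o from 4 to 10 cm, centred spherical target
      r_t = 2 cm, L0 = 20 cm: attenuation vs object size.
    * ``fig2`` — target placed at mean detector distances L0 = 18..22 cm in
      an R_o = 10 cm object: smearing vs target location.
    * ``fig3`` — chords subtending pi, 3pi/4, pi/2 and pi/3 through an
      R_o = 10 cm object (r_t = 2 cm, L0 = 20 cm): incidence angle changes
      the path length.
    * ``fig4`` — elliptical target a = 1, b = 3 cm centred in an R_o = 10 cm
      object, incidence angles 0..pi/2: shape changes the effective radius.
    * ``fig6`` — the reference single scene (r_t = 0.5 cm, L0 = 20 cm) whose
      medium values anchor the intensity scale.
    * ``fig8`` — bare spherical target, r_t from 0.5 to 3 cm, L0 = 20 cm:
      target size trades peak height against smearing.
    """
    medium = default_medium()
    if name == "fig1":
        return [
            SceneConfig(
                medium=medium,
                beam=default_beam(),
                target=SphericalTarget(2.0),
                obj=SphericalObject(float(R_o)),
                label=f"R_o={R_o}",
            )
            for R_o in range(4, 11)
        ]
    if name == "fig2":
        return [
            SceneConfig(
                medium=medium,
                beam=default_beam(L0=float(L0)),
                target=SphericalTarget(2.0, center_offset=float(20 - L0)),
                obj=SphericalObject(10.0),
                label=f"L0={L0}",
            )
            for L0 in range(18, 23)
        ]
    if name == "fig3":
        return [
            SceneConfig(
                medium=medium,
                beam=default_beam(),
                target=SphericalTarget(2.0),
                obj=SphericalObject(10.0),
                subtended_angle=C,
                label=f"C={C:.4f}",
            )
            for C in (math.pi, 3 * math.pi / 4, math.pi / 2, math.pi / 3)
        ]
    if name == "fig4":
        return [
            SceneConfig(
                medium=medium,
                beam=default_beam(incidence_angle=phi),
                target=EllipticalTarget(a=1.0, b=3.0),
                obj=SphericalObject(10.0),
                label=f"phi={phi:.4f}",
            )
            for phi in (0.0, math.pi / 8, math.pi / 4, 3 * math.pi / 8, math.pi / 2)
        ]
    if name == "fig6":
        return [
            SceneConfig(
                medium=medium,
                beam=default_beam(),
                target=SphericalTarget(0.5),
                label="reference",
            )
        ]
    if name == "fig8":
        return [
            SceneConfig(
                medium=medium,
                beam=default_beam(),
                target=SphericalTarget(r_t),
                label=f"r_t={r_t}",
            )
            for r_t in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
        ]
    raise ValueError(f"unknown sweep {name!r}; choose from {SWEEP_NAMES}")
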