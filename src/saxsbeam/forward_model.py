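"""Forward model of the background-subtracted scattering profile.

The relative scattered intensity of a pencil beam through an attenuating
object containing a target of scatterers is

    I / I0 = sigma * exp(-mu * l) * integral rho_t(x) dx ,

with ``sigma`` the differential scattering cross-section (cm^2), ``mu`` the
linear attenuation coefficient shared by object and target (cm^-1), ``l``
the total straight-through path length of the beam through the object (cm)
and ``rho_t`` the volumetric number density of scatterers (cm^-3) along the
beam inside the target.  Because the scattering angle is small, the scatter
event location barely changes the total path, so a single exponential with
the undeflected chord is used for attenuation.

On an ideal photon-counting detector the profile of an extended target is a
near-rectangular step in q: each slice of the target sits at a different
distance from the detector and is therefore recorded at a slightly
different apparent q.  Detector signal degradation is modeled by convolving
that step with a unit-area triangular kernel whose base width is a fixed
fraction (default 0.35) of the geometric q spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TextIO, Union

import numpy as np

from .geometry import (
    BeamGeometry,
    EllipticalTarget,
    SphericalTarget,
    chord_length_impact,
    half_angle_from_q,
    relative_q_spread,
)

__all__ = [
    "MediumProperties",
    "DensityProfile",
    "ScatteringProfile",
    "TriangularKernel",
    "QSettings",
    "SceneConfig",
    "relative_intensity",
    "build_step_profile",
    "make_triangular_kernel",
    "smear_profile",
    "default_q_grid",
    "simulate_scene",
    "write_profile",
    "read_profile",
]

#: Minimum number of kernel samples across the triangle base.
_MIN_KERNEL_SAMPLES = 9

TargetLike = Union[SphericalTarget, EllipticalTarget, float]


@dataclass(frozen=True)
class MediumProperties:
    """Physical properties of the object/target medium.

    mu : linear attenuation coefficient, cm^-1 (grey/white matter ~0.30 at
        diagnostic energies); shared by object and target.
    rho_t : volumetric number density of scatterers inside the target, cm^-3.
    sigma : differential scattering cross-section per scatterer, cm^2.
    """

    mu: float
    rho_t: float
    sigma: float

    def __post_init__(self) -> None:
        for name in ("mu", "rho_t", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(
                    f"{name} must be non-negative, got {getattr(self, name)}"
                )


@dataclass(frozen=True)
class DensityProfile:
    """Scatterer density sampled along the beam inside the target.

    ``positions`` are cm offsets from the target centre along the beam
    (strictly increasing); ``densities`` are rho_t(x) >= 0 in cm^-3.
    A non-uniform amyloid distribution is modeled by varying the samples.
    """

    positions: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        den = np.asarray(self.densities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "densities", den)
        if pos.ndim != 1 or pos.shape != den.shape:
            raise ValueError("positions and densities must be matching 1-D arrays")
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(den < 0):
            raise ValueError("densities must be non-negative")

    @classmethod
    def uniform(cls, rho_t: float, r_t: float, n: int = 129) -> "DensityProfile":
        """Uniform density ``rho_t`` across a target of radius ``r_t``."""
        x = np.linspace(-r_t, r_t, n)
        return cls(x, np.full(n, rho_t, dtype=float))

    @property
    def half_extent(self) -> float:
        return float(max(abs(self.positions[0]), abs(self.positions[-1])))

    def line_integral(self) -> float:
        """Trapezoidal integral of rho_t(x) dx, cm^-2."""
        return float(np.trapezoid(self.densities, self.positions))


@dataclass(frozen=True)
class ScatteringProfile:
    """Relative intensity I/I0 per unit q, sampled on an increasing q grid."""

    q_grid: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q_grid, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q_grid", q)
        object.__setattr__(self, "intensity", i)
        if q.ndim != 1 or q.shape != i.shape or q.size < 2:
            raise ValueError("q_grid and intensity must be matching 1-D arrays")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q_grid must be strictly increasing")
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(i))):
            raise ValueError("profile contains non-finite values")
        if np.any(i < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def q_step(self) -> float:
        return float(self.q_grid[1] - self.q_grid[0])

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        steps = np.diff(self.q_grid)
        return bool(np.allclose(steps, steps[0], rtol=rtol))

    def area(self) -> float:
        """Trapezoidal area under the profile (the total relative intensity)."""
        return float(np.trapezoid(self.intensity, self.q_grid))


@dataclass(frozen=True)
class TriangularKernel:
    """Unit-area symmetric triangular smearing kernel on a uniform q step."""

    base_width: float
    q_step: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if np.any(s < 0):
            raise ValueError("kernel samples must be non-negative")
        if not np.allclose(s, s[::-1]):
            raise ValueError("kernel must be symmetric")
        area = float(s.sum() * self.q_step)
        if abs(area - 1.0) > 1e-9:
            raise ValueError(f"kernel area must be 1, got {area}")

    @property
    def half_samples(self) -> int:
        return (len(self.samples) - 1) // 2


def relative_intensity(
    medium: MediumProperties,
    density: DensityProfile,
    path_length: float,
) -> float:
    """Total relative scattered intensity I/I0 of one beam.

    ``sigma * exp(-mu*l) * integral rho_t(x) dx`` with the density integral
    evaluated by trapezoidal quadrature over the density profile.  For a
    uniform density this reduces to ``sigma * rho_t * 2 r_t * exp(-mu*l)``.
    """
    if path_length < 0:
        raise ValueError(f"path_length must be non-negative, got {path_length}")
    extent = density.positions[-1] - density.positions[0]
    if path_length < extent - 1e-12:
        raise ValueError(
            f"path_length {path_length} shorter than the target extent {extent}"
        )
    return medium.sigma * math.exp(-medium.mu * path_length) * density.line_integral()


def default_q_grid(
    q_center: float,
    q_spread: float,
    n_samples: int = 2048,
    span_factor: float = 1.5,
) -> np.ndarray:
    """Uniform q grid spanning ``q_center +- span_factor * q_spread``."""
    if q_spread <= 0:
        raise ValueError(f"q_spread must be positive, got {q_spread}")
    if n_samples < 16:
        raise ValueError(f"n_samples too small: {n_samples}")
    half = span_factor * q_spread
    lo = max(q_center - half, 0.0)
    return np.linspace(lo, q_center + half, n_samples)


def _resolve_target(
    target: TargetLike, beam: BeamGeometry
) -> float:
    if isinstance(target, SphericalTarget):
        return target.effective_radius(beam.incidence_angle)
    if isinstance(target, EllipticalTarget):
        return target.effective_radius(beam.incidence_angle)
    r = float(target)
    if r < 0:
        raise ValueError(f"effective target radius must be non-negative, got {r}")
    return r


def build_step_profile(
    medium: MediumProperties,
    target: TargetLike,
    beam: BeamGeometry,
    q_center: float,
    q_grid: np.ndarray,
    *,
    density: DensityProfile | None = None,
    path_length: float | None = None,
    n_slices: int | None = None,
) -> ScatteringProfile:
    """Unsmeared (ideal-detector) scattering profile of one beam.

    The target is cut into thin slices along the beam.  A slice at signed
    offset ``x`` from the target centre (positive toward the detector) sits
    at distance ``L0 - x`` from the detector and is recorded at the apparent
    q of that distance, so the slice intensities spread into a
    near-rectangular step around ``q_center``.  Slice contributions are
    finally rescaled so the area under the profile equals the total
    relative intensity of the beam, making the profile consistent with the
    attenuated line-integral model at any grid resolution.

    ``target`` may be a :class:`SphericalTarget`, an
    :class:`EllipticalTarget` (resolved at the beam incidence angle) or a
    plain effective radius in cm (e.g. measured from a segmented mask).
    ``path_length`` is the attenuation path through the object; if omitted
    it defaults to the target diameter (a bare, unembedded target).
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.ndim != 1 or q_grid.size < 16:
        raise ValueError("q_grid must be a 1-D array with at least 16 samples")
    steps = np.diff(q_grid)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
        raise ValueError("q_grid must be strictly increasing and uniform")

    r_eff = _resolve_target(target, beam)
    if density is None:
        if r_eff == 0:
            # no target extent: nothing scatters on this path
            return ScatteringProfile(q_grid, np.zeros_like(q_grid))
        density = DensityProfile.uniform(medium.rho_t, r_eff)
    else:
        r_eff = max(r_eff, density.half_extent)

    if path_length is None:
        path_length = 2.0 * r_eff
    total = relative_intensity(medium, density, path_length)

    dq = float(steps[0])
    intensity = np.zeros_like(q_grid)
    if total == 0.0:
        return ScatteringProfile(q_grid, intensity)

    if n_slices is None:
        n_slices = max(4 * q_grid.size, 1024)

    x0, x1 = float(density.positions[0]), float(density.positions[-1])
    edges = np.linspace(x0, x1, n_slices + 1)
    x = 0.5 * (edges[:-1] + edges[1:])
    dx = edges[1] - edges[0]
    rho = np.interp(x, density.positions, density.densities)
    weights = rho * dx

    # slice at offset x (toward the detector) is L0 - x from the detector
    L_event = beam.L0 - x
    theta = half_angle_from_q(q_center, beam.wavelength)
    ring = L_event * math.tan(2.0 * theta)
    q_app = (4.0 * math.pi / beam.wavelength) * np.sin(0.5 * np.arctan2(ring, beam.L0))

    if q_app.min() < q_grid[0] or q_app.max() > q_grid[-1]:
        raise ValueError(
            f"q_grid [{q_grid[0]:.6g}, {q_grid[-1]:.6g}] does not contain the "
            f"profile support [{q_app.min():.6g}, {q_app.max():.6g}]"
        )

    # linear (cloud-in-cell) deposition conserves the deposited weight
    pos = (q_app - q_grid[0]) / dq
    left = np.clip(np.floor(pos).astype(int), 0, q_grid.size - 2)
    frac = pos - left
    np.add.at(intensity, left, weights * (1.0 - frac))
    np.add.at(intensity, left + 1, weights * frac)
    intensity /= dq

    raw_area = float(np.trapezoid(intensity, q_grid))
    intensity *= total / raw_area
    return ScatteringProfile(q_grid, intensity)


def make_triangular_kernel(
    q_spread: float, q_step: float, width_factor: float = 0.35
) -> TriangularKernel:
    """Unit-area triangular kernel with base width ``width_factor * q_spread``.

    ``q_spread`` is the geometric spread of q of the unsmeared step
    (``q_center * dq/q``); the kernel emulates detector signal degradation.
    Requires at least ~9 samples across the base for a faithful shape.
    """
    if q_spread <= 0:
        raise ValueError(f"q_spread must be positive, got {q_spread}")
    if q_step <= 0:
        raise ValueError(f"q_step must be positive, got {q_step}")
    base = width_factor * q_spread
    if q_step >= base / (_MIN_KERNEL_SAMPLES - 1) * 2:
        raise ValueError(
            f"q_step {q_step:.6g} too coarse for kernel base {base:.6g}: "
            f"need at least {_MIN_KERNEL_SAMPLES} samples across the base"
        )
    half = base / 2.0
    m = int(math.ceil(half / q_step))
    offsets = np.arange(-m, m + 1) * q_step
    samples = np.maximum(1.0 - np.abs(offsets) / half, 0.0)
    samples /= samples.sum() * q_step
    return TriangularKernel(base_width=base, q_step=q_step, samples=samples)


def smear_profile(
    profile: ScatteringProfile, kernel: TriangularKernel
) -> ScatteringProfile:
    """Convolve the profile with the detector kernel.

    The output grid is extended by the kernel half-width on each side so no
    intensity is clipped; the unit-area kernel conserves the total area.
    """
    if not profile.is_uniform():
        raise ValueError("smearing requires a uniform q grid")
    dq = profile.q_step
    if not math.isclose(dq, kernel.q_step, rel_tol=1e-9):
        raise ValueError(
            f"kernel q_step {kernel.q_step:.6g} does not match profile "
            f"q_step {dq:.6g}"
        )
    m = kernel.half_samples
    smeared = np.convolve(profile.intensity, kernel.samples, mode="full") * dq
    n = profile.q_grid.size
    q_out = profile.q_grid[0] + np.arange(-m, n + m) * dq
    smeared = np.maximum(smeared, 0.0)  # clip convolution round-off
    return ScatteringProfile(q_out, smeared)


# ---------------------------------------------------------------------------
# scene-level convenience


@dataclass(frozen=True)
class QSettings:
    """Scattering-vector grid and kernel settings.

    ``q_center`` is the central q of the target's diffraction feature in
    nm^-1 (default 13.4, the cross-beta sheet spacing of ~4.7 Angstrom
    characteristic of amyloid fibrils).
    """

    q_center: float = 13.4
    n_samples: int = 2048
    span_factor: float = 1.5
    kernel_width_factor: float = 0.35

    def __post_init__(self) -> None:
        if self.q_center <= 0:
            raise ValueError(f"q_center must be positive, got {self.q_center}")


@dataclass(frozen=True)
class SceneConfig:
    """One analytic scene: medium + beam + target, optionally embedded in a
    spherical object.  ``label`` is free text for reports."""

    medium: MediumProperties
    beam: BeamGeometry
    target: TargetLike
    obj: SphericalObject | None = None
    subtended_angle: float | None = None  # overrides impact parameter chord
    label: str = ""

    def path_length(self) -> float:
        """Attenuation path: chord through the object, or the bare-target
        diameter when no object is modeled."""
        if self.obj is None:
            return 2.0 * _resolve_target(self.target, self.beam)
        if self.subtended_angle is not None:
            from .geometry import chord_length_subtended

            return chord_length_subtended(self.obj.R_o, self.subtended_angle)
        return chord_length_impact(self.obj.R_o, self.beam.impact_parameter)


def simulate_scene(
    scene: SceneConfig,
    qset: QSettings = QSettings(),
    *,
    smear: bool = True,
    density: DensityProfile | None = None,
) -> ScatteringProfile:
    """Forward-model one scene: build the step profile and smear it."""
    beam = scene.beam
    r_eff = _resolve_target(scene.target, beam)
    theta = half_angle_from_q(qset.q_center, beam.wavelength)
    spread = qset.q_center * relative_q_spread(theta, beam.L0, r_eff)
    q_grid = default_q_grid(
        qset.q_center, spread, qset.n_samples, qset.span_factor
    )
    profile = build_step_profile(
        scene.medium,
        scene.target,
        beam,
        qset.q_center,
        q_grid,
        density=density,
        path_length=scene.path_length(),
    )
    if not smear:
        return profile
    kernel = make_triangular_kernel(
        spread, profile.q_step, qset.kernel_width_factor
    )
    return smear_profile(profile, kernel)


# ---------------------------------------------------------------------------
# text I/O


def write_profile(
    profile: ScatteringProfile,
    sink: str | TextIO,
    header: dict | None = None,
) -> None:
    """Write a profile as two-column TSV (q_nm_inv, relative_intensity).

    ``header`` key/value pairs are recorded as ``# key = value`` comment
    lines; numbers use 9 significant digits so identical runs produce
    byte-identical files.
    """
    own = isinstance(sink, str)
    fh = open(sink, "w") if own else sink
    try:
        for key, value in (header or {}).items():
            fh.write(f"# {key} = {value}\n")
        fh.write("q_nm_inv\trelative_intensity\n")
        for q, i in zip(profile.q_grid, profile.intensity):
            fh.write(f"{q:.9e}\t{i:.9e}\n")
    finally:
        if own:
            fh.close()


def read_profile(source: str | TextIO) -> ScatteringProfile:
    """Read a profile written by :func:`write_profile`."""
    own = isinstance(source, str)
    fh = open(source) if own else source
    try:
        rows = []
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("q_nm_inv"):
                continue
            q_s, i_s = line.split("\t")
            rows.append((float(q_s), float(i_s)))
    finally:
        if own:
            fh.close()
    if not rows:
        raise ValueError("no profile samples found")
    arr = np.array(rows)
    return ScatteringProfile(arr[:, 0], arr[:, 1])
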