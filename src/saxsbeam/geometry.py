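"""Closed-form scattering and path-length geometry.

All geometric lengths are in centimetres, wavelengths in nanometres and
scattering vectors in inverse nanometres.  Angles are radians.  Throughout
the package ``theta`` names the *half* scattering angle: the beam is
deflected by ``2*theta`` at a scatter event.

The central quantities are

* the scattering-vector magnitude ``q = 4 pi sin(theta) / lambda``,
* the relative smearing ``dq/q`` of an extended target, caused by the
  uncertainty in the scatter event's distance to the detector,
* chord lengths of pencil beams through a spherical object, which set the
  Beer-Lambert attenuation path, and
* the "apparent" q recorded by a detector that assumes every event
  happened at the mean target-to-detector distance ``L0``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "BeamGeometry",
    "SphericalObject",
    "SphericalTarget",
    "EllipticalTarget",
    "wavelength_from_energy",
    "half_angle_from_q",
    "scattering_vector",
    "relative_q_spread",
    "chord_length_subtended",
    "chord_length_impact",
    "ellipse_radius",
    "scatter_event_path_length",
    "apparent_q",
]

#: hc in keV * nm; lambda[nm] = HC_KEV_NM / E[keV]
HC_KEV_NM = 1.23984193


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in nm for a beam energy in keV."""
    if energy_kev <= 0:
        raise ValueError(f"beam energy must be positive, got {energy_kev}")
    return HC_KEV_NM / energy_kev


@dataclass(frozen=True)
class BeamGeometry:
    """One candidate pencil-beam path.

    Parameters
    ----------
    wavelength : float
        Photon wavelength in nm (monoenergetic beam).
    L0 : float
        Mean target-to-detector distance in cm.
    incidence_angle : float
        Beam incidence angle ``phi`` in radians, measured as in the polar
        form of an ellipse (0 along the minor axis of an elliptical target).
    impact_parameter : float
        Perpendicular offset of the beam line from the object centre, cm.
    """

    wavelength: float
    L0: float
    incidence_angle: float = 0.0
    impact_parameter: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")
        if self.L0 <= 0:
            raise ValueError(f"L0 must be positive, got {self.L0}")
        if self.impact_parameter < 0:
            raise ValueError(
                f"impact_parameter must be non-negative, got {self.impact_parameter}"
            )

    @classmethod
    def from_energy(
        cls,
        energy_kev: float,
        L0: float,
        incidence_angle: float = 0.0,
        impact_parameter: float = 0.0,
    ) -> "BeamGeometry":
        return cls(
            wavelength=wavelength_from_energy(energy_kev),
            L0=L0,
            incidence_angle=incidence_angle,
            impact_parameter=impact_parameter,
        )


@dataclass(frozen=True)
class SphericalObject:
    """Attenuating spherical object (e.g. the head) of radius ``R_o`` cm."""

    R_o: float

    def __post_init__(self) -> None:
        if self.R_o <= 0:
            raise ValueError(f"object radius must be positive, got {self.R_o}")


@dataclass(frozen=True)
class SphericalTarget:
    """Spherical scattering target of radius ``r_t`` cm.

    ``center_offset`` is the signed distance of the target centre from the
    object centre along the beam axis (positive toward the detector).
    """

    r_t: float
    center_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.r_t <= 0:
            raise ValueError(f"target radius must be positive, got {self.r_t}")

    def check_embedded(self, obj: SphericalObject) -> None:
        if abs(self.center_offset) + self.r_t > obj.R_o:
            raise ValueError(
                f"target (r_t={self.r_t}, offset={self.center_offset}) "
                f"does not fit inside object of radius {obj.R_o}"
            )

    def effective_radius(self, incidence_angle: float = 0.0) -> float:
        """Radius seen by the beam; independent of angle for a sphere."""
        return self.r_t


@dataclass(frozen=True)
class EllipticalTarget:
    """Elliptical target with minor semi-axis ``a`` and major semi-axis ``b`` (cm).

    ``orientation`` rotates the ellipse; the effective radius seen by a beam
    incident at angle ``phi`` is ``ellipse_radius(a, b, phi - orientation)``.
    """

    a: float
    b: float
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.a <= self.b:
            raise ValueError(f"require 0 < a <= b, got a={self.a}, b={self.b}")

    def effective_radius(self, incidence_angle: float = 0.0) -> float:
        return ellipse_radius(self.a, self.b, incidence_angle - self.orientation)


def scattering_vector(theta_half: float, wavelength: float) -> float:
    """Scattering-vector magnitude ``q = 4 pi sin(theta) / lambda`` in nm^-1.

    ``theta_half`` is half the scattering angle (the beam deflects by
    ``2*theta_half``); ``wavelength`` is in nm.
    """
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    if not 0 <= theta_half < math.pi / 2:
        raise ValueError(f"theta_half must lie in [0, pi/2), got {theta_half}")
    return 4.0 * math.pi * math.sin(theta_half) / wavelength


def half_angle_from_q(q: float, wavelength: float) -> float:
    """Inverse of :func:`scattering_vector`: half scattering angle for ``q``."""
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    s = q * wavelength / (4.0 * math.pi)
    if not 0 <= s < 1:
        raise ValueError(f"q={q} out of range for wavelength {wavelength}")
    return math.asin(s)


def relative_q_spread(theta_half: float, L0: float, r_t: float) -> float:
    """Relative spread ``dq/q`` of the scattering vector for a target of
    radius ``r_t`` centred at mean detector distance ``L0``.

    A scatter event at the far edge of the target is ``L0 + r_t`` from the
    detector; rays from there land on a different detector ring than rays
    from the mean distance, spreading the recorded q values.  The geometric
    closed form is::

        dq/q = 2 - 2 / ( sin(theta) * sqrt( ((L0 + r_t)/(L0 tan(theta)))^2 + 1 ) )

    which reduces to ``2 r_t / (L0 + r_t)`` at small angles and vanishes for
    a point target.
    """
    if L0 <= 0:
        raise ValueError(f"L0 must be positive, got {L0}")
    if r_t < 0:
        raise ValueError(f"r_t must be non-negative, got {r_t}")
    if not 0 < theta_half < math.pi / 2:
        raise ValueError(
            f"theta_half must lie in (0, pi/2), got {theta_half}"
        )
    if r_t == 0:
        return 0.0  # the expression collapses to 2 - 2 identically
    ratio = (L0 + r_t) / (L0 * math.tan(theta_half))
    return 2.0 - 2.0 / (math.sin(theta_half) * math.sqrt(ratio * ratio + 1.0))


def chord_length_subtended(R_o: float, C: float) -> float:
    """Chord length ``d = 2 R_o sin(C/2)`` for central angle ``C`` in [0, 2pi]."""
    if R_o <= 0:
        raise ValueError(f"R_o must be positive, got {R_o}")
    if not 0 <= C <= 2 * math.pi:
        raise ValueError(f"subtended angle must lie in [0, 2pi], got {C}")
    return 2.0 * R_o * math.sin(C / 2.0)


def chord_length_impact(R_o: float, impact_parameter: float) -> float:
    """Chord length of a beam with perpendicular offset ``impact_parameter``
    from the centre of a sphere of radius ``R_o``.

    Equivalent to :func:`chord_length_subtended` with
    ``C = 2 arccos(b / R_o)``.  A beam with ``b > R_o`` misses the object:
    the function returns 0 and emits a warning.
    """
    if R_o <= 0:
        raise ValueError(f"R_o must be positive, got {R_o}")
    if impact_parameter < 0:
        raise ValueError(
            f"impact_parameter must be non-negative, got {impact_parameter}"
        )
    if impact_parameter > R_o:
        warnings.warn(
            f"beam misses object: impact parameter {impact_parameter} exceeds "
            f"object radius {R_o}",
            stacklevel=2,
        )
        return 0.0
    return 2.0 * math.sqrt(R_o * R_o - impact_parameter * impact_parameter)


def ellipse_radius(a: float, b: float, phi: float) -> float:
    """Polar radius of an ellipse at angle ``phi`` from the minor axis.

    ``r_e^2 = (a b)^2 / (b^2 cos^2(phi) + a^2 sin^2(phi))`` with minor
    semi-axis ``a`` and major semi-axis ``b``; pi-periodic in ``phi``.
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"semi-axes must be positive, got a={a}, b={b}")
    c, s = math.cos(phi), math.sin(phi)
    return (a * b) / math.sqrt(b * b * c * c + a * a * s * s)


def scatter_event_path_length(
    entry_depth: float,
    two_theta: float,
    obj: SphericalObject,
    impact_parameter: float = 0.0,
) -> float:
    """Total in-object path of a ray scattered once at ``entry_depth`` along
    its chord, deflected by ``two_theta``.

    The incoming segment is the straight distance from the entry point to the
    scatter point; the outgoing segment is the distance from the scatter
    point to the object boundary along the deflected direction (the law-of-
    sines solution of the scatter-point / centre / exit-point triangle).
    At small ``two_theta`` the total converges to the undeflected chord,
    which is why Beer-Lambert attenuation can use the straight-through path.
    """
    b = impact_parameter
    R = obj.R_o
    if b > R:
        raise ValueError(f"impact parameter {b} exceeds object radius {R}")
    chord = chord_length_impact(R, b)
    if not 0 <= entry_depth <= chord:
        raise ValueError(
            f"scatter point outside object: entry_depth={entry_depth} "
            f"not in [0, {chord}]"
        )
    # beam travels along +x at y = b; entry at x = -sqrt(R^2 - b^2)
    x = -math.sqrt(R * R - b * b) + entry_depth
    y = b
    ux, uy = math.cos(two_theta), math.sin(two_theta)
    # exit segment s solves |P + s u| = R for the deflected unit direction u
    pu = x * ux + y * uy
    disc = pu * pu - (x * x + y * y) + R * R
    s = -pu + math.sqrt(max(disc, 0.0))
    return entry_depth + s


def apparent_q(
    L_event: float, q_true: float, L0: float, wavelength: float
) -> float:
    """q recorded by a detector that assumes the scatter event happened at
    the mean distance ``L0`` when it actually happened at ``L_event``.

    The event paints a ring of radius ``R = L_event tan(2 theta)`` on the
    detector; read back with the assumed distance this ring corresponds to a
    half-angle ``theta' = arctan(R / L0) / 2`` and hence an apparent
    ``q' = 4 pi sin(theta') / lambda``.  Events closer to the detector than
    ``L0`` appear at smaller q; ``L_event = L0`` is the identity.
    """
    if L_event <= 0 or L0 <= 0:
        raise ValueError(
            f"distances must be positive, got L_event={L_event}, L0={L0}"
        )
    theta = half_angle_from_q(q_true, wavelength)
    ring = L_event * math.tan(2.0 * theta)
    theta_apparent = 0.5 * math.atan2(ring, L0)
    return scattering_vector(theta_apparent, wavelength)
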