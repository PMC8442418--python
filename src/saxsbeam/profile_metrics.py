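"""Scattering-profile summaries consumed by the figure of merit.

Three numbers characterize how distinguishable a profile is: the peak
relative intensity ``I_p``, the total relative intensity ``I_t`` (area
under the curve, in nm^-1 times relative units) and the spread ``delta_q``
reported as the half-width at half-maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import ScatteringProfile

__all__ = ["ProfileSummary", "peak_intensity", "total_intensity", "hwhm_spread", "summarize"]


@dataclass(frozen=True)
class ProfileSummary:
    I_p: float
    I_t: float
    delta_q: float


def peak_intensity(profile: ScatteringProfile) -> float:
    """Maximum intensity sample of the profile."""
    if profile.intensity.size == 0:
        raise ValueError("empty profile")
    return float(profile.intensity.max())


def total_intensity(profile: ScatteringProfile) -> float:
    """Area under the profile (trapezoidal), units nm^-1 x relative units."""
    if profile.intensity.size == 0:
        raise ValueError("empty profile")
    if not profile.is_uniform():
        raise ValueError("total intensity requires a uniform q grid")
    return profile.area()


def hwhm_spread(profile: ScatteringProfile) -> float:
    """Half-width at half-maximum of the profile.

    Defined as half of the q distance between the *outermost* crossings of
    ``I_p / 2``, with linear interpolation between grid samples.  Using the
    outermost crossings makes the measure deterministic on the flat-topped
    trapezoids produced by smearing a step, and recovers ``w/2`` exactly in
    the ideal-rectangle limit.
    """
    y = profile.intensity
    q = profile.q_grid
    if y.size == 0:
        raise ValueError("empty profile")
    peak = float(y.max())
    if peak <= 0:
        raise ValueError("profile has no positive intensity")
    half = peak / 2.0
    above = y >= half
    if above[0] or above[-1]:
        raise ValueError(
            "profile does not fall below half-maximum at the grid edges; "
            "widen the q grid"
        )
    idx = np.nonzero(above)[0]
    i0, i1 = int(idx[0]), int(idx[-1])
    # interpolate the outermost upward and downward crossings
    q_left = np.interp(half, [y[i0 - 1], y[i0]], [q[i0 - 1], q[i0]])
    q_right = np.interp(half, [y[i1 + 1], y[i1]], [q[i1 + 1], q[i1]])
    return float(q_right - q_left) / 2.0


def summarize(profile: ScatteringProfile) -> ProfileSummary:
    """All three summaries of one profile."""
    return ProfileSummary(
        I_p=peak_intensity(profile),
        I_t=total_intensity(profile),
        delta_q=hwhm_spread(profile),
    )
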