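"""Figure-of-merit scoring and ranking of candidate beam orientations.

A beam path is effective when its scattering peak is easy to distinguish
(high peak intensity ``I_p``, high total intensity ``I_t``, little smearing
``delta_q``) and delivers little dose (short attenuation path ``l``, dose
being taken proportional to path length through tissue):

    Omega = I_p * I_t / (l * delta_q)

Paths are ranked by Omega; the normalized score ``Omega / Omega_max`` is
computed over the surviving candidates of one scan.  Radiosensitive
structures (cornea, optic lens, oral cavity) are carried as an "excluded"
mask label: by default intersecting paths are only reported, with an
optional policy that removes them from the ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .forward_model import (
    MediumProperties,
    QSettings,
    ScatteringProfile,
    build_step_profile,
    default_q_grid,
    make_triangular_kernel,
    smear_profile,
)
from .geometry import BeamGeometry, half_angle_from_q, relative_q_spread
from .profile_metrics import summarize
from .raster_paths import LabeledMask, PathMeasurement, scan_paths

__all__ = [
    "FOMRecord",
    "figure_of_merit",
    "rank_paths",
    "evaluate_mask_scan",
    "write_fom_table",
    "read_fom_table",
]

logger = logging.getLogger(__name__)

EXCLUSION_POLICIES = ("off", "drop")


@dataclass(frozen=True)
class FOMRecord:
    """Per-path summary: profile metrics, dose proxy and figure of merit."""

    path: str
    I_p: float
    I_t: float
    delta_q: float
    l: float
    omega: float
    orientation: str = ""
    index: int = 0
    candidate: bool = True
    intersects_excluded: bool = False
    omega_norm: float | None = None
    excluded_reason: str | None = None

    @classmethod
    def from_metrics(
        cls,
        path: str,
        I_p: float,
        I_t: float,
        delta_q: float,
        l: float,
        **kwargs,
    ) -> "FOMRecord":
        return cls(
            path=path,
            I_p=I_p,
            I_t=I_t,
            delta_q=delta_q,
            l=l,
            omega=figure_of_merit(I_p, I_t, delta_q, l),
            **kwargs,
        )


def figure_of_merit(I_p: float, I_t: float, delta_q: float, l: float) -> float:
    """``Omega = I_p * I_t / (l * delta_q)``.

    Linear in both intensity summaries, inverse in the smearing and in the
    dose proxy ``l``.  Paths with no target on them are handled upstream by
    the candidacy flag, so zero ``l`` or ``delta_q`` here is an error.
    """
    if l <= 0:
        raise ValueError(f"path length must be positive, got {l}")
    if delta_q <= 0:
        raise ValueError(f"delta_q must be positive, got {delta_q}")
    if I_p < 0 or I_t < 0:
        raise ValueError("intensities must be non-negative")
    return I_p * I_t / (l * delta_q)


def _sort_key(record: FOMRecord):
    # ties in omega break deterministically by (orientation, index)
    return (-record.omega, record.orientation, record.index)


def rank_paths(
    records: Sequence[FOMRecord], exclusion_policy: str = "off"
) -> list[FOMRecord]:
    """Rank candidate paths by Omega descending and attach ``omega_norm``.

    ``exclusion_policy``:

    * ``"off"`` (default): paths through excluded structures stay in the
      ranking; a warning lists them.
    * ``"drop"``: such paths are removed from the ranking (kept in the
      output with a reason, no rank or normalized score).

    Non-candidate paths (no target) are likewise retained unranked.
    ``omega_norm`` is Omega over the maximum Omega of the surviving
    candidates of this call.
    """
    if exclusion_policy not in EXCLUSION_POLICIES:
        raise ValueError(
            f"unknown exclusion policy {exclusion_policy!r}; "
            f"choose from {EXCLUSION_POLICIES}"
        )
    ranked: list[FOMRecord] = []
    side: list[FOMRecord] = []
    flagged = [r.path for r in records if r.intersects_excluded]
    if flagged and exclusion_policy == "off":
        logger.warning(
            "paths intersect excluded (radiosensitive) regions but remain "
            "ranked: %s",
            ", ".join(flagged),
        )
    for rec in records:
        if not rec.candidate:
            side.append(replace(rec, omega_norm=None, excluded_reason="no target on path"))
        elif exclusion_policy == "drop" and rec.intersects_excluded:
            side.append(
                replace(rec, omega_norm=None, excluded_reason="intersects excluded region")
            )
        else:
            ranked.append(rec)
    if not ranked:
        raise ValueError("all paths were excluded or non-candidates; nothing to rank")
    ranked.sort(key=_sort_key)
    omega_max = ranked[0].omega
    if omega_max <= 0:
        raise ValueError("no path has a positive figure of merit")
    ranked = [replace(r, omega_norm=r.omega / omega_max) for r in ranked]
    return ranked + side


def evaluate_mask_scan(
    mask: LabeledMask,
    medium: MediumProperties,
    beam: BeamGeometry,
    qset: QSettings = QSettings(),
    *,
    orientations: Sequence[str] = ("row", "column"),
    stride: int = 1,
    include_target_in_path: bool = True,
) -> list[FOMRecord]:
    """Score every axis-aligned path through a labeled mask.

    For each candidate path the step profile is built from the measured
    effective target radius and attenuation length, smeared with the
    detector kernel, summarized and scored.  The target-to-detector
    distance is ``beam.L0`` for every path (a fixed-detector scan).
    Returns unranked records in scan order; see :func:`rank_paths`.
    """
    measurements = scan_paths(
        mask,
        orientations,
        stride,
        include_target_in_path=include_target_in_path,
    )
    records = []
    for m in measurements:
        records.append(_score_measurement(m, medium, beam, qset))
    return records


def _score_measurement(
    m: PathMeasurement,
    medium: MediumProperties,
    beam: BeamGeometry,
    qset: QSettings,
) -> FOMRecord:
    label = f"{m.orientation} {m.index}"
    common = dict(
        orientation=m.orientation,
        index=m.index,
        intersects_excluded=m.intersects_excluded,
    )
    if not m.is_candidate:
        return FOMRecord(
            path=label,
            I_p=0.0,
            I_t=0.0,
            delta_q=0.0,
            l=m.l,
            omega=0.0,
            candidate=False,
            **common,
        )
    try:
        profile = _path_profile(m, medium, beam, qset)
        metrics = summarize(profile)
        omega = figure_of_merit(metrics.I_p, metrics.I_t, metrics.delta_q, m.l)
    except ValueError as exc:
        raise ValueError(f"path '{label}': {exc}") from exc
    return FOMRecord(
        path=label,
        I_p=metrics.I_p,
        I_t=metrics.I_t,
        delta_q=metrics.delta_q,
        l=m.l,
        omega=omega,
        **common,
    )


def _path_profile(
    m: PathMeasurement,
    medium: MediumProperties,
    beam: BeamGeometry,
    qset: QSettings,
) -> ScatteringProfile:
    theta = half_angle_from_q(qset.q_center, beam.wavelength)
    spread = qset.q_center * relative_q_spread(theta, beam.L0, m.r_t_eff)
    q_grid = default_q_grid(qset.q_center, spread, qset.n_samples, qset.span_factor)
    profile = build_step_profile(
        medium,
        m.r_t_eff,
        beam,
        qset.q_center,
        q_grid,
        path_length=m.l,
    )
    kernel = make_triangular_kernel(spread, profile.q_step, qset.kernel_width_factor)
    return smear_profile(profile, kernel)


def write_fom_table(
    records: Sequence[FOMRecord], sink: str | Path, top: int | None = None
) -> None:
    """Write (ranked) FOM records as TSV; ``top`` keeps the N best ranked."""
    rows = list(records)
    if top is not None:
        ranked = [r for r in rows if r.omega_norm is not None][:top]
        rest = [r for r in rows if r.omega_norm is None]
        rows = ranked + rest
    with open(sink, "w") as fh:
        fh.write(
            "orientation\tindex\tI_p\tI_t_nm_inv\tdelta_q_nm_inv\tl_cm\t"
            "omega\tomega_norm\tcandidate\texcluded_reason\n"
        )
        for r in rows:
            norm = f"{r.omega_norm:.9e}" if r.omega_norm is not None else "NA"
            reason = r.excluded_reason or ""
            fh.write(
                f"{r.orientation}\t{r.index}\t{r.I_p:.9e}\t{r.I_t:.9e}\t"
                f"{r.delta_q:.9e}\t{r.l:.9e}\t{r.omega:.9e}\t{norm}\t"
                f"{int(r.candidate)}\t{reason}\n"
            )


def read_fom_table(source: str | Path) -> list[FOMRecord]:
    """Read records written by :func:`write_fom_table` (e.g. to re-rank)."""
    records: list[FOMRecord] = []
    with open(source) as fh:
        header = fh.readline()
        if not header.startswith("orientation\t"):
            raise ValueError(f"{source} is not a figure-of-merit table")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 10:
                raise ValueError(f"malformed row in {source}: {line!r}")
            orientation, index, I_p, I_t, delta_q, l, omega, norm, cand, reason = parts
            records.append(
                FOMRecord(
                    path=f"{orientation} {index}",
                    orientation=orientation,
                    index=int(index),
                    I_p=float(I_p),
                    I_t=float(I_t),
                    delta_q=float(delta_q),
                    l=float(l),
                    omega=float(omega),
                    omega_norm=None if norm == "NA" else float(norm),
                    candidate=bool(int(cand)),
                    excluded_reason=reason or None,
                )
            )
    return records
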