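"""Labeled 2-D raster masks and Cartesian pencil-beam path measurement.

A mask labels every pixel of a segmented scout image as background/air (0),
object (attenuating non-target tissue, 1), target (scattering region, 2) or
excluded (radiosensitive structure such as cornea, optic lens or oral
cavity, 3).  A pencil beam along a grid row or column is measured by pixel
counting: the attenuation path length is the in-object distance and the
effective target radius is half the in-target distance.

Both target and object pixels contribute to the attenuation path because
they share the same linear attenuation coefficient; set
``include_target_in_path=False`` to count object pixels only (the two
conventions differ by one target diameter).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LabeledMask",
    "PathMeasurement",
    "LABEL_BACKGROUND",
    "LABEL_OBJECT",
    "LABEL_TARGET",
    "LABEL_EXCLUDED",
    "GRAY_LEVELS",
    "read_mask",
    "write_mask",
    "trace_axis_path",
    "scan_paths",
    "write_path_table",
]

LABEL_BACKGROUND = 0
LABEL_OBJECT = 1
LABEL_TARGET = 2
LABEL_EXCLUDED = 3

_VALID_LABELS = frozenset({0, 1, 2, 3})

#: 8-bit gray value for each label in PGM/PNG masks.
GRAY_LEVELS = {0: 0, 1: 85, 2: 170, 3: 255}
_GRAY_TO_LABEL = {v: k for k, v in GRAY_LEVELS.items()}


@dataclass(frozen=True)
class LabeledMask:
    """2-D label raster with a physical pixel size in cm."""

    labels: np.ndarray
    pixel_size: float
    name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError("labels must be integers")
            arr = arr.astype(np.int64)
        object.__setattr__(self, "labels", arr)
        if arr.ndim != 2:
            raise ValueError(f"labels must be a 2-D grid, got shape {arr.shape}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        bad = set(np.unique(arr)) - _VALID_LABELS
        if bad:
            raise ValueError(
                f"unknown labels {sorted(int(b) for b in bad)}; "
                f"valid labels are {sorted(_VALID_LABELS)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def transposed(self) -> "LabeledMask":
        return replace(self, labels=self.labels.T.copy())


@dataclass(frozen=True)
class PathMeasurement:
    """Pixel-counting measurement of one axis-aligned pencil-beam path."""

    orientation: str  # "row" | "column"
    index: int
    l: float  # attenuation path length, cm
    r_t_eff: float  # effective target radius, cm
    target_pixels: int
    object_pixels: int
    intersects_excluded: bool

    @property
    def is_candidate(self) -> bool:
        """A path with no target pixels produces no scatter signal."""
        return self.target_pixels > 0


def read_mask(source: str | Path, pixel_size: float, name: str = "") -> LabeledMask:
    """Read a labeled mask from PGM/PNG (gray levels 0/85/170/255) or from
    an integer CSV of labels (comma-separated, no header)."""
    path = Path(source)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        try:
            arr = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"non-rectangular or non-integer CSV {path}: {exc}") from exc
        labels = arr
    elif suffix in {".pgm", ".png"}:
        import imageio.v3 as iio

        gray = np.asarray(iio.imread(path))
        if gray.ndim == 3:  # collapse grayscale-encoded-as-RGB
            if not np.all(gray[..., 0] == gray[..., 1]) or not np.all(
                gray[..., 0] == gray[..., 2]
            ):
                raise ValueError(f"{path} is not a grayscale image")
            gray = gray[..., 0]
        unknown = sorted(int(v) for v in np.unique(gray) if int(v) not in _GRAY_TO_LABEL)
        if unknown:
            raise ValueError(
                f"unmapped gray values {unknown} in {path}; expected "
                f"{sorted(_GRAY_TO_LABEL)}"
            )
        lut = np.zeros(256, dtype=np.int64)
        for g, lab in _GRAY_TO_LABEL.items():
            lut[g] = lab
        labels = lut[gray.astype(np.int64)]
    else:
        raise ValueError(f"unsupported mask format {suffix!r} (use .pgm, .png or .csv)")
    return LabeledMask(labels=labels, pixel_size=pixel_size, name=name or path.stem)


def write_mask(mask: LabeledMask, sink: str | Path, format: str | None = None) -> None:
    """Write a mask; the format is inferred from the suffix unless given.

    PGM/PNG use the fixed 4-level gray mapping; CSV stores raw labels.
    ``read_mask(write_mask(m))`` is the identity.
    """
    path = Path(sink)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        np.savetxt(path, mask.labels, fmt="%d", delimiter=",")
    elif fmt in {"pgm", "png"}:
        lut = np.zeros(4, dtype=np.uint8)
        for lab, g in GRAY_LEVELS.items():
            lut[lab] = g
        gray = lut[mask.labels]
        import imageio.v3 as iio

        iio.imwrite(path, gray)
    else:
        raise ValueError(f"unsupported mask format {fmt!r} (use pgm, png or csv)")


def trace_axis_path(
    mask: LabeledMask,
    orientation: str,
    index: int,
    *,
    include_target_in_path: bool = True,
) -> PathMeasurement:
    """Measure the pencil beam along a full grid row or column."""
    if orientation not in {"row", "column"}:
        raise ValueError(f"orientation must be 'row' or 'column', got {orientation!r}")
    n_rows, n_cols = mask.shape
    limit = n_rows if orientation == "row" else n_cols
    if not 0 <= index < limit:
        raise IndexError(f"{orientation} index {index} out of range [0, {limit})")
    line = mask.labels[index, :] if orientation == "row" else mask.labels[:, index]
    target = int(np.count_nonzero(line == LABEL_TARGET))
    obj = int(np.count_nonzero(line == LABEL_OBJECT))
    excluded = bool(np.any(line == LABEL_EXCLUDED))
    attenuating = obj + target if include_target_in_path else obj
    return PathMeasurement(
        orientation=orientation,
        index=index,
        l=attenuating * mask.pixel_size,
        r_t_eff=target * mask.pixel_size / 2.0,
        target_pixels=target,
        object_pixels=obj,
        intersects_excluded=excluded,
    )


def scan_paths(
    mask: LabeledMask,
    orientations: Iterable[str] = ("row", "column"),
    stride: int = 1,
    *,
    include_target_in_path: bool = True,
) -> list[PathMeasurement]:
    """Trace every ``stride``-th row and/or column, rows first then columns,
    indices ascending (a deterministic ordering)."""
    orients = list(dict.fromkeys(orientations))
    if not orients:
        raise ValueError("at least one orientation is required")
    bad = [o for o in orients if o not in {"row", "column"}]
    if bad:
        raise ValueError(f"unknown orientations {bad}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    n_rows, n_cols = mask.shape
    out: list[PathMeasurement] = []
    for orientation in ("row", "column"):
        if orientation not in orients:
            continue
        limit = n_rows if orientation == "row" else n_cols
        for index in range(0, limit, stride):
            out.append(
                trace_axis_path(
                    mask,
                    orientation,
                    index,
                    include_target_in_path=include_target_in_path,
                )
            )
    return out


def write_path_table(measurements: Sequence[PathMeasurement], sink: str | Path) -> None:
    """Write path measurements as TSV."""
    with open(sink, "w") as fh:
        fh.write(
            "orientation\tindex\tl_cm\tr_t_eff_cm\ttarget_pixels\t"
            "object_pixels\texcluded_flag\n"
        )
        for m in measurements:
            fh.write(
                f"{m.orientation}\t{m.index}\t{m.l:.9e}\t{m.r_t_eff:.9e}\t"
                f"{m.target_pixels}\t{m.object_pixels}\t{int(m.intersects_excluded)}\n"
            )
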