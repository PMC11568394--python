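"""Keypoint data model and annotation / measurement file I/O.

Coordinate convention (used by every downstream module): image pixel
coordinates with the origin at the top-left corner and y increasing caudally
(down the image).  A vertebra's *upper* (superior, cranial) endplate therefore
has the smaller y.  Corners are stored in the fixed order

    upper-left, upper-right, lower-right, lower-left  (UL, UR, LR, LL)

and the order is validated, never inferred.  Angles are unit-free; pixel
spacing, when present, is metadata only.

Annotations are stored as JSON (schema shipped in ``cobbkit/schemas``),
measurement tables as flat CSV with columns
``subject_id,method,rater,replicate,angle``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import AnnotationValidationError, SchemaError

__all__ = [
    "VertebraKeypoints",
    "SpineAnnotation",
    "PairedMeasurements",
    "read_annotations",
    "write_annotations",
    "read_measurements",
    "write_measurements",
    "MEASUREMENT_COLUMNS",
]

MEASUREMENT_COLUMNS = ["subject_id", "method", "rater", "replicate", "angle"]


@dataclass(frozen=True)
class VertebraKeypoints:
    """One vertebra's four corner keypoints.

    Parameters
    ----------
    label:
        Anatomical level (``"T1"``–``"T12"``, ``"L1"``–``"L5"``) or an integer
        index for synthetic spines without anatomy.
    corners:
        ``(4, 2)`` array of pixel coordinates in the fixed order UL, UR, LR,
        LL (image coordinates, y increases caudally).
    """

    label: str | int
    corners: np.ndarray

    def __post_init__(self) -> None:
        corners = np.asarray(self.corners, dtype=float)
        object.__setattr__(self, "corners", corners)
        self.validate()

    def validate(self) -> None:
        c = self.corners
        if c.shape != (4, 2):
            raise AnnotationValidationError(
                f"vertebra {self.label!r}: expected 4 corner points, "
                f"got array of shape {c.shape}"
            )
        if not np.all(np.isfinite(c)):
            raise AnnotationValidationError(
                f"vertebra {self.label!r}: non-finite corner coordinate"
            )
        if np.any(c < 0):
            raise AnnotationValidationError(
                f"vertebra {self.label!r}: negative corner coordinate"
            )
        upper_y = c[[0, 1], 1].mean()
        lower_y = c[[2, 3], 1].mean()
        if not upper_y < lower_y:
            raise AnnotationValidationError(
                f"vertebra {self.label!r}: upper corners are not cranial to "
                f"lower corners (mean upper y={upper_y:.3f} >= "
                f"mean lower y={lower_y:.3f}); corner order must be UL, UR, LR, LL"
            )
        quad = Polygon(c)
        if not quad.is_valid or quad.area <= 0:
            raise AnnotationValidationError(
                f"vertebra {self.label!r}: corners do not form a simple "
                "quadrilateral"
            )

    @property
    def centroid(self) -> np.ndarray:
        """Mean of the four corners, ``(x, y)`` in pixels."""
        return self.corners.mean(axis=0)

    def upper_edge(self) -> tuple[np.ndarray, np.ndarray]:
        """The two corners of the superior endplate (UL, UR)."""
        return self.corners[0], self.corners[1]

    def lower_edge(self) -> tuple[np.ndarray, np.ndarray]:
        """The two corners of the inferior endplate (LL, LR)."""
        return self.corners[3], self.corners[2]


# Anatomical levels in cranial→caudal order, for label validation and
# end-vertebra offset arithmetic.
ANATOMICAL_LEVELS = [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)]
_LEVEL_INDEX = {lvl: i for i, lvl in enumerate(ANATOMICAL_LEVELS)}


def level_index(label: str | int) -> int:
    """Ordinal position of a vertebral label (T1=0 … L5=16, or the integer itself)."""
    if isinstance(label, int):
        return label
    try:
        return _LEVEL_INDEX[str(label)]
    except KeyError:
        raise AnnotationValidationError(f"unknown vertebral level {label!r}") from None


@dataclass
class SpineAnnotation:
    """An ordered cranial→caudal spine annotation for one radiograph."""

    subject_id: str
    vertebrae: list[VertebraKeypoints]
    image_size: tuple[int, int] | None = None
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.vertebrae) < 4:
            raise AnnotationValidationError(
                f"subject {self.subject_id!r}: need >= 4 vertebrae, "
                f"got {len(self.vertebrae)}"
            )
        ys = [v.centroid[1] for v in self.vertebrae]
        for i in range(1, len(ys)):
            if not ys[i] > ys[i - 1]:
                raise AnnotationValidationError(
                    f"subject {self.subject_id!r}: vertebra "
                    f"{self.vertebrae[i].label!r} centroid y={ys[i]:.3f} does "
                    f"not increase past {self.vertebrae[i - 1].label!r} "
                    f"(y={ys[i - 1]:.3f}); vertebrae must be ordered cranial→caudal"
                )
        labels = [v.label for v in self.vertebrae]
        if any(isinstance(l, str) for l in labels):
            if len(set(labels)) != len(labels):
                raise AnnotationValidationError(
                    f"subject {self.subject_id!r}: duplicate vertebral labels"
                )
            idx = [level_index(l) for l in labels]
            if idx != sorted(idx):
                raise AnnotationValidationError(
                    f"subject {self.subject_id!r}: anatomical labels out of order"
                )

    @property
    def centroids(self) -> np.ndarray:
        """``(n, 2)`` array of vertebral centroids, cranial→caudal."""
        return np.array([v.centroid for v in self.vertebrae])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpineAnnotation):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.image_size == other.image_size
            and self.pixel_spacing == other.pixel_spacing
            and len(self.vertebrae) == len(other.vertebrae)
            and all(
                a.label == b.label and np.array_equal(a.corners, b.corners)
                for a, b in zip(self.vertebrae, other.vertebrae)
            )
        )


class PairedMeasurements:
    """Long-format Cobb-angle measurement records.

    Wraps a DataFrame with columns ``subject_id, method, rater, replicate,
    angle``; every ``(subject_id, method, rater, replicate)`` key is unique and
    angles are non-negative.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"measurement table missing column(s): {missing}")
        frame = frame[MEASUREMENT_COLUMNS].copy()
        frame["replicate"] = frame["replicate"].astype(int)
        frame["angle"] = frame["angle"].astype(float)
        if (frame["angle"] < 0).any():
            bad = frame.loc[frame["angle"] < 0].iloc[0]
            raise AnnotationValidationError(
                f"negative angle {bad['angle']} for subject {bad['subject_id']!r}"
            )
        keys = frame[["subject_id", "method", "rater", "replicate"]]
        dup = keys.duplicated()
        if dup.any():
            bad = keys[dup].iloc[0].tolist()
            raise AnnotationValidationError(
                f"duplicate measurement key {tuple(bad)}"
            )
        self.frame = frame.reset_index(drop=True)
        self.n_clamped: int = 0  # set by generators that clamp negative draws

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairedMeasurements):
            return NotImplemented
        return self.frame.equals(other.frame)

    def methods(self) -> list[str]:
        return list(self.frame["method"].unique())

    def pivot(
        self, columns: str, method: str | None = None, rater: str | None = None
    ) -> pd.DataFrame:
        """Subject × ``columns`` wide table (columns = 'rater' or 'replicate').

        Remaining keys must be constant after the optional filters; raises
        :class:`DesignError` on missing cells (checked by the caller's design
        validation, not here).
        """
        df = self.frame
        if method is not None:
            df = df[df["method"] == method]
        if rater is not None:
            df = df[df["rater"] == rater]
        return df.pivot_table(
            index="subject_id", columns=columns, values="angle", aggfunc="mean"
        )


def _vertebra_to_obj(v: VertebraKeypoints) -> dict:
    label = v.label if isinstance(v.label, (str, int)) else str(v.label)
    return {"label": label, "corners": v.corners.tolist()}


def _annotation_to_obj(a: SpineAnnotation) -> dict:
    return {
        "subject_id": a.subject_id,
        "image_size": list(a.image_size) if a.image_size is not None else None,
        "pixel_spacing": a.pixel_spacing,
        "vertebrae": [_vertebra_to_obj(v) for v in a.vertebrae],
    }


def write_annotations(
    annotations: Iterable[SpineAnnotation], path: str | Path
) -> None:
    """Write annotations to the documented JSON container (lossless)."""
    obj = {"annotations": [_annotation_to_obj(a) for a in annotations]}
    Path(path).write_text(json.dumps(obj, indent=1))


def read_annotations(path: str | Path) -> list[SpineAnnotation]:
    """Read and validate an annotation JSON file.

    Raises :class:`SchemaError` on malformed JSON (naming the byte offset) or
    a structurally wrong container, :class:`AnnotationValidationError` when an
    annotation violates an invariant (naming subject and vertebra).
    """
    text = Path(path).read_text()
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as e:
        raise SchemaError(
            f"{path}: malformed JSON at byte offset {e.pos}: {e.msg}"
        ) from e
    if not isinstance(obj, dict) or "annotations" not in obj:
        raise SchemaError(f"{path}: missing top-level 'annotations' array")
    out: list[SpineAnnotation] = []
    for entry in obj["annotations"]:
        try:
            vertebrae = [
                VertebraKeypoints(label=v["label"], corners=np.asarray(v["corners"]))
                for v in entry["vertebrae"]
            ]
            ann = SpineAnnotation(
                subject_id=entry["subject_id"],
                vertebrae=vertebrae,
                image_size=tuple(entry["image_size"])
                if entry.get("image_size")
                else None,
                pixel_spacing=entry.get("pixel_spacing"),
            )
        except KeyError as e:
            raise SchemaError(f"{path}: annotation entry missing field {e}") from e
        out.append(ann)
    return out


def write_measurements(measurements: PairedMeasurements, path: str | Path) -> None:
    """Write a measurement table as CSV (UTF-8, '.' decimal separator)."""
    measurements.frame.to_csv(path, index=False)


def read_measurements(path: str | Path) -> PairedMeasurements:
    """Read and validate a measurement CSV.

    Raises :class:`SchemaError` on a missing column,
    :class:`AnnotationValidationError` on duplicate keys or negative angles.
    """
    frame = pd.read_csv(path)
    return PairedMeasurements(frame)
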