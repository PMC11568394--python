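"""Cobb-angle measurement from endplate lines.

For each bending segment, lines are fitted to the superior and inferior
endplates of every member vertebra (the line through the two annotated corner
keypoints of that edge).  A loop then iterates through all admissible line
pairs — superior endplate of a cranial-or-equal vertebra against inferior
endplate of a caudal-or-equal vertebra — and computes the intersection angle

    theta = arctan( |(m1 - m2) / (1 + m1 * m2)| )

for slopes m1, m2, evaluated in the numerically equivalent direction-vector
form ``arccos(|d1 . d2|)`` so vertical endplates need no special case.
Angles below the 5° floor are ignored; the largest surviving angle is the
segment's Cobb angle, and its two vertebrae are the curve's end vertebrae.
Across segments the two largest angles are the major and minor curves, and
severity follows the clinical bands (mild < 25°, 25–45° moderate, > 45°
severe).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import SpineAnnotation, VertebraKeypoints, level_index
from .curve import (
    CenterlineFit,
    CurveSegment,
    fit_centerline_mls,
    second_derivative_poly,
    segment_by_inflection,
)
from .errors import AnnotationValidationError, PairingError

__all__ = [
    "EndplateLine",
    "CobbMeasurement",
    "CobbReport",
    "MeasureConfig",
    "fit_endplate_line",
    "angle_between",
    "segment_cobb",
    "measure_spine",
    "classify_severity",
    "end_vertebra_offsets",
]


@dataclass(frozen=True)
class EndplateLine:
    """A line through a vertebral endplate's two corner keypoints."""

    vertebra_index: int
    edge: str  # "upper" | "lower"
    direction: np.ndarray  # unit 2-vector, direction_x >= 0
    anchor: np.ndarray

    @property
    def slope(self) -> float:
        """dy/dx of the line; ``inf`` for a vertical line."""
        dx, dy = self.direction
        if dx == 0.0:
            return math.inf
        return dy / dx


@dataclass(frozen=True)
class CobbMeasurement:
    segment: CurveSegment
    angle: float
    upper_end_vertebra: str | int
    lower_end_vertebra: str | int
    upper_line: EndplateLine
    lower_line: EndplateLine


@dataclass(frozen=True)
class CobbReport:
    """Per-segment Cobb angles with major/minor designation and severity."""

    subject_id: str
    measurements: tuple[CobbMeasurement, ...]
    major: CobbMeasurement | None
    minor: CobbMeasurement | None
    severity: str | None

    @property
    def major_angle(self) -> float | None:
        return self.major.angle if self.major else None

    @property
    def minor_angle(self) -> float | None:
        return self.minor.angle if self.minor else None

    def to_dict(self) -> dict:
        def _m(m: CobbMeasurement) -> dict:
            return {
                "angle": m.angle,
                "upper_end_vertebra": m.upper_end_vertebra,
                "lower_end_vertebra": m.lower_end_vertebra,
                "vertebra_indices": list(m.segment.vertebra_indices)
                if m.segment
                else None,
            }

        return {
            "subject_id": self.subject_id,
            "measurements": [_m(m) for m in self.measurements],
            "major": _m(self.major) if self.major else None,
            "minor": _m(self.minor) if self.minor else None,
            "severity": self.severity,
        }

    def to_rows(self) -> list[dict]:
        """Flat rows for the CSV mirror: one per measured segment."""
        rows = []
        for m in sorted(self.measurements, key=lambda m: m.angle, reverse=True):
            role = (
                "major" if m is self.major else "minor" if m is self.minor else ""
            )
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "angle": m.angle,
                    "upper_end": m.upper_end_vertebra,
                    "lower_end": m.lower_end_vertebra,
                    "role": role,
                    "severity": self.severity if role == "major" else "",
                }
            )
        return rows


@dataclass(frozen=True)
class MeasureConfig:
    """Tunable parameters of the measurement pipeline."""

    bandwidth: float | str = "auto"
    grid_size: int = 200
    poly_degree: int = 6
    floor: float = 5.0


def fit_endplate_line(vertebra: VertebraKeypoints, edge: str, index: int = -1) -> EndplateLine:
    """Line through the two corners of the named endplate.

    With exactly two points the fit is exact interpolation.  The direction is
    normalized with ``direction_x >= 0``; a vertical endplate gets direction
    ``(0, 1)``.
    """
    if edge == "upper":
        p0, p1 = vertebra.upper_edge()
    elif edge == "lower":
        p0, p1 = vertebra.lower_edge()
    else:
        raise ValueError(f"edge must be 'upper' or 'lower', got {edge!r}")
    d = np.asarray(p1, float) - np.asarray(p0, float)
    norm = float(np.hypot(*d))
    if norm == 0.0:
        raise AnnotationValidationError(
            f"vertebra {vertebra.label!r}: coincident {edge} corner points"
        )
    d = d / norm
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d
    return EndplateLine(
        vertebra_index=index, edge=edge, direction=d, anchor=np.asarray(p0, float)
    )


def angle_between(line1: EndplateLine, line2: EndplateLine) -> float:
    """Intersection angle of two endplate lines, degrees in [0, 90].

    Equals ``arctan(|(m1 - m2)/(1 + m1*m2)|)`` whenever both slopes are
    defined and ``1 + m1*m2 != 0``; perpendicular lines give 90 and vertical
    lines are handled naturally by the direction-vector form.
    """
    c = abs(float(np.dot(line1.direction, line2.direction)))
    c = min(c, 1.0)
    return math.degrees(math.acos(c))


def segment_cobb(
    segment: CurveSegment,
    annotation: SpineAnnotation,
    floor: float = 5.0,
) -> CobbMeasurement | None:
    """Maximal endplate intersection angle over all line pairs in a segment.

    Enumerates every pair (superior endplate of vertebra i, inferior endplate
    of vertebra j) with i <= j inside the segment, discards pairs below the
    floor, and returns the pair of maximal angle.  Ties are broken by the
    longest vertebral span ``j - i``, then the most cranial ``i``.  Returns
    ``None`` when no pair survives the floor.
    """
    idx = segment.vertebra_indices
    uppers = {
        i: fit_endplate_line(annotation.vertebrae[i], "upper", i) for i in idx
    }
    lowers = {
        j: fit_endplate_line(annotation.vertebrae[j], "lower", j) for j in idx
    }
    best: tuple[float, int, int] | None = None  # (angle, span, -i) ordering
    best_pair: tuple[int, int] | None = None
    for i in idx:
        for j in idx:
            if j < i:
                continue
            theta = angle_between(uppers[i], lowers[j])
            if theta < floor:
                continue
            key = (theta, j - i, -i)
            if best is None or key > best:
                best = key
                best_pair = (i, j)
    if best_pair is None:
        return None
    i, j = best_pair
    return CobbMeasurement(
        segment=segment,
        angle=best[0],
        upper_end_vertebra=annotation.vertebrae[i].label,
        lower_end_vertebra=annotation.vertebrae[j].label,
        upper_line=uppers[i],
        lower_line=lowers[j],
    )


def classify_severity(angle: float) -> str:
    """Clinical severity band: mild < 25°, 25° <= moderate <= 45°, severe > 45°."""
    if angle < 0:
        raise ValueError(f"Cobb angle must be non-negative, got {angle}")
    if angle < 25.0:
        return "mild"
    if angle <= 45.0:
        return "moderate"
    return "severe"


def measure_spine(
    annotation: SpineAnnotation, config: MeasureConfig | None = None
) -> CobbReport:
    """Full automatic pipeline: centerline → segmentation → Cobb per segment.

    The major angle is the largest surviving segment angle, the minor the
    second largest (absent when fewer than two segments survive the floor);
    severity is classified from the major angle.  A spine where no segment
    survives yields an empty report with no severity.
    """
    config = config or MeasureConfig()
    fit = fit_centerline_mls(
        annotation, bandwidth=config.bandwidth, grid_size=config.grid_size
    )
    fit = second_derivative_poly(fit, degree=config.poly_degree)
    segments = segment_by_inflection(fit, annotation)
    measurements = []
    for seg in segments:
        m = segment_cobb(seg, annotation, floor=config.floor)
        if m is not None:
            measurements.append(m)
    ranked = sorted(measurements, key=lambda m: m.angle, reverse=True)
    major = ranked[0] if ranked else None
    minor = ranked[1] if len(ranked) > 1 else None
    severity = classify_severity(major.angle) if major else None
    return CobbReport(
        subject_id=annotation.subject_id,
        measurements=tuple(measurements),
        major=major,
        minor=minor,
        severity=severity,
    )


_OFFSET_BINS = [-2, -1, 0, 1, 2]


def end_vertebra_offsets(
    reports_a: list[CobbReport], reports_b: list[CobbReport]
) -> pd.DataFrame:
    """Tabulate end-vertebra level offsets between two measurement methods.

    Reports are paired by ``subject_id``; each must carry a major measurement
    with level labels.  For the upper and lower end vertebrae separately, the
    offset is the level of method A minus method B in vertebral levels
    (negative = A more cranial, positive = A more caudal), binned over
    −2…+2 plus ``"other"``.  Returns a tidy frame with columns
    ``edge, offset, count, percent``; percentages sum to 100 per edge within
    rounding.
    """
    by_b = {r.subject_id: r for r in reports_b}
    rows = []
    for ra in reports_a:
        if ra.subject_id not in by_b:
            raise PairingError(f"subject {ra.subject_id!r} missing from method B")
        rb = by_b[ra.subject_id]
        if ra.major is None or rb.major is None:
            raise PairingError(
                f"subject {ra.subject_id!r}: missing major measurement"
            )
        for edge, la, lb in (
            ("upper", ra.major.upper_end_vertebra, rb.major.upper_end_vertebra),
            ("lower", ra.major.lower_end_vertebra, rb.major.lower_end_vertebra),
        ):
            rows.append((edge, level_index(la) - level_index(lb)))
    df = pd.DataFrame(rows, columns=["edge", "offset"])
    n_per_edge = df.groupby("edge").size()
    out = []
    for edge in ("upper", "lower"):
        sub = df[df["edge"] == edge]["offset"]
        n = len(sub)
        for off in _OFFSET_BINS:
            cnt = int((sub == off).sum())
            out.append((edge, off, cnt, 100.0 * cnt / n if n else float("nan")))
        cnt_other = int((~sub.isin(_OFFSET_BINS)).sum())
        out.append((edge, "other", cnt_other, 100.0 * cnt_other / n if n else float("nan")))
    return pd.DataFrame(out, columns=["edge", "offset", "count", "percent"])
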