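"""Parametric synthetic spines with analytically known Cobb angles.

The generator emulates the output contract of a keypoint detector — four
corner points per vertebra, ordered cranial→caudal — on spines whose
centerline is a sum of sinusoids,

    x(y) = sum_i A_i * sin(k_i * y + phi_i),        y in [0, L],

in image coordinates (y increases caudally).  Vertebrae are rigid rectangles
centred on the centerline at equal y spacing, rotated so their endplates are
exactly perpendicular to the local tangent; the true orientation of a
vertebra is therefore ``arctan(dx/dy)`` at its centroid, and the true Cobb
angle of a bending segment is the max−min orientation over its member
vertebrae.  Ground truth is computed from the unperturbed geometry before any
corner noise is added, so it can serve as the oracle for the measurement
pipeline.

Default geometry emulates a full-length standing radiograph at typical
detector resolution: 17 thoracolumbar vertebrae over an 800-px span, bodies
60 px wide and 40 px tall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import PairedMeasurements, SpineAnnotation, VertebraKeypoints
from .cobb import CobbMeasurement, CobbReport
from .errors import GenerationError

__all__ = [
    "SpineShapeParams",
    "GroundTruth",
    "generate_spine",
    "analytic_cobb",
    "single_curve_params",
    "s_curve_params",
    "simulate_paired_measurements",
    "simulate_crossed_design",
    "simulate_offset_reports",
]


@dataclass(frozen=True)
class SpineShapeParams:
    """Shape and noise parameters of a synthetic spine.

    ``centerline`` is a list of sinusoid terms ``(amplitude px, wavenumber
    1/px, phase rad)`` summed to give lateral displacement x(y) over
    ``y in [0, span]``.
    """

    n_vertebrae: int = 17
    centerline: tuple[tuple[float, float, float], ...] = ()
    span: float = 800.0
    vertebra_height: float = 40.0
    vertebra_width: float = 60.0
    keypoint_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 4:
            raise GenerationError("need at least 4 vertebrae")
        if self.span <= 0:
            raise GenerationError("span must be positive")
        if self.vertebra_height * self.n_vertebrae > 1.2 * self.span:
            raise GenerationError(
                "vertebrae overlap grossly: height * n exceeds 1.2 * span"
            )
        if self.keypoint_noise_sd < 0:
            raise GenerationError("noise sd must be non-negative")

    # --- analytic centerline -------------------------------------------------

    def x(self, y: np.ndarray | float) -> np.ndarray | float:
        out = 0.0
        for a, k, phi in self.centerline:
            out = out + a * np.sin(k * np.asarray(y, float) + phi)
        return out + np.zeros_like(np.asarray(y, float))

    def dx(self, y: np.ndarray | float) -> np.ndarray | float:
        out = 0.0
        for a, k, phi in self.centerline:
            out = out + a * k * np.cos(k * np.asarray(y, float) + phi)
        return out + np.zeros_like(np.asarray(y, float))

    def d2x(self, y: np.ndarray | float) -> np.ndarray | float:
        out = 0.0
        for a, k, phi in self.centerline:
            out = out - a * k * k * np.sin(k * np.asarray(y, float) + phi)
        return out + np.zeros_like(np.asarray(y, float))

    def centroid_y(self) -> np.ndarray:
        """Equally spaced centroid ordinates with half-spacing margins."""
        n = self.n_vertebrae
        return (np.arange(n) + 0.5) * self.span / n


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for a synthetic spine.

    Orientations are tangent angles ``arctan(dx/dy)`` in degrees at each
    centroid; each segment's true Cobb equals max−min orientation over its
    member vertebrae.  ``inflection_y`` are the sign-change ordinates of
    x''(y) interior to the centroid range, in annotation coordinates.
    """

    segment_angles: tuple[float, ...]
    segment_members: tuple[tuple[int, ...], ...]
    orientations: tuple[float, ...]
    inflection_y: tuple[float, ...]


def _inflection_zeros(params: SpineShapeParams, lo: float, hi: float) -> list[float]:
    """Sign-change ordinates of x'' on [lo, hi] by dense bracketing + bisection."""
    from scipy.optimize import brentq

    grid = np.linspace(lo, hi, 4001)
    vals = np.asarray(params.d2x(grid), float)
    zeros: list[float] = []
    for i in range(1, len(grid) - 1):
        if vals[i] == 0.0 and vals[i - 1] * vals[i + 1] < 0:
            zeros.append(float(grid[i]))
    for i in range(len(grid) - 1):
        if vals[i] * vals[i + 1] < 0:
            zeros.append(float(brentq(lambda y: float(params.d2x(y)), grid[i], grid[i + 1])))
    return sorted(zeros)


def _true_segments(params: SpineShapeParams) -> tuple[list[list[int]], list[float]]:
    """Partition centroids by the sign of x'' and list interior inflections."""
    ys = params.centroid_y()
    zeros = _inflection_zeros(params, ys[0], ys[-1])
    edges = [ys[0] - 1.0] + zeros + [ys[-1] + 1.0]
    members: list[list[int]] = []
    for k in range(len(edges) - 1):
        m = [i for i, y in enumerate(ys) if edges[k] < y <= edges[k + 1]]
        if m:
            members.append(m)
    return members, zeros


def _ground_truth(params: SpineShapeParams, y_shift: float) -> GroundTruth:
    ys = params.centroid_y()
    orient = np.degrees(np.arctan(np.asarray(params.dx(ys), float)))
    members, zeros = _true_segments(params)
    seg_angles = []
    seg_members = []
    for m in members:
        if len(m) < 2:
            continue
        seg_angles.append(float(orient[m].max() - orient[m].min()))
        seg_members.append(tuple(m))
    return GroundTruth(
        segment_angles=tuple(seg_angles),
        segment_members=tuple(seg_members),
        orientations=tuple(float(o) for o in orient),
        inflection_y=tuple(z + y_shift for z in zeros),
    )


def generate_spine(params: SpineShapeParams) -> tuple[SpineAnnotation, GroundTruth]:
    """Generate a detector-contract annotation plus its analytic ground truth.

    Corners are perturbed by i.i.d. isotropic Gaussian noise of sd
    ``keypoint_noise_sd`` (seeded); ground truth comes from the unperturbed
    geometry.  The whole spine is shifted so all coordinates are non-negative.
    """
    ys = params.centroid_y()
    xs = np.asarray(params.x(ys), float)
    slopes = np.asarray(params.dx(ys), float)

    w2 = params.vertebra_width / 2.0
    h2 = params.vertebra_height / 2.0
    corners = np.empty((params.n_vertebrae, 4, 2))
    for i, (xc, yc, s) in enumerate(zip(xs, ys, slopes)):
        norm = math.hypot(1.0, s)
        t = np.array([s, 1.0]) / norm       # tangent, points caudally
        u = np.array([1.0, -s]) / norm      # endplate direction
        c = np.array([xc, yc])
        corners[i, 0] = c - w2 * u - h2 * t  # UL
        corners[i, 1] = c + w2 * u - h2 * t  # UR
        corners[i, 2] = c + w2 * u + h2 * t  # LR
        corners[i, 3] = c - w2 * u + h2 * t  # LL

    if params.keypoint_noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        corners = corners + rng.normal(
            0.0, params.keypoint_noise_sd, size=corners.shape
        )

    # shift into the non-negative quadrant with a small margin
    margin = 10.0
    x_shift = margin - corners[..., 0].min()
    y_shift = margin - corners[..., 1].min()
    corners[..., 0] += x_shift
    corners[..., 1] += y_shift

    cy = corners.mean(axis=1)[:, 1]
    if not np.all(np.diff(cy) > 0):
        raise GenerationError(
            "generated centroids are not monotone in y; reduce amplitude or "
            "keypoint noise"
        )
    vertebrae = [
        VertebraKeypoints(label=i, corners=corners[i])
        for i in range(params.n_vertebrae)
    ]
    ann = SpineAnnotation(
        subject_id=f"synthetic-{params.seed}",
        vertebrae=vertebrae,
    )
    return ann, _ground_truth(params, y_shift)


def analytic_cobb(params: SpineShapeParams) -> list[float]:
    """True Cobb angle per bending segment, ignoring keypoint noise.

    For each maximal interval between sign changes of x''(y) containing at
    least two centroids, returns max−min of the centroid orientation angles.
    For a single sinusoid spanning a half-period with dense vertebrae this
    approaches ``2 * arctan(A * k)`` degrees.
    """
    return list(_ground_truth(params, 0.0).segment_angles)


def single_curve_params(
    target_angle: float,
    n_vertebrae: int = 17,
    span: float = 800.0,
    keypoint_noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> SpineShapeParams:
    """Half-period C-curve whose discrete true Cobb equals ``target_angle``.

    Uses x(y) = A sin(pi y / L); the outermost centroids sit at the slope
    extrema among centroids, so the amplitude solving
    ``2 arctan(A k cos(pi/(2n))) = target`` gives an exact discrete truth.
    """
    k = math.pi / span
    a = math.tan(math.radians(target_angle / 2.0)) / (k * math.cos(math.pi / (2 * n_vertebrae)))
    return SpineShapeParams(
        n_vertebrae=n_vertebrae,
        centerline=((a, k, 0.0),),
        span=span,
        keypoint_noise_sd=keypoint_noise_sd,
        seed=seed,
        **kwargs,
    )


def s_curve_params(
    amplitude: float = 60.0,
    asymmetry: float = 10.0,
    n_vertebrae: int = 17,
    span: float = 800.0,
    keypoint_noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> SpineShapeParams:
    """Full-period S-curve (two opposite bends, one interior inflection).

    ``x(y) = A sin(2 pi y / L) + B sin(pi y / L)``: the small half-period
    term (amplitude ``asymmetry``) deepens one lobe so the major and minor
    angles differ while keeping a single interior inflection for
    ``|B| < 4 A``.
    """
    return SpineShapeParams(
        n_vertebrae=n_vertebrae,
        centerline=(
            (amplitude, 2.0 * math.pi / span, 0.0),
            (asymmetry, math.pi / span, 0.0),
        ),
        span=span,
        keypoint_noise_sd=keypoint_noise_sd,
        seed=seed,
        **kwargs,
    )


def simulate_paired_measurements(
    truths: list[float],
    methods: list[tuple[str, float, float]],
    n_replicates: int = 1,
    subject_sd: float = 0.0,
    seed: int = 0,
) -> PairedMeasurements:
    """Simulate a long-format measurement table around known true angles.

    Each measurement is ``truth + subject_effect + bias + N(0, sd^2)`` with
    the subject effect (sd ``subject_sd``) shared across methods and
    replicates, and the residual drawn independently per replicate.  Negative
    draws are clamped at zero; the clamp count is attached to the result as
    ``n_clamped``.  The rater column is constant (``"r1"``) — use
    :func:`simulate_crossed_design` for multi-rater tables.
    """
    for name, _, sd in methods:
        if sd < 0:
            raise ValueError(f"method {name!r}: sd must be non-negative")
    rng = np.random.default_rng(seed)
    truths = np.asarray(truths, float)
    subj_eff = (
        rng.normal(0.0, subject_sd, size=len(truths))
        if subject_sd > 0
        else np.zeros(len(truths))
    )
    rows = []
    n_clamped = 0
    for si, t in enumerate(truths):
        sid = f"s{si:05d}"
        for name, bias, sd in methods:
            noise = rng.normal(0.0, sd, size=n_replicates) if sd > 0 else np.zeros(n_replicates)
            for rep in range(1, n_replicates + 1):
                val = t + subj_eff[si] + bias + noise[rep - 1]
                if val < 0:
                    val = 0.0
                    n_clamped += 1
                rows.append((sid, name, "r1", rep, val))
    pm = PairedMeasurements(
        pd.DataFrame(rows, columns=["subject_id", "method", "rater", "replicate", "angle"])
    )
    pm.n_clamped = n_clamped
    return pm


def simulate_crossed_design(
    n_subjects: int,
    n_raters: int = 2,
    between_sd: float = 10.0,
    error_sd: float = 1.0,
    mean_angle: float = 50.0,
    rater_biases: list[float] | None = None,
    seed: int = 0,
) -> PairedMeasurements:
    """Fully crossed subject × rater table for ICC simulation.

    Subject true angles are ``N(mean_angle, between_sd^2)``; each rater
    observes the subject value plus an optional rater bias and independent
    ``N(0, error_sd^2)`` error.  With no rater bias the population ICC(2,1)
    is ``between_sd^2 / (between_sd^2 + error_sd^2)``.  Negative draws are
    clamped at zero (count attached as ``n_clamped``).
    """
    rng = np.random.default_rng(seed)
    biases = rater_biases or [0.0] * n_raters
    subj = rng.normal(mean_angle, between_sd, size=n_subjects)
    rows = []
    n_clamped = 0
    for si in range(n_subjects):
        sid = f"s{si:05d}"
        for ri in range(n_raters):
            val = subj[si] + biases[ri] + rng.normal(0.0, error_sd)
            if val < 0:
                val = 0.0
                n_clamped += 1
            rows.append((sid, "sim", f"r{ri + 1}", 1, val))
    pm = PairedMeasurements(
        pd.DataFrame(rows, columns=["subject_id", "method", "rater", "replicate", "angle"])
    )
    pm.n_clamped = n_clamped
    return pm


_LEVELS = [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)]


def simulate_offset_reports(
    offset_probs: dict[int, float],
    n_subjects: int,
    seed: int = 0,
) -> tuple[list[CobbReport], list[CobbReport]]:
    """Paired report lists whose end-vertebra level offsets follow a multinomial.

    Method B's major curve always runs T8→L2; method A's upper and lower end
    vertebrae are offset from B's by levels drawn independently from
    ``offset_probs`` (level offset → probability, positive = A more caudal).
    Only the fields used by the offset tabulation are populated.
    """
    rng = np.random.default_rng(seed)
    offs = sorted(offset_probs)
    p = np.array([offset_probs[o] for o in offs], float)
    p = p / p.sum()
    upper_b, lower_b = _LEVELS.index("T8"), _LEVELS.index("L2")

    def _report(sid: str, upper: str, lower: str) -> CobbReport:
        m = CobbMeasurement(
            segment=None, angle=30.0, upper_end_vertebra=upper,
            lower_end_vertebra=lower, upper_line=None, lower_line=None,
        )
        return CobbReport(
            subject_id=sid, measurements=(m,), major=m, minor=None,
            severity="moderate",
        )

    reports_a, reports_b = [], []
    for si in range(n_subjects):
        sid = f"s{si:05d}"
        du = offs[rng.choice(len(offs), p=p)]
        dl = offs[rng.choice(len(offs), p=p)]
        reports_b.append(_report(sid, _LEVELS[upper_b], _LEVELS[lower_b]))
        reports_a.append(_report(sid, _LEVELS[upper_b + du], _LEVELS[lower_b + dl]))
    return reports_a, reports_b
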