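"""Spinal centerline fitting and inflection-based curve segmentation.

The centerline is modelled as lateral displacement x as a function of the
craniocaudal coordinate y (the spine is assumed roughly vertical in the
radiograph).  It is fitted to the vertebral centroids by moving least squares
(MLS): at every query point on a dense y grid, a local quadratic is fitted by
weighted least squares with a Gaussian kernel, and its value at the query
point is taken.  A single global polynomial is then fitted to the sampled
curve; its analytic second derivative locates the inflection points, and sign
changes of the second derivative split the spine into oppositely bending
segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .annotation import SpineAnnotation
from .errors import ConditioningError, InsufficientDataError

__all__ = [
    "CenterlineFit",
    "CurveSegment",
    "fit_centerline_mls",
    "second_derivative_poly",
    "segment_by_inflection",
]


@dataclass(frozen=True)
class CenterlineFit:
    """A fitted spinal centerline sampled on a dense y grid.

    ``poly_coeffs`` and ``second_derivative`` are populated by
    :func:`second_derivative_poly`; they hold the global polynomial (ascending
    power order, original pixel coordinates) and its analytic second
    derivative evaluated on ``sample_y``.
    """

    sample_y: np.ndarray
    sample_x: np.ndarray
    bandwidth: float
    poly_degree: int | None = None
    poly_coeffs: np.ndarray | None = None
    second_derivative: np.ndarray | None = None


@dataclass(frozen=True)
class CurveSegment:
    """A maximal run of vertebrae bending in one direction.

    ``vertebra_indices`` indexes into ``SpineAnnotation.vertebrae`` and is
    contiguous; ``direction`` is the sign of the centerline's second
    derivative on the segment (+1 = bending toward larger x).
    """

    vertebra_indices: tuple[int, ...]
    direction: int
    boundary_y: tuple[float, float]


def _gaussian_weights(dy: np.ndarray, bandwidth: float) -> np.ndarray:
    return np.exp(-0.5 * (dy / bandwidth) ** 2)


def fit_centerline_mls(
    annotation: SpineAnnotation,
    bandwidth: float | str = "auto",
    grid_size: int = 200,
) -> CenterlineFit:
    """Fit the centerline through vertebral centroids by moving least squares.

    At each grid point y*, fits the quadratic q minimizing
    ``sum_i w(y_i - y*) * (x_i - q(y_i))^2`` over the centroids (x_i, y_i)
    with Gaussian weight of the given bandwidth, and evaluates q(y*).  The
    local basis reproduces polynomials up to degree 2 exactly for any
    bandwidth.

    Parameters
    ----------
    bandwidth:
        Gaussian kernel width in pixels, or ``"auto"`` for 2x the median
        inter-centroid spacing.
    grid_size:
        Number of grid samples spanning [min centroid y, max centroid y].
    """
    cents = annotation.centroids
    if len(cents) < 4:
        raise InsufficientDataError(
            f"subject {annotation.subject_id!r}: MLS needs >= 4 centroids"
        )
    xs, ys = cents[:, 0], cents[:, 1]
    spacing = float(np.median(np.diff(ys)))
    if bandwidth == "auto":
        h = 2.0 * spacing
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    grid = np.linspace(ys.min(), ys.max(), grid_size)
    fitted = np.empty_like(grid)
    for k, yq in enumerate(grid):
        dy = ys - yq
        w = _gaussian_weights(dy, h)
        # centered local basis: q(y) = a0 + a1*(y-yq) + a2*(y-yq)^2 ; a0 = q(yq)
        fitted[k] = _local_fit(dy, xs, w, degree=2)
    return CenterlineFit(sample_y=grid, sample_x=fitted, bandwidth=h)


def _local_fit(dy: np.ndarray, x: np.ndarray, w: np.ndarray, degree: int) -> float:
    sw = np.sqrt(w)
    basis = np.vander(dy, degree + 1, increasing=True)
    A = basis * sw[:, None]
    b = x * sw
    coef, _, rank, _ = np.linalg.lstsq(A, b)
    if rank < degree + 1:
        if degree == 2:
            warnings.warn(
                "singular local quadratic system; falling back to local linear",
                RuntimeWarning,
                stacklevel=3,
            )
            return _local_fit(dy, x, w, degree=1)
        # weighted mean as last resort
        return float(np.sum(w * x) / np.sum(w))
    return float(coef[0])


def second_derivative_poly(fit: CenterlineFit, degree: int = 6) -> CenterlineFit:
    """Fit a global polynomial to the sampled centerline and attach its
    analytic second derivative.

    The fit is performed on a centered/scaled ordinate for conditioning;
    coefficients are reported in original pixel coordinates (ascending power).
    """
    y, x = fit.sample_y, fit.sample_x
    if degree < 2:
        raise ValueError("polynomial degree must be >= 2")
    if degree >= len(y):
        raise ValueError("polynomial degree must be < number of grid samples")
    # Polynomial.fit maps y onto [-1, 1] internally before solving.
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            poly = np.polynomial.Polynomial.fit(y, x, deg=degree)
        except np.exceptions.RankWarning as e:
            raise ConditioningError(
                f"degenerate design matrix for degree-{degree} polynomial fit"
            ) from e
    d2 = poly.deriv(2)(y)
    coeffs = poly.convert().coef
    return replace(
        fit,
        poly_degree=degree,
        poly_coeffs=coeffs,
        second_derivative=np.asarray(d2, dtype=float),
    )


def _dead_band(fit: CenterlineFit) -> float:
    span = float(np.ptp(fit.sample_y))
    scale = max(float(np.ptp(fit.sample_x)), 1.0)
    return 1e-12 * scale / max(span, 1.0) ** 2


def segment_by_inflection(
    fit: CenterlineFit, annotation: SpineAnnotation
) -> list[CurveSegment]:
    """Split the spine into bending segments at inflection points.

    Boundaries sit at sign changes of the fitted second derivative (linearly
    interpolated between grid points).  Each vertebra joins the segment
    containing its centroid y.  Segments with fewer than 2 vertebrae are
    merged into the adjacent segment with larger mean curvature magnitude; a
    spine whose second derivative never changes sign yields one segment.
    """
    if fit.second_derivative is None:
        raise ValueError("fit has no second derivative; run second_derivative_poly")
    y, d2 = fit.sample_y, fit.second_derivative
    tol = _dead_band(fit)
    sign = np.where(np.abs(d2) <= tol, 0, np.sign(d2)).astype(int)

    # Fill dead-band zeros with the nearest non-zero sign so a flat stretch
    # does not spawn segments; an all-zero curve is one straight segment.
    nz = np.nonzero(sign)[0]
    if len(nz) == 0:
        filled = np.ones_like(sign)
    else:
        filled = sign.copy()
        last = sign[nz[0]]
        for i in range(len(filled)):
            if filled[i] == 0:
                filled[i] = last
            else:
                last = filled[i]

    # boundaries: indices i where filled[i] != filled[i+1]
    boundaries: list[float] = []
    for i in range(len(y) - 1):
        if filled[i] != filled[i + 1]:
            y0, y1, v0, v1 = y[i], y[i + 1], d2[i], d2[i + 1]
            if v1 != v0:
                yc = y0 + (0.0 - v0) / (v1 - v0) * (y1 - y0)
                yc = float(np.clip(yc, y0, y1))
            else:
                yc = float(0.5 * (y0 + y1))
            boundaries.append(yc)

    edges = [float(y[0])] + boundaries + [float(y[-1])]
    cents_y = annotation.centroids[:, 1]

    intervals: list[dict] = []
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        in_grid = (y >= lo) & (y <= hi)
        mean_d2 = float(np.mean(d2[in_grid])) if in_grid.any() else 0.0
        direction = 1 if mean_d2 >= 0 else -1
        if k == 0:
            members = np.nonzero(cents_y <= hi)[0]
        elif k == len(edges) - 2:
            members = np.nonzero(cents_y > lo)[0]
        else:
            members = np.nonzero((cents_y > lo) & (cents_y <= hi))[0]
        intervals.append(
            {
                "lo": lo,
                "hi": hi,
                "members": [int(m) for m in members],
                "mean_d2": mean_d2,
                "dir": direction,
            }
        )

    intervals = [iv for iv in intervals if iv["members"]]

    # merge under-populated segments into the neighbour with larger |mean d2|
    changed = True
    while changed and len(intervals) > 1:
        changed = False
        for k, iv in enumerate(intervals):
            if len(iv["members"]) >= 2:
                continue
            neighbours = []
            if k > 0:
                neighbours.append(k - 1)
            if k < len(intervals) - 1:
                neighbours.append(k + 1)
            target = max(neighbours, key=lambda j: abs(intervals[j]["mean_d2"]))
            tgt = intervals[target]
            tgt["members"] = sorted(tgt["members"] + iv["members"])
            tgt["lo"] = min(tgt["lo"], iv["lo"])
            tgt["hi"] = max(tgt["hi"], iv["hi"])
            del intervals[k]
            changed = True
            break

    # collapse any same-direction adjacency created by merging
    merged: list[dict] = []
    for iv in intervals:
        if merged and merged[-1]["dir"] == iv["dir"]:
            prev = merged[-1]
            prev["members"] = sorted(prev["members"] + iv["members"])
            prev["hi"] = iv["hi"]
            n0, n1 = len(prev["members"]), len(iv["members"])
            prev["mean_d2"] = (n0 * prev["mean_d2"] + n1 * iv["mean_d2"]) / (n0 + n1)
        else:
            merged.append(iv)

    return [
        CurveSegment(
            vertebra_indices=tuple(iv["members"]),
            direction=iv["dir"],
            boundary_y=(iv["lo"], iv["hi"]),
        )
        for iv in merged
    ]
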