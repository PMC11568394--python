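"""Reliability and method-agreement statistics for paired Cobb angles.

Implements the reliability battery of a method-comparison study: the
two-way random-effects, absolute-agreement, single-measurement intraclass
correlation coefficient ICC(2,1) with its F-based 95% confidence interval
and consistency bands; Bland-Altman 95% limits of agreement with the exact
1.96 z-multiplier; mean absolute error; and the strict <5° accuracy rate —
all optionally stratified by clinical severity of the reference measurement.

ICC(2,1) is computed from the classical mean-squares decomposition of the
fully crossed subject × rater table:

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

with MS_R, MS_C, MS_E the between-subject, between-rater and residual mean
squares, n subjects and k raters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import PairedMeasurements
from .cobb import classify_severity
from .errors import DesignError, PairingError

__all__ = [
    "ICCResult",
    "BlandAltmanResult",
    "StratumStats",
    "AgreementReport",
    "icc2_1",
    "icc_absolute_agreement",
    "bland_altman",
    "accuracy_rate",
    "mean_absolute_error",
    "stratified_agreement",
    "icc_band",
]

SEVERITY_ORDER = ["mild", "moderate", "severe"]


def icc_band(estimate: float) -> str:
    """Consistency band for an ICC estimate.

    below-poor < 0.250 <= poor < 0.500 <= moderate < 0.700 <= good < 0.900
    <= excellent.
    """
    if estimate >= 0.900:
        return "excellent"
    if estimate >= 0.700:
        return "good"
    if estimate >= 0.500:
        return "moderate"
    if estimate >= 0.250:
        return "poor"
    return "below-poor"


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    band: str
    model: str
    p_value: float
    n_subjects: int
    n_columns: int

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "band": self.band,
            "model": self.model,
            "p_value": self.p_value,
            "n_subjects": self.n_subjects,
            "n_columns": self.n_columns,
        }


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    pair_means: np.ndarray = field(repr=False, compare=False, default=None)
    differences: np.ndarray = field(repr=False, compare=False, default=None)

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
        }


def icc2_1(matrix: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) — two-way random effects, absolute agreement, single measures.

    ``matrix`` is the complete n-subjects × k-columns table (columns are
    raters or replicates).  The point estimate comes from the mean-squares
    decomposition above; the confidence interval is the standard F-based
    interval and the p-value tests H0: ICC = 0 via F = MS_R / MS_E on
    (n-1, (n-1)(k-1)) degrees of freedom.
    """
    x = np.asarray(matrix, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DesignError("ICC needs an n x k table with n >= 2 subjects, k >= 2 columns")
    if not np.all(np.isfinite(x)):
        raise DesignError("ICC table contains missing values; the design must be complete")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DesignError("zero total variance; ICC undefined")
    if ss_rows == 0:
        import warnings

        warnings.warn(
            "zero between-subject variance; ICC estimate is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    est = (msr - mse) / denom

    # F-based CI (two-way random, absolute agreement, single measures)
    if mse == 0 and msc == msr:
        lo = hi = est
        p = 0.0
    else:
        a = (k * est) / (n * (1.0 - est)) if est < 1.0 else np.inf
        b = 1.0 + (k * est * (n - 1.0)) / (n * (1.0 - est)) if est < 1.0 else np.inf
        if np.isinf(a) or mse == 0:
            lo = hi = est
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
        if mse > 0:
            f_obs = msr / mse
            p = float(sps.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))
        else:
            p = 0.0
    lo = float(min(lo, est))
    hi = float(max(hi, est))
    return ICCResult(
        estimate=float(est),
        ci_low=lo,
        ci_high=hi,
        band=icc_band(float(est)),
        model="ICC(2,1) two-way random, absolute agreement, single measures",
        p_value=p,
        n_subjects=n,
        n_columns=k,
    )


def _complete_pivot(
    data: PairedMeasurements, columns: str, method: str | None, rater: str | None
) -> pd.DataFrame:
    df = data.frame
    if method is not None:
        df = df[df["method"] == method]
    if rater is not None:
        df = df[df["rater"] == rater]
    if df.empty:
        raise DesignError("no measurements after filtering")
    counts = df.pivot_table(
        index="subject_id", columns=columns, values="angle", aggfunc="count"
    )
    bad = counts.isna() | (counts != 1)
    if bad.to_numpy().any():
        cells = [
            f"({s}, {c})"
            for s in counts.index
            for c in counts.columns
            if bad.loc[s, c]
        ]
        raise DesignError(
            f"incomplete crossed design; missing/duplicated cells: {cells[:10]}"
            + (" ..." if len(cells) > 10 else "")
        )
    return df.pivot_table(index="subject_id", columns=columns, values="angle")


def icc_absolute_agreement(
    data: PairedMeasurements,
    grouping: str = "raters",
    method: str | None = None,
    rater: str | None = None,
) -> ICCResult:
    """ICC(2,1) over a crossed design extracted from a measurement table.

    ``grouping="raters"`` builds the subject × rater table (inter-observer
    reliability, optionally for one method); ``grouping="replicates"`` builds
    subject × replicate for one rater (intra-observer repeatability).
    """
    if grouping == "raters":
        wide = _complete_pivot(data, "rater", method, None)
    elif grouping == "replicates":
        wide = _complete_pivot(data, "replicate", method, rater)
    else:
        raise ValueError("grouping must be 'raters' or 'replicates'")
    return icc2_1(wide.to_numpy())


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement of two paired measurement vectors.

    Differences are ``a - b``; the limits of agreement are
    ``mean ± 1.96 × SD`` with the sample SD (n−1 denominator) and the exact
    1.96 z-multiplier.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError(f"paired vectors must match: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise PairingError("Bland-Altman needs at least 3 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=len(d),
        pair_means=(a + b) / 2.0,
        differences=d,
    )


def accuracy_rate(
    a: np.ndarray, b: np.ndarray, threshold: float = 5.0
) -> tuple[float, int]:
    """Fraction of pairs with ``|a - b| < threshold`` (strict), plus the count."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError(f"paired vectors must match: {a.shape} vs {b.shape}")
    hits = np.abs(a - b) < threshold
    return float(hits.mean()), int(hits.sum())


def mean_absolute_error(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError(f"paired vectors must match: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


@dataclass(frozen=True)
class StratumStats:
    n: int
    bland_altman: BlandAltmanResult | None
    mae: float | None
    accuracy: float | None
    accurate_n: int | None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bland_altman": self.bland_altman.to_dict() if self.bland_altman else None,
            "mae": self.mae,
            "accuracy": self.accuracy,
            "accurate_n": self.accurate_n,
        }


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement battery of one or more test methods against a reference."""

    reference_method: str
    icc: dict[str, ICCResult]
    overall: dict[str, StratumStats]
    strata: dict[str, dict[str, StratumStats]]  # method -> severity -> stats
    accuracy_threshold: float

    def to_dict(self) -> dict:
        return {
            "reference_method": self.reference_method,
            "accuracy_threshold": self.accuracy_threshold,
            "methods": {
                m: {
                    "icc": self.icc[m].to_dict(),
                    "overall": self.overall[m].to_dict(),
                    "strata": {
                        s: st.to_dict() for s, st in self.strata[m].items()
                    },
                }
                for m in self.icc
            },
        }

    def to_frame(self) -> pd.DataFrame:
        """Flat CSV-friendly view: one row per method × stratum."""
        rows = []
        for m in self.icc:
            for stratum, st in [("overall", self.overall[m])] + list(
                self.strata[m].items()
            ):
                ba = st.bland_altman
                rows.append(
                    {
                        "method": m,
                        "stratum": stratum,
                        "n": st.n,
                        "icc": self.icc[m].estimate if stratum == "overall" else None,
                        "mean_diff": ba.mean_diff if ba else None,
                        "sd_diff": ba.sd_diff if ba else None,
                        "loa_low": ba.loa_low if ba else None,
                        "loa_high": ba.loa_high if ba else None,
                        "mae": st.mae,
                        "accuracy": st.accuracy,
                        "accurate_n": st.accurate_n,
                    }
                )
        return pd.DataFrame(rows)


def _stratum_stats(a: np.ndarray, b: np.ndarray, threshold: float) -> StratumStats:
    n = len(a)
    if n == 0:
        return StratumStats(0, None, None, None, None)
    ba = bland_altman(a, b) if n >= 3 else None
    rate, cnt = accuracy_rate(a, b, threshold)
    return StratumStats(n, ba, mean_absolute_error(a, b), rate, cnt)


def stratified_agreement(
    measurements: PairedMeasurements,
    reference_method: str,
    accuracy_threshold: float = 5.0,
) -> AgreementReport:
    """Agreement battery of every method against the reference, overall and
    within severity strata.

    Angles are averaged over raters and replicates to one value per subject
    and method.  Severity strata (mild/moderate/severe) are assigned from the
    reference method's angle, mirroring grouping by the manual measurement.
    """
    df = measurements.frame
    if reference_method not in df["method"].unique():
        raise PairingError(f"reference method {reference_method!r} not present")
    per = df.groupby(["subject_id", "method"])["angle"].mean().unstack("method")
    if per[reference_method].isna().any():
        missing = per.index[per[reference_method].isna()][0]
        raise PairingError(
            f"reference method missing for subject {missing!r}"
        )
    ref = per[reference_method]
    severity = ref.map(classify_severity)

    icc: dict[str, ICCResult] = {}
    overall: dict[str, StratumStats] = {}
    strata: dict[str, dict[str, StratumStats]] = {}
    for m in per.columns:
        if m == reference_method:
            continue
        if per[m].isna().any():
            missing = per.index[per[m].isna()][0]
            raise PairingError(f"method {m!r} missing for subject {missing!r}")
        a = per[m].to_numpy()
        b = ref.to_numpy()
        icc[m] = icc2_1(np.column_stack([a, b]))
        overall[m] = _stratum_stats(a, b, accuracy_threshold)
        strata[m] = {}
        for s in SEVERITY_ORDER:
            mask = (severity == s).to_numpy()
            strata[m][s] = _stratum_stats(a[mask], b[mask], accuracy_threshold)
    return AgreementReport(
        reference_method=reference_method,
        icc=icc,
        overall=overall,
        strata=strata,
        accuracy_threshold=accuracy_threshold,
    )
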