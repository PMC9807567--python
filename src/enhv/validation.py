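"""Model validation by intraclass correlation (ICC).

A normative model is validated on an independent healthy cohort by
treating, for each region, the measured volume and the model's ENHV as two
"raters" of the same n subjects and computing the intraclass correlation
for a two-way model, single measures, absolute agreement — ICC(A,1) in
McGraw & Wong's nomenclature.  Absolute agreement is essential here: a
model that is perfectly correlated with the measurements but biased by a
constant offset is *not* a valid normative reference, and ICC(A,1)
penalises exactly that bias (unlike the Pearson correlation).

The point estimate uses the two-way crossed ANOVA mean squares (n subjects
× k = 2 raters)::

    ICC(A,1) = (MS_rows − MS_err) /
               (MS_rows + (k−1)·MS_err + (k/n)·(MS_cols − MS_err))

with the standard F-based confidence interval and the MS_rows/MS_err
F-test for ICC > 0.  Reliability bands: < 0.4 poor, [0.4, 0.6) fair,
[0.6, 0.75) good, [0.75, 1.0] excellent; a model is considered valid for a
region when ICC > 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as st

from .exceptions import AnalysisError
from .model import NormativeVolumeResults, _cohort_frame
from .rois import RoiId

#: ICC above which a region's normative equation is considered valid.
VALIDITY_THRESHOLD = 0.4

#: Left-closed reliability bands on the ICC scale.
BANDS = (
    (0.75, "excellent"),
    (0.6, "good"),
    (0.4, "fair"),
    (-np.inf, "poor"),
)


@dataclass(frozen=True)
class IccResult:
    """ICC(A,1) for one region: point estimate, 95% CI, p, band, validity."""

    roi: RoiId
    icc: float
    ci_low: float
    ci_high: float
    p: float
    band: str
    valid: bool


def classify_icc(icc: float) -> str:
    """Reliability band of an ICC value.

    Bands are left-closed: 0.4 → fair, 0.6 → good, 0.75 → excellent.
    Negative estimates (possible under ICC(A,1)) classify as poor.
    """
    if icc > 1 + 1e-9:
        raise AnalysisError(f"ICC cannot exceed 1, got {icc}")
    icc = min(icc, 1.0)  # forgive float round-off at perfect agreement
    for lower, name in BANDS:
        if icc >= lower:
            return name
    raise AssertionError("unreachable")  # pragma: no cover


def icc_absolute_single(x, y, confidence: float = 0.95):
    """ICC(A,1) between two equal-length rating vectors.

    Returns ``(icc, ci_low, ci_high, p)``.  The CI is the McGraw & Wong
    F-based interval with Satterthwaite denominator degrees of freedom;
    the p-value tests ICC > 0 via F = MS_rows / MS_err on
    (n−1, (n−1)(k−1)) df.

    Raises :class:`AnalysisError` on unequal lengths, n < 5, or constant
    input (the ICC is undefined without between-subject variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("icc_absolute_single requires two equal-length 1-d vectors")
    n = len(x)
    if n < 5:
        raise AnalysisError(f"need at least 5 paired observations, got {n}")
    data = np.column_stack([x, y])
    if np.ptp(data) == 0 or (np.ptp(x) == 0 and np.ptp(y) == 0):
        raise AnalysisError("ICC undefined for constant ratings")
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise AnalysisError("degenerate ANOVA decomposition (zero denominator)")
    icc = (msr - mse) / denom

    # H0: ICC = 0
    if mse == 0:
        p = 0.0
    else:
        f_obs = msr / mse
        p = float(st.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))

    # McGraw & Wong CI
    alpha = 1 - confidence
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        ci_low, ci_high = 1.0, 1.0
    else:
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den if v_den > 0 else 1.0
        f_l = st.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = st.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    return float(icc), float(ci_low), float(ci_high), float(p)


def validate_model(results: NormativeVolumeResults, cohort) -> list[IccResult]:
    """Validate a model on a healthy cohort disjoint from the fitting one.

    For every modelled region, computes ICC(A,1) between measured volumes
    and model ENHVs across subjects.  The caller is responsible for the
    cohorts actually being disjoint.
    """
    frame = _cohort_frame(cohort)
    predicted = results.predict_frame(frame)
    out = []
    for roi in results.equations:
        measured = frame[str(roi)].to_numpy(float)
        icc, lo, hi, p = icc_absolute_single(measured, predicted[str(roi)].to_numpy())
        out.append(IccResult(roi=roi, icc=icc, ci_low=lo, ci_high=hi, p=p,
                             band=classify_icc(icc), valid=icc > VALIDITY_THRESHOLD))
    return out


def validation_report(results_list: list[IccResult]) -> dict:
    """JSON-ready per-region validation report (ICC, CI, p, band, valid)."""
    return {
        str(r.roi): {
            "icc": r.icc,
            "ci95": [r.ci_low, r.ci_high],
            "p": r.p,
            "band": r.band,
            "valid": r.valid,
        }
        for r in results_list
    }
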