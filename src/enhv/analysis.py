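"""ENHV-adjusted volumes and the patient-vs-control analysis battery.

The central quantity is the *ENHV-adjusted volume*::

    adjusted (% of ENHV) = 100 · measured volume / ENHV

100 means the region is exactly as large as expected for a healthy person
of the same ICV, age and sex; ``percent_loss = 100 − adjusted`` quantifies
atrophy.  The conventional comparator, the *proportions method*
(measured / ICV), is computed alongside.

The battery applied to a diffuse-axonal-injury (DAI) cohort versus healthy
controls comprises:

* Mann–Whitney U group comparisons with Bonferroni correction
  (:func:`compare_groups`);
* within-patient regional comparisons — Wilcoxon signed-rank of whole
  brainstem vs cerebrum, Friedman across the three brainstem subfields,
  Bonferroni-corrected pairwise Wilcoxon tests
  (:func:`within_subject_region_comparison`);
* Pearson / first-order partial correlation of posttraumatic-amnesia (PTA)
  duration with adjusted volumes, controlling for time since injury
  (:func:`pta_correlation`).

All tests are two-tailed.  Exact nonparametric p-values are used for small
tie-free samples (both groups ≤ 25, resp. n ≤ 25 pairs); the normal
approximation with tie correction otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as st

from .exceptions import AnalysisError
from .model import NormativeVolumeResults, _cohort_frame
from .rois import BRAINSTEM_SUBFIELDS, RoiId

#: Largest per-group sample size for which exact (enumeration-based)
#: Mann–Whitney / Wilcoxon p-values are used when the data are tie-free.
EXACT_THRESHOLD = 25

#: Default Bonferroni family for the group comparison: ICV plus the five
#: analysis regions, i.e. the six tested quantities.
DEFAULT_FAMILY_SIZE = 6


# ---------------------------------------------------------------------------
# elementary quantities


def enhv_adjusted_volume(measured, enhv):
    """Measured volume as a percentage of ENHV (broadcasts over arrays)."""
    measured = np.asarray(measured, dtype=float)
    enhv = np.asarray(enhv, dtype=float)
    if np.any(measured <= 0) or np.any(enhv <= 0):
        raise AnalysisError("measured volume and ENHV must be positive")
    out = 100.0 * measured / enhv
    return out if out.ndim else float(out)


def icv_proportion_volume(measured, icv):
    """Conventional proportions-method correction: measured / ICV."""
    measured = np.asarray(measured, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if np.any(icv <= 0):
        raise AnalysisError("icv must be positive")
    out = measured / icv
    return out if out.ndim else float(out)


def adjusted_volume_table(results: NormativeVolumeResults, cohort) -> pd.DataFrame:
    """Per-subject, per-region adjusted volumes.

    Returns a long-format DataFrame with columns ``subject_id, roi,
    measured, enhv, adjusted, percent_loss, icv_proportion`` (plus the
    clinical covariates carried through when present).
    """
    frame = _cohort_frame(cohort).reset_index(drop=True)
    predicted = results.predict_frame(frame)
    records = []
    carry = [c for c in ("pta_weeks", "time_since_injury_months", "group_label")
             if c in frame.columns]
    for roi in results.equations:
        measured = frame[str(roi)].to_numpy(float)
        enhv = predicted[str(roi)].to_numpy(float)
        adjusted = enhv_adjusted_volume(measured, enhv)
        block = pd.DataFrame({
            "subject_id": frame["subject_id"],
            "roi": str(roi),
            "measured": measured,
            "enhv": enhv,
            "adjusted": adjusted,
            "percent_loss": 100.0 - adjusted,
            "icv_proportion": icv_proportion_volume(measured, frame["icv"].to_numpy(float)),
        })
        for c in carry:
            block[c] = frame[c].to_numpy()
        records.append(block)
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class GroupComparisonResult:
    """Mann–Whitney comparison of one quantity between two groups."""

    name: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u_stat: float
    p_raw: float
    p_bonferroni: float
    family_size: int

    @property
    def significant(self) -> bool:
        return self.p_bonferroni < 0.05


def _mannwhitney(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if tie_free and max(len(a), len(b)) <= EXACT_THRESHOLD else "asymptotic"
    res = st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(group_a: pd.DataFrame, group_b: pd.DataFrame, columns,
                   family_size: int = DEFAULT_FAMILY_SIZE) -> list[GroupComparisonResult]:
    """Two-sided Mann–Whitney U per column, Bonferroni-corrected.

    ``group_a``/``group_b`` are subject-level DataFrames (e.g. DAI patients
    and healthy controls) sharing ``columns`` — typically the ICV plus the
    measured or adjusted volumes of the five regions.  ``family_size``
    defaults to 6 (ICV + five regions) and must cover the number of tests.
    """
    columns = list(columns)
    if len(group_a) == 0 or len(group_b) == 0:
        raise AnalysisError("both groups must be non-empty")
    if family_size < len(columns):
        raise AnalysisError(
            f"family_size {family_size} smaller than number of tests {len(columns)}"
        )
    out = []
    for col in columns:
        a = group_a[col].to_numpy(float)
        b = group_b[col].to_numpy(float)
        u, p = _mannwhitney(a, b)
        out.append(GroupComparisonResult(
            name=col,
            mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
            mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
            u_stat=u, p_raw=p,
            p_bonferroni=min(1.0, family_size * p),
            family_size=family_size,
        ))
    return out


# ---------------------------------------------------------------------------
# within-subject regional comparisons


def _wilcoxon(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    if np.all(d == 0):
        return 0.0, 1.0
    tie_free = len(np.unique(np.abs(d[d != 0]))) == np.count_nonzero(d)
    method = "exact" if tie_free and len(d) <= EXACT_THRESHOLD else "approx"
    res = st.wilcoxon(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def within_subject_region_comparison(adjusted: pd.DataFrame) -> dict:
    """Within-patient comparison of adjusted volumes across regions.

    ``adjusted`` is the long table from :func:`adjusted_volume_table`
    restricted to one group.  Computes (a) Wilcoxon signed-rank of whole
    brainstem vs cerebrum, (b) the Friedman test across the three
    brainstem subfields, and (c) the three pairwise Wilcoxon tests with
    Bonferroni correction (m = 3).  Subjects with incomplete regional data
    are dropped with a warning.
    """
    wide = adjusted.pivot(index="subject_id", columns="roi", values="adjusted")
    needed = [str(r) for r in (RoiId.whole_brainstem, RoiId.cerebrum, *BRAINSTEM_SUBFIELDS)]
    missing_cols = [c for c in needed if c not in wide.columns]
    if missing_cols:
        raise AnalysisError(f"adjusted table lacks regions {missing_cols}")
    complete = wide.dropna(subset=needed)
    if len(complete) < len(wide):
        warnings.warn(
            f"dropping {len(wide) - len(complete)} subject(s) with incomplete "
            "regional data from within-subject comparison", stacklevel=2,
        )
    if len(complete) < 5:
        raise AnalysisError("need at least 5 complete subjects")

    w_stat, w_p = _wilcoxon(complete[str(RoiId.whole_brainstem)],
                            complete[str(RoiId.cerebrum)])
    sub = [complete[str(r)].to_numpy(float) for r in BRAINSTEM_SUBFIELDS]
    f_stat, f_p = st.friedmanchisquare(*sub)
    pairs = {}
    names = [str(r) for r in BRAINSTEM_SUBFIELDS]
    for i in range(3):
        for j in range(i + 1, 3):
            s, p = _wilcoxon(complete[names[i]], complete[names[j]])
            pairs[f"{names[i]}_vs_{names[j]}"] = {
                "statistic": s, "p_raw": p, "p_bonferroni": min(1.0, 3 * p),
            }
    return {
        "n": int(len(complete)),
        "whole_brainstem_vs_cerebrum": {"statistic": w_stat, "p": w_p},
        "friedman_subfields": {"statistic": float(f_stat), "p": float(f_p)},
        "pairwise_subfields": pairs,
    }


# ---------------------------------------------------------------------------
# correlation with injury severity


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson or first-order partial correlation for one region."""

    roi: RoiId
    r: float
    p: float
    n: int
    method: str  # pearson | partial | proportions_partial
    covariate: Optional[str] = None


def partial_correlation(x, y, z):
    """First-order partial correlation r_xy·z with two-sided p on n−3 df.

    Closed form: (r_xy − r_xz·r_yz) / √((1−r_xz²)(1−r_yz²)) — identical to
    the Pearson correlation of the OLS residuals of x and y on z.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = len(x)
    if n < 5:
        raise AnalysisError(f"need at least 5 observations, got {n}")
    if np.ptp(z) == 0:
        # constant covariate: residualization is a no-op
        r, p = st.pearsonr(x, y)
        return float(r), float(p)
    r_xy = st.pearsonr(x, y)[0]
    r_xz = st.pearsonr(x, z)[0]
    r_yz = st.pearsonr(y, z)[0]
    denom = np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    if denom == 0:
        raise AnalysisError("covariate perfectly correlated with a variable")
    r = (r_xy - r_xz * r_yz) / denom
    df = n - 3
    if abs(r) >= 1:
        return float(np.clip(r, -1, 1)), 0.0
    t = r * np.sqrt(df / (1 - r ** 2))
    p = 2 * st.t.sf(abs(t), df)
    return float(r), float(p)


def pta_correlation(adjusted: pd.DataFrame, control_for_tsi: bool = True,
                    use_proportions: bool = False) -> list[CorrelationResult]:
    """Correlate PTA duration with per-region adjusted volumes.

    ``adjusted`` is the long table from :func:`adjusted_volume_table` for
    the patient group; it must carry ``pta_weeks`` (and
    ``time_since_injury_months`` when ``control_for_tsi``).  With
    ``use_proportions`` the conventional ICV-proportion volume replaces the
    ENHV-adjusted volume.  P-values are two-sided and uncorrected.
    """
    value_col = "icv_proportion" if use_proportions else "adjusted"
    if "pta_weeks" not in adjusted.columns or adjusted["pta_weeks"].isna().any():
        raise AnalysisError("PTA duration required for every subject")
    if control_for_tsi and (
        "time_since_injury_months" not in adjusted.columns
        or adjusted["time_since_injury_months"].isna().any()
    ):
        raise AnalysisError("time since injury required for every subject when controlling")
    out = []
    for roi_name, block in adjusted.groupby("roi", sort=False):
        pta = block["pta_weeks"].to_numpy(float)
        val = block[value_col].to_numpy(float)
        n = len(block)
        if n < 5:
            raise AnalysisError(f"{roi_name}: need at least 5 subjects, got {n}")
        if control_for_tsi:
            tsi = block["time_since_injury_months"].to_numpy(float)
            r, p = partial_correlation(pta, val, tsi)
            method = "proportions_partial" if use_proportions else "partial"
            cov = "time_since_injury_months"
        else:
            r, p = st.pearsonr(pta, val)
            method = "pearson"
            cov = None
        out.append(CorrelationResult(roi=RoiId(roi_name), r=float(r), p=float(p),
                                     n=n, method=method, covariate=cov))
    return out


# ---------------------------------------------------------------------------
# descriptive summaries


def summarize_loss(adjusted: pd.DataFrame, group_label: Optional[str] = None) -> pd.DataFrame:
    """Per-region mean ± sd of adjusted volume and mean percent loss.

    ``adjusted`` is the long table; optionally filtered to one
    ``group_label``.  Mean percent loss is ``100 − mean(adjusted)``.
    """
    table = adjusted
    if group_label is not None:
        table = table[table["group_label"] == group_label]
    if len(table) == 0:
        raise AnalysisError("no subjects to summarize")
    rows = []
    for roi_name, block in table.groupby("roi", sort=False):
        vals = block["adjusted"].to_numpy(float)
        rows.append({
            "roi": roi_name,
            "n": len(vals),
            "mean_adjusted": float(vals.mean()),
            "sd_adjusted": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "mean_percent_loss": float(100.0 - vals.mean()),
        })
    return pd.DataFrame(rows).set_index("roi")
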