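"""Normative model of expected normal healthy volume (ENHV).

The model estimates, for a healthy adult of given intracranial volume
(ICV, mm³), age (years) and sex (male = 1, female = 0), the expected
volume of five brain regions: whole brainstem, medulla, pons, midbrain and
cerebrum.  Each region's equation takes one of three forms::

    form 1:  ENHV = a·ICV + b                                   (pooled sexes)
    form 2:  ENHV = (1−sex)·(a_f·ICV + b_f) + sex·(a_m·ICV + b_m)
    form 3:  ENHV = (1−sex)·(a_f·ICV + b_f·age + c_f)
             + sex·(a_m·ICV + b_m·age + c_m)

A subject's measured volume divided by their ENHV ("ENHV-adjusted volume",
see :mod:`enhv.analysis`) expresses regional volume as a percentage of what
a healthy person of the same head size, age and sex would be expected to
have — a stricter head-size correction than the conventional volume/ICV
proportion, which wrongly assumes regional volume is proportional to ICV
(the fitted intercepts are positive for every region).

The model-building procedure mirrors how the published coefficient set was
derived on 182 healthy adults:

1. *Screening* — Pearson correlation of each regional volume with age and
   with ICV; a predictor enters the regression only if its correlation is
   significant at strict two-sided p < 0.05.  ICV is always retained.
2. *Interaction test* — per region, the linear model
   ``volume ~ sex + ICV + sex:ICV`` is fitted and the sex×ICV interaction
   is F-tested on (1, n−4) degrees of freedom; a significant interaction
   triggers sex-stratified regression.
3. *Equation assembly* — ordinary least squares per sex subgroup (or
   pooled), fused with the sex dummy into a single equation.

:class:`NormativeVolumeModel` is the fitting entry point;
:func:`published_model` returns the printed coefficient set (exactly as
published, i.e. at 3 significant figures — predictions carry that
rounding).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .data import SubjectMorphometry, require_columns, subjects_to_frame
from .exceptions import ModelInputError
from .rois import ANALYSIS_ROIS, RoiId

#: Significance threshold used throughout the building procedure (strict:
#: a correlation with p exactly 0.050 does not qualify).
ALPHA = 0.05

# The published coefficient set, kept as printed (3 significant figures).
# Decimal text avoids any float round-trip drift in serialization.
_PUBLISHED_TEXT: dict[RoiId, dict[str, str]] = {
    RoiId.medulla: {"a": "1.35E-03", "b": "2.65E+03"},
    RoiId.whole_brainstem: {
        "a_f": "3.92E-03", "b_f": "1.80E+04", "a_m": "9.50E-03", "b_m": "1.10E+04",
    },
    RoiId.pons: {
        "a_f": "2.01E-03", "b_f": "1.08E+04", "a_m": "5.74E-03", "b_m": "6.06E+03",
    },
    RoiId.midbrain: {
        "a_f": "1.19E-03", "b_f": "3.55E+03", "a_m": "2.20E-03", "b_m": "2.30E+03",
    },
    RoiId.cerebrum: {
        "a_f": "2.90E-01", "b_f": "-1.54E+03", "c_f": "6.03E+05",
        "a_m": "4.41E-01", "b_m": "-2.01E+03", "c_m": "4.11E+05",
    },
}

_FORM_KEYS = {
    1: ("a", "b"),
    2: ("a_f", "b_f", "a_m", "b_m"),
    3: ("a_f", "b_f", "c_f", "a_m", "b_m", "c_m"),
}


@dataclass(frozen=True)
class RoiModelEquation:
    """One region's ENHV equation.

    ``coefficients`` maps the form's coefficient names (see
    :data:`_FORM_KEYS`) to values.  A pooled fit that includes age (a case
    that never arises with the published calibration but can with other
    cohorts) is stored as a degenerate form 3 with identical female and
    male blocks and ``sex_stratified=False``.
    """

    roi: RoiId
    form: int
    coefficients: dict[str, float]
    sex_stratified: bool = True
    stderr: Optional[dict[str, float]] = None

    def __post_init__(self):
        if self.form not in _FORM_KEYS:
            raise ModelInputError(f"unknown equation form {self.form}")
        missing = [k for k in _FORM_KEYS[self.form] if k not in self.coefficients]
        if missing:
            raise ModelInputError(
                f"form {self.form} equation for {self.roi} missing coefficients {missing}"
            )
        if self.form == 1 and self.sex_stratified:
            raise ModelInputError("form 1 equations are never sex-stratified")

    @property
    def uses_age(self) -> bool:
        return self.form == 3

    def predict(self, icv, age=None, sex=None):
        """Evaluate the equation.  Broadcasts over array inputs."""
        icv = np.asarray(icv, dtype=float)
        if np.any(icv <= 0):
            raise ModelInputError("icv must be positive")
        c = self.coefficients
        if self.form == 1:
            return c["a"] * icv + c["b"]
        if sex is None:
            raise ModelInputError(f"{self.roi}: sex (0/1) required for form {self.form}")
        sex = np.asarray(sex)
        if not np.all(np.isin(sex, (0, 1))):
            raise ModelInputError("sex must be coded 0 (female) or 1 (male)")
        sex = sex.astype(float)
        if self.form == 2:
            female = c["a_f"] * icv + c["b_f"]
            male = c["a_m"] * icv + c["b_m"]
        else:
            if age is None:
                raise ModelInputError(f"{self.roi}: age required for form 3")
            age = np.asarray(age, dtype=float)
            if np.any(age <= 0):
                raise ModelInputError("age must be positive")
            female = c["a_f"] * icv + c["b_f"] * age + c["c_f"]
            male = c["a_m"] * icv + c["b_m"] * age + c["c_m"]
        result = (1.0 - sex) * female + sex * male
        return result if result.ndim else float(result)


@dataclass(frozen=True)
class ScreeningResult:
    """Pearson screening of one region's volume against age and ICV."""

    roi: RoiId
    r_age: float
    p_age: float
    r_icv: float
    p_icv: float

    @property
    def include_age(self) -> bool:
        return self.p_age < ALPHA

    @property
    def include_icv(self) -> bool:
        return self.p_icv < ALPHA


@dataclass(frozen=True)
class InteractionResult:
    """Sex × ICV interaction F-test for one region.

    The "two-way ANOVA" is the linear model with continuous ICV
    (``volume ~ sex + ICV + sex:ICV``), whose interaction F-test has
    (1, n−4) degrees of freedom.
    """

    roi: RoiId
    f_stat: float
    df_num: int
    df_den: int
    p: float

    @property
    def stratify(self) -> bool:
        return self.p < ALPHA


def _cohort_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        return cohort
    return subjects_to_frame(list(cohort))


def screen_variables(cohort, roi: RoiId) -> ScreeningResult:
    """Pearson-correlate a region's volume with age and with ICV (pooled
    over sexes), returning two-sided p-values and inclusion flags."""
    frame = _cohort_frame(cohort)
    require_columns(frame, ["age", "icv", str(roi)])
    vol = frame[str(roi)].to_numpy(float)
    for name in ("age", "icv", str(roi)):
        if np.std(frame[name].to_numpy(float)) == 0:
            raise ModelInputError(f"zero-variance column {name!r} in screening")
    r_age, p_age = st.pearsonr(frame["age"].to_numpy(float), vol)
    r_icv, p_icv = st.pearsonr(frame["icv"].to_numpy(float), vol)
    return ScreeningResult(roi=roi, r_age=float(r_age), p_age=float(p_age),
                           r_icv=float(r_icv), p_icv=float(p_icv))


def test_sex_icv_interaction(cohort, roi: RoiId) -> InteractionResult:
    """F-test of the sex×ICV interaction in ``volume ~ sex + ICV + sex:ICV``."""
    frame = _cohort_frame(cohort)
    require_columns(frame, ["sex", "icv", str(roi)])
    sex = frame["sex"].to_numpy(float)
    counts = [int((sex == s).sum()) for s in (0, 1)]
    if min(counts) == 0:
        raise ModelInputError(
            f"{roi}: cohort contains a single sex; fit a pooled (form 1) equation instead"
        )
    if min(counts) < 5:
        raise ModelInputError(
            f"{roi}: need at least 5 subjects of each sex for the interaction test"
        )
    icv = frame["icv"].to_numpy(float)
    y = frame[str(roi)].to_numpy(float)
    X = np.column_stack([np.ones_like(icv), sex, icv, sex * icv])
    res = sm.OLS(y, X).fit()
    t_int = res.tvalues[3]
    f_stat = float(t_int ** 2)
    df_den = len(y) - 4
    p = float(st.f.sf(f_stat, 1, df_den))
    return InteractionResult(roi=roi, f_stat=f_stat, df_num=1, df_den=df_den, p=p)


def _ols(y, cols):
    X = np.column_stack(cols + [np.ones_like(y)])
    if len(y) < X.shape[1] + 1:
        raise ModelInputError(
            f"subgroup of {len(y)} subjects too small for {X.shape[1]} parameters"
        )
    return sm.OLS(y, X).fit()


def fit_equation(cohort, roi: RoiId, screening: ScreeningResult,
                 interaction: Optional[InteractionResult]) -> RoiModelEquation:
    """Assemble a region's equation from its screening and interaction
    results by ordinary least squares.

    ICV is always an explanatory variable; if its screening correlation is
    not significant a warning is emitted but ICV is retained.  Age enters
    only when screened in.  A significant interaction yields per-sex fits
    fused with the sex dummy; otherwise a pooled fit.
    """
    frame = _cohort_frame(cohort)
    if not screening.include_icv:
        warnings.warn(
            f"{roi}: ICV-volume correlation not significant "
            f"(p={screening.p_icv:.3g}); ICV retained as a predictor anyway",
            stacklevel=2,
        )
    stratify = interaction.stratify if interaction is not None else False
    use_age = screening.include_age
    y_all = frame[str(roi)].to_numpy(float)

    if stratify:
        coeffs: dict[str, float] = {}
        errs: dict[str, float] = {}
        for sex_code, suffix in ((0, "f"), (1, "m")):
            sub = frame[frame["sex"] == sex_code]
            y = sub[str(roi)].to_numpy(float)
            cols = [sub["icv"].to_numpy(float)]
            if use_age:
                cols.append(sub["age"].to_numpy(float))
            res = _ols(y, cols)
            if use_age:
                coeffs[f"a_{suffix}"], coeffs[f"b_{suffix}"], coeffs[f"c_{suffix}"] = map(float, res.params)
                errs[f"a_{suffix}"], errs[f"b_{suffix}"], errs[f"c_{suffix}"] = map(float, res.bse)
            else:
                coeffs[f"a_{suffix}"], coeffs[f"b_{suffix}"] = map(float, res.params)
                errs[f"a_{suffix}"], errs[f"b_{suffix}"] = map(float, res.bse)
        form = 3 if use_age else 2
        return RoiModelEquation(roi=roi, form=form, coefficients=coeffs,
                                sex_stratified=True, stderr=errs)

    cols = [frame["icv"].to_numpy(float)]
    if use_age:
        cols.append(frame["age"].to_numpy(float))
    res = _ols(y_all, cols)
    if use_age:
        a, b, c = map(float, res.params)
        ea, eb, ec = map(float, res.bse)
        coeffs = {"a_f": a, "b_f": b, "c_f": c, "a_m": a, "b_m": b, "c_m": c}
        errs = {"a_f": ea, "b_f": eb, "c_f": ec, "a_m": ea, "b_m": eb, "c_m": ec}
        return RoiModelEquation(roi=roi, form=3, coefficients=coeffs,
                                sex_stratified=False, stderr=errs)
    a, b = map(float, res.params)
    ea, eb = map(float, res.bse)
    return RoiModelEquation(roi=roi, form=1, coefficients={"a": a, "b": b},
                            sex_stratified=False, stderr={"a": ea, "b": eb})


class NormativeVolumeModel:
    """Normative ENHV model specification bound to a healthy cohort.

    Parameters
    ----------
    cohort : DataFrame or sequence of SubjectMorphometry
        Healthy subjects with ``age, sex, icv`` and the five analysis-ROI
        volume columns (mm³).
    rois : sequence of RoiId, optional
        Regions to model (default: the five analysis ROIs).

    Examples
    --------
    >>> model = NormativeVolumeModel(cohort)
    >>> results = model.fit()
    >>> results.predict(RoiId.pons, icv=1.5e6, sex=1)
    """

    def __init__(self, cohort, rois=ANALYSIS_ROIS):
        frame = _cohort_frame(cohort)
        require_columns(frame, ["age", "sex", "icv"] + [str(r) for r in rois])
        if len(frame) < 10:
            raise ModelInputError("need at least 10 subjects to build a normative model")
        self.frame = frame.reset_index(drop=True)
        self.rois = tuple(rois)

    @classmethod
    def from_subjects(cls, subjects: list[SubjectMorphometry], **kwargs):
        return cls(subjects_to_frame(subjects), **kwargs)

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def fit(self) -> "NormativeVolumeResults":
        """Run screening, interaction tests and OLS; return results.

        Deterministic given the cohort.  With a single-sex cohort the
        interaction test is impossible and every region falls back to a
        pooled ICV-only (form 1) equation, with a warning.
        """
        sexes = self.frame["sex"].nunique()
        single_sex = sexes < 2
        if single_sex:
            warnings.warn(
                "cohort contains a single sex: interaction tests are impossible; "
                "fitting pooled ICV-only (form 1) equations for every region",
                stacklevel=2,
            )
        equations: dict[RoiId, RoiModelEquation] = {}
        screening: dict[RoiId, ScreeningResult] = {}
        interactions: dict[RoiId, InteractionResult] = {}
        for roi in self.rois:
            scr = screen_variables(self.frame, roi)
            screening[roi] = scr
            if single_sex:
                scr = ScreeningResult(roi=roi, r_age=scr.r_age, p_age=1.0,
                                      r_icv=scr.r_icv, p_icv=scr.p_icv)
                equations[roi] = fit_equation(self.frame, roi, scr, None)
                continue
            inter = test_sex_icv_interaction(self.frame, roi)
            interactions[roi] = inter
            equations[roi] = fit_equation(self.frame, roi, scr, inter)
        n_male = int((self.frame["sex"] == 1).sum())
        provenance = {
            "source": "fitted",
            "n": self.n_obs,
            "n_male": n_male,
            "n_female": self.n_obs - n_male,
            "screening": {
                str(r): {"r_age": s.r_age, "p_age": s.p_age,
                         "r_icv": s.r_icv, "p_icv": s.p_icv,
                         "include_age": s.include_age, "include_icv": s.include_icv}
                for r, s in screening.items()
            },
            "interaction": {
                str(r): {"f": i.f_stat, "df": [i.df_num, i.df_den],
                         "p": i.p, "stratify": i.stratify}
                for r, i in interactions.items()
            },
        }
        return NormativeVolumeResults(equations=equations, provenance=provenance,
                                      model=self)


@dataclass
class NormativeVolumeResults:
    """Fitted (or published) set of per-region ENHV equations.

    Attributes
    ----------
    equations : dict mapping RoiId to RoiModelEquation
    provenance : dict
        ``{"source": "published"}`` or a record of every decision the
        builder made (sample sizes, screening r/p, interaction F/p).
    """

    equations: dict[RoiId, RoiModelEquation]
    provenance: dict = field(default_factory=dict)
    model: Optional[NormativeVolumeModel] = None

    def predict(self, roi: Union[RoiId, str], icv, age=None, sex=None):
        """ENHV (mm³) for the given region and covariates.

        ``age`` is required only for regions whose equation uses age (the
        cerebrum with the published calibration); ``sex`` for any
        sex-stratified equation.  Broadcasts over arrays.
        """
        roi = RoiId(roi)
        if roi not in self.equations:
            raise ModelInputError(f"no equation for region {roi}")
        return self.equations[roi].predict(icv, age=age, sex=sex)

    def predict_frame(self, cohort) -> pd.DataFrame:
        """Per-subject ENHV for every modelled region.

        Returns a DataFrame indexed like the cohort with one ENHV column
        per region (named by the ROI).
        """
        frame = _cohort_frame(cohort)
        out = {}
        for roi, eq in self.equations.items():
            out[str(roi)] = eq.predict(
                frame["icv"].to_numpy(float),
                age=frame["age"].to_numpy(float) if eq.uses_age else None,
                sex=frame["sex"].to_numpy(float),
            )
        return pd.DataFrame(out, index=frame.index)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the equation set and fitting provenance."""
        lines = ["Normative ENHV model"]
        src = self.provenance.get("source", "unknown")
        if src == "fitted":
            lines.append(
                f"  fitted on n={self.provenance['n']} healthy subjects "
                f"({self.provenance['n_male']} male / {self.provenance['n_female']} female)"
            )
        else:
            lines.append(f"  source: {src}")
        lines.append("")
        header = f"  {'region':<16}{'form':<6}coefficients"
        lines.append(header)
        lines.append("  " + "-" * (len(header) + 30))
        for roi, eq in self.equations.items():
            coeffs = ", ".join(f"{k}={v:.6g}" for k, v in eq.coefficients.items())
            lines.append(f"  {str(roi):<16}{eq.form:<6}{coeffs}")
            if eq.stderr:
                ses = ", ".join(f"se({k})={v:.3g}" for k, v in eq.stderr.items())
                lines.append(f"  {'':<22}{ses}")
        inter = self.provenance.get("interaction")
        if inter:
            lines.append("")
            lines.append(f"  {'region':<16}{'sex x ICV F':<14}{'df':<10}{'p':<10}stratified")
            for roi, rec in inter.items():
                lines.append(
                    f"  {roi:<16}{rec['f']:<14.3g}"
                    f"{'(%d, %d)' % tuple(rec['df']):<10}{rec['p']:<10.3g}{rec['stratify']}"
                )
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        """Serialize to the model-JSON schema (coefficients as decimal text)."""
        doc = {
            "version": 1,
            "provenance": self.provenance,
            "equations": {
                str(roi): {
                    "form": eq.form,
                    "coefficients": {k: repr(v) for k, v in eq.coefficients.items()},
                    "uses_age": eq.uses_age,
                    "sex_stratified": eq.sex_stratified,
                    "stderr": eq.stderr,
                }
                for roi, eq in self.equations.items()
            },
        }
        return json.dumps(doc, indent=2)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "NormativeVolumeResults":
        doc = json.loads(text)
        equations = {}
        for roi_name, rec in doc["equations"].items():
            roi = RoiId(roi_name)
            equations[roi] = RoiModelEquation(
                roi=roi,
                form=rec["form"],
                coefficients={k: float(v) for k, v in rec["coefficients"].items()},
                sex_stratified=rec["sex_stratified"],
                stderr=rec.get("stderr"),
            )
        return cls(equations=equations, provenance=doc.get("provenance", {}))

    @classmethod
    def load(cls, path) -> "NormativeVolumeResults":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def build_model(cohort) -> NormativeVolumeResults:
    """Convenience wrapper: ``NormativeVolumeModel(cohort).fit()``."""
    return NormativeVolumeModel(cohort).fit()


def published_model() -> NormativeVolumeResults:
    """The published ENHV coefficient set (fit on 182 healthy East Asian
    adults, 99 male / 83 female, aged 18–64).

    Coefficients are stored exactly as printed, at 3 significant figures;
    predictions therefore carry that rounding (relative error up to ~0.5%
    of each term).
    """
    equations = {}
    for roi, text in _PUBLISHED_TEXT.items():
        form = {2: 1, 4: 2, 6: 3}[len(text)]
        equations[roi] = RoiModelEquation(
            roi=roi, form=form,
            coefficients={k: float(v) for k, v in text.items()},
            sex_stratified=form != 1,
        )
    # canonical ROI order
    equations = {roi: equations[roi] for roi in ANALYSIS_ROIS}
    return NormativeVolumeResults(
        equations=equations,
        provenance={"source": "published",
                    "note": "coefficients as printed, 3 significant figures"},
    )


def predict_enhv(results: NormativeVolumeResults, roi, icv, age=None, sex=None):
    """Functional alias for :meth:`NormativeVolumeResults.predict`."""
    return results.predict(roi, icv, age=age, sex=sex)
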