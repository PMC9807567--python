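"""Synthetic healthy and DAI-like cohorts, plus cohort-engineering utilities.

No subject-level data accompany the published normative model, so the
toolkit ships a seeded generator that emulates the *statistical structure*
the model assumes:

* **Healthy cohort** — sex by a male fraction, age uniform over the study
  range, ICV normal with a configurable male–female mean offset, and each
  region's volume equal to its true normative equation plus independent
  Gaussian residual noise.  The residual standard deviations are not
  published; they are solved in closed form (:func:`calibrate_residual_sd`)
  so that the population ICV–volume Pearson correlations match the study's
  reported values (0.496/0.567/0.677/0.614/0.828 for medulla/pons/
  midbrain/whole brainstem/cerebrum).
* **DAI cohort** — demographics as above, posttraumatic-amnesia (PTA)
  duration and time since injury from truncated discretised log-normals,
  and per-region ENHV-adjusted volumes from a linear latent-severity
  model: ``adjusted = mean + r·sd·z_PTA + sd·√(1−r²)·noise``, which
  reproduces the target PTA–volume correlations by construction.  Measured
  volume is then ``adjusted/100 × ENHV``.

Everything is deterministic under a seed (byte-identical CSVs and fixture
files).  The module also implements the study's cohort-engineering
procedures: the age-controlled 4:1 permuted-block split and random-number
matched-control selection.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .data import SubjectMorphometry
from .exceptions import EnhvError
from .model import NormativeVolumeResults, published_model
from .rois import ANALYSIS_ROIS, RoiId

# Published cohort summaries used as calibration constants.
ICV_VOLUME_R = {
    "medulla": 0.496, "pons": 0.567, "midbrain": 0.677,
    "whole_brainstem": 0.614, "cerebrum": 0.828,
}
DAI_MEAN_ADJUSTED = {
    "whole_brainstem": 86.1, "medulla": 91.1, "pons": 83.7,
    "midbrain": 88.1, "cerebrum": 92.6,
}
DAI_ADJUSTED_SD = {
    "whole_brainstem": 11.4, "medulla": 10.2, "pons": 11.6,
    "midbrain": 14.8, "cerebrum": 7.2,
}
PTA_EFFECT_R = {
    "whole_brainstem": -0.528, "pons": -0.537, "midbrain": -0.572,
    "medulla": -0.283, "cerebrum": -0.313,
}


class GeneratorConfig(BaseModel):
    """All distributional parameters of the synthetic cohorts.

    Defaults reproduce the published study conditions: a healthy cohort of
    182 (99 male), ages 18–68, pooled ICV 15.44E+05 ± 1.92E+05 mm³; a DAI
    cohort of 22 (17 male) with the published adjusted-volume means/SDs and
    PTA-linked atrophy correlations.  ``icv_sd`` is the *pooled* standard
    deviation; the within-sex spread is derived after removing the
    male–female mean offset (default 10% of the mean ICV).
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    seed: int = 0
    # healthy cohort
    n_healthy: int = 182
    male_fraction: float = 99 / 182
    age_range: tuple[float, float] = (18.0, 68.0)
    icv_mean: float = 15.44e5
    icv_sd: float = 1.92e5
    sex_icv_offset: float = 1.544e5  # male minus female mean ICV, mm³
    #: residual noise per region, mm³; None → calibrated from icv_volume_r
    residual_sd: Optional[dict[str, float]] = None
    icv_volume_r: dict[str, float] = Field(default_factory=lambda: dict(ICV_VOLUME_R))
    # DAI cohort
    n_dai: int = 22
    dai_male_fraction: float = 17 / 22
    dai_age_range: tuple[float, float] = (21.0, 61.0)
    dai_mean_adjusted: dict[str, float] = Field(default_factory=lambda: dict(DAI_MEAN_ADJUSTED))
    dai_adjusted_sd: dict[str, float] = Field(default_factory=lambda: dict(DAI_ADJUSTED_SD))
    pta_effect_r: dict[str, float] = Field(default_factory=lambda: dict(PTA_EFFECT_R))
    pta_range: tuple[int, int] = (1, 26)      # weeks
    pta_median: float = 7.5                   # weeks
    pta_log_sigma: float = 0.75
    tsi_range: tuple[float, float] = (5.0, 355.0)  # months
    tsi_median: float = 53.0
    tsi_log_sigma: float = 0.9
    # anatomy fractions used only for FreeSurfer fixture files
    cortical_gm_fraction: float = 0.50   # of cerebrum
    subcortical_gm_fraction: float = 0.06
    scp_fraction: float = 0.009          # of whole brainstem (< 3%)

    def true_equations(self) -> NormativeVolumeResults:
        """The coefficient set volumes are generated from (published set)."""
        return published_model()

    def within_sex_icv_sd(self) -> float:
        p = self.male_fraction
        var_w = self.icv_sd ** 2 - p * (1 - p) * self.sex_icv_offset ** 2
        if var_w <= 0:
            raise EnhvError(
                "sex_icv_offset too large for the pooled icv_sd: "
                "within-sex ICV variance would be negative"
            )
        return math.sqrt(var_w)


def _sex_blocks(eq):
    """Per-sex (a_icv, b_age, c) triples of an equation, any form."""
    c = eq.coefficients
    if eq.form == 1:
        blk = (c["a"], 0.0, c["b"])
        return blk, blk
    if eq.form == 2:
        return (c["a_f"], 0.0, c["b_f"]), (c["a_m"], 0.0, c["b_m"])
    return (c["a_f"], c["b_f"], c["c_f"]), (c["a_m"], c["b_m"], c["c_m"])


def calibrate_residual_sd(config: GeneratorConfig,
                          equations: Optional[NormativeVolumeResults] = None) -> dict[str, float]:
    """Solve the per-region residual SD (mm³) from the target ICV–volume
    Pearson correlations, using exact mixture moments of the generator.

    With sex S ~ Bernoulli(p), ICV = μ_S + W (W within-sex normal), age
    uniform and independent, and V = a_S·ICV + b_S·age + c_S + ε, both
    cov(ICV, V) and the noise-free var(V) have closed forms; the residual
    variance is whatever brings corr(ICV, V) down to the target.  Raises
    if a target correlation is unattainable (would need negative noise).
    """
    if equations is None:
        equations = config.true_equations()
    p = config.male_fraction
    delta = config.sex_icv_offset
    sigma_w2 = config.within_sex_icv_sd() ** 2
    mu_f = config.icv_mean - p * delta
    mu_m = mu_f + delta
    lo, hi = config.age_range
    var_age = (hi - lo) ** 2 / 12.0
    mean_age = (hi + lo) / 2.0
    var_icv = sigma_w2 + p * (1 - p) * delta ** 2

    out = {}
    for roi, eq in equations.equations.items():
        (a_f, b_f, c_f), (a_m, b_m, c_m) = _sex_blocks(eq)
        ev_f = a_f * mu_f + b_f * mean_age + c_f
        ev_m = a_m * mu_m + b_m * mean_age + c_m
        dv = ev_m - ev_f
        cov_icv = ((1 - p) * a_f + p * a_m) * sigma_w2 + p * (1 - p) * delta * dv
        var_clean = (
            (1 - p) * (a_f ** 2 * sigma_w2 + b_f ** 2 * var_age)
            + p * (a_m ** 2 * sigma_w2 + b_m ** 2 * var_age)
            + p * (1 - p) * dv ** 2
        )
        r = config.icv_volume_r[str(roi)]
        sd_total = cov_icv / (math.sqrt(var_icv) * r)
        var_eps = sd_total ** 2 - var_clean
        if var_eps <= 0:
            raise EnhvError(
                f"{roi}: target ICV-volume r={r} unattainable "
                "(noise-free correlation is already lower)"
            )
        out[str(roi)] = math.sqrt(var_eps)
    return out


def _draw_demographics(rng, n, male_fraction, age_range, config):
    sex = (rng.random(n) < male_fraction).astype(int)
    age = rng.uniform(age_range[0], age_range[1], n)
    sigma_w = config.within_sex_icv_sd()
    mu_f = config.icv_mean - config.male_fraction * config.sex_icv_offset
    # within-sex deviations truncated at ±3σ: keeps the head-size range
    # physiologic and guarantees regional volumes stay below the ICV
    w = np.clip(rng.normal(0.0, sigma_w, n), -3 * sigma_w, 3 * sigma_w)
    icv = mu_f + sex * config.sex_icv_offset + w
    return sex, age, icv


def _parse_level_volumes(rng, config, cerebrum, whole_brainstem):
    """Split the cerebrum into its three tissue classes and add an SCP, for
    FreeSurfer fixture files.  Fractions jitter slightly around canonical
    values; the three tissue volumes sum exactly to the cerebrum."""
    f_cort = config.cortical_gm_fraction + rng.normal(0.0, 0.01)
    f_sub = config.subcortical_gm_fraction + rng.normal(0.0, 0.003)
    cortical = f_cort * cerebrum
    subcort = f_sub * cerebrum
    white = cerebrum - cortical - subcort
    scp = max((config.scp_fraction + rng.normal(0.0, 0.001)) * whole_brainstem, 1.0)
    return {
        RoiId.cortical_gm: cortical,
        RoiId.subcortical_gm: subcort,
        RoiId.cerebral_wm: white,
        RoiId.scp: scp,
    }


def generate_healthy_cohort(config: Optional[GeneratorConfig] = None,
                            n: Optional[int] = None,
                            seed: Optional[int] = None,
                            id_prefix: str = "HC") -> list[SubjectMorphometry]:
    """Generate a healthy cohort from the true normative equations.

    Each region's volume is its equation value plus independent Gaussian
    noise (clipped positive), with noise calibrated to the target
    ICV–volume correlations unless ``config.residual_sd`` overrides it.
    Deterministic for a given seed.
    """
    config = config or GeneratorConfig()
    n = n if n is not None else config.n_healthy
    rng = np.random.default_rng(config.seed if seed is None else seed)
    equations = config.true_equations()
    resid = config.residual_sd or calibrate_residual_sd(config, equations)

    sex, age, icv = _draw_demographics(rng, n, config.male_fraction,
                                       config.age_range, config)
    subjects = []
    for i in range(n):
        volumes = {}
        for roi, eq in equations.equations.items():
            clean = eq.predict(icv[i], age=age[i], sex=sex[i])
            vol = clean + rng.normal(0.0, resid[str(roi)])
            volumes[roi] = max(vol, 1.0)
        volumes.update(_parse_level_volumes(
            rng, config, volumes[RoiId.cerebrum], volumes[RoiId.whole_brainstem]))
        subjects.append(SubjectMorphometry(
            subject_id=f"{id_prefix}{i + 1:04d}",
            age=float(age[i]), sex=int(sex[i]), icv=float(icv[i]),
            volumes={k: float(v) for k, v in volumes.items()},
            group_label="healthy",
        ))
    return subjects


def _truncated_lognormal(rng, n, median, sigma, lo, hi):
    draws = rng.lognormal(mean=math.log(median), sigma=sigma, size=n)
    return np.clip(draws, lo, hi)


def generate_dai_cohort(config: Optional[GeneratorConfig] = None,
                        model: Optional[NormativeVolumeResults] = None,
                        n: Optional[int] = None,
                        seed: Optional[int] = None,
                        id_prefix: str = "DAI") -> list[SubjectMorphometry]:
    """Generate a DAI-like patient cohort.

    Adjusted volumes follow the latent-severity model described in the
    module docstring; measured volumes are reconstructed through the given
    model's ENHV (published model by default).  Deterministic under seed.
    """
    config = config or GeneratorConfig()
    model = model or config.true_equations()
    n = n if n is not None else config.n_dai
    rng = np.random.default_rng(config.seed if seed is None else seed)

    sex, age, icv = _draw_demographics(rng, n, config.dai_male_fraction,
                                       config.dai_age_range, config)
    pta = np.rint(_truncated_lognormal(
        rng, n, config.pta_median, config.pta_log_sigma,
        config.pta_range[0], config.pta_range[1])).astype(int)
    pta = np.clip(pta, config.pta_range[0], config.pta_range[1])
    tsi = _truncated_lognormal(rng, n, config.tsi_median, config.tsi_log_sigma,
                               config.tsi_range[0], config.tsi_range[1])
    sd_pta = pta.std()
    z = (pta - pta.mean()) / sd_pta if sd_pta > 0 else np.zeros(n)

    subjects_volumes = [dict() for _ in range(n)]
    for roi, eq in model.equations.items():
        mean = config.dai_mean_adjusted[str(roi)]
        sd = config.dai_adjusted_sd[str(roi)]
        r = config.pta_effect_r[str(roi)]
        noise = rng.normal(0.0, 1.0, n)
        adjusted = mean + r * sd * z + sd * math.sqrt(max(0.0, 1 - r ** 2)) * noise
        adjusted = np.maximum(adjusted, 1.0)
        for i in range(n):
            enhv = eq.predict(icv[i], age=age[i], sex=sex[i])
            subjects_volumes[i][roi] = float(adjusted[i] / 100.0 * enhv)

    subjects = []
    for i in range(n):
        volumes = subjects_volumes[i]
        volumes.update(_parse_level_volumes(
            rng, config, volumes[RoiId.cerebrum], volumes[RoiId.whole_brainstem]))
        subjects.append(SubjectMorphometry(
            subject_id=f"{id_prefix}{i + 1:04d}",
            age=float(age[i]), sex=int(sex[i]), icv=float(icv[i]),
            volumes={k: float(v) for k, v in volumes.items()},
            pta_weeks=int(pta[i]),
            time_since_injury_months=float(tsi[i]),
            group_label="dai",
        ))
    return subjects


# ---------------------------------------------------------------------------
# cohort-engineering utilities


def split_permuted_block(cohort: Sequence[SubjectMorphometry],
                         ratio: tuple[int, int] = (4, 1),
                         age_controlled: bool = True,
                         seed: Optional[int] = None):
    """Split a cohort into two groups at the given ratio by permuted blocks.

    Subjects are sorted by age (when ``age_controlled``) and partitioned
    into consecutive blocks of ``sum(ratio)``; within each full block a
    random permutation sends ``ratio[0]`` subjects to group A and
    ``ratio[1]`` to group B, which balances the age distributions.  A final
    short block of r subjects contributes ``round(r·ratio[1]/block)`` to B,
    with half-way ties resolved in favour of A; the extra B members are
    drawn from the short block by the same random permutation.
    """
    cohort = list(cohort)
    block = sum(ratio)
    if len(cohort) < block:
        raise EnhvError(f"cohort of {len(cohort)} too small for a {ratio} split")
    rng = np.random.default_rng(seed)
    order = sorted(cohort, key=lambda s: (s.age, s.subject_id)) if age_controlled \
        else [cohort[i] for i in rng.permutation(len(cohort))]
    group_a, group_b = [], []
    n_full = len(order) // block
    for bi in range(n_full):
        members = order[bi * block:(bi + 1) * block]
        perm = rng.permutation(block)
        for j, idx in enumerate(perm):
            (group_b if j < ratio[1] else group_a).append(members[idx])
    remainder = order[n_full * block:]
    r = len(remainder)
    if r:
        frac = r * ratio[1] / block
        b_extra = int(math.floor(frac)) if (frac - math.floor(frac)) <= 0.5 \
            else int(math.ceil(frac))
        perm = rng.permutation(r)
        for j, idx in enumerate(perm):
            (group_b if j < b_extra else group_a).append(remainder[idx])
    return group_a, group_b


def select_matched_controls(pool: Sequence[SubjectMorphometry],
                            n_male: int, n_female: int,
                            seed: Optional[int] = None) -> list[SubjectMorphometry]:
    """Random-number matched-control selection.

    Assigns every pool member a uniform random number and keeps the
    ``n_male`` males and ``n_female`` females with the highest numbers.
    """
    pool = list(pool)
    rng = np.random.default_rng(seed)
    tickets = rng.random(len(pool))
    males = [(t, i) for (t, i) in zip(tickets, range(len(pool))) if pool[i].sex == 1]
    females = [(t, i) for (t, i) in zip(tickets, range(len(pool))) if pool[i].sex == 0]
    if len(males) < n_male or len(females) < n_female:
        raise EnhvError(
            f"pool has {len(males)} males / {len(females)} females; "
            f"requested {n_male} / {n_female}"
        )
    chosen = sorted(males, reverse=True)[:n_male] + sorted(females, reverse=True)[:n_female]
    return [pool[i] for _, i in sorted(chosen, key=lambda t: t[1])]


# ---------------------------------------------------------------------------
# FreeSurfer-format fixture files


def write_fixture_subject(subject: SubjectMorphometry, directory) -> tuple[Path, Path]:
    """Write syntactically valid ``aseg.stats`` and
    ``brainstemSsVolumes.v10.txt`` files for one subject.

    The subject must carry all parse-level volumes (cerebral tissue
    classes, brainstem subfields, SCP).  Values are written with full
    ``repr`` precision so the :mod:`enhv.freesurfer` parsers round-trip
    them exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    v = subject.volumes
    needed = (RoiId.cortical_gm, RoiId.cerebral_wm, RoiId.subcortical_gm,
              RoiId.medulla, RoiId.pons, RoiId.midbrain, RoiId.scp,
              RoiId.whole_brainstem)
    missing = [str(r) for r in needed if r not in v]
    if missing:
        raise EnhvError(f"subject {subject.subject_id} lacks parse-level volumes {missing}")

    aseg = directory / "aseg.stats"
    aseg.write_text(
        "# Title Segmentation Statistics\n"
        f"# subjectname {subject.subject_id}\n"
        f"# Measure Cortex, CortexVol, Total cortical gray matter volume, "
        f"{v[RoiId.cortical_gm]!r}, mm^3\n"
        f"# Measure CerebralWhiteMatter, CerebralWhiteMatterVol, "
        f"Total cerebral white matter volume, {v[RoiId.cerebral_wm]!r}, mm^3\n"
        f"# Measure SubCortGray, SubCortGrayVol, Subcortical gray matter volume, "
        f"{v[RoiId.subcortical_gm]!r}, mm^3\n"
        f"# Measure EstimatedTotalIntraCranialVol, eTIV, "
        f"Estimated Total Intracranial Volume, {subject.icv!r}, mm^3\n"
        "# ColHeaders Index SegId NVoxels Volume_mm3 StructName\n"
        "  1   4  7938  8255.6  Left-Lateral-Ventricle\n"
        "  2  43  7723  8022.1  Right-Lateral-Ventricle\n",
        encoding="utf-8",
    )
    stem = directory / "brainstemSsVolumes.v10.txt"
    stem.write_text(
        f"Medulla {v[RoiId.medulla]!r}\n"
        f"Pons {v[RoiId.pons]!r}\n"
        f"Midbrain {v[RoiId.midbrain]!r}\n"
        f"SCP {v[RoiId.scp]!r}\n"
        f"Whole_brainstem {v[RoiId.whole_brainstem]!r}\n",
        encoding="utf-8",
    )
    return aseg, stem


def write_fixture_cohort(subjects: Sequence[SubjectMorphometry], directory) -> Path:
    """Write one fixture directory per subject under ``directory``."""
    directory = Path(directory)
    for s in subjects:
        write_fixture_subject(s, directory / s.subject_id)
    return directory
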