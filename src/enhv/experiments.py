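"""Seeded replication experiments over the full modelling pipeline.

:func:`replicate_study` re-enacts the whole study design on synthetic
cohorts, many times: fit the normative model on a fresh healthy cohort,
validate it on a disjoint cohort, apply it to a disjoint control subsample
and to a DAI cohort, and record the headline quantities of each replicate.
This is the basis for calibration checks — e.g. how often the fitted model
reproduces the published equation forms, or where the held-out adjusted-
volume means land.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .analysis import adjusted_volume_table, pta_correlation, summarize_loss
from .data import subjects_to_frame
from .model import build_model
from .rois import RoiId
from .simulate import GeneratorConfig, generate_dai_cohort, generate_healthy_cohort
from .validation import validate_model

#: Equation forms of the published model, the reference decision path.
PUBLISHED_FORMS = {
    RoiId.medulla: 1, RoiId.whole_brainstem: 2, RoiId.pons: 2,
    RoiId.midbrain: 2, RoiId.cerebrum: 3,
}


def replicate_study(n_replicates: int = 50, seed: int = 0,
                    config: Optional[GeneratorConfig] = None,
                    n_fit: int = 182, n_validation: int = 47,
                    n_controls: int = 60, n_patients: int = 22) -> pd.DataFrame:
    """Run the full pipeline on ``n_replicates`` independent seed sets.

    Per replicate (all cohorts mutually disjoint, seeds derived from
    ``seed``):

    1. generate a healthy fitting cohort (``n_fit``) and fit the model;
    2. generate a healthy validation cohort (``n_validation``) and record
       the minimum ICC across the five regions;
    3. generate a healthy control subsample (``n_controls``) and record the
       min/max across regions of the group-mean ENHV-adjusted volume;
    4. generate a DAI cohort (``n_patients``) and record whether the PTA
       partial correlations (controlling time since injury) are
       significantly negative in whole brainstem, pons and midbrain, and
       whether the pons shows the greatest mean loss among the subfields.

    Returns one row per replicate with columns ``forms_match``,
    ``min_icc``, ``min_mean_adjusted``, ``max_mean_adjusted``,
    ``pta_sig_all``, ``pons_greatest_loss``.
    """
    config = config or GeneratorConfig()
    child_seeds = (np.random.SeedSequence(seed)
                   .generate_state(4 * n_replicates, dtype=np.uint64) % (2 ** 31))
    rows = []
    severity_rois = ("whole_brainstem", "pons", "midbrain")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for rep in range(n_replicates):
            s1, s2, s3, s4 = (int(s) for s in child_seeds[4 * rep:4 * rep + 4])
            fit_frame = subjects_to_frame(generate_healthy_cohort(config, n=n_fit, seed=s1))
            results = build_model(fit_frame)
            forms_match = all(results.equations[roi].form == form
                              for roi, form in PUBLISHED_FORMS.items())

            val_frame = subjects_to_frame(
                generate_healthy_cohort(config, n=n_validation, seed=s2))
            min_icc = min(r.icc for r in validate_model(results, val_frame))

            hc_frame = subjects_to_frame(
                generate_healthy_cohort(config, n=n_controls, seed=s3))
            hc_means = (adjusted_volume_table(results, hc_frame)
                        .groupby("roi")["adjusted"].mean())

            dai_frame = subjects_to_frame(
                generate_dai_cohort(config, model=results, n=n_patients, seed=s4))
            dai_adjusted = adjusted_volume_table(results, dai_frame)
            partial = {str(c.roi): c for c in pta_correlation(dai_adjusted)}
            pta_sig_all = all(partial[r].r < 0 and partial[r].p < 0.05
                              for r in severity_rois)
            losses = summarize_loss(dai_adjusted)["mean_percent_loss"]
            pons_greatest = (losses["pons"] > losses["midbrain"]
                             and losses["pons"] > losses["medulla"])

            rows.append({
                "forms_match": forms_match,
                "min_icc": float(min_icc),
                "min_mean_adjusted": float(hc_means.min()),
                "max_mean_adjusted": float(hc_means.max()),
                "pta_sig_all": pta_sig_all,
                "pons_greatest_loss": pons_greatest,
            })
    return pd.DataFrame(rows)
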