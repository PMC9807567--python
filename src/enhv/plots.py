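"""Diagnostic plots for normative volume models.

Thin matplotlib helpers; every function accepts an existing ``ax`` and
returns it, so figures compose the usual way.
"""

from __future__ import annotations

import numpy as np

from .model import NormativeVolumeResults, _cohort_frame
from .rois import RoiId


def plot_volume_vs_icv(cohort, roi, results: NormativeVolumeResults | None = None, ax=None):
    """Scatter a region's volume against ICV, by sex, with the model's
    regression lines overlaid when ``results`` is given.

    The positive y-intercepts visible here are why the proportions method
    (volume/ICV) over-corrects small regions.
    """
    import matplotlib.pyplot as plt

    frame = _cohort_frame(cohort)
    roi = RoiId(roi)
    if ax is None:
        _, ax = plt.subplots()
    for sex, label, color in ((0, "female", "tab:orange"), (1, "male", "tab:blue")):
        sub = frame[frame["sex"] == sex]
        ax.scatter(sub["icv"], sub[str(roi)], s=12, alpha=0.6, label=label, color=color)
        if results is not None and roi in results.equations:
            eq = results.equations[roi]
            grid = np.linspace(frame["icv"].min(), frame["icv"].max(), 50)
            age = float(frame["age"].mean()) if eq.uses_age else None
            ax.plot(grid, eq.predict(grid, age=age, sex=sex), color=color, lw=1.5)
    ax.set_xlabel("ICV (mm³)")
    ax.set_ylabel(f"{roi} volume (mm³)")
    ax.legend()
    return ax


def plot_adjusted_vs_pta(adjusted, roi, ax=None):
    """Scatter ENHV-adjusted volume against PTA duration for one region."""
    import matplotlib.pyplot as plt

    roi = RoiId(roi)
    block = adjusted[adjusted["roi"] == str(roi)]
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(block["pta_weeks"], block["adjusted"], s=20)
    ax.axhline(100.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("PTA duration (weeks)")
    ax.set_ylabel(f"{roi} adjusted volume (% of ENHV)")
    return ax
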