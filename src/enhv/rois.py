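"""Region-of-interest identifiers.

The toolkit analyses five regions: the whole brainstem, its three major
subfields (medulla oblongata, pons, midbrain), and the cerebrum (cortical
gray + cerebral white + subcortical gray matter).  The superior cerebellar
peduncle (SCP) is parsed from FreeSurfer output but excluded from analysis:
it is a residual-like minor subfield amounting to less than 3% of the whole
brainstem, too small and noisy for a stable normative equation.
"""

from __future__ import annotations

from enum import Enum


class RoiId(str, Enum):
    """Identifier for a brain region of interest.

    The five *analysis* ROIs receive normative equations; the remaining
    members exist only at the parsing level (``cortical_gm``,
    ``cerebral_wm`` and ``subcortical_gm`` are combined into ``cerebrum``;
    ``scp`` is excluded from analysis).
    """

    whole_brainstem = "whole_brainstem"
    medulla = "medulla"
    pons = "pons"
    midbrain = "midbrain"
    cerebrum = "cerebrum"
    # raw-parse-only members
    cortical_gm = "cortical_gm"
    cerebral_wm = "cerebral_wm"
    subcortical_gm = "subcortical_gm"
    scp = "scp"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The five ROIs that receive normative model equations, in canonical order.
ANALYSIS_ROIS: tuple[RoiId, ...] = (
    RoiId.whole_brainstem,
    RoiId.medulla,
    RoiId.pons,
    RoiId.midbrain,
    RoiId.cerebrum,
)

#: The three brainstem subfields compared in within-subject analyses.
BRAINSTEM_SUBFIELDS: tuple[RoiId, ...] = (RoiId.medulla, RoiId.pons, RoiId.midbrain)

#: ROIs parsed from files but never modelled.
PARSE_ONLY_ROIS: tuple[RoiId, ...] = (
    RoiId.cortical_gm,
    RoiId.cerebral_wm,
    RoiId.subcortical_gm,
    RoiId.scp,
)
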