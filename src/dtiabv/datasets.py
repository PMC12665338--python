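"""Bundled worked-example tables.

``LONGITUDINAL_VOLUMES`` holds group-mean (± SD) ICV-standardized structure
volumes in mL for a longitudinal bvFTD cohort — 19 patients scanned at
baseline and again after one year — alongside 39 controls, for 24 standard
cortical and subcortical structures.  It is the input of the package's
worked example: :func:`dtiabv.abv.percent_change` applied to the baseline
and follow-up means yields the signed percent volume change per structure.
"""

from __future__ import annotations

import pandas as pd

# structure: (control_mean, control_sd, baseline_mean, baseline_sd,
#             followup_mean, followup_sd)   [mL]
_LONGITUDINAL = {
    "Cerebrum GM":    (533.7, 55.0, 426.5, 63.9, 406.3, 67.4),
    "Cerebrum WM":    (389.5, 28.8, 389.0, 51.1, 392.0, 60.2),
    "Frontal lobe R": (151.6, 10.8, 131.3, 19.6, 129.2, 23.0),
    "Frontal lobe L": (153.0, 11.3, 130.4, 21.3, 127.4, 25.0),
    "Temporal lobe R": (92.3, 6.1, 82.1, 13.4, 80.3, 14.0),
    "Temporal lobe L": (93.7, 6.7, 81.6, 10.6, 79.1, 11.7),
    "Parietal lobe R": (82.8, 5.4, 74.8, 9.6, 73.1, 10.0),
    "Parietal lobe L": (86.1, 6.2, 75.2, 10.0, 73.7, 11.3),
    "Occipital lobe R": (62.1, 4.7, 55.4, 8.5, 54.2, 8.0),
    "Occipital lobe L": (60.0, 4.9, 53.3, 8.4, 52.3, 7.7),
    "Insula R":        (8.1, 0.8, 6.8, 1.1, 6.5, 1.2),
    "Insula L":        (8.4, 0.7, 7.0, 1.0, 6.6, 1.1),
    "Cerebellum":    (113.3, 10.4, 102.3, 10.8, 98.5, 12.0),
    "Brainstem":      (30.1, 2.5, 30.0, 2.7, 29.0, 2.5),
    "Hippocampus R":   (3.4, 0.3, 2.9, 0.5, 2.8, 0.5),
    "Hippocampus L":   (3.2, 0.3, 2.7, 0.4, 2.6, 0.4),
    "Amygdala R":      (1.9, 0.2, 1.6, 0.3, 1.5, 0.3),
    "Amygdala L":      (1.7, 0.2, 1.4, 0.2, 1.4, 0.2),
    "Caudate R":       (2.2, 0.2, 1.7, 0.5, 1.5, 0.5),
    "Caudate L":       (2.3, 0.3, 1.7, 0.6, 1.6, 0.6),
    "Putamen R":       (3.2, 0.5, 2.5, 0.5, 2.3, 0.5),
    "Putamen L":       (3.3, 0.5, 2.5, 0.6, 2.1, 0.6),
    "Thalamus R":      (6.0, 0.6, 5.1, 0.7, 5.0, 0.7),
    "Thalamus L":      (6.3, 0.7, 5.1, 0.8, 5.0, 0.8),
}


def longitudinal_volumes() -> pd.DataFrame:
    """The worked-example group-mean volume table as a DataFrame."""
    return pd.DataFrame.from_dict(
        _LONGITUDINAL, orient="index",
        columns=["control_mean", "control_sd", "baseline_mean", "baseline_sd",
                 "followup_mean", "followup_sd"],
    ).rename_axis("structure")


LONGITUDINAL_VOLUMES = longitudinal_volumes()
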