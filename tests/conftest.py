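"""Shared fixtures: the published validation-table values, frozen.

The fusion ladder is the SLC34A2-ROS1 five-point dilution series (molecular
copies); the CNA ladder is the ERBB2/HER2 series (fold change), where
dilutions 4-5 reported no call. The control-chart bands are the published
+/-3 SD QC ranges of the five monitored positive-control analytes.
"""

from __future__ import annotations

import math

import pandas as pd
import pytest

from cfnaval.stats import DilutionSeries

# dilution -> replicate molecular copies (SLC34A2-ROS1)
FUSION_LADDER = {
    "D1": [549, 652],
    "D2": [272, 321, 287],
    "D3": [158, 171, 141],
    "D4": [66, 98, 81],
    "D5": [49, 46, 31],
}
# dilution -> (printed average, printed CV)
FUSION_PRINTED = {
    "D1": ("601", "12.1%"),
    "D2": ("293", "8.6%"),
    "D3": ("157", "9.6%"),
    "D4": ("82", "19.6%"),
    "D5": ("42", "23.0%"),
}

# dilution -> replicate fold changes (ERBB2/HER2); None = no call reported
CNA_LADDER = {
    "D1": [5.64, 5.08],
    "D2": [2.27, 2.35, 2.27],
    "D3": [1.4, 1.42, 1.38],
    "D4": [None, None, None],
    "D5": [None, None, None],
}
CNA_PRINTED = {"D1": ("5.36", "7.4%"), "D2": ("2.30", "2.0%"), "D3": ("1.40", "1.4%")}

# analyte -> (lower, upper) published +/-3 SD QC range
CONTROL_RANGES = {
    "CCDC6-RET": (525.0, 2605.0),
    "EML4-ALK": (2880.0, 7474.0),
    "CD74-ROS1": (276.0, 1671.0),
    "ERBB2": (2.14, 3.77),
    "MYC": (1.73, 3.18),
}


def ladder_to_series(ladder: dict, variant_kind: str, target_id: str) -> DilutionSeries:
    """Build a DilutionSeries from a printed ladder; None means no call."""
    records = []
    for dilution, values in ladder.items():
        for i, v in enumerate(values, start=1):
            detected = v is not None
            records.append(
                dict(
                    dilution=dilution,
                    replicate=f"R{i}",
                    measurement=float(v) if detected else math.nan,
                    call="detected" if detected else "not_detected",
                )
            )
    return DilutionSeries(
        variant_kind=variant_kind,
        target_id=target_id,
        rows=pd.DataFrame.from_records(records),
        dilution_order=tuple(ladder),
    )


@pytest.fixture
def fusion_series() -> DilutionSeries:
    return ladder_to_series(FUSION_LADDER, "fusion", "SLC34A2-ROS1")


@pytest.fixture
def cna_series() -> DilutionSeries:
    return ladder_to_series(CNA_LADDER, "cna", "ERBB2")
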