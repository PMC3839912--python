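"""Spot-ratio partitioning of a protein pool into adsorbed / non-adsorbed groups.

Each 2-DE gel is normalized to its total spot intensity; the ratio of a
protein's relative intensity in the adsorbed-fraction gel over its relative
intensity in the non-adsorbed-fraction gel classifies it as adsorbed (AP),
non-adsorbed (NAP) or intermediate.  The classification thresholds are
10^0.2 (~1.58) and 10^-0.2 (~0.63), with strict inequalities on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SpotTable

#: Ratio above which a protein counts as adsorbed (printed as 1.58).
RATIO_UPPER = 10.0 ** 0.2
#: Ratio below which a protein counts as non-adsorbed (printed as 0.63).
RATIO_LOWER = 10.0 ** -0.2

ADSORBED = "adsorbed"
NON_ADSORBED = "non_adsorbed"
INTERMEDIATE = "intermediate"
UNMATCHED = "unmatched"

LABELS = (ADSORBED, NON_ADSORBED, INTERMEDIATE, UNMATCHED)


@dataclass
class PartitionResult:
    """Per-protein relative intensities, ratio and group label.

    ``table`` has one row per distinct protein across both gels with columns
    ``rel_adsorbed``, ``rel_nonadsorbed``, ``ratio`` and ``label``.  The
    ratio is +inf for proteins seen only in the adsorbed gel and NaN for
    proteins seen only in the non-adsorbed gel (flagged values keep them out
    of numeric distribution plots); the presence pattern still assigns a label.
    """

    table: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        c = self.table["label"].value_counts().to_dict()
        return {label: int(c.get(label, 0)) for label in LABELS}

    def ids_with_label(self, label: str) -> list[str]:
        return list(self.table.index[self.table["label"] == label])


def normalize_spots(table: SpotTable) -> SpotTable:
    """Divide every spot volume by the gel total so volumes sum to 1."""
    total = table.total  # SpotTable invariant guarantees total > 0
    return SpotTable(
        gel_id=table.gel_id,
        protein_ids=list(table.protein_ids),
        volumes=table.volumes / total,
    )


def classify(ratio: float, upper: float = RATIO_UPPER, lower: float = RATIO_LOWER) -> str:
    """Classify a relative-intensity ratio into adsorbed / non-adsorbed /
    intermediate.  Boundary equality falls in the intermediate group
    (strict inequalities on both sides)."""
    if not ratio > 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    if ratio > upper:
        return ADSORBED
    if ratio < lower:
        return NON_ADSORBED
    return INTERMEDIATE


def partition(
    adsorbed: SpotTable,
    nonadsorbed: SpotTable,
    upper: float = RATIO_UPPER,
    lower: float = RATIO_LOWER,
) -> PartitionResult:
    """Partition proteins into AP / NAP / intermediate groups.

    Both tables are normalized internally.  Proteins with nonzero volume in
    both gels get a numeric ratio; proteins present in only one gel are
    labelled by presence (adsorbed-only -> adsorbed with ratio +inf,
    non-adsorbed-only -> non_adsorbed with ratio NaN).  Proteins listed with
    zero volume in both gels are labelled ``unmatched``.
    """
    rel_a = normalize_spots(adsorbed).as_series()
    rel_n = normalize_spots(nonadsorbed).as_series()
    all_ids = list(dict.fromkeys(list(rel_a.index) + list(rel_n.index)))

    rows = []
    for pid in all_ids:
        va = float(rel_a.get(pid, 0.0))
        vn = float(rel_n.get(pid, 0.0))
        if va > 0 and vn > 0:
            ratio = va / vn
            label = classify(ratio, upper=upper, lower=lower)
        elif va > 0:
            ratio, label = np.inf, ADSORBED
        elif vn > 0:
            ratio, label = np.nan, NON_ADSORBED
        else:
            ratio, label = np.nan, UNMATCHED
        rows.append((pid, va, vn, ratio, label))

    table = pd.DataFrame(
        rows, columns=["protein_id", "rel_adsorbed", "rel_nonadsorbed", "ratio", "label"]
    ).set_index("protein_id")
    if not ((table["label"] != UNMATCHED).any()):
        raise ValueError("no protein present in either gel")
    return PartitionResult(table=table)
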