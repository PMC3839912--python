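"""Per-protein physicochemical feature battery.

Implements the residue-class composition fractions used in the group
comparison (aromatic, polar, beta-strand, hydrophobic, alpha-helix, basic,
acidic, neutral), the 20 per-residue fractions, length, average molecular
weight, isoelectric point (Henderson-Hasselbalch bisection on the EMBOSS
pKa set), the Kyte-Doolittle GRAVY index, and the sliding-window charge
cluster ratio (12-residue window, >=3 charged residues of one sign).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AMINO_ACIDS, ProteinRecord

# ---------------------------------------------------------------------------
# Residue-class registry

#: Residue classes used in the AP-vs-NAP comparison.  "neutral" is defined
#: as everything except the four charged residues K, R, E, D, so the basic,
#: acidic and neutral fractions always sum to 1.
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "aromatic": frozenset("FWYH"),
    "polar": frozenset("RKEDQN"),
    "beta_strand": frozenset("VIYCWFT"),
    "hydrophobic": frozenset("CLVIMFW"),
    "alpha_helix": frozenset("EALMQKRH"),
    "basic": frozenset("RK"),
    "acidic": frozenset("ED"),
    "neutral": frozenset(set(AMINO_ACIDS) - set("KRED")),
}

#: Average residue (i.e. water-subtracted) masses, Da.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "E": -3.5, "Q": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: EMBOSS pKa values for the ionizable groups.
PKA = {
    "n_term": 8.6, "c_term": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}
_POSITIVE_GROUPS = ("H", "K", "R")
_NEGATIVE_GROUPS = ("C", "D", "E", "Y")


@dataclass(frozen=True)
class ResidueClassDef:
    """A named set of one-letter residue codes."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members <= set(AMINO_ACIDS):
            raise ValueError(f"class {self.name!r}: members outside the 20-letter alphabet")


@dataclass(frozen=True)
class ChargeClusterParams:
    """Sliding-window parameters for the charge-cluster statistic."""

    window: int = 12
    threshold: int = 3
    positive_set: frozenset[str] = frozenset("RK")
    negative_set: frozenset[str] = frozenset("DE")

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 1 <= self.threshold <= self.window:
            raise ValueError("threshold must be in [1, window]")


def _check_seq(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"illegal residues: {''.join(sorted(bad))}")
    return seq


def class_fraction(seq: str, members: frozenset[str] | set[str] | str) -> float:
    """Fraction of residues that belong to the given class."""
    seq = _check_seq(seq)
    if isinstance(members, str):
        members = RESIDUE_CLASSES[members]
    return sum(seq.count(aa) for aa in members) / len(seq)


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da (residue masses plus one water)."""
    seq = _check_seq(seq)
    return sum(RESIDUE_MASS[aa] for aa in seq) + WATER_MASS


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at the given pH (termini included)."""
    seq = _check_seq(seq)
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA["n_term"]))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA["c_term"] - ph))
    for aa in _POSITIVE_GROUPS:
        charge += seq.count(aa) / (1.0 + 10.0 ** (ph - PKA[aa]))
    for aa in _NEGATIVE_GROUPS:
        charge -= seq.count(aa) / (1.0 + 10.0 ** (PKA[aa] - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so bisection always
    converges; iteration stops when |charge| < *tol*.
    """
    seq = _check_seq(seq)
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(200):
        ph = 0.5 * (lo + hi)
        q = net_charge(seq, ph)
        if abs(q) < tol:
            break
        if q > 0:
            lo = ph
        else:
            hi = ph
    return ph


def gravy(seq: str) -> float:
    """Mean Kyte-Doolittle hydropathy per residue."""
    seq = _check_seq(seq)
    return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)


def charge_cluster_ratio(
    seq: str,
    polarity: str = "positive",
    params: ChargeClusterParams | None = None,
) -> float:
    """Fraction of 12-residue sliding windows containing >= 3 charged
    residues of the requested sign.

    Returns NaN (feature flagged missing) for sequences shorter than the
    window; such values are excluded from the group statistics.
    """
    seq = _check_seq(seq)
    params = params or ChargeClusterParams()
    if polarity == "positive":
        charged = params.positive_set
    elif polarity == "negative":
        charged = params.negative_set
    else:
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    n, w = len(seq), params.window
    if n < w:
        return math.nan
    indicator = np.fromiter((aa in charged for aa in seq), dtype=int, count=n)
    window_counts = np.convolve(indicator, np.ones(w, dtype=int), mode="valid")
    return float(np.mean(window_counts >= params.threshold))


def feature_vector(
    record: ProteinRecord, cluster_params: ChargeClusterParams | None = None
) -> pd.Series:
    """All registered features for one protein, as a named Series.

    Contains the 8 class fractions, the 20 per-residue fractions, length,
    molecular weight, isoelectric point, GRAVY and the two charge-cluster
    ratios (NaN when the sequence is shorter than the window).
    """
    seq = record.sequence
    values: dict[str, float] = {}
    for name, members in RESIDUE_CLASSES.items():
        values[name] = class_fraction(seq, members)
    for aa in AMINO_ACIDS:
        values[aa] = seq.count(aa) / len(seq)
    values["length"] = float(len(seq))
    values["molecular_weight"] = molecular_weight(seq)
    values["isoelectric_point"] = isoelectric_point(seq)
    values["gravy"] = gravy(seq)
    values["positive_cluster_ratio"] = charge_cluster_ratio(seq, "positive", cluster_params)
    values["negative_cluster_ratio"] = charge_cluster_ratio(seq, "negative", cluster_params)
    return pd.Series(values, name=record.id)


def feature_matrix(
    records: list[ProteinRecord], cluster_params: ChargeClusterParams | None = None
) -> pd.DataFrame:
    """Proteins x features matrix (one row per protein, indexed by id)."""
    if not records:
        raise ValueError("no records")
    return pd.DataFrame([feature_vector(r, cluster_params) for r in records])


FEATURE_NAMES: tuple[str, ...] = tuple(
    feature_matrix([ProteinRecord("_probe", AMINO_ACIDS)]).columns
)
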