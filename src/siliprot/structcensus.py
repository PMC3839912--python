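"""Census of intramolecular noncovalent attractive interactions in a structure.

Five interaction types are enumerated between residue pairs with
distance-cutoff criteria: ionic (salt bridges, cation-anion atom distance
<= 6 A), cation-pi (Arg/Lys cation atom to aromatic ring centroid <= 6 A),
pi-pi (ring centroid to ring centroid within 4.5-7 A, aromatic = F/Y/W/H
including His by the Hueckel rule), side-chain/side-chain hydrogen bonds
(donor N/O to acceptor N/O <= 3.5 A, distance-only since hydrogens may be
absent), and hydrophobic contacts (side-chain C/S atoms of the hydrophobic
class {C,L,V,I,M,F,W} <= 5 A).  Each residue pair is counted at most once
per type and counts are normalized per amino acid (residues parsed in the
monomer).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import AA3_TO_1, Atom, Structure

logger = logging.getLogger(__name__)

INTERACTION_TYPES = ("ionic", "cation_pi", "pi_pi", "hbond_sc_sc", "hydrophobic")

#: Side-chain cation group atoms (positively charged at neutral pH).
CATION_ATOMS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
#: Side-chain anion group atoms.
ANION_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
#: Aromatic ring heavy atoms; the centroid requires the complete set.
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    # Trp: single pi system, centroid = mean of all 9 ring heavy atoms
    "TRP": ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
}
#: Side-chain N/O hydrogen-bond donors, by residue type.
SC_DONOR_ATOMS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "ASN": ("ND2",),
    "GLN": ("NE2",), "HIS": ("ND1", "NE2"), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "TRP": ("NE1",),
}
#: Side-chain N/O hydrogen-bond acceptors, by residue type.
SC_ACCEPTOR_ATOMS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "ASN": ("OD1",),
    "GLN": ("OE1",), "HIS": ("ND1", "NE2"),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
}
#: Residues of the hydrophobic class whose side-chain C/S atoms count.
HYDROPHOBIC_RESIDUES = {"CYS", "LEU", "VAL", "ILE", "MET", "PHE", "TRP"}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class CensusParams:
    """Distance cutoffs (A) and the minimum sequence separation for pairs."""

    ionic_cutoff: float = 6.0
    cation_pi_cutoff: float = 6.0
    pi_pi_range: tuple[float, float] = (4.5, 7.0)
    hbond_cutoff: float = 3.5
    hydrophobic_cutoff: float = 5.0
    min_seq_separation: int = 2

    def __post_init__(self) -> None:
        cuts = (self.ionic_cutoff, self.cation_pi_cutoff, self.hbond_cutoff,
                self.hydrophobic_cutoff, *self.pi_pi_range)
        if any(c <= 0 for c in cuts):
            raise ValueError("all cutoffs must be positive")
        if not self.pi_pi_range[0] < self.pi_pi_range[1]:
            raise ValueError("pi_pi_range lower bound must be below upper bound")


@dataclass
class ResidueGeometry:
    """Derived interaction-relevant atom groups for one residue."""

    key: tuple[str, int]
    residue_name: str
    cation_atoms: np.ndarray        # (k, 3), possibly empty
    anion_atoms: np.ndarray
    ring_centroid: np.ndarray | None
    donor_atoms: np.ndarray
    acceptor_atoms: np.ndarray
    hydrophobic_atoms: np.ndarray


def _element_of(atom: Atom) -> str:
    if atom.element:
        return atom.element.upper()
    name = atom.name.lstrip("0123456789")
    return name[:1].upper()


def _coords_for(atoms: list[Atom], names: tuple[str, ...]) -> np.ndarray:
    sel = [a.coords for a in atoms if a.name in names]
    return np.array(sel).reshape(len(sel), 3)


def residue_geometry(structure: Structure) -> list[ResidueGeometry]:
    """Derive cation/anion/donor/acceptor/hydrophobic atom groups and
    aromatic ring centroids for every residue.

    Incomplete side chains yield partial (or empty) atom groups; an
    aromatic residue missing ring atoms gets no centroid, and the count of
    such residues is logged.
    """
    geoms: list[ResidueGeometry] = []
    n_incomplete_rings = 0
    for key, atoms in structure.residues.items():
        resname = atoms[0].residue_name
        centroid = None
        if resname in RING_ATOMS:
            ring = _coords_for(atoms, RING_ATOMS[resname])
            if len(ring) == len(RING_ATOMS[resname]):
                centroid = ring.mean(axis=0)
            else:
                n_incomplete_rings += 1
        hydrophobic = np.empty((0, 3))
        if resname in HYDROPHOBIC_RESIDUES:
            sel = [
                a.coords for a in atoms
                if a.name not in _BACKBONE and _element_of(a) in ("C", "S")
            ]
            hydrophobic = np.array(sel).reshape(len(sel), 3)
        geoms.append(ResidueGeometry(
            key=key,
            residue_name=resname,
            cation_atoms=_coords_for(atoms, CATION_ATOMS.get(resname, ())),
            anion_atoms=_coords_for(atoms, ANION_ATOMS.get(resname, ())),
            ring_centroid=centroid,
            donor_atoms=_coords_for(atoms, SC_DONOR_ATOMS.get(resname, ())),
            acceptor_atoms=_coords_for(atoms, SC_ACCEPTOR_ATOMS.get(resname, ())),
            hydrophobic_atoms=hydrophobic,
        ))
    if n_incomplete_rings:
        logger.info("residue_geometry: %d aromatic residues with incomplete rings",
                    n_incomplete_rings)
    return geoms


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return np.inf
    return float(cdist(a, b).min())


def _pairs(geoms: list[ResidueGeometry], min_sep: int):
    for gi, gj in itertools.combinations(geoms, 2):
        if abs(gi.key[1] - gj.key[1]) < min_sep:
            continue
        yield gi, gj


def detect_ionic(geoms, params: CensusParams | None = None):
    """Residue pairs with a cation atom within the ionic cutoff of an
    anion atom (salt bridges)."""
    params = params or CensusParams()
    out = []
    for gi, gj in _pairs(geoms, params.min_seq_separation):
        d = min(_min_dist(gi.cation_atoms, gj.anion_atoms),
                _min_dist(gj.cation_atoms, gi.anion_atoms))
        if d <= params.ionic_cutoff:
            out.append((gi.key, gj.key))
    return out


def detect_cation_pi(geoms, params: CensusParams | None = None):
    """Residue pairs with an Arg/Lys cation atom within the cutoff of an
    aromatic ring centroid."""
    params = params or CensusParams()
    out = []
    for gi, gj in _pairs(geoms, params.min_seq_separation):
        d = np.inf
        if gj.ring_centroid is not None:
            d = min(d, _min_dist(gi.cation_atoms, gj.ring_centroid[None, :]))
        if gi.ring_centroid is not None:
            d = min(d, _min_dist(gj.cation_atoms, gi.ring_centroid[None, :]))
        if d <= params.cation_pi_cutoff:
            out.append((gi.key, gj.key))
    return out


def detect_pi_pi(geoms, params: CensusParams | None = None):
    """Aromatic residue pairs whose ring centroids are within the pi-pi
    distance window."""
    params = params or CensusParams()
    lo, hi = params.pi_pi_range
    out = []
    for gi, gj in _pairs(geoms, params.min_seq_separation):
        if gi.ring_centroid is None or gj.ring_centroid is None:
            continue
        d = float(np.linalg.norm(gi.ring_centroid - gj.ring_centroid))
        if lo <= d <= hi:
            out.append((gi.key, gj.key))
    return out


def detect_hbond_sc_sc(geoms, params: CensusParams | None = None):
    """Residue pairs with a side-chain donor N/O within the H-bond cutoff
    of the other residue's side-chain acceptor N/O (distance-only)."""
    params = params or CensusParams()
    out = []
    for gi, gj in _pairs(geoms, params.min_seq_separation):
        d = min(_min_dist(gi.donor_atoms, gj.acceptor_atoms),
                _min_dist(gj.donor_atoms, gi.acceptor_atoms))
        if d <= params.hbond_cutoff:
            out.append((gi.key, gj.key))
    return out


def detect_hydrophobic(geoms, params: CensusParams | None = None):
    """Pairs of hydrophobic-class residues with side-chain C/S atoms within
    the hydrophobic cutoff."""
    params = params or CensusParams()
    out = []
    for gi, gj in _pairs(geoms, params.min_seq_separation):
        if _min_dist(gi.hydrophobic_atoms, gj.hydrophobic_atoms) <= params.hydrophobic_cutoff:
            out.append((gi.key, gj.key))
    return out


_DETECTORS = {
    "ionic": detect_ionic,
    "cation_pi": detect_cation_pi,
    "pi_pi": detect_pi_pi,
    "hbond_sc_sc": detect_hbond_sc_sc,
    "hydrophobic": detect_hydrophobic,
}


@dataclass
class InteractionCensus:
    """Per-structure interaction counts, raw and normalized per amino acid."""

    structure_id: str
    n_residues: int
    counts: dict[str, int]
    per_aa: dict[str, float]

    @property
    def total_per_aa(self) -> float:
        return float(sum(self.per_aa.values()))

    @classmethod
    def from_per_aa(cls, structure_id: str, n_residues: int,
                    per_aa: dict[str, float]) -> "InteractionCensus":
        """Build a census from already-normalized per-amino-acid values
        (e.g. published group means used as inputs)."""
        per_aa = {t: float(per_aa.get(t, 0.0)) for t in INTERACTION_TYPES}
        counts = {t: int(round(v * n_residues)) for t, v in per_aa.items()}
        return cls(structure_id, n_residues, counts, per_aa)


def census(structure: Structure, params: CensusParams | None = None) -> InteractionCensus:
    """Run all five detectors on a structure and normalize per residue."""
    params = params or CensusParams()
    n = structure.n_residues
    if n == 0:
        raise ValueError("empty structure")
    geoms = residue_geometry(structure)
    counts = {t: len(det(geoms, params)) for t, det in _DETECTORS.items()}
    per_aa = {t: c / n for t, c in counts.items()}
    return InteractionCensus(structure.id, n, counts, per_aa)


def format_percent(value: float) -> str:
    """Percent formatting convention: one decimal below 10%, integer above."""
    return f"{value:.1f}%" if abs(value) < 10 else f"{value:.0f}%"


def percent_increase(mean_a: float, mean_b: float) -> float | None:
    """Percent increase of B over A, 100*(B-A)/A; None (undefined) when the
    reference mean A is zero."""
    if mean_a == 0:
        return None
    return 100.0 * (mean_b - mean_a) / mean_a


@dataclass
class GroupCensusSummary:
    """Per-type group means and the percent increase of group B over A.

    The mean is the unweighted mean of per-amino-acid values over the
    structures of each group.  percent_increase[t] is 100*(B-A)/A, or None
    (undefined) when the group-A mean is zero.  The key ``"total"`` covers
    the summed per-AA interactions.
    """

    mean_a: dict[str, float]
    mean_b: dict[str, float]
    percent_increase: dict[str, float | None]

    def formatted(self) -> dict[str, str]:
        return {
            t: ("n/a" if v is None else format_percent(v))
            for t, v in self.percent_increase.items()
        }


def group_summary(
    censuses_a: list[InteractionCensus], censuses_b: list[InteractionCensus]
) -> GroupCensusSummary:
    """Summarize two groups of censuses (e.g. AP vs NAP structures)."""
    if not censuses_a or not censuses_b:
        raise ValueError("both groups must be non-empty")

    def _means(censuses):
        means = {
            t: float(np.mean([c.per_aa[t] for c in censuses]))
            for t in INTERACTION_TYPES
        }
        means["total"] = float(np.mean([c.total_per_aa for c in censuses]))
        return means

    mean_a, mean_b = _means(censuses_a), _means(censuses_b)
    pct = {t: percent_increase(mean_a[t], mean_b[t]) for t in mean_a}
    return GroupCensusSummary(mean_a=mean_a, mean_b=mean_b, percent_increase=pct)
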