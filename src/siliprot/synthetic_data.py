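"""Synthetic inputs carrying ground truth for every pipeline stage.

Three generators emulate the statistical structure of the real inputs:

* ``gen_sequences`` draws yeast-like globular protein sequences for the
  adsorbed (AP) and non-adsorbed (NAP) groups, with the AP residue
  frequencies depleted in aromatics (F, W, Y, H) and enriched in Arg/Glu.
* ``gen_structure`` builds toy single-chain structures in which a requested
  number of interaction pairs of each type is planted inside its distance
  window while everything else is kept far outside all windows; the exact
  expected interaction census is returned alongside the structure.
* ``gen_spot_tables`` builds a pair of log-normal 2-DE spot-volume tables
  whose post-normalization intensity ratios land in the AP / NAP /
  intermediate bands of the planted labels, so that partitioning recovers
  the labels exactly.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AA1_TO_3, AMINO_ACIDS, Atom, ProteinRecord, SpotTable, Structure
from .partition import ADSORBED, INTERMEDIATE, NON_ADSORBED
from .structcensus import INTERACTION_TYPES, InteractionCensus

#: Amino-acid frequencies of the S. cerevisiae proteome (renormalized).
YEAST_AA_FREQS: dict[str, float] = {
    "A": 0.0551, "C": 0.0132, "D": 0.0578, "E": 0.0656, "F": 0.0441,
    "G": 0.0498, "H": 0.0217, "I": 0.0657, "K": 0.0730, "L": 0.0957,
    "M": 0.0209, "N": 0.0613, "P": 0.0438, "Q": 0.0394, "R": 0.0445,
    "S": 0.0900, "T": 0.0588, "V": 0.0558, "W": 0.0104, "Y": 0.0337,
}


# ---------------------------------------------------------------------------
# Sequences

@dataclass
class SeqGenParams:
    """Conditions for the AP/NAP sequence pool.

    Group sizes default to the 31/46 AP/NAP split of the yeast study design;
    AP sequences are drawn from the background with aromatic frequencies
    scaled by (1 - aromatic_depletion) and Arg/Glu by
    (1 + arg_glu_enrichment), then renormalized.  Lengths are log-normal
    (mu, sigma on the log scale) truncated to ``length_range``.
    """

    n_ap: int = 31
    n_nap: int = 46
    background: dict[str, float] | None = None
    aromatic_depletion: float = 0.5
    arg_glu_enrichment: float = 0.2
    length_mu: float = 5.86
    length_sigma: float = 0.55
    length_range: tuple[int, int] = (50, 1500)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.aromatic_depletion < 1:
            raise ValueError("aromatic_depletion must be in [0, 1)")
        if self.arg_glu_enrichment < 0:
            raise ValueError("arg_glu_enrichment must be >= 0")
        if self.n_ap < 0 or self.n_nap < 0:
            raise ValueError("group sizes must be non-negative")


def _normalized_freqs(freqs: dict[str, float]) -> np.ndarray:
    vec = np.array([freqs[aa] for aa in AMINO_ACIDS], dtype=float)
    if np.any(vec < 0) or vec.sum() <= 0:
        raise ValueError("degenerate frequency vector")
    return vec / vec.sum()


def ap_frequencies(params: SeqGenParams) -> np.ndarray:
    """Background frequencies with the AP compositional shifts applied."""
    freqs = dict(params.background or YEAST_AA_FREQS)
    for aa in "FWYH":
        freqs[aa] *= 1.0 - params.aromatic_depletion
    for aa in "RE":
        freqs[aa] *= 1.0 + params.arg_glu_enrichment
    return _normalized_freqs(freqs)


def _draw_length(rng: np.random.Generator, params: SeqGenParams) -> int:
    lo, hi = params.length_range
    for _ in range(10000):
        n = int(round(rng.lognormal(params.length_mu, params.length_sigma)))
        if lo <= n <= hi:
            return n
    raise RuntimeError("length distribution incompatible with truncation range")


def gen_sequences(params: SeqGenParams | None = None
                  ) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Generate labeled AP and NAP protein sequences.

    Returns the records plus a ground-truth label map
    (id -> ``"adsorbed"`` / ``"non_adsorbed"``).
    """
    params = params or SeqGenParams()
    rng = np.random.default_rng(params.seed)
    aa = np.array(list(AMINO_ACIDS))
    bg = _normalized_freqs(params.background or YEAST_AA_FREQS)
    apf = ap_frequencies(params)

    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    for i in range(params.n_ap):
        n = _draw_length(rng, params)
        seq = "".join(rng.choice(aa, size=n, p=apf))
        rec = ProteinRecord(f"AP_{i + 1:03d}", seq)
        records.append(rec)
        labels[rec.id] = ADSORBED
    for i in range(params.n_nap):
        n = _draw_length(rng, params)
        seq = "".join(rng.choice(aa, size=n, p=bg))
        rec = ProteinRecord(f"NAP_{i + 1:03d}", seq)
        records.append(rec)
        labels[rec.id] = NON_ADSORBED
    return records, labels


# ---------------------------------------------------------------------------
# Structures

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # uniform rotation from a random quaternion
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _pentagon(center, radius=1.19):
    ang = np.linspace(0, 2 * np.pi, 5, endpoint=False)
    return [np.array(center) + radius * np.array([np.cos(a), np.sin(a), 0.0])
            for a in ang]


def _hexagon(center, radius=1.39, plane="xy"):
    ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    pts = []
    for a in ang:
        if plane == "xy":
            pts.append(np.array(center) + radius * np.array([np.cos(a), np.sin(a), 0.0]))
        else:  # ring normal along x
            pts.append(np.array(center) + radius * np.array([0.0, np.cos(a), np.sin(a)]))
    return pts


# Idealized local-coordinate residue templates (CA + side-chain atoms with
# the atom names the census cares about).  Geometry is plausible, not
# crystallographic: rings are exact regular polygons so centroids are defined.
def _build_templates() -> dict[str, list[tuple[str, np.ndarray]]]:
    t: dict[str, list[tuple[str, np.ndarray]]] = {}
    ca = np.zeros(3)

    def res(name, *atoms):
        t[name] = [("CA", ca)] + [(n, np.asarray(p, float)) for n, p in atoms]

    res("GLY")
    res("ALA", ("CB", (1.53, 0, 0)))
    res("PRO", ("CB", (1.53, 0, 0)), ("CG", (2.2, 1.3, 0)), ("CD", (1.4, 2.3, 0.3)))
    res("SER", ("CB", (1.53, 0, 0)), ("OG", (2.2, 1.25, 0)))
    res("THR", ("CB", (1.53, 0, 0)), ("OG1", (2.2, 1.25, 0)), ("CG2", (2.2, -1.2, 0.4)))
    res("CYS", ("CB", (1.53, 0, 0)), ("SG", (2.4, 1.4, 0)))
    res("VAL", ("CB", (1.53, 0, 0)), ("CG1", (2.2, 1.25, 0)), ("CG2", (2.2, -1.2, 0.4)))
    res("LEU", ("CB", (1.53, 0, 0)), ("CG", (2.4, 1.2, 0)),
        ("CD1", (3.9, 1.2, 0)), ("CD2", (1.9, 2.4, 0.6)))
    res("ILE", ("CB", (1.53, 0, 0)), ("CG1", (2.4, 1.2, 0)),
        ("CG2", (2.0, -1.3, 0.3)), ("CD1", (3.9, 1.3, 0)))
    res("MET", ("CB", (1.53, 0, 0)), ("CG", (2.4, 1.2, 0)),
        ("SD", (3.9, 1.3, 0)), ("CE", (4.6, 2.7, 0)))
    res("ASN", ("CB", (1.53, 0, 0)), ("CG", (2.4, 1.2, 0)),
        ("OD1", (3.6, 1.1, 0)), ("ND2", (1.9, 2.4, 0.4)))
    res("GLN", ("CB", (1.53, 0, 0)), ("CG", (2.4, 1.2, 0)), ("CD", (3.8, 1.3, 0)),
        ("OE1", (4.5, 0.3, 0)), ("NE2", (4.3, 2.5, 0.3)))
    res("ASP", ("CB", (1.53, 0, 0)), ("CG", (2.4, 1.2, 0)),
        ("OD1", (3.6, 1.1, 0)), ("OD2", (1.9, 2.4, 0.4)))
    res("GLU", ("CB", (1.53, 0, 0)), ("CG", (2.4, 1.2, 0)), ("CD", (3.8, 1.3, 0)),
        ("OE1", (4.9, 1.2, 0)), ("OE2", (3.4, 2.5, 0.3)))
    res("LYS", ("CB", (1.53, 0, 0)), ("CG", (2.4, 1.2, 0)), ("CD", (3.9, 1.3, 0)),
        ("CE", (4.6, 2.6, 0)), ("NZ", (6.0, 2.7, 0)))
    res("ARG", ("CB", (1.53, 0, 0)), ("CG", (2.4, 1.2, 0)), ("CD", (3.9, 1.3, 0)),
        ("NE", (4.6, 2.6, 0)), ("CZ", (5.9, 2.8, 0)),
        ("NH1", (6.8, 1.9, 0)), ("NH2", (6.3, 4.1, 0.2)))
    his_ring = _pentagon((3.3, 0.8, 0))
    res("HIS", ("CB", (1.53, 0, 0)),
        *zip(("CG", "ND1", "CE1", "NE2", "CD2"), his_ring))
    phe_ring = _hexagon((3.6, 0.9, 0))
    res("PHE", ("CB", (1.53, 0, 0)),
        *zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), phe_ring))
    res("TYR", ("CB", (1.53, 0, 0)),
        *zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), phe_ring),
        ("OH", (6.4, 1.6, 0)))
    trp_pent = _pentagon((2.9, 0.7, 0))
    trp_hex = _hexagon((5.0, 1.3, 0))
    res("TRP", ("CB", (1.53, 0, 0)),
        *zip(("CG", "CD1", "NE1", "CE2", "CD2"), trp_pent),
        *zip(("CE3", "CZ3", "CH2", "CZ2"), trp_hex[:4]))
    return t


RESIDUE_TEMPLATES = _build_templates()


@dataclass
class StructGenParams:
    """Conditions for a planted-interaction toy structure.

    ``planted`` lists (interaction type, count) pairs; each planted pair
    consumes two residues, the rest are inert fillers (Gly/Ala/Pro).
    Units are placed on a jittered cubic lattice whose spacing guarantees
    at least ~12 A between residues of different units, i.e. outside every
    detection window.
    """

    n_residues: int = 50
    box_size: float = 150.0
    planted: tuple[tuple[str, int], ...] = ()
    seed: int = 0


# Local constructions of planted pairs.  Distances are drawn inside each
# type's detection window but outside every other type's window; residue
# types are chosen so no second interaction type can fire within a pair.
def _plant_ionic(rng):
    d = rng.uniform(4.2, 5.9)
    a = ("ARG", [("CA", (-4.0, 0, 0.5)), ("NE", (-1.6, -0.9, 0)),
                 ("CZ", (-0.8, 0.7, 0)), ("NH1", (0, 0, 0)), ("NH2", (-0.8, 2.0, 0))])
    b = ("GLU", [("CA", (d + 3.5, 0, 0.5)), ("CD", (d + 0.7, 1.0, 0)),
                 ("OE1", (d, 0, 0)), ("OE2", (d + 0.6, 2.1, 0))])
    return a, b


def _plant_cation_pi(rng):
    d = rng.uniform(4.0, 5.8)
    ring = _hexagon((d, 0, 0), plane="yz")
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    a = ("LYS", [("CA", (0, 0, 3.0)), ("CE", (0, 0, 1.5)), ("NZ", (0, 0, 0))])
    b = ("PHE", [("CA", (d, 4.4, 0)), ("CB", (d, 2.9, 0))] + list(zip(names, ring)))
    return a, b


def _plant_pi_pi(rng):
    d = rng.uniform(5.0, 6.8)
    names = ("CG", "ND1", "CE1", "NE2", "CD2")
    ring_a = _pentagon((0, 0, 0))
    ring_b = _pentagon((0, 0, d))
    a = ("HIS", [("CA", (4.2, 0, 0)), ("CB", (2.7, 0, 0))] + list(zip(names, ring_a)))
    b = ("HIS", [("CA", (4.2, 0, d)), ("CB", (2.7, 0, d))] + list(zip(names, ring_b)))
    return a, b


def _plant_hbond(rng):
    d = rng.uniform(2.6, 3.4)
    a = ("SER", [("CA", (-2.5, -1.0, 0)), ("CB", (-1.0, -1.0, 0)), ("OG", (0, 0, 0))])
    b = ("ASN", [("CA", (d + 3.7, 1.2, 0)), ("CB", (d + 2.2, 1.2, 0)),
                 ("CG", (d + 0.8, 1.0, 0)), ("OD1", (d, 0, 0)), ("ND2", (d + 0.4, 2.3, 0))])
    return a, b


def _plant_hydrophobic(rng):
    d = rng.uniform(4.0, 4.9)
    a = ("LEU", [("CA", (-2.0, -3.8, 0)), ("CB", (-1.2, -2.6, 0)),
                 ("CG", (-0.9, -1.2, 0)), ("CD1", (0, 0, 0)), ("CD2", (-2.2, -1.5, 0.8))])
    b = ("LEU", [("CA", (d + 2.0, -3.8, 0)), ("CB", (d + 1.2, -2.6, 0)),
                 ("CG", (d + 0.9, -1.2, 0)), ("CD1", (d, 0, 0)),
                 ("CD2", (d + 2.2, -1.5, 0.8))])
    return a, b


_PLANT_BUILDERS = {
    "ionic": _plant_ionic,
    "cation_pi": _plant_cation_pi,
    "pi_pi": _plant_pi_pi,
    "hbond_sc_sc": _plant_hbond,
    "hydrophobic": _plant_hydrophobic,
}

_FILLER_RESIDUES = ("GLY", "ALA", "PRO")
#: Required clearance between atoms of different placement units (A);
#: comfortably outside the widest detection window (7 A).
_UNIT_CLEARANCE = 12.0
_JITTER = 2.0


def _lattice_sites(box: float, spacing: float, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    m = int(box // spacing)
    if m**3 < n:
        raise ValueError(
            f"infeasible spec: {n} placement units at spacing {spacing:.0f} A "
            f"do not fit in a {box:.0f} A box"
        )
    cells = np.array(list(itertools.product(range(m), repeat=3)), dtype=float)
    chosen = cells[rng.choice(len(cells), size=n, replace=False)]
    jitter = rng.uniform(-_JITTER, _JITTER, size=(n, 3))
    return (chosen + 0.5) * spacing + jitter


def gen_structure(params: StructGenParams | None = None
                  ) -> tuple[Structure, InteractionCensus]:
    """Build a toy structure with planted interactions plus its exact census.

    Residues of a planted pair sit inside their type's cutoff window; all
    other inter-residue distances exceed 12 A, outside every window.  The
    returned census is the construction's ground truth, independent of the
    detectors.
    """
    params = params or StructGenParams()
    rng = np.random.default_rng(params.seed)
    for itype, count in params.planted:
        if itype not in _PLANT_BUILDERS:
            raise ValueError(f"unknown interaction type {itype!r}")
        if count < 0:
            raise ValueError("planted counts must be >= 0")
    n_pairs = sum(c for _, c in params.planted)
    n_fillers = params.n_residues - 2 * n_pairs
    if n_fillers < 0:
        raise ValueError(
            f"infeasible spec: {n_pairs} pairs need {2 * n_pairs} residues, "
            f"have {params.n_residues}"
        )

    # Build every unit in centered local coordinates first (a unit is one
    # planted pair or one filler residue); the lattice spacing then follows
    # from the largest unit radius so different units keep their clearance.
    units: list[list[tuple[str, list[tuple[str, np.ndarray]]]]] = []
    for itype, count in params.planted:
        for _ in range(count):
            res_a, res_b = _PLANT_BUILDERS[itype](rng)
            units.append([
                (res_a[0], [(nm, np.asarray(p, float)) for nm, p in res_a[1]]),
                (res_b[0], [(nm, np.asarray(p, float)) for nm, p in res_b[1]]),
            ])
    for _ in range(n_fillers):
        resname = _FILLER_RESIDUES[rng.integers(len(_FILLER_RESIDUES))]
        units.append([(resname, [(nm, p.copy())
                                 for nm, p in RESIDUE_TEMPLATES[resname]])])

    max_radius = 0.0
    for unit in units:
        coords = np.array([p for _, named in unit for _, p in named])
        center = 0.5 * (coords.max(axis=0) + coords.min(axis=0))
        for _, named in unit:
            for entry in range(len(named)):
                named[entry] = (named[entry][0], named[entry][1] - center)
        coords -= center
        max_radius = max(max_radius, float(np.linalg.norm(coords, axis=1).max()))

    spacing = 2.0 * max_radius + _UNIT_CLEARANCE + 4.0 * _JITTER
    sites = _lattice_sites(params.box_size, spacing, len(units), rng)

    members_a: list[tuple[str, list[tuple[str, np.ndarray]]]] = []
    members_b: list[tuple[str, list[tuple[str, np.ndarray]]]] = []
    fillers: list[tuple[str, list[tuple[str, np.ndarray]]]] = []
    for unit, site in zip(units, sites):
        rot = _random_rotation(rng)
        placed = [(resname, [(nm, rot @ p + site) for nm, p in named])
                  for resname, named in unit]
        if len(placed) == 2:
            members_a.append(placed[0])
            members_b.append(placed[1])
        else:
            fillers.append(placed[0])

    # Residue numbering: pair members go to opposite ends of the chain so
    # every planted pair clears the minimum sequence separation.
    ordered = members_a + fillers
    seqnums = list(range(1, len(ordered) + 1))
    start_b = len(ordered) + 2
    ordered += members_b
    seqnums += list(range(start_b, start_b + len(members_b)))

    atoms: list[Atom] = []
    serial = 1
    for (resname, named_coords), seqnum in zip(ordered, seqnums):
        for name, xyz in named_coords:
            atoms.append(Atom(
                serial=serial, name=name, residue_name=resname, chain="A",
                residue_seq=seqnum, coords=np.asarray(xyz, float),
                element=name.lstrip("0123456789")[0],
            ))
            serial += 1

    structure = Structure(id=f"synthetic_{params.seed}", atoms=atoms)
    counts = {t: 0 for t in INTERACTION_TYPES}
    for itype, count in params.planted:
        counts[itype] += count
    n = structure.n_residues
    expected = InteractionCensus(
        structure_id=structure.id, n_residues=n,
        counts=counts, per_aa={t: c / n for t, c in counts.items()},
    )
    return structure, expected


def gen_random_structure(n_residues: int = 50, box: float = 40.0,
                         seed: int = 0) -> Structure:
    """A random dense toy structure (no ground truth) for oracle testing.

    Residue types are drawn from all 20 templates and thrown uniformly into
    a small box, so many atom pairs straddle the census cutoffs.
    """
    rng = np.random.default_rng(seed)
    names = list(RESIDUE_TEMPLATES)
    atoms: list[Atom] = []
    serial = 1
    for i in range(n_residues):
        resname = names[rng.integers(len(names))]
        rot = _random_rotation(rng)
        site = rng.uniform(0, box, size=3)
        for name, xyz in RESIDUE_TEMPLATES[resname]:
            atoms.append(Atom(
                serial=serial, name=name, residue_name=resname, chain="A",
                residue_seq=i + 1, coords=rot @ xyz + site,
                element=name.lstrip("0123456789")[0],
            ))
            serial += 1
    return Structure(id=f"random_{seed}", atoms=atoms)


# ---------------------------------------------------------------------------
# Spot tables

def gen_spot_tables(labels: dict[str, str], seed: int = 0
                    ) -> tuple[SpotTable, SpotTable]:
    """Generate adsorbed/non-adsorbed gel spot tables for planted labels.

    Log-normal base volumes are drawn per protein and intensity ratios are
    planted in the band of each label (log10 ratio in [0.35, 0.9] for AP,
    [-0.9, -0.35] for NAP, within +-0.08 of 0 for intermediates).  Because
    per-gel normalization rescales all ratios by a common factor, gel
    weights are rebalanced with one linear solve so the post-normalization
    ratios equal the planted ones exactly and ``partition`` recovers every
    label.  Label sets entirely above (or below) ratio 1 cannot satisfy the
    normalization constraint and raise ``ValueError``.
    """
    if not labels:
        raise ValueError("need at least one protein")
    ids = list(labels)
    lab = np.array([labels[i] for i in ids])
    known = {ADSORBED, NON_ADSORBED, INTERMEDIATE}
    unknown = set(lab) - known
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n = len(ids)
    base = rng.lognormal(0.0, 1.0, n)

    ap = lab == ADSORBED
    nap = lab == NON_ADSORBED
    inter = lab == INTERMEDIATE
    log_rho = np.zeros(n)
    log_rho[ap] = rng.uniform(0.35, 0.9, ap.sum())
    log_rho[nap] = rng.uniform(-0.9, -0.35, nap.sum())
    mags = rng.uniform(0.01, 0.08, inter.sum())
    if ap.any() and not nap.any():
        signs = -np.ones(inter.sum())
    elif nap.any() and not ap.any():
        signs = np.ones(inter.sum())
    else:
        signs = np.where(np.arange(inter.sum()) % 2 == 0, -1.0, 1.0)
    log_rho[inter] = signs * mags
    rho = 10.0 ** log_rho

    # Rebalance so sum(base * rho) == sum(base): then normalizing each gel
    # to total 1 leaves every planted ratio unchanged.
    excess = base * (rho - 1.0)
    gain, loss = excess > 0, excess < 0
    if gain.any() and loss.any():
        beta = excess[gain].sum() / (-excess[loss].sum())
        base = base.copy()
        base[loss] *= beta
    elif gain.any() or loss.any():
        if not inter.all():
            raise ValueError(
                "infeasible label spec: ratios cannot all sit on one side of 1"
            )
        # a single intermediate protein normalizes to ratio exactly 1

    adsorbed_volumes = base * rho * 10.0 ** rng.uniform(2, 4)
    nonadsorbed_volumes = base * 10.0 ** rng.uniform(2, 4)
    return (
        SpotTable("adsorbed_gel", ids, adsorbed_volumes),
        SpotTable("nonadsorbed_gel", ids, nonadsorbed_volumes),
    )
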