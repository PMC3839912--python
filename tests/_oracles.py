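"""Independent brute-force oracles used by the tests.

These are deliberately naive re-derivations (pure-Python loops, direct
definitions) kept separate from the package implementation so that
agreement between the two routes is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np

from siliprot.structcensus import (
    ANION_ATOMS,
    CATION_ATOMS,
    HYDROPHOBIC_RESIDUES,
    INTERACTION_TYPES,
    RING_ATOMS,
    SC_ACCEPTOR_ATOMS,
    SC_DONOR_ATOMS,
)


def pair_count_relative_effect(x, y) -> float:
    """p-hat by its definition: (#{x<y} + 0.5 #{x=y}) / (n1*n2)."""
    total = 0.0
    for xv in x:
        for yv in y:
            if xv < yv:
                total += 1.0
            elif xv == yv:
                total += 0.5
    return total / (len(x) * len(y))


def bh_step_up(pvalues) -> np.ndarray:
    """BH adjusted p-values straight from the step-up definition."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running_min = min(running_min, p[idx] * m / (rank_from_top + 1))
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)


def _dist(p, q) -> float:
    return float(sum((a - b) ** 2 for a, b in zip(p, q)) ** 0.5)


def _named(atoms, names):
    return [a.coords for a in atoms if a.name in names]


def _ring_centroid(atoms):
    resname = atoms[0].residue_name
    if resname not in RING_ATOMS:
        return None
    pts = _named(atoms, RING_ATOMS[resname])
    if len(pts) != len(RING_ATOMS[resname]):
        return None
    return np.mean(pts, axis=0)


def brute_force_census_counts(structure, params) -> dict[str, int]:
    """Exhaustive O(n^2 * atoms^2) enumeration of all five interaction types."""
    residues = list(structure.residues.items())
    counts = dict.fromkeys(INTERACTION_TYPES, 0)
    backbone = {"N", "CA", "C", "O", "OXT"}
    for (key_i, atoms_i), (key_j, atoms_j) in itertools.combinations(residues, 2):
        if abs(key_i[1] - key_j[1]) < params.min_seq_separation:
            continue
        res_i, res_j = atoms_i[0].residue_name, atoms_j[0].residue_name

        hit = False
        for u, v in ((atoms_i, atoms_j), (atoms_j, atoms_i)):
            for cat in _named(u, CATION_ATOMS.get(u[0].residue_name, ())):
                for an in _named(v, ANION_ATOMS.get(v[0].residue_name, ())):
                    if _dist(cat, an) <= params.ionic_cutoff:
                        hit = True
        counts["ionic"] += hit

        cen_i, cen_j = _ring_centroid(atoms_i), _ring_centroid(atoms_j)
        hit = False
        for u, cen in ((atoms_i, cen_j), (atoms_j, cen_i)):
            if cen is None:
                continue
            for cat in _named(u, CATION_ATOMS.get(u[0].residue_name, ())):
                if _dist(cat, cen) <= params.cation_pi_cutoff:
                    hit = True
        counts["cation_pi"] += hit

        if cen_i is not None and cen_j is not None:
            d = _dist(cen_i, cen_j)
            counts["pi_pi"] += params.pi_pi_range[0] <= d <= params.pi_pi_range[1]

        hit = False
        for u, v in ((atoms_i, atoms_j), (atoms_j, atoms_i)):
            for don in _named(u, SC_DONOR_ATOMS.get(u[0].residue_name, ())):
                for acc in _named(v, SC_ACCEPTOR_ATOMS.get(v[0].residue_name, ())):
                    if _dist(don, acc) <= params.hbond_cutoff:
                        hit = True
        counts["hbond_sc_sc"] += hit

        hit = False
        if res_i in HYDROPHOBIC_RESIDUES and res_j in HYDROPHOBIC_RESIDUES:
            side_i = [a.coords for a in atoms_i
                      if a.name not in backbone and a.name.lstrip("0123456789")[0] in "CS"]
            side_j = [a.coords for a in atoms_j
                      if a.name not in backbone and a.name.lstrip("0123456789")[0] in "CS"]
            for p in side_i:
                for q in side_j:
                    if _dist(p, q) <= params.hydrophobic_cutoff:
                        hit = True
        counts["hydrophobic"] += hit
    return counts
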