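import numpy as np
import pytest

from _oracles import brute_force_census_counts
from siliprot import (
    Atom,
    CensusParams,
    InteractionCensus,
    Structure,
    census,
    detect_cation_pi,
    detect_hbond_sc_sc,
    detect_hydrophobic,
    detect_ionic,
    detect_pi_pi,
    gen_random_structure,
    gen_structure,
    group_summary,
    residue_geometry,
)
from siliprot.structcensus import format_percent, percent_increase
from siliprot.synthetic_data import StructGenParams, _random_rotation


def make_structure(*residues):
    """residues: (resname, residue_seq, [(atom_name, xyz), ...])"""
    atoms = []
    serial = 1
    for resname, seq, named in residues:
        for name, xyz in named:
            atoms.append(Atom(serial, name, resname, "A", seq, np.asarray(xyz, float),
                              name.lstrip("0123456789")[0]))
            serial += 1
    return Structure(id="constructed", atoms=atoms)


def hexagon(center, radius=1.39):
    ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    return [np.asarray(center) + radius * np.array([np.cos(a), np.sin(a), 0])
            for a in ang]


PHE_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


class TestResidueGeometry:
    def test_phe_centroid_at_hexagon_center(self):
        st = make_structure(
            ("PHE", 1, [("CA", (9, 9, 9))] + list(zip(PHE_RING_NAMES, hexagon((1, 2, 3))))),
        )
        geom = residue_geometry(st)[0]
        np.testing.assert_allclose(geom.ring_centroid, [1, 2, 3], atol=1e-12)

    def test_incomplete_ring_has_no_centroid(self):
        st = make_structure(
            ("PHE", 1, [("CA", (0, 0, 0))] + list(zip(PHE_RING_NAMES[:4], hexagon((0, 0, 0))))),
        )
        assert residue_geometry(st)[0].ring_centroid is None

    def test_glycine_has_empty_groups(self):
        st = make_structure(("GLY", 1, [("CA", (0, 0, 0))]))
        geom = residue_geometry(st)[0]
        assert len(geom.cation_atoms) == 0
        assert len(geom.anion_atoms) == 0
        assert len(geom.donor_atoms) == 0
        assert len(geom.acceptor_atoms) == 0
        assert len(geom.hydrophobic_atoms) == 0
        assert geom.ring_centroid is None

    def test_arg_with_missing_nh2_keeps_partial_cation_set(self):
        st = make_structure(
            ("ARG", 1, [("CA", (0, 0, 0)), ("NH1", (1, 0, 0)), ("NE", (2, 0, 0))]),
        )
        geom = residue_geometry(st)[0]
        assert len(geom.cation_atoms) == 2


def _two_residue(resname_a, atoms_a, resname_b, atoms_b):
    return make_structure((resname_a, 1, atoms_a), (resname_b, 5, atoms_b))


class TestDetectors:
    @pytest.mark.parametrize("distance,expected", [(5.9, 1), (6.1, 0)])
    def test_ionic_cutoff_at_6A(self, distance, expected):
        st = _two_residue(
            "ARG", [("CA", (-3, 0, 0)), ("NH1", (0, 0, 0))],
            "GLU", [("CA", (distance + 3, 0, 0)), ("OE1", (0, 0, distance))],
        )
        assert len(detect_ionic(residue_geometry(st))) == expected

    @pytest.mark.parametrize("distance,expected", [(5.0, 1), (6.5, 0)])
    def test_cation_pi_cutoff_at_6A(self, distance, expected):
        ring = list(zip(PHE_RING_NAMES, hexagon((0, 0, distance))))
        st = _two_residue(
            "LYS", [("CA", (0, -3, 0)), ("NZ", (0, 0, 0))],
            "PHE", [("CA", (4, 0, distance))] + ring,
        )
        assert len(detect_cation_pi(residue_geometry(st))) == expected

    @pytest.mark.parametrize("distance,expected", [(5.0, 1), (4.0, 0), (7.5, 0)])
    def test_pi_pi_window_4p5_to_7A(self, distance, expected):
        st = _two_residue(
            "PHE", [("CA", (4, 0, 0))] + list(zip(PHE_RING_NAMES, hexagon((0, 0, 0)))),
            "PHE", [("CA", (4, 0, distance))] + list(zip(PHE_RING_NAMES, hexagon((0, 0, distance)))),
        )
        assert len(detect_pi_pi(residue_geometry(st))) == expected

    @pytest.mark.parametrize("distance,expected", [(2.8, 1), (3.6, 0)])
    def test_hbond_cutoff_at_3p5A(self, distance, expected):
        st = _two_residue(
            "SER", [("CA", (-3, 0, 0)), ("OG", (0, 0, 0))],
            "ASP", [("CA", (distance + 3, 0, 0)), ("OD1", (distance, 0, 0))],
        )
        assert len(detect_hbond_sc_sc(residue_geometry(st))) == expected

    @pytest.mark.parametrize("distance,expected", [(4.5, 1), (5.2, 0)])
    def test_hydrophobic_cutoff_at_5A(self, distance, expected):
        st = _two_residue(
            "LEU", [("CA", (-3, 0, 0)), ("CD1", (0, 0, 0))],
            "LEU", [("CA", (distance + 3, 0, 0)), ("CD1", (distance, 0, 0))],
        )
        assert len(detect_hydrophobic(residue_geometry(st))) == expected

    def test_adjacent_residues_excluded_by_sequence_separation(self):
        st = make_structure(
            ("ARG", 1, [("CA", (-3, 0, 0)), ("NH1", (0, 0, 0))]),
            ("GLU", 2, [("CA", (8, 0, 0)), ("OE1", (5, 0, 0))]),
        )
        assert detect_ionic(residue_geometry(st)) == []
        relaxed = CensusParams(min_seq_separation=1)
        assert len(detect_ionic(residue_geometry(st), relaxed)) == 1

    def test_pairs_counted_once_despite_multiple_atom_contacts(self):
        st = _two_residue(
            "ARG", [("CA", (-3, 0, 0)), ("NH1", (0, 0, 0)), ("NH2", (0.5, 1, 0)),
                    ("NE", (-1, -1, 0))],
            "GLU", [("CA", (8, 0, 0)), ("OE1", (4, 0, 0)), ("OE2", (4.5, 1, 0))],
        )
        assert len(detect_ionic(residue_geometry(st))) == 1


class TestCensus:
    def test_planted_structure_counts_recovered(self):
        params = StructGenParams(
            n_residues=20, planted=(("ionic", 2), ("pi_pi", 1)), seed=3
        )
        structure, expected = gen_structure(params)
        result = census(structure)
        assert result.counts == expected.counts
        assert result.per_aa["ionic"] == pytest.approx(0.1)
        assert result.per_aa["pi_pi"] == pytest.approx(0.05)
        assert result.total_per_aa == pytest.approx(0.15)

    def test_isolated_residues_give_all_zero(self):
        structure, _ = gen_structure(StructGenParams(n_residues=10, seed=1))
        result = census(structure)
        assert all(c == 0 for c in result.counts.values())

    def test_total_equals_sum_of_components(self, rng):
        structure = gen_random_structure(40, 35.0, seed=11)
        result = census(structure)
        assert result.total_per_aa == pytest.approx(
            sum(result.per_aa.values()), abs=1e-12
        )

    def test_empty_structure_is_an_error(self):
        with pytest.raises(ValueError):
            census(Structure(id="x", atoms=[]))

    def test_matches_brute_force_oracle_on_random_structures(self):
        params = CensusParams()
        for seed in range(30):
            structure = gen_random_structure(50, 40.0, seed=seed)
            assert census(structure, params).counts == brute_force_census_counts(
                structure, params
            )

    def test_invariant_under_rigid_body_motion(self, rng):
        for seed in range(5):
            structure = gen_random_structure(40, 35.0, seed=seed)
            rot = _random_rotation(rng)
            shift = rng.uniform(-50, 50, 3)
            moved = Structure(
                id=structure.id,
                atoms=[
                    Atom(a.serial, a.name, a.residue_name, a.chain, a.residue_seq,
                         rot @ a.coords + shift, a.element)
                    for a in structure.atoms
                ],
            )
            assert census(structure).counts == census(moved).counts

    def test_enlarging_cutoffs_never_decreases_counts(self):
        tight = CensusParams()
        loose = CensusParams(
            ionic_cutoff=8, cation_pi_cutoff=8, pi_pi_range=(3.5, 9),
            hbond_cutoff=4.5, hydrophobic_cutoff=7,
        )
        for seed in range(10):
            structure = gen_random_structure(50, 40.0, seed=seed)
            tight_counts = census(structure, tight).counts
            loose_counts = census(structure, loose).counts
            for itype in tight_counts:
                assert loose_counts[itype] >= tight_counts[itype]

    def test_atom_order_reversal_gives_same_census(self):
        structure = gen_random_structure(40, 35.0, seed=2)
        reversed_structure = Structure(id=structure.id, atoms=structure.atoms[::-1])
        assert census(structure).counts == census(reversed_structure).counts


class TestGroupSummary:
    def test_percent_increase_from_published_group_means(self):
        # census objects built from per-AA group means; B-over-A increases
        ap = InteractionCensus.from_per_aa("ap_mean", 1000, {
            "ionic": 0.100, "cation_pi": 0.02, "pi_pi": 0.026,
            "hbond_sc_sc": 0.278, "hydrophobic": 0.785,
        })
        nap = InteractionCensus.from_per_aa("nap_mean", 1000, {
            "ionic": 0.102, "cation_pi": 0.026, "pi_pi": 0.046,
            "hbond_sc_sc": 0.325, "hydrophobic": 0.858,
        })
        summary = group_summary([ap], [nap])
        assert round(summary.percent_increase["pi_pi"]) == 77
        assert round(summary.percent_increase["cation_pi"]) == 30
        assert round(summary.percent_increase["ionic"]) == 2
        assert round(summary.percent_increase["hbond_sc_sc"]) == 17
        # the published total row is computed from the printed totals
        assert round(percent_increase(1.204, 1.359)) == 13

    def test_zero_group_a_mean_is_flagged_undefined(self):
        a = InteractionCensus.from_per_aa("a", 10, {"ionic": 0.0})
        b = InteractionCensus.from_per_aa("b", 10, {"ionic": 0.1})
        summary = group_summary([a], [b])
        assert summary.percent_increase["ionic"] is None
        assert summary.formatted()["ionic"] == "n/a"

    def test_percent_formatting_convention(self):
        assert format_percent(9.5) == "9.5%"
        assert format_percent(77.2) == "77%"

    def test_empty_group_is_an_error(self):
        c = InteractionCensus.from_per_aa("a", 10, {"ionic": 0.1})
        with pytest.raises(ValueError):
            group_summary([], [c])
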