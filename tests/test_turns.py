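"""Turn detection, the 30/45 tolerance rule, type assignment, annotations."""

import math

import numpy as np
import pytest

from turnext.fixtures import all_coil_for, build_backbone, make_turn_structure
from turnext.geometry import compute_dihedrals
from turnext.secondary import SSRecord
from turnext.turns import (DihedralQuad, assign_classical, assign_extended,
                           assign_obsolete, assign_turns, classify_extent,
                           detect_turns, label_regions, load_regions,
                           matches_definition)

# ---------------------------------------------------------------------------
# brute-force oracle, independent of the package's angle helpers


def oracle_delta(a, b):
    d = math.fmod(abs(a - b), 360.0)
    return min(d, 360.0 - d)


def oracle_matches(quad, canonical, tol_main=30.0, tol_loose=45.0):
    devs = [oracle_delta(q, c) for q, c in zip(quad, canonical)]
    for loose in range(4):
        ok = all(d <= (tol_loose if j == loose else tol_main)
                 for j, d in enumerate(devs))
        if ok:
            return True
    return False


def oracle_assign_classical(quad, cis, definitions):
    best, best_key = "IV", None
    for d in definitions:
        if d.tier != "classical":
            continue
        if d.requires_cis_pro_i2 and not cis:
            continue
        if oracle_matches(quad, d.canonical):
            devs = [oracle_delta(q, c) for q, c in zip(quad, d.canonical)]
            key = (math.sqrt(sum(x * x for x in devs) / 4.0), d.name)
            if best_key is None or key < best_key:
                best, best_key = d.name, key
    return best


# ---------------------------------------------------------------------------


class TestMatchesDefinition:
    def test_exact_and_single_loose_angle(self, definitions):
        d = next(x for x in definitions if x.name == "I")
        assert matches_definition(d.canonical, d)
        shifted = DihedralQuad(d.canonical.phi1 + 40.0, d.canonical.psi1,
                               d.canonical.phi2, d.canonical.psi2)
        assert matches_definition(shifted, d)
        double = DihedralQuad(d.canonical.phi1 + 40.0, d.canonical.psi1 + 40.0,
                              d.canonical.phi2, d.canonical.psi2)
        assert not matches_definition(double, d)

    def test_tolerances_inclusive_at_bounds(self, definitions):
        d = next(x for x in definitions if x.name == "I")
        at30 = DihedralQuad(d.canonical.phi1, d.canonical.psi1,
                            d.canonical.phi2 + 30.0, d.canonical.psi2 + 30.0)
        assert matches_definition(at30, d)
        at45 = DihedralQuad(d.canonical.phi1 + 45.0, d.canonical.psi1,
                            d.canonical.phi2, d.canonical.psi2)
        assert matches_definition(at45, d)
        over45 = DihedralQuad(d.canonical.phi1 + 45.1, d.canonical.psi1,
                              d.canonical.phi2, d.canonical.psi2)
        assert not matches_definition(over45, d)

    def test_deviation_wraps_across_180(self, definitions):
        d = next(x for x in definitions if x.name == "VIb")  # psi2 = 160
        wrapped = DihedralQuad(d.canonical.phi1, d.canonical.psi1,
                               d.canonical.phi2, -175.0)  # 25 deg from 160
        assert matches_definition(wrapped, d)


class TestAssignment:
    def test_classical_exact_and_cis_gate(self, definitions):
        q2 = next(d for d in definitions if d.name == "II").canonical
        assert assign_classical(q2, False, definitions) == "II"
        qvib = next(d for d in definitions if d.name == "VIb").canonical
        assert assign_classical(qvib, True, definitions) == "VIb"
        assert assign_classical(qvib, False, definitions) == "IV"

    def test_extended_centers_and_misc(self, definitions):
        assert assign_classical(DihedralQuad(-120, 130, 55, 41), False,
                                definitions) == "IV"
        assert assign_extended(DihedralQuad(-120, 130, 55, 41),
                               definitions) == "IV1"
        assert assign_extended(DihedralQuad(-85, -15, -125, 55),
                               definitions) == "IV2"
        assert assign_extended(DihedralQuad(0, 0, 0, 0),
                               definitions) == "IV_misc"
        for c in [(-120, 130, 55, 41), (0, 0, 0, 0)]:
            assert not any(
                oracle_matches(c, d.canonical) for d in definitions
                if d.tier == ("extended" if c == (0, 0, 0, 0) else "classical"))

    def test_obsolete_annotation_rides_alongside(self, definitions):
        """A type-III conformation is mainly assigned I, annotated III."""
        q3 = DihedralQuad(-60, -30, -60, -30)
        # deviation from type I canonicals is (0, 0, 30, 30): inside the rule
        assert assign_classical(q3, False, definitions) == "I"
        assert assign_obsolete(q3, definitions) == "III"
        assert assign_obsolete(DihedralQuad(-120, 130, 55, 41),
                               definitions) is None

    def test_mirror_symmetry(self, definitions):
        """Negating all angles of I and II canonicals gives I' and II'."""
        for name, mirror in [("I", "I'"), ("II", "II'")]:
            q = next(d for d in definitions if d.name == name).canonical
            neg = DihedralQuad(*(-v for v in q))
            assert assign_classical(neg, False, definitions) == mirror

    def test_agrees_with_brute_force_oracle(self, definitions):
        rng = np.random.default_rng(42)
        quads = rng.uniform(-180.0, 180.0, size=(2000, 4))
        for row in quads:
            q = DihedralQuad(*row)
            for cis in (False, True):
                assert assign_classical(q, cis, definitions) == \
                    oracle_assign_classical(q, cis, definitions)


class TestDetection:
    def test_canonical_fixture_yields_one_turn(self, definitions):
        chain, ss = make_turn_structure("I", definitions)
        turns = detect_turns(chain, compute_dihedrals(chain), ss)
        starts = [t.start_residue for t in turns]
        assert starts == [2]
        assert turns[0].ca_distance_i_i3 < 7.0

    def test_helical_central_residues_block_detection(self, definitions):
        chain, ss = make_turn_structure("I", definitions)
        for r in ss:
            if r.residue_number in (3, 4):
                r.dssp_code = "H"
        assert detect_turns(chain, compute_dihedrals(chain), ss) == []

    def test_strand_window_needs_a_coil(self, definitions):
        chain, ss = make_turn_structure("I", definitions)
        for r in ss:
            r.dssp_code = "E"
        assert detect_turns(chain, compute_dihedrals(chain), ss) == []
        ss[1].dssp_code = " "  # residue i becomes coil
        assert len(detect_turns(chain, compute_dihedrals(chain), ss)) == 1

    def test_extended_chain_exceeds_distance_gate(self):
        chain = build_backbone([(-139.0, 135.0, 180.0)] * 6, ["ALA"] * 6)
        ss = all_coil_for(chain)
        assert detect_turns(chain, compute_dihedrals(chain), ss) == []


class TestExtentAndRegions:
    def test_synthetic_traces_at_180_and_90_degrees(self):
        chain, _ = make_turn_structure("I")
        turns = assign_turns(chain, compute_dihedrals(chain), all_coil_for(chain))
        t = turns[0]
        i = t.start_index
        # overwrite the CA trace with exact synthetic directions
        chain[i].coords_CA = np.array([0.0, 0.0, 0.0])
        chain[i + 1].coords_CA = np.array([1.0, 0.0, 0.0])
        chain[i + 2].coords_CA = np.array([1.0, 1.0, 0.0])
        chain[i + 3].coords_CA = np.array([0.0, 1.0, 0.0])
        extent, _ = classify_extent(chain, t)
        assert extent == "full"  # u2 = -u1
        chain[i + 3].coords_CA = np.array([1.0, 1.0, 1.0])
        extent, _ = classify_extent(chain, t)
        assert extent == "half"  # u2 perpendicular to u1

    def test_extent_against_vector_oracle(self):
        """Extent from built coordinates matches an explicit angle computation."""
        for name in ("I", "II", "IV1"):
            chain, ss = make_turn_structure(name)
            t = assign_turns(chain, compute_dihedrals(chain), ss)[0]
            i = t.start_index
            u1 = chain[i + 1].coords_CA - chain[i].coords_CA
            u2 = chain[i + 3].coords_CA - chain[i + 2].coords_CA
            theta = math.degrees(math.acos(
                np.dot(u1, u2) / (np.linalg.norm(u1) * np.linalg.norm(u2))))
            assert t.extent == ("full" if theta >= 135.0 else "half")
            assert t.crawford_short == (t.ca_distance_i_i3 < 5.7)

    @pytest.mark.parametrize("quad,wt,efimov", [
        ((-120, 130, 55, 41), ("beta_E", "alpha_L"), ("beta_E", "alpha_L")),
        ((-85, -15, -125, 55), ("alpha_R", "beta_E"), ("gamma", "delta")),
        ((-97, -2, -117, -11), ("alpha_R", "alpha_R"), ("gamma", "gamma")),
    ])
    def test_region_labels(self, regions, quad, wt, efimov):
        q = DihedralQuad(*quad)
        assert label_regions(q, "wilmot_thornton", regions) == wt
        assert label_regions(q, "efimov", regions) == efimov

    def test_point_outside_all_boxes_unassigned(self, regions):
        assert label_regions(DihedralQuad(0, 0, 0, 0), "wilmot_thornton",
                             regions) == ("unassigned", "unassigned")

    def test_overlapping_region_config_rejected(self, tmp_path):
        bad = tmp_path / "regions.yaml"
        bad.write_text(
            "s:\n"
            "  - {name: a, phi: [-180.0, 0.0], psi: [0.0, 90.0]}\n"
            "  - {name: b, phi: [-90.0, 90.0], psi: [45.0, 180.0]}\n")
        with pytest.raises(ValueError, match="overlap"):
            load_regions(bad)


class TestFullPipelineInvariants:
    def test_each_turn_gets_exactly_one_final_type(self, definitions):
        names = {"I", "I'", "II", "II'", "VIII", "VIa1", "VIa2", "VIb",
                 "IV1", "IV2", "IV3", "IV4", "IV_misc"}
        for d in definitions:
            if d.tier == "obsolete":
                continue
            chain, ss = make_turn_structure(d.name, definitions)
            for t in assign_turns(chain, compute_dihedrals(chain), ss,
                                  definitions):
                assert t.assigned_type in names
                assert t.ca_distance_i_i3 < 7.0

    def test_self_assignment_of_active_types(self, definitions):
        """Fixtures at canonical quads recover their own type.

        IV4 is the documented exception: its center lies within the 30/45
        tolerance of the classical type I definition (deviations 37, 28,
        27, 11 deg), and classical matching takes precedence, so a quad at
        exactly the IV4 center is a type I turn.
        """
        for d in definitions:
            if d.tier == "obsolete":
                continue
            chain, ss = make_turn_structure(d.name, definitions)
            t = [x for x in assign_turns(chain, compute_dihedrals(chain), ss,
                                         definitions)
                 if x.start_residue == 2][0]
            expected = "I" if d.name == "IV4" else d.name
            assert t.assigned_type == expected
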