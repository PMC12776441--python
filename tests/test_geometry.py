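"""Rigid-base frames, step/pair parameters, photodimer distances and pucker."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phototf.geometry import (STANDARD_BASES, PYRIMIDINE_RING, BaseFrame, Residue,
                              StructureModel, confidence_filter, compare_states,
                              d22, d64, dipyrimidine_geometry, fit_base_frame,
                              interbase_angle, load_structure, pair_parameters,
                              phase_from_torsions, pseudorotation,
                              stacking_overlap, step_parameters,
                              DipyrimidineGeometry)


def make_residue(base, R=None, t=None, chain="A", index=1, extra=None, conf=80.0):
    R = np.eye(3) if R is None else R
    t = np.zeros(3) if t is None else np.asarray(t, dtype=float)
    atoms = {a: R @ np.array(x) + t for a, x in STANDARD_BASES[base].items()}
    if extra:
        atoms.update({k: R @ np.asarray(v, dtype=float) + t for k, v in extra.items()})
    return Residue(chain, index, "D" + base, base, atoms,
                   {a: conf for a in atoms})


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=int(seed)).as_matrix()
    t = rng.normal(0, 10, 3)
    return R, t


class TestBaseFrame:
    def test_identity_fit(self):
        f = fit_base_frame(make_residue("T"))
        assert f.rmsd < 1e-9
        assert np.allclose(f.axes, np.eye(3), atol=1e-9)
        assert np.allclose(f.origin, 0, atol=1e-9)

    @pytest.mark.parametrize("base", ["A", "C", "G", "T"])
    def test_rotation_equivariance(self, base):
        R, t = random_rigid(3)
        f = fit_base_frame(make_residue(base, R, t))
        assert np.allclose(f.axes, R, atol=1e-9)
        assert np.allclose(f.origin, t, atol=1e-9)
        assert np.linalg.det(f.axes) == pytest.approx(1.0)

    def test_noisy_fit_matches_kabsch_oracle(self):
        rng = np.random.default_rng(7)
        res = make_residue("C")
        names = [a for a in PYRIMIDINE_RING if a in res.atoms]
        for a in names:
            res.atoms[a] = res.atoms[a] + rng.normal(0, 0.05, 3)
        f = fit_base_frame(res)
        # brute-force oracle: scan rotations via scipy align_vectors
        P = np.array([STANDARD_BASES["C"][a] for a in names])
        Q = np.array([res.atoms[a] for a in names])
        rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert f.rmsd == pytest.approx(rssd / np.sqrt(len(names)), abs=1e-9)

    def test_degenerate_atoms_error(self):
        res = make_residue("T")
        for a in res.atoms:
            res.atoms[a] = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_base_frame(res)


class TestStepParameters:
    def test_coincident_frames_zero(self):
        f = BaseFrame(np.zeros(3), np.eye(3))
        sp = step_parameters(f, f)
        assert np.allclose([sp.shift, sp.slide, sp.rise, sp.tilt, sp.roll,
                            sp.twist], 0, atol=1e-12)

    def test_pure_slide(self):
        f1 = BaseFrame(np.zeros(3), np.eye(3))
        f2 = BaseFrame(np.array([0, 1.5, 0.0]), np.eye(3))
        sp = step_parameters(f1, f2)
        assert sp.slide == pytest.approx(1.5, abs=1e-12)
        assert np.allclose([sp.shift, sp.rise, sp.tilt, sp.roll, sp.twist], 0,
                           atol=1e-12)

    def test_ideal_helix_round_trip(self):
        """Constructed twist/rise/shift/slide recovered to 1e-6."""
        twist, rise, shift, slide = 36.0, 3.4, 0.7, 1.5
        Rz = Rotation.from_rotvec([0, 0, math.radians(twist)]).as_matrix()
        Rm = Rotation.from_rotvec([0, 0, math.radians(twist / 2)]).as_matrix()
        f1 = BaseFrame(np.zeros(3), np.eye(3))
        f2 = BaseFrame(Rm @ np.array([shift, slide, rise]), Rz)
        sp = step_parameters(f1, f2)
        assert sp.twist == pytest.approx(twist, abs=1e-6)
        assert sp.rise == pytest.approx(rise, abs=1e-6)
        assert sp.shift == pytest.approx(shift, abs=1e-6)
        assert sp.slide == pytest.approx(slide, abs=1e-6)

    def test_tilt_roll_round_trip(self):
        """A bend about a known hinge decomposes into the planted tilt/roll."""
        tilt, roll = 4.0, 8.0
        gamma = math.hypot(tilt, roll)
        phi = math.atan2(tilt, roll)
        f1 = BaseFrame(np.zeros(3), np.eye(3))
        # hinge in the xy-plane at angle (90 - phi) from x: rotating f2 by
        # gamma about it produces roll = gamma cos(phi), tilt = gamma sin(phi)
        hinge = np.array([math.cos(math.pi / 2 - phi),
                          math.sin(math.pi / 2 - phi), 0.0])
        R2 = Rotation.from_rotvec(hinge * math.radians(gamma)).as_matrix()
        sp = step_parameters(f1, BaseFrame(np.zeros(3), R2))
        assert sp.roll == pytest.approx(roll, abs=1e-6)
        assert sp.tilt == pytest.approx(tilt, abs=1e-6)
        assert sp.twist == pytest.approx(0.0, abs=1e-6)


class TestPairParameters:
    def test_ideal_antiparallel_pair_zero(self):
        f1 = BaseFrame(np.zeros(3), np.eye(3))
        f2 = BaseFrame(np.zeros(3), np.eye(3) @ np.diag([1.0, -1.0, -1.0]))
        pp = pair_parameters(f1, f2)
        assert np.allclose([pp.shear, pp.stretch, pp.stagger, pp.buckle,
                            pp.propeller, pp.opening], 0, atol=1e-12)

    def test_parallel_frames_rejected(self):
        f1 = BaseFrame(np.zeros(3), np.eye(3))
        with pytest.raises(ValueError):
            pair_parameters(f1, f1, misorientation_tol_deg=90.0)


class TestDistances:
    def test_d22_three_four_five(self):
        r5 = make_residue("T")
        # translate so the C5-C6 midpoints differ by a (3,4,0) vector
        m = (r5.atoms["C5"] + r5.atoms["C6"]) / 2
        r3 = make_residue("T", t=np.array([3.0, 4.0, 0.0]))
        assert d22(r5, r3) == pytest.approx(5.0)

    def test_d64_acceptor_selection(self):
        r5 = make_residue("T")
        rT = make_residue("T", t=[1, 0, 0])
        rC = make_residue("C", t=[1, 0, 0])
        assert d64(r5, rT) == pytest.approx(
            np.linalg.norm(r5.atoms["C5"] - rT.atoms["O4"]))
        assert d64(r5, rC) == pytest.approx(
            np.linalg.norm(r5.atoms["C5"] - rC.atoms["N4"]))

    def test_purine_rejected(self):
        with pytest.raises(ValueError):
            d22(make_residue("A"), make_residue("T"))

    def test_rigid_motion_invariance(self):
        r5 = make_residue("T")
        r3 = make_residue("C", t=[1.0, 2.0, 3.2])
        R, t = random_rigid(11)
        r5r = make_residue("T", R, t)
        r3r = make_residue("C", R, R @ np.array([1.0, 2.0, 3.2]) + t)
        assert abs(d22(r5, r3) - d22(r5r, r3r)) < 1e-9
        assert abs(d64(r5, r3) - d64(r5r, r3r)) < 1e-9
        o1 = stacking_overlap(r5, r3)
        o2 = stacking_overlap(r5r, r3r)
        assert abs(o1 - o2) < 1e-9


class TestStackingOverlap:
    square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)

    def test_half_offset_unit_squares(self):
        assert stacking_overlap(self.square,
                                self.square + [0.5, 0, 0]) == pytest.approx(0.5)

    def test_eclipsed_equals_ring_area(self):
        r = make_residue("T")
        r2 = make_residue("T", t=[0, 0, 3.4])
        ring = np.array([r.atoms[a] for a in PYRIMIDINE_RING])
        from shapely.geometry import Polygon
        area = Polygon(ring[:, :2]).area
        assert stacking_overlap(r, r2) == pytest.approx(area, rel=1e-9)

    def test_separated_rings_zero(self):
        assert stacking_overlap(self.square, self.square + [5, 0, 0]) == 0.0

    def test_symmetric_and_bounded(self):
        r5 = make_residue("T")
        r3 = make_residue("C", Rotation.from_euler("x", 8, degrees=True).as_matrix(),
                          [0.5, 0.5, 3.4])
        o = stacking_overlap(r5, r3)
        assert o == pytest.approx(stacking_overlap(r3, r5), abs=1e-12)
        from shapely.geometry import Polygon
        a5 = Polygon(np.array([r5.atoms[a] for a in PYRIMIDINE_RING])[:, :2]).area
        assert 0 <= o <= a5 * 1.01

    def test_perpendicular_flagged(self):
        perp = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        r2 = np.array([perp @ p for p in self.square]) + [0, 0, 2]
        assert stacking_overlap(self.square, r2) is None


class TestPseudorotation:
    def test_symmetric_torsions_give_c3p_endo(self):
        sp = phase_from_torsions((-20.0, 30.0, -35.0, 30.0, -20.0))
        # numerator (nu4+nu1)-(nu3+nu0) = 0, nu2 < 0 -> P = 180 (C3'-exo);
        # with nu2 > 0 the phase is 0 (C3'-endo)
        sp = phase_from_torsions((20.0, -30.0, 35.0, -30.0, 20.0))
        assert sp.phase == pytest.approx(0.0)
        assert sp.label == "C3'-endo"

    def test_window_labels(self):
        tau = 38.0
        for P0, label in [(18, "C3'-endo"), (150, "C2'-endo"), (162, "C2'-endo"),
                          (54, "C4'-exo"), (252.1, "O4'-exo")]:
            nus = [tau * math.cos(math.radians(P0 + 144 * (j - 2)))
                   for j in range(5)]
            sp = phase_from_torsions(nus)
            assert sp.phase == pytest.approx(P0, abs=1e-9)
            assert sp.amplitude == pytest.approx(tau, abs=1e-9)
            assert sp.label == label

    def test_constructed_sugar_matches_hand_formula(self):
        """3D furanose ring: the module's P equals a hand evaluation of the
        arctangent formula on independently computed torsions."""
        rng = np.random.default_rng(5)
        # a puckered five-ring: pentagon with out-of-plane displacements
        names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
        ang = np.arange(5) * 2 * math.pi / 5
        coords = np.column_stack([1.4 * np.cos(ang), 1.4 * np.sin(ang),
                                  0.35 * np.cos(2 * ang + 1.1)])
        res = make_residue("T", extra=dict(zip(names, coords)))

        def torsion(p0, p1, p2, p3):  # independent oracle implementation
            b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            x = np.dot(n1, n2)
            y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
            return math.degrees(math.atan2(y, x))

        a = {n: coords[i] for i, n in enumerate(names)}
        nus = [torsion(a["C4'"], a["O4'"], a["C1'"], a["C2'"]),
               torsion(a["O4'"], a["C1'"], a["C2'"], a["C3'"]),
               torsion(a["C1'"], a["C2'"], a["C3'"], a["C4'"]),
               torsion(a["C2'"], a["C3'"], a["C4'"], a["O4'"]),
               torsion(a["C3'"], a["C4'"], a["O4'"], a["C1'"])]
        num = (nus[4] + nus[1]) - (nus[3] + nus[0])
        den = 2 * nus[2] * (math.sin(math.radians(36)) + math.sin(math.radians(72)))
        p_hand = math.degrees(math.atan2(num, den)) % 360
        sp = pseudorotation(res)
        assert sp.phase == pytest.approx(p_hand, abs=1e-9)
        assert np.allclose(sp.nu, nus, atol=1e-9)


class TestInterbaseAngle:
    @pytest.mark.parametrize("p,b,expect", [(3, 4, 5.0), (0, 0, 0.0),
                                            (-6, 8, 10.0)])
    def test_values(self, p, b, expect):
        assert interbase_angle(p, b) == pytest.approx(expect)


class TestStructureIO:
    def _write_structure(self, tmp_path, bvals=(80.0, 80.0), n_res=2, fmt="cif"):
        import gemmi
        st = gemmi.Structure()
        st.name = "toy"
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        bases = ["DT", "DC", "DT", "DT", "DC", "DT", "DT", "DT"]
        for i in range(n_res):
            res = gemmi.Residue()
            res.name = bases[i % len(bases)]
            res.seqid = gemmi.SeqId(i + 1, " ")
            letter = res.name[1]
            for aname, xyz in STANDARD_BASES[letter].items():
                at = gemmi.Atom()
                at.name = aname
                at.pos = gemmi.Position(xyz[0], xyz[1], xyz[2] + 3.4 * i)
                at.element = gemmi.Element(aname[0])
                at.b_iso = bvals[min(i, len(bvals) - 1)]
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        path = tmp_path / f"toy.{fmt}"
        if fmt == "cif":
            st.make_mmcif_document().write_file(str(path))
        else:
            st.write_pdb(str(path))
        return path

    @pytest.mark.parametrize("fmt", ["cif", "pdb"])
    def test_minimal_structure_parses(self, tmp_path, fmt):
        path = self._write_structure(tmp_path, fmt=fmt)
        model = load_structure(path)
        residues = model.all_residues()
        assert [r.base for r in residues] == ["T", "C"]
        assert residues[0].mean_confidence == pytest.approx(80.0)
        n_atoms = sum(len(r.atoms) for r in residues)
        assert n_atoms == len(STANDARD_BASES["T"]) + len(STANDARD_BASES["C"])

    def test_no_dna_chain_errors(self, tmp_path):
        import gemmi
        st = gemmi.Structure()
        st.add_model(gemmi.Model("1"))
        p = tmp_path / "empty.cif"
        st.make_mmcif_document().write_file(str(p))
        with pytest.raises(ValueError):
            load_structure(p)

    def test_confidence_filter_rules(self, tmp_path):
        # 8 residues; trim 3 from each end leaves residues 4,5 (0-based 3,4)
        path = self._write_structure(tmp_path,
                                     bvals=(10, 10, 10, 80, 80, 10, 10, 10),
                                     n_res=8)
        model = load_structure(path)
        ok, retained = confidence_filter(model, 70.0, trim_bp=3)
        assert ok and len(retained) == 2          # low-confidence termini trimmed
        ok2, _ = confidence_filter(model, 70.0, trim_bp=2)
        assert not ok2                             # interior low residue fails
        # an interior residue just below the threshold fails the structure
        (tmp_path / "b").mkdir()
        pathb = self._write_structure(tmp_path / "b",
                                      bvals=(80, 80, 80, 69.9, 80, 80, 80, 80),
                                      n_res=8)
        okb, _ = confidence_filter(load_structure(pathb), 70.0, 3)
        assert not okb


class TestCompareStates:
    def _geoms(self, values, state):
        return [DipyrimidineGeometry("s%d" % i, state, "TT", d22=v, d64=v + 1,
                                     overlap=v / 2, shift=0.1, slide=0.2,
                                     rise=3.3, interbase_angle=v,
                                     propeller=1.0, buckle=2.0)
                for i, v in enumerate(values)]

    def test_identical_states(self):
        b = self._geoms([3.0, 3.5, 4.0, 4.5], "bound")
        u = self._geoms([3.0, 3.5, 4.0, 4.5], "unbound")
        df = compare_states(b, u).set_index("parameter")
        assert df.loc["d22", "fold_change"] == pytest.approx(1.0)
        assert df.loc["d22", "p"] == 1.0

    def test_shifted_states_small_p(self):
        b = self._geoms([10.0, 10.5, 11.0, 11.5, 12.0], "bound")
        u = self._geoms([3.0, 3.5, 4.0, 4.5, 5.0], "unbound")
        df = compare_states(b, u).set_index("parameter")
        assert df.loc["d22", "p"] < 0.02
        assert df.loc["d22", "fold_change"] == pytest.approx(11.0 / 4.0)

    def test_thresholds_flag_only_when_configured(self):
        b = self._geoms([3.0, 3.2, 3.4], "bound")
        u = self._geoms([4.0, 4.2, 4.4], "unbound")
        df = compare_states(b, u)
        assert not df["reactive_flag"].any()
        df2 = compare_states(b, u, {"d22": (3.0, 3.6)}).set_index("parameter")
        assert bool(df2.loc["d22", "reactive_flag"])
        with pytest.raises(ValueError):
            compare_states(b, u, {"d22": (5.0, 3.0)})

    def test_too_few_structures(self):
        with pytest.raises(ValueError):
            compare_states(self._geoms([1, 2], "bound"),
                           self._geoms([1, 2, 3], "unbound"))


class TestDipyrimidineGeometry:
    def test_assembled_step_with_pairs(self):
        flip = np.diag([1.0, -1.0, -1.0])
        Rz = Rotation.from_rotvec([0, 0, math.radians(36)]).as_matrix()
        r5 = make_residue("T", index=1)
        p5 = make_residue("A", R=flip, index=8)
        r3 = make_residue("T", Rz, [0, 0, 3.4], index=2)
        p3 = make_residue("A", R=Rz @ flip, t=[0, 0, 3.4], index=7)
        g = dipyrimidine_geometry(r5, r3, p5, p3, "toy", "bound")
        assert g.step == "TT"
        assert g.rise == pytest.approx(3.4, abs=1e-6)
        assert g.interbase_angle == pytest.approx(0.0, abs=1e-6)
        assert g.d22 > 0 and g.d64 > 0
        assert g.pucker5 is None  # no sugar atoms in the toy bases
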