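"""Kabsch fitting, RMSD metrics, dihedral computation and D-score."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tcrmotion import structure_io as sio
from tcrmotion import superposition as sp
from tcrmotion import synthetic_data as sd

from conftest import random_cloud, random_rigid


def _residues_from_coords(coords_list):
    return [sd._make_residue(i + 1, "A", c) for i, c in enumerate(coords_list)]


def _translate(residues, t):
    out = []
    for r in residues:
        atoms = {n: sio.AtomRecord(n, a.element, a.coords + t) for n, a in r.atoms.items()}
        out.append(sio.Residue(r.imgt_number, r.insertion_code, r.aa, atoms))
    return out


class TestKabsch:
    def test_identity_on_equal_clouds(self, rng):
        P = random_cloud(rng)
        fit = sp.kabsch_fit(P, P)
        assert fit.fit_rmsd < 1e-12
        assert np.allclose(fit.transform.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(fit.transform.translation, 0, atol=1e-10)

    def test_recovers_applied_rigid_motion(self, rng):
        P = random_cloud(rng)
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        Q = P @ Rz.T + t
        fit = sp.kabsch_fit(P, Q)
        assert fit.fit_rmsd < 1e-10
        assert np.allclose(fit.transform.rotation, Rz, atol=1e-10)
        assert np.allclose(fit.transform.translation, t, atol=1e-9)

    def test_matches_independent_rotation_optimizer(self, rng):
        """fit_rmsd equals a brute-force minimum over rotations."""

        def best_rmsd(P, Q):
            Pc = P - P.mean(axis=0)
            Qc = Q - Q.mean(axis=0)

            def cost(rotvec):
                R = Rotation.from_rotvec(rotvec).as_matrix()
                return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

            best = np.inf
            for _ in range(12):
                res = minimize(cost, rng.normal(scale=2.0, size=3), method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
                best = min(best, res.fun)
            return best

        for _ in range(5):
            P = random_cloud(rng)
            Q = random_cloud(rng)
            assert sp.kabsch_fit(P, Q).fit_rmsd == pytest.approx(best_rmsd(P, Q), abs=1e-6)

    def test_invariant_to_rigid_premotion_of_either_cloud(self, rng):
        P, Q = random_cloud(rng), random_cloud(rng)
        base = sp.kabsch_fit(P, Q).fit_rmsd
        for _ in range(5):
            R1, t1 = random_rigid(rng)
            R2, t2 = random_rigid(rng)
            moved = sp.kabsch_fit(P @ R1.T + t1, Q @ R2.T + t2).fit_rmsd
            assert moved == pytest.approx(base, abs=1e-8)

    def test_degenerate_point_sets_raise(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(sp.DegeneracyError):
            sp.kabsch_fit(line, line + 1.0)

    def test_rotation_is_always_proper(self, rng):
        # reflection-prone target: mirrored cloud
        P = random_cloud(rng)
        Q = P * np.array([1.0, 1.0, -1.0])
        fit = sp.kabsch_fit(P, Q)
        assert np.linalg.det(fit.transform.rotation) == pytest.approx(1.0, abs=1e-10)


class TestBackboneRmsd:
    def test_uniform_translation_gives_its_magnitude(self):
        coords = sd.build_backbone([(-120, 130)] * 5)
        a = _residues_from_coords(coords)
        b = _translate(a, np.array([3.0, 4.0, 0.0]))
        assert sp.backbone_rmsd(a, b) == pytest.approx(5.0, abs=1e-12)
        assert sp.backbone_rmsd(a, b, superpose_first=True) == pytest.approx(0.0, abs=1e-9)

    def test_superposed_never_exceeds_unsuperposed(self, rng):
        coords = sd.build_backbone([(-100, 120)] * 6)
        a = _residues_from_coords(coords)
        for _ in range(10):
            b = [
                sio.Residue(r.imgt_number, r.insertion_code, r.aa,
                            {n: sio.AtomRecord(n, at.element,
                                               at.coords + rng.normal(scale=1.0, size=3))
                             for n, at in r.atoms.items()})
                for r in a
            ]
            assert (sp.backbone_rmsd(a, b, superpose_first=True)
                    <= sp.backbone_rmsd(a, b) + 1e-12)

    def test_correspondence_is_by_imgt_number(self):
        coords = sd.build_backbone([(-120, 130)] * 4)
        a = _residues_from_coords(coords)
        b = _translate(a, np.zeros(3))
        b = [b[0], b[2], b[3]]  # drop residue 2 on one side
        assert sp.backbone_rmsd(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_empty_overlap_raises(self):
        coords = sd.build_backbone([(-120, 130)] * 3)
        a = _residues_from_coords(coords)
        b = [sio.Residue(r.imgt_number + 50, "", r.aa, r.atoms) for r in a]
        with pytest.raises(sp.EmptySelectionError):
            sp.backbone_rmsd(a, b)


class TestPerResidueHeavyRmsd:
    def test_single_atom_move_follows_rms_formula(self):
        coords = sd.build_backbone([(-120, 130)] * 1)[0]
        # build an 8-atom residue by adding pseudo side-chain heavy atoms
        extra = {f"C{i}": coords["CA"] + np.array([0.5 * i, 1.0, 0.3]) for i in range(1, 4)}
        all_coords = {**coords, **extra}
        assert len(all_coords) == 8
        a = [sd._make_residue(1, "K", all_coords)]
        moved = dict(all_coords)
        moved["C3"] = moved["C3"] + np.array([0.0, 0.0, 1.0])
        b = [sd._make_residue(1, "K", moved)]
        # one atom displaced by 1 Å among 8 shared atoms
        [(key, value)] = sp.per_residue_heavy_rmsd(a, b)
        assert value == pytest.approx(1.0 / np.sqrt(8), abs=1e-12)

    def test_matches_direct_rms_formula_on_random_perturbations(self, rng):
        coords = sd.build_backbone([(-120, 130)] * 5)
        a = _residues_from_coords(coords)
        b = []
        expected = []
        for r in a:
            disp = {n: rng.normal(scale=0.4, size=3) for n in r.atoms}
            atoms = {n: sio.AtomRecord(n, at.element, at.coords + disp[n])
                     for n, at in r.atoms.items()}
            b.append(sio.Residue(r.imgt_number, r.insertion_code, r.aa, atoms))
            expected.append(np.sqrt(np.mean([np.sum(d ** 2) for d in disp.values()])))
        values = [v for _, v in sp.per_residue_heavy_rmsd(a, b)]
        assert values == pytest.approx(expected, abs=1e-12)

    def test_no_shared_atoms_is_absent_not_zero(self):
        a = [sd._make_residue(1, "A", sd.build_backbone([(-120, 130)])[0])]
        b = [sio.Residue(1, "", "A", {"XX": sio.AtomRecord("XX", "C", np.zeros(3))})]
        assert sp.per_residue_heavy_rmsd(a, b) == []


class TestDihedrals:
    def test_helix_construction_angles_are_recovered(self):
        coords = sd.build_backbone([(-57.0, -47.0)] * 8)
        series = sp.compute_dihedrals(_residues_from_coords(coords))
        assert np.allclose(np.rad2deg(series.phi[1:]), -57.0, atol=1e-6)
        assert np.allclose(np.rad2deg(series.psi[:-1]), -47.0, atol=1e-6)
        assert np.isnan(series.phi[0]) and np.isnan(series.psi[-1])

    def test_chain_break_suppresses_crossing_angles(self):
        coords = sd.build_backbone([(-120.0, 130.0)] * 6)
        shifted = [
            {k: v + (np.array([50.0, 0, 0]) if i >= 3 else 0) for k, v in c.items()}
            for i, c in enumerate(coords)
        ]
        series = sp.compute_dihedrals(_residues_from_coords(shifted))
        assert np.isnan(series.phi[3]) and np.isnan(series.psi[2])
        assert not np.isnan(series.phi[2]) and not np.isnan(series.psi[3])

    def test_torsions_match_biopython_oracle(self, rng):
        from Bio.PDB.vectors import Vector, calc_dihedral

        for _ in range(20):
            coords = sd.build_backbone(
                [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
                 for _ in range(4)]
            )
            residues = _residues_from_coords(coords)
            series = sp.compute_dihedrals(residues)
            for i in range(1, 4):
                ref = calc_dihedral(
                    Vector(*residues[i - 1].atoms["C"].coords),
                    Vector(*residues[i].atoms["N"].coords),
                    Vector(*residues[i].atoms["CA"].coords),
                    Vector(*residues[i].atoms["C"].coords),
                )
                assert series.phi[i] == pytest.approx(ref, abs=1e-9)


class TestDscore:
    def _series(self, phi, psi):
        n = len(phi)
        return sp.DihedralSeries([(i + 1, "") for i in range(n)],
                                 np.asarray(phi, float), np.asarray(psi, float))

    def test_identical_series_score_zero(self):
        a = self._series([0.5, -1.0], [1.2, 2.0])
        assert sp.dscore(a, a) == pytest.approx(0.0, abs=1e-15)

    def test_pi_flip_of_one_phi_scores_four(self):
        a = self._series([0.0], [1.0])
        b = self._series([np.pi], [1.0])
        assert sp.dscore(a, b) == pytest.approx(4.0, abs=1e-12)

    def test_symmetric_and_two_pi_invariant(self, rng):
        for _ in range(10):
            phi_a, psi_a = rng.uniform(-np.pi, np.pi, (2, 5))
            phi_b, psi_b = rng.uniform(-np.pi, np.pi, (2, 5))
            a = self._series(phi_a, psi_a)
            b = self._series(phi_b, psi_b)
            assert sp.dscore(a, b) == pytest.approx(sp.dscore(b, a), abs=1e-12)
            shifted = self._series(phi_b + 2 * np.pi, psi_b - 2 * np.pi)
            assert sp.dscore(a, shifted) == pytest.approx(sp.dscore(a, b), abs=1e-9)

    def test_bounded_by_eight_per_residue(self, rng):
        n = 6
        a = self._series(rng.uniform(-np.pi, np.pi, n), rng.uniform(-np.pi, np.pi, n))
        b = self._series(rng.uniform(-np.pi, np.pi, n), rng.uniform(-np.pi, np.pi, n))
        assert 0 <= sp.dscore(a, b) <= 8 * n

    def test_missing_angles_are_skipped_not_imputed(self):
        a = self._series([np.nan, 1.0], [0.5, 1.5])
        b = self._series([2.0, 1.0], [0.5, np.nan])
        # only phi_2, psi_1 contribute; both equal -> 0
        assert sp.dscore(a, b) == pytest.approx(0.0, abs=1e-15)

    def test_from_coordinates_matches_brute_force_geometry(self, rng):
        """Full path: coordinates -> dihedrals -> D-score vs a four-point oracle."""
        from Bio.PDB.vectors import Vector, calc_dihedral

        def oracle_dscore(res_a, res_b):
            total = 0.0
            for i in range(1, len(res_a) - 1):
                for names in (("C", "N", "CA", "C"), ("N", "CA", "C", "N")):
                    if names[0] == "C":  # phi: C(i-1), N, CA, C
                        pa = [res_a[i - 1].atoms["C"].coords, res_a[i].atoms["N"].coords,
                              res_a[i].atoms["CA"].coords, res_a[i].atoms["C"].coords]
                        pb = [res_b[i - 1].atoms["C"].coords, res_b[i].atoms["N"].coords,
                              res_b[i].atoms["CA"].coords, res_b[i].atoms["C"].coords]
                    else:  # psi: N, CA, C, N(i+1)
                        pa = [res_a[i].atoms["N"].coords, res_a[i].atoms["CA"].coords,
                              res_a[i].atoms["C"].coords, res_a[i + 1].atoms["N"].coords]
                        pb = [res_b[i].atoms["N"].coords, res_b[i].atoms["CA"].coords,
                              res_b[i].atoms["C"].coords, res_b[i + 1].atoms["N"].coords]
                    ta = calc_dihedral(*[Vector(*p) for p in pa])
                    tb = calc_dihedral(*[Vector(*p) for p in pb])
                    total += 2 * (1 - np.cos(ta - tb))
            return total

        for _ in range(10):
            tors_a = [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
                      for _ in range(5)]
            tors_b = [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
                      for _ in range(5)]
            res_a = _residues_from_coords(sd.build_backbone(tors_a))
            res_b = _residues_from_coords(sd.build_backbone(tors_b))
            # restrict to interior residues so both sides carry phi and psi
            sa = sp.compute_dihedrals(res_a)
            sb = sp.compute_dihedrals(res_b)
            mine = sum(
                2 * (1 - np.cos(sa.phi[i] - sb.phi[i])) + 2 * (1 - np.cos(sa.psi[i] - sb.psi[i]))
                for i in range(1, 4)
            )
            assert mine == pytest.approx(oracle_dscore(res_a, res_b), abs=1e-9)


class TestAlignments:
    def test_framework_alignment_undoes_rigid_motion(self, toy_tcr, rng):
        R, t = random_rigid(rng)
        moved = toy_tcr.transformed(R, t)
        back, fit = sp.align_tcr_framework(moved, toy_tcr)
        assert fit.fit_rmsd < 1e-8
        assert np.max(np.abs(back.all_coords() - toy_tcr.all_coords())) < 1e-6

    def test_displaced_loop_leaves_framework_fit_clean(self, toy_tcr):
        spec = sd.PerturbationSpec("CDR3b", rigid_displacement=2.0, seed=5)
        apo, holo, _ = sd.make_apo_holo_pair(toy_tcr, spec)
        aligned, fit = sp.align_tcr_framework(apo, holo)
        assert fit.fit_rmsd < 1e-8
        loops_a = sp.loop_residues(aligned, "CDR3b")
        loops_h = sp.loop_residues(holo, "CDR3b")
        assert sp.backbone_rmsd(loops_a, loops_h) == pytest.approx(2.0, abs=1e-9)

    def test_mhc_floor_alignment_undoes_rigid_motion(self, toy_pmhc, rng):
        R, t = random_rigid(rng)
        moved = toy_pmhc.transformed(R, t)
        back, fit = sp.align_mhc_floor(moved, toy_pmhc)
        assert fit.fit_rmsd < 1e-8
        pep_a = back.chain("peptide").residues
        pep_b = toy_pmhc.chain("peptide").residues
        assert sp.backbone_rmsd(pep_a, pep_b) < 1e-6

    def test_floor_config_override_changes_fitted_atom_count(self, toy_pmhc):
        import copy

        small_cfg = sio.RegionConfig(groove_floor=tuple(range(1, 30)))
        small = copy.deepcopy(toy_pmhc)
        small.chains = [sio.assign_regions(c, small_cfg) if c.role == "mhc_heavy" else c
                        for c in small.chains]
        _, fit_default = sp.align_mhc_floor(toy_pmhc, toy_pmhc)
        _, fit_small = sp.align_mhc_floor(small, small)
        assert fit_small.n_atoms < fit_default.n_atoms

    def test_too_few_shared_framework_residues_raise(self, toy_tcr):
        import copy

        stripped = copy.deepcopy(toy_tcr)
        for chain in stripped.chains:
            keep = set(chain.regions["FR"][:1])
            chain.residues = [r for r in chain.residues
                              if r.key in keep or r.key not in set(chain.regions["FR"])]
            chain.regions["FR"] = [k for k in chain.regions["FR"] if k in keep]
        with pytest.raises(sp.AlignmentError):
            sp.align_tcr_framework(stripped, toy_tcr)
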