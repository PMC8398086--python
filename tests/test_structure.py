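"""PDB I/O, superposition RMSD, dihedrals and hydrogen-bond geometry."""

import numpy as np
import pytest

import specbind as sb
from specbind.structure import (
    Atom,
    StructureError,
    Structure,
    backbone_rmsd,
    dihedral,
    UndefinedDihedralError,
)
from specbind.synthetic import euler_rotation


class TestPDBIO:
    def test_single_model_round_trip(self, tmp_path, helix20):
        p = tmp_path / "h.pdb"
        sb.write_pdb(helix20, p)
        back = sb.read_pdb(p)
        assert isinstance(back, Structure)
        assert len(back) == len(helix20)
        # PDB stores 3 decimals
        assert np.abs(back.coords - helix20.coords).max() < 5e-4 + 1e-12

    def test_multi_model_round_trip(self, tmp_path, helix20):
        frames = tuple(
            sb.apply_rigid_motion(helix20, rotation=(10.0 * i, 0, 0)) for i in range(3)
        )
        traj = sb.Trajectory(frames, (0.0, 20.0, 40.0))
        p = tmp_path / "t.pdb"
        sb.write_pdb(traj, p)
        back = sb.read_pdb(p)
        assert isinstance(back, sb.Trajectory)
        assert len(back) == 3

    def test_malformed_atom_record_raises(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  N   ALA A   1    garbage coords here\nEND\n")
        with pytest.raises(StructureError):
            sb.read_pdb(p)


def _toy(coords, name="X"):
    return Structure(
        tuple(
            Atom("CA", "C", "GLY", i + 1, "A", np.asarray(c, float))
            for i, c in enumerate(coords)
        )
    )


def _grid_rmsd_oracle(P, Q, step0=20.0, rounds=6):
    """Brute-force oracle: minimize coordinate RMSD over an Euler-angle grid
    refined around the best cell (no closed-form algebra shared with the
    Kabsch implementation)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def scan(alphas, betas, gammas, best):
        for a in alphas:
            for b in betas:
                for g in gammas:
                    R = euler_rotation(a, b, g)
                    r = np.sqrt(((Pc @ R.T - Qc) ** 2).sum() / len(P))
                    if r < best[0]:
                        best = (r, (a, b, g))
        return best

    # full rotation space first, then local refinement around the best cell
    full = np.arange(-180.0, 180.0, step0)
    half = np.arange(-90.0, 91.0, step0)
    best = scan(full, half, full, (np.inf, (0.0, 0.0, 0.0)))
    step = step0
    for _ in range(rounds):
        step /= 4.0
        a0, b0, g0 = best[1]
        local = np.arange(-4, 5) * step
        best = scan(local + a0, local + b0, local + g0, best)
    return best[0]


class TestBackboneRMSD:
    def test_identical_is_zero(self, helix20):
        assert backbone_rmsd(helix20, helix20) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, helix20):
        moved = sb.apply_rigid_motion(helix20, rotation=(33.0, -21.0, 75.0), translation=(5, 5, 5))
        assert backbone_rmsd(helix20, moved) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_arguments(self, helix20):
        jig = sb.apply_rigid_motion(helix20, rotation=(5, 5, 5), jitter_sd=0.3, seed=3)
        assert backbone_rmsd(helix20, jig) == pytest.approx(backbone_rmsd(jig, helix20), rel=1e-9)

    def test_agrees_with_rotation_grid_oracle(self):
        rng = np.random.default_rng(11)
        P = rng.normal(size=(4, 3)) * 2.0
        Q = rng.normal(size=(4, 3)) * 2.0
        ours = backbone_rmsd(_toy(Q), _toy(P))
        oracle = _grid_rmsd_oracle(P, Q)
        assert ours == pytest.approx(oracle, abs=1e-3)
        assert ours <= oracle + 1e-9  # closed form is the true minimum

    def test_agrees_with_reference_superposition(self, helix20):
        # independent cross-check against biotite's superimposition
        import biotite.structure as bts

        jig = sb.apply_rigid_motion(helix20, rotation=(40, 10, -30), jitter_sd=0.4, seed=5)
        sel = ("N", "CA", "C")
        P = np.array([a.coord for a in jig.atoms if a.name in sel])
        Q = np.array([a.coord for a in helix20.atoms if a.name in sel])
        fixed = bts.AtomArray(len(Q))
        fixed.coord[:] = Q
        mobile = bts.AtomArray(len(P))
        mobile.coord[:] = P
        fitted, _ = bts.superimpose(fixed, mobile)
        ref = np.sqrt(((fitted.coord - Q) ** 2).sum() / len(Q))
        # reference library stores coordinates in float32
        assert backbone_rmsd(helix20, jig) == pytest.approx(ref, abs=1e-5)

    def test_atom_mismatch_reported(self, helix20):
        trimmed = Structure(helix20.atoms[:-3])
        with pytest.raises(StructureError, match="unmatched"):
            backbone_rmsd(helix20, trimmed)


class TestRMSDSeries:
    def test_rigid_trajectory_is_zero(self, helix20):
        frames = tuple(
            sb.apply_rigid_motion(helix20, rotation=(15.0 * i, 5.0 * i, 0)) for i in range(4)
        )
        series = sb.rmsd_series(sb.Trajectory(frames, (0.0, 20.0, 40.0, 60.0)))
        assert all(r == pytest.approx(0.0, abs=1e-9) for _, r in series)
        assert series[0] == (0.0, pytest.approx(0.0, abs=1e-12))

    def test_single_frame(self, helix20):
        series = sb.rmsd_series(sb.Trajectory((helix20,), (0.0,)))
        assert len(series) == 1
        assert series[0][0] == 0.0 and series[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_jittered_frames_match_monte_carlo_band(self):
        # isotropic jitter sigma on M matched atoms: superposition removes ~6
        # degrees of freedom, so RMSD ~ sigma*sqrt(3) up to O(1/M)
        chain = sb.build_ideal_chain(30, -57.0, -47.0)
        sigma = 0.5
        frames = [chain] + [
            sb.apply_rigid_motion(chain, jitter_sd=sigma, seed=s) for s in range(1, 21)
        ]
        series = sb.rmsd_series(sb.Trajectory(tuple(frames), tuple(map(float, range(21)))))
        mean_rmsd = np.mean([r for _, r in series[1:]])
        expected = sigma * np.sqrt(3.0)
        assert mean_rmsd == pytest.approx(expected, rel=0.10)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        assert dihedral([1, 1, 0], [0, 1, 0], [0, 0, 0], [-1, 0, 0]) == pytest.approx(180.0)

    def test_sign_convention_hand_example(self):
        # p4 rotated +90 deg (clockwise looking down p2->p3) from cis
        ang = dihedral([1, 1, 0], [0, 1, 0], [0, 0, 0], [0, 0.0, -1.0])
        assert ang == pytest.approx(-90.0) or ang == pytest.approx(90.0)
        # must agree with the community convention (checked vs biotite)
        import biotite.structure as bts

        pts = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0], [0, 0, -1.0]])
        arr = bts.AtomArray(4)
        arr.coord[:] = pts
        ref = float(np.degrees(bts.dihedral(arr[0], arr[1], arr[2], arr[3])))
        assert ang == pytest.approx(ref, abs=1e-6)

    def test_collinear_raises(self):
        with pytest.raises(UndefinedDihedralError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_built_chain_omega_recovered(self, helix20):
        from specbind.structure import backbone_dihedrals

        oms = [e["omega"] for e in backbone_dihedrals(helix20) if e["omega"] is not None]
        assert all(abs(abs(o) - 180.0) < 1e-6 for o in oms)


class TestHBonds:
    def test_fixture_detection(self):
        assert len(sb.detect_hbonds(sb.make_hbond_fixture(2.9, 180.0))) == 1
        assert len(sb.detect_hbonds(sb.make_hbond_fixture(5.0, 180.0))) == 0

    def test_rigid_motion_invariance(self):
        fx = sb.make_hbond_fixture(3.0, 160.0)
        moved = sb.apply_rigid_motion(fx, rotation=(45, 30, 60), translation=(10, -4, 2))
        assert len(sb.detect_hbonds(fx)) == len(sb.detect_hbonds(moved)) == 1

    def test_heavy_atom_mode_without_hydrogens(self):
        fx = sb.make_hbond_fixture(2.9, 180.0)
        noh = Structure(tuple(a for a in fx.atoms if a.element != "H"))
        bonds = sb.detect_hbonds(noh)
        assert len(bonds) == 1 and bonds[0].angle_DHA is None

    def test_series_constant_and_alternating(self):
        bonded = sb.make_hbond_fixture(2.9, 180.0)
        unbonded = sb.make_hbond_fixture(5.0, 180.0)
        const = sb.Trajectory((bonded, bonded, bonded), (0.0, 1.0, 2.0))
        assert [c for _, c in sb.hbond_series(const)] == [1, 1, 1]
        alt = sb.Trajectory((bonded, unbonded, bonded, unbonded), (0.0, 1.0, 2.0, 3.0))
        assert [c for _, c in sb.hbond_series(alt)] == [1, 0, 1, 0]

    def test_chain_selection(self):
        fx = sb.make_hbond_fixture(2.9, 180.0)
        # donor and acceptor share chain A: a cross-chain A/B restriction drops it
        traj = sb.Trajectory((fx,), (0.0,))
        assert sb.hbond_series(traj, donor_chains=["A"], acceptor_chains=["B"]) == [(0.0, 0)]
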