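"""Rotational and membrane observables against independent oracles."""

import numpy as np
import pytest

from rotorprobe import simulate as sim
from rotorprobe.trajectory import (
    AutocorrelationResult,
    NonDecayingACFError,
    VectorTrajectory,
    com_rdf,
    density_profile,
    deuterium_order_param,
    dihedral_angle,
    membrane_geometry,
    p2_acf,
    plane_normal,
    relaxation_time,
    rotational_relaxation,
)


class TestDihedralAngle:
    def test_planar_cis_is_zero(self):
        assert dihedral_angle([1, 0, 0], [0, 0, 0], [0, 1, 0],
                              [1, 1, 0]) == pytest.approx(0.0, abs=1e-10)

    def test_planar_trans_is_180(self):
        assert dihedral_angle([1, 0, 0], [0, 0, 0], [0, 1, 0],
                              [-1, 1, 0]) == pytest.approx(180.0)

    def test_collinear_raises(self):
        with pytest.raises(ValueError, match="collinear"):
            dihedral_angle([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_matches_mdanalysis_on_random_quadruples(self):
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(7)
        for _ in range(50):
            pts = rng.normal(size=(4, 3))
            ref = np.degrees(calc_dihedrals(*(p[None] for p in pts)))[0]
            # the reference implementation works in single precision
            assert dihedral_angle(*pts) == pytest.approx(ref, abs=1e-4)

    def test_gauche_plus_sign_convention(self):
        # rotate the trans fourth point by -120 deg about the central bond:
        # MDAnalysis is the independent referee for the sign
        from MDAnalysis.lib.distances import calc_dihedrals

        pts = np.array([[1, 0, 0], [0, 0, 0], [0, 1, 0],
                        [0.5, 1.0, np.sqrt(3) / 2]])
        ref = np.degrees(calc_dihedrals(*(p[None] for p in pts)))[0]
        got = dihedral_angle(*pts)
        assert got == pytest.approx(ref, abs=1e-4)
        assert abs(abs(got) - 60.0) < 1e-6


class TestPlaneNormal:
    def test_xy_plane(self):
        n = plane_normal([0, 0, 0], [1, 0, 0], [1, 1, 0])
        assert np.allclose(n, [0, 0, 1])

    def test_unit_norm_and_antisymmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 3))
            n = plane_normal(a, b, c)
            assert np.linalg.norm(n) == pytest.approx(1.0)
            assert np.allclose(plane_normal(c, b, a), -n)

    def test_collinear_raises(self):
        with pytest.raises(ValueError, match="collinear"):
            plane_normal([0, 0, 0], [1, 1, 1], [2, 2, 2])


def _brute_force_p2(vectors, n_lags):
    """Double-loop oracle for C_p(t), averaged over origins and trajectories."""
    out = np.zeros(n_lags)
    for lag in range(n_lags):
        vals = []
        for traj in vectors:
            for s in range(traj.shape[0] - lag):
                x = traj[s] @ traj[s + lag]
                vals.append(0.5 * (3.0 * x * x - 1.0))
        out[lag] = np.mean(vals)
    return out / out[0]


class TestP2Acf:
    def test_constant_vector_gives_one(self):
        v = np.tile([0.0, 0.0, 1.0], (50, 1))
        acf = p2_acf(VectorTrajectory(v, dt=1.0))
        assert np.allclose(acf.values, 1.0)
        assert acf.lags[0] == 0.0

    def test_iid_random_vectors_decorrelate(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(20, 500, 3))
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        acf = p2_acf(VectorTrajectory(v, dt=1.0), max_lag=10.0)
        # <P2> over the sphere is zero; allow 3 / sqrt(n_origins)
        bound = 3.0 / np.sqrt(acf.n_origins[1:])
        assert np.all(np.abs(acf.values[1:]) < bound)

    def test_matches_brute_force_oracle(self):
        traj = sim.gen_rotational_diffusion(0.01, 1.0, 199, n_traj=3, seed=9)
        acf = p2_acf(traj, max_lag=60.0)
        oracle = _brute_force_p2(traj.vectors, 61)
        assert np.allclose(acf.values, oracle, atol=1e-12)

    def test_diffusion_matches_exponential_law(self):
        # ensemble C_p at 5 lags within 3 standard errors (over independent
        # trajectories) of exp(-6 D t)
        D = 0.002
        traj = sim.gen_rotational_diffusion(D, 1.0, 4000, n_traj=60, seed=2)
        per_traj = np.stack([
            p2_acf(VectorTrajectory(traj.vectors[i], traj.dt),
                   max_lag=200.0).values
            for i in range(traj.n_traj)])
        mean = per_traj.mean(axis=0)
        se = per_traj.std(axis=0, ddof=1) / np.sqrt(traj.n_traj)
        for i in (20, 50, 100, 150, 200):
            expect = np.exp(-6.0 * D * i * traj.dt)
            assert abs(mean[i] - expect) < 3.0 * se[i]

    def test_too_few_frames_raises(self):
        with pytest.raises(ValueError, match="two frames"):
            p2_acf(VectorTrajectory(np.array([[0.0, 0.0, 1.0]]), dt=1.0))


class TestRelaxationTime:
    def test_exact_exponential_both_methods(self):
        lags = np.arange(0.0, 400.0, 1.0)
        acf = AutocorrelationResult(lags, np.exp(-lags / 50.0),
                                    np.full(lags.size, 1000))
        for method in ("exp_fit", "integral"):
            summ = relaxation_time(acf, method=method)
            assert summ.tau == pytest.approx(50.0, rel=1e-3)

    def test_rotational_diffusion_recovers_tau(self):
        traj = sim.gen_rotational_diffusion(1.0 / (6.0 * 50.0), 0.5, 8000,
                                            n_traj=60, seed=3)
        summ = rotational_relaxation(traj, max_lag=300.0)
        assert summ.tau == pytest.approx(50.0, rel=0.10)
        assert summ.uncertainty > 0.0 and summ.n_blocks == 5

    def test_tau_scales_inversely_with_diffusion(self):
        taus = []
        for i, D in enumerate([1.0 / 300.0, 1.0 / 1200.0]):
            traj = sim.gen_rotational_diffusion(D, 0.25, 6000, n_traj=50,
                                                seed=20 + i)
            taus.append(rotational_relaxation(traj, max_lag=250.0).tau)
        assert taus[0] / taus[1] == pytest.approx(0.25, rel=0.15)

    def test_exp_fit_and_integral_agree_on_monoexponential(self):
        traj = sim.gen_rotational_diffusion(1.0 / 240.0, 0.5, 6000,
                                            n_traj=40, seed=4)
        t1 = rotational_relaxation(traj, method="exp_fit", max_lag=250.0).tau
        t2 = rotational_relaxation(traj, method="integral", max_lag=250.0).tau
        assert t1 == pytest.approx(t2, rel=0.15)

    def test_non_decaying_acf_flagged(self):
        lags = np.arange(0.0, 10.0)
        acf = AutocorrelationResult(lags, np.full(10, 0.9), np.full(10, 10))
        with pytest.raises(NonDecayingACFError):
            relaxation_time(acf)

    def test_mobility_ordering_is_preserved(self):
        # three environments with decreasing mobility => strictly
        # increasing relaxation times (the solvent / bilayer ordering)
        taus = []
        for i, D in enumerate([1.0 / 60.0, 1.0 / 300.0, 1.0 / 900.0]):
            traj = sim.gen_rotational_diffusion(D, 0.5, 6000, n_traj=40,
                                                seed=30 + i)
            taus.append(rotational_relaxation(traj, max_lag=700.0).tau)
        assert taus[0] < taus[1] < taus[2]


class TestOrderParameters:
    def test_all_parallel_is_one(self):
        frames = sim.gen_membrane_snapshot(32, 0.0, 3.8, 4.0, seed=1,
                                           ch_perp=False)
        prof = deuterium_order_param(frames)
        assert np.allclose(prof.s_cd, 1.0, atol=1e-12)

    def test_all_perpendicular_is_minus_half(self, membrane_frames):
        prof = deuterium_order_param(membrane_frames)
        assert np.allclose(prof.s_cd, -0.5, atol=1e-9)

    def test_isotropic_orientations_average_to_zero(self):
        # hand-built frame: C-H bond directions drawn uniformly on the
        # sphere, for which the spherical average of P2 is exactly zero
        import pandas as pd

        from rotorprobe.trajectory import LipidFrame

        rng = np.random.default_rng(8)
        n = 4000
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
        pos, rows = [], []
        for leaflet, z in (("upper", 4.0), ("lower", 1.0)):
            pos.append([2.0, 2.0, z])
            rows.append({"role": "phosphate", "lipid_id": 0,
                         "leaflet": leaflet, "chain": "", "carbon_index": -1,
                         "parent": -1, "mass": 94.97})
        for i in range(n):
            c = np.array([2.0, 2.0, 2.5])
            ci = len(pos)
            pos.append(c)
            rows.append({"role": "chain-carbon", "lipid_id": 0,
                         "leaflet": "upper", "chain": "sn1",
                         "carbon_index": i, "parent": -1, "mass": 12.011})
            pos.append(c + 0.109 * dirs[i])
            rows.append({"role": "chain-hydrogen", "lipid_id": 0,
                         "leaflet": "upper", "chain": "sn1",
                         "carbon_index": i, "parent": ci, "mass": 1.008})
        frame = LipidFrame(positions=np.array(pos),
                           atoms=pd.DataFrame(rows),
                           box=np.array([5.0, 5.0, 5.0]))
        prof = deuterium_order_param(frame)
        assert abs(prof.s_cd.mean()) < 3.0 / np.sqrt(n)

    def test_tilt_spread_recovery_against_monte_carlo_oracle(self):
        # construction: S_CD = -1/2 <P2(cos beta)> for chains tilted by
        # beta ~ N(0, sd) with perpendicular C-H bonds; the oracle is a
        # direct Monte-Carlo average over the same tilt law
        sd = 20.0
        frames = sim.gen_membrane_snapshot(100, sd, 3.8, 8.0, seed=13,
                                           n_frames=5)
        prof = deuterium_order_param(frames)
        beta = np.random.default_rng(99).normal(0.0, np.deg2rad(sd), 200_000)
        oracle = -0.5 * np.mean(0.5 * (3.0 * np.cos(beta) ** 2 - 1.0))
        got = np.average(prof.s_cd, weights=prof.n)
        assert got == pytest.approx(oracle, abs=0.02)

    def test_bounds_respected(self):
        frames = sim.gen_membrane_snapshot(32, 25.0, 3.8, 4.0, seed=9)
        prof = deuterium_order_param(frames)
        assert np.all(prof.s_cd >= -0.5 - 1e-12)
        assert np.all(prof.s_cd <= 1.0 + 1e-12)

    def test_probe_proximity_selection(self):
        frames = sim.gen_membrane_snapshot(32, 0.0, 3.8, 4.0, seed=10,
                                           include_probe=True)
        near = deuterium_order_param(frames, probe_cutoff_nm=1.5)
        full = deuterium_order_param(frames)
        assert near.n.sum() < full.n.sum()
        assert np.allclose(near.s_cd, -0.5, atol=1e-9)


class TestRdf:
    def test_uniform_points_give_unit_g(self):
        rng = np.random.default_rng(12)
        box = np.array([10.0, 10.0, 10.0])
        pts = rng.uniform(0, 10, size=(10_000, 3))
        g = com_rdf(pts, pts, box, bins=40)
        mid = (g.r > 1.0) & (g.r < 4.0)
        assert np.allclose(g.g[mid], 1.0, atol=0.05)

    def test_matches_mdanalysis_interrdf(self):
        import MDAnalysis as mda
        from MDAnalysis.analysis.rdf import InterRDF

        rng = np.random.default_rng(3)
        box = np.array([6.0, 6.0, 6.0])
        a = rng.uniform(0, 6, size=(300, 3))
        b = rng.uniform(0, 6, size=(400, 3))
        ours = com_rdf(a, b, box, bins=30, r_max=2.9)

        u = mda.Universe.empty(700, trajectory=True)
        u.atoms.positions = np.vstack([a, b]) * 10.0  # nm -> A
        u.dimensions = [60.0, 60.0, 60.0, 90.0, 90.0, 90.0]
        rdf = InterRDF(u.atoms[:300], u.atoms[300:], nbins=30,
                       range=(0.0, 29.0))
        rdf.run()
        assert np.allclose(ours.g, rdf.results.rdf, atol=1e-6)

    def test_excluded_zone_is_zero(self):
        # two widely separated clusters: no pairs below their gap
        a = np.full((50, 3), 1.0) + np.random.default_rng(0).normal(
            0, 0.01, (50, 3))
        b = np.full((50, 3), 4.0) + np.random.default_rng(1).normal(
            0, 0.01, (50, 3))
        g = com_rdf(a, b, np.array([10.0, 10.0, 10.0]), bins=20, r_max=4.0)
        assert np.all(g.g[g.r < 3.0] == 0.0)

    def test_intensive_under_density_matched_doubling(self):
        rng = np.random.default_rng(5)
        box1 = np.array([8.0, 8.0, 8.0])
        pts1 = rng.uniform(0, 8, size=(2000, 3))
        g1 = com_rdf(pts1, pts1, box1, bins=20, r_max=3.9)
        box2 = np.array([8.0, 8.0, 16.0])
        pts2 = rng.uniform(0, 1, size=(4000, 3)) * box2
        g2 = com_rdf(pts2, pts2, box2, bins=20, r_max=3.9)
        assert np.allclose(g1.g, g2.g, atol=0.1)


class TestDensityAndGeometry:
    def test_mass_conservation(self, membrane_frames):
        fr = membrane_frames[0]
        prof = density_profile(fr, bins=40)
        slab = fr.box[2] / 40 * fr.box[0] * fr.box[1]
        assert prof.density.sum() * slab == pytest.approx(
            fr.atoms.mass.sum(), rel=1e-9)

    def test_phosphate_profile_is_bimodal(self, membrane_frames):
        prof = density_profile(membrane_frames, roles=["phosphate"], bins=40)
        d = prof.density.to_numpy()
        interior = d[1:-1]
        peaks = np.nonzero((interior >= np.roll(d, 1)[1:-1])
                           & (interior >= np.roll(d, -1)[1:-1])
                           & (interior > 0))[0]
        assert peaks.size == 2

    def test_uniform_fixture_gives_flat_profile(self):
        rng = np.random.default_rng(4)
        import pandas as pd

        from rotorprobe.trajectory import LipidFrame

        n = 20_000
        frame = LipidFrame(
            positions=rng.uniform(0, 5, size=(n, 3)),
            atoms=pd.DataFrame({"role": ["probe"] * n, "lipid_id": -1,
                                "leaflet": "", "chain": "",
                                "carbon_index": -1, "parent": -1,
                                "mass": 1.0}),
            box=np.array([5.0, 5.0, 5.0]))
        prof = density_profile(frame, bins=20)
        expect = n / 125.0
        sigma = np.sqrt(n / 20) / (125.0 / 20)
        assert np.all(np.abs(prof.density - expect) < 3.0 * sigma)

    def test_area_per_lipid_exact(self):
        frames = sim.gen_membrane_snapshot(200, 0.0, 3.8, 8.0, seed=2)
        geo = membrane_geometry(frames)
        assert geo.area_per_lipid_A2 == pytest.approx(6400.0 / 100.0)

    def test_thickness_recovered_within_bin(self, membrane_frames):
        geo = membrane_geometry(membrane_frames)
        assert abs(geo.thickness_A - 38.0) <= 0.5  # bin width in A

    def test_sterols_do_not_change_area_per_lipid(self):
        plain = sim.gen_membrane_snapshot(72, 0.0, 3.8, 6.0, seed=6)
        sterol = sim.gen_membrane_snapshot(72, 0.0, 3.8, 6.0, seed=6,
                                           n_sterols=20)
        assert membrane_geometry(plain).area_per_lipid_A2 == \
            membrane_geometry(sterol).area_per_lipid_A2

    def test_box_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            sim.gen_membrane_snapshot(400, 0.0, 3.8, 4.0, seed=0)
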