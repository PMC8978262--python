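"""Fluence estimation, DVH curves, threshold dosimetry and probes."""

import math

import numpy as np
import pytest

import tetradose as td
from tetradose.dosimetry import (
    FluenceField,
    ThresholdSet,
    analytic_point_fluence,
    boundary_exitance,
    compute_dvh,
    coverage,
    fluence_from_score,
    interface_faces,
    line_probe,
    necrosis_mask,
    surface_fluence,
)
from tetradose.engine import RawScore, SimConfig, run_mc


def _fake_score(mesh, absorbed=None, tracklen=None):
    nt = mesh.n_tets
    return RawScore(
        absorbed=absorbed if absorbed is not None else np.zeros(nt),
        exited=np.zeros(mesh.n_boundary_faces),
        tracklen=tracklen if tracklen is not None else np.zeros(nt),
        ledger={},
    )


class TestFluenceFromScore:
    def test_absorption_unit_arithmetic(self):
        # one 1 cm^3 tet, mu_a = 1 cm^-1, 20% absorbed, 100 mW source
        verts = 10.0 * np.array(
            [[0, 0, 0], [1.817, 0, 0], [0, 1.817, 0], [0, 0, 1.817]]
        )
        mesh = td.build_tetra_mesh(verts, np.array([[0, 1, 2, 3]]), np.array([0]))
        assert mesh.volume[0] == pytest.approx(1000.0, rel=1e-3)
        mesh.volume[0] = 1000.0  # pin the volume for exact arithmetic
        mats = {0: td.Material(0, "t", 0.1, 0.0, 0.0, 1.0)}
        sc = _fake_score(mesh, absorbed=np.array([0.2]))
        fld = fluence_from_score(sc, mesh, mats, 100.0, estimator="absorption")
        assert fld.phi[0] == pytest.approx(20.0, rel=1e-12)  # mW/cm^2

    def test_zero_score_zero_field(self, small_box_mesh, soft_tissue):
        sc = _fake_score(small_box_mesh)
        for est in ("absorption", "track_length"):
            fld = fluence_from_score(sc, small_box_mesh, soft_tissue, 50.0, est)
            assert not fld.phi.any()

    def test_mu_a_zero_flagged_undefined(self, small_box_mesh, clear_material):
        sc = _fake_score(small_box_mesh)
        with pytest.warns(UserWarning, match="undefined"):
            fld = fluence_from_score(sc, small_box_mesh, clear_material, 1.0,
                                     estimator="absorption")
        assert fld.undefined.all()

    def test_estimators_agree_on_absorbing_phantom(self, small_box_mesh, soft_tissue):
        src = [td.PointSource(position=(10, 10, 10), power=1.0)]
        sc = run_mc(small_box_mesh, soft_tissue, src,
                    SimConfig(n_packets=100_000, seed=21))
        fa = fluence_from_score(sc, small_box_mesh, soft_tissue, 1.0, "absorption")
        ft = fluence_from_score(sc, small_box_mesh, soft_tissue, 1.0, "track_length")
        w = small_box_mesh.volume
        ma = (fa.phi * w).sum() / w.sum()
        mt = (ft.phi * w).sum() / w.sum()
        assert ma == pytest.approx(mt, rel=0.03)

    def test_field_ledger_consistency(self, small_box_mesh, soft_tissue):
        """Volume-integrated Phi mu_a equals the absorbed power."""
        src = [td.PointSource(position=(10, 10, 10), power=1.0)]
        sc = run_mc(small_box_mesh, soft_tissue, src,
                    SimConfig(n_packets=20_000, seed=22))
        P = 37.0
        fld = fluence_from_score(sc, small_box_mesh, soft_tissue, P, "absorption")
        mu_a = soft_tissue[0].mu_a
        # phi [mW/cm^2] * mu_a [mm^-1] * V [mm^3] / 100 -> mW
        absorbed_power = (fld.phi * mu_a * small_box_mesh.volume).sum() / 100.0
        expected = P * sc.ledger["absorbed_total"] / sc.ledger["emitted"]
        assert absorbed_power == pytest.approx(expected, rel=1e-6)


class TestDVH:
    def _uniform_mesh(self):
        return td.generate_phantom(
            td.PhantomSpec(kind="box", extents=(10, 10, 10), cells=(3, 3, 3))
        )

    def test_uniform_field_steps_at_threshold(self):
        mesh = self._uniform_mesh()
        fld = FluenceField(phi=np.full(mesh.n_tets, 5.0), estimator="track_length",
                           total_power=1.0)
        dvh = compute_dvh(fld, ThresholdSet({0: 5.0}), mesh, bins=200)
        x, y = dvh[0]
        assert y[x <= 100.0] == pytest.approx(100.0)
        assert x.max() == pytest.approx(100.0)

    def test_two_element_halfway(self):
        # second apex mirrors the origin across the shared face plane
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
             [2.0 / 3.0, 2.0 / 3.0, 2.0 / 3.0]],
            dtype=float,
        )
        tets = np.array([[0, 1, 2, 3], [4, 1, 2, 3]])
        mesh = td.build_tetra_mesh(verts, tets, np.array([0, 0]))
        assert mesh.volume[0] == pytest.approx(mesh.volume[1])
        fld = FluenceField(phi=np.array([0.5, 2.0]), estimator="track_length",
                           total_power=1.0)
        dvh = compute_dvh(fld, ThresholdSet({0: 1.0}), mesh, bins=500)
        x, y = dvh[0]
        k = np.searchsorted(x, 100.0)
        assert y[k] == pytest.approx(50.0)

    def test_matches_exhaustive_counting_oracle(self):
        mesh = td.generate_phantom(
            td.PhantomSpec(kind="box", extents=(10, 10, 10), cells=(3, 3, 2))
        )
        rng = np.random.default_rng(33)
        phi = rng.uniform(0, 10, size=mesh.n_tets)
        T = 4.0
        fld = FluenceField(phi=phi, estimator="track_length", total_power=1.0)
        dvh = compute_dvh(fld, ThresholdSet({0: T}), mesh, bins=97)
        x, y = dvh[0]
        vol = mesh.volume
        for xi, yi in zip(x, y):
            expected = 100.0 * vol[(phi / T * 100.0) >= xi].sum() / vol.sum()
            assert yi == pytest.approx(expected, abs=1e-9)

    def test_monotone_and_starts_at_100(self):
        mesh = self._uniform_mesh()
        rng = np.random.default_rng(34)
        for _ in range(5):
            fld = FluenceField(phi=rng.exponential(1.0, mesh.n_tets),
                               estimator="track_length", total_power=1.0)
            x, y = compute_dvh(fld, ThresholdSet({0: 1.0}), mesh, bins=100)[0]
            assert y[0] == pytest.approx(100.0)
            assert (np.diff(y) <= 1e-12).all()

    def test_missing_threshold_rejected(self):
        mesh = self._uniform_mesh()
        fld = FluenceField(phi=np.ones(mesh.n_tets), estimator="track_length",
                           total_power=1.0)
        with pytest.raises(ValueError, match="threshold"):
            compute_dvh(fld, ThresholdSet({5: 1.0}), mesh, regions=[0])


class TestCoverageAndNecrosis:
    def _mesh(self):
        return td.generate_phantom(
            td.PhantomSpec(kind="box", extents=(10, 10, 10), cells=(3, 3, 3))
        )

    def test_all_above(self):
        mesh = self._mesh()
        fld = FluenceField(phi=np.full(mesh.n_tets, 2.0), estimator="track_length",
                           total_power=1.0)
        assert coverage(fld, ThresholdSet({0: 1.0}), mesh, 0) == 1.0

    def test_bruteforce_random(self):
        mesh = self._mesh()
        rng = np.random.default_rng(35)
        phi = rng.uniform(0, 2, size=mesh.n_tets)
        thr = ThresholdSet({0: 1.0})
        fld = FluenceField(phi=phi, estimator="track_length", total_power=1.0)
        expected = mesh.volume[phi >= 1.0].sum() / mesh.volume.sum()
        assert coverage(fld, thr, mesh, 0) == pytest.approx(expected, rel=1e-12)
        mask, vols = necrosis_mask(fld, thr, mesh)
        assert np.array_equal(mask, phi >= 1.0)
        assert vols[0] == pytest.approx(mesh.volume[phi >= 1.0].sum())

    def test_coverage_matches_dvh_at_threshold(self):
        mesh = self._mesh()
        rng = np.random.default_rng(36)
        phi = rng.uniform(0, 3, size=mesh.n_tets)
        thr = ThresholdSet({0: 1.0})
        fld = FluenceField(phi=phi, estimator="track_length", total_power=1.0)
        bins = 1000
        x, y = compute_dvh(fld, thr, mesh, bins=bins)[0]
        cov = coverage(fld, thr, mesh, 0)
        y_at_100 = np.interp(100.0, x, y) / 100.0
        bin_width_vol = 1.0 / bins * 100  # generous one-bin slack
        assert abs(cov - y_at_100) <= bin_width_vol

    def test_empty_region_rejected(self):
        mesh = self._mesh()
        fld = FluenceField(phi=np.ones(mesh.n_tets), estimator="track_length",
                           total_power=1.0)
        with pytest.raises(ValueError, match="no tets"):
            coverage(fld, ThresholdSet({3: 1.0}), mesh, 3)


class TestAnalyticPointFluence:
    def test_reference_value(self):
        # mu_a = 0.01, mu_s' = 1 mm^-1, P = 1 mW, r = 10 mm
        val = analytic_point_fluence(10.0, 1.0, 0.01, 1.0)
        assert val / 100.0 == pytest.approx(4.23e-3, rel=5e-3)  # mm^-2

    def test_ratio_identity(self):
        mu_a, msp = 0.02, 1.5
        m = td.Material.from_reduced(0, "t", mu_a, msp, 0.0, 1.0)
        mu_eff = td.derive_optics(m).mu_eff
        r1, r2 = 6.0, 14.0
        ratio = analytic_point_fluence(r1, 1.0, mu_a, msp) / analytic_point_fluence(
            r2, 1.0, mu_a, msp
        )
        assert ratio == pytest.approx((r2 / r1) * math.exp(-mu_eff * (r1 - r2)),
                                      rel=1e-12)

    def test_monotone_decay(self):
        rs = np.arange(1.0, 40.0)
        vals = [analytic_point_fluence(r, 1.0, 0.01, 1.0) for r in rs]
        assert (np.diff(vals) < 0).all()

    def test_singularity_rejected(self):
        with pytest.raises(ValueError):
            analytic_point_fluence(0.0, 1.0, 0.01, 1.0)


class TestLineProbe:
    def test_uniform_field_constant(self, small_box_mesh):
        fld = FluenceField(phi=np.full(small_box_mesh.n_tets, 3.0),
                           estimator="track_length", total_power=1.0)
        d, v = line_probe(fld, small_box_mesh, (2, 10, 10), (18, 10, 10), 20)
        assert np.allclose(v, 3.0)
        assert d[-1] == pytest.approx(16.0)

    def test_matches_locate_lookup(self, small_box_mesh):
        rng = np.random.default_rng(37)
        phi = rng.uniform(0, 1, small_box_mesh.n_tets)
        fld = FluenceField(phi=phi, estimator="track_length", total_power=1.0)
        d, v = line_probe(fld, small_box_mesh, (1, 1, 1), (19, 19, 19), 15)
        t = np.linspace(0, 1, 15)
        pts = np.array([1, 1, 1]) + t[:, None] * np.array([18, 18, 18])
        for p, vi in zip(pts, v):
            assert vi == phi[td.locate_tetra(small_box_mesh, p)]

    def test_outside_points_flagged_nan(self, small_box_mesh):
        fld = FluenceField(phi=np.ones(small_box_mesh.n_tets),
                           estimator="track_length", total_power=1.0)
        _, v = line_probe(fld, small_box_mesh, (10, 10, 10), (10, 10, 40), 10)
        assert np.isnan(v[-1])
        assert v[0] == 1.0

    def test_single_sample_at_centroid(self, small_box_mesh):
        phi = np.arange(small_box_mesh.n_tets, dtype=float)
        fld = FluenceField(phi=phi, estimator="track_length", total_power=1.0)
        c = small_box_mesh.centroids[5]
        _, v = line_probe(fld, small_box_mesh, c, c, 1)
        assert v[0] == 5.0


def test_interface_and_surface_fluence():
    mesh = td.generate_phantom(
        td.PhantomSpec(kind="sphere_in_box", extents=(20, 20, 20), cells=(6, 6, 6),
                       sphere_radius=5.0)
    )
    faces = interface_faces(mesh, 1, 0)
    assert len(faces) > 0
    assert (mesh.region[faces[:, 0]] == 1).all()
    nbs = mesh.adjacency[faces[:, 0], faces[:, 1]]
    assert (mesh.region[nbs] == 0).all()
    phi = np.where(mesh.region == 1, 4.0, 2.0)
    fld = FluenceField(phi=phi, estimator="track_length", total_power=1.0)
    sv = surface_fluence(fld, mesh, faces)
    assert np.allclose(sv, 3.0)


def test_boundary_exitance_units(small_box_mesh, clear_material):
    src = [td.PointSource(position=(10, 10, 10), power=2.0)]
    sc = run_mc(small_box_mesh, clear_material, src, SimConfig(n_packets=5000, seed=4))
    ex = boundary_exitance(sc, small_box_mesh, 2.0)
    # all emitted power leaves: sum over faces of exitance*area/100 = power
    total = (ex * small_box_mesh.boundary_area).sum() / 100.0
    assert total == pytest.approx(2.0, rel=1e-12)
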