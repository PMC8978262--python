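"""Power-allocation LP, surface-limit scaling, annealing, plan evaluation."""

import numpy as np
import pytest

import tetradose as td
from tetradose.dosimetry import ThresholdSet
from tetradose.planning import (
    AnnealSchedule,
    DoseMatrix,
    InfeasiblePlanError,
    Plan,
    PlanConfig,
    anneal_placement,
    build_dose_matrix,
    enforce_surface_limit,
    evaluate_plan,
    optimize_powers,
    sub_seed,
)


def _toy_dm(phi, region, volumes=None):
    phi = np.asarray(phi, dtype=float)
    region = np.asarray(region, dtype=np.int32)
    volumes = np.ones(len(region)) if volumes is None else np.asarray(volumes, float)
    from tetradose.sources import PointSource

    srcs = [PointSource(position=(0, 0, 0), power=1.0) for _ in range(phi.shape[1])]
    return DoseMatrix(phi=phi, sources=srcs, volumes=volumes, region=region,
                      seeds=[0] * phi.shape[1], packets=0)


class TestOptimizePowersLP:
    def test_single_source_analytic(self):
        # one tumour element, phi = 0.25, T = 1 -> minimal passing power is 4
        dm = _toy_dm([[0.25]], [1])
        plan = optimize_powers(dm, ThresholdSet({1: 1.0}),
                               PlanConfig(coverage_target=1.0, oar_regions=()))
        assert plan.powers[0] == pytest.approx(4.0, rel=1e-9)
        assert plan.coverage == 1.0

    def test_mirror_symmetric_equal_powers(self):
        dm = _toy_dm([[0.3, 0.1], [0.1, 0.3]], [1, 1])
        plan = optimize_powers(dm, ThresholdSet({1: 1.0}),
                               PlanConfig(coverage_target=1.0, oar_regions=()))
        assert plan.powers[0] == pytest.approx(plan.powers[1], rel=1e-6)

    def test_lp_matches_grid_search_oracle(self):
        rng = np.random.default_rng(50)
        for trial in range(3):
            n_el, n_src = 20, 3
            region = np.array([1] * 8 + [2] * 12, dtype=np.int32)
            phi = rng.uniform(0.05, 1.0, size=(n_el, n_src))
            vols = rng.uniform(0.5, 2.0, size=n_el)
            dm = _toy_dm(phi, region, vols)
            thr = ThresholdSet({1: 1.0, 2: 1.0})
            w_t = 4.0
            cfg = PlanConfig(coverage_target=1e-9, tumor_weight=w_t,
                             oar_regions=(2,), max_escalations=0)
            plan = optimize_powers(dm, thr, cfg)

            def objective(p):
                dose = phi @ p
                over = np.maximum(dose[region == 2] - 1.0, 0.0)
                under = np.maximum(1.0 - dose[region == 1], 0.0)
                return (vols[region == 2] * over).sum() + w_t * (
                    vols[region == 1] * under
                ).sum()

            from test_acceptance import _refining_grid_search

            best = _refining_grid_search(objective, lo=0.0, hi=6.0)
            assert plan.objective <= best + 1e-9
            assert plan.objective == pytest.approx(best, rel=0.01)

    def test_weight_escalation_reaches_coverage(self):
        # OAR pressure keeps doses low at w_t = 1; escalation must fix it
        rng = np.random.default_rng(51)
        phi = np.vstack([rng.uniform(0.2, 0.4, size=(10, 2)),
                         rng.uniform(0.3, 0.6, size=(10, 2))])
        region = np.array([1] * 10 + [2] * 10, dtype=np.int32)
        dm = _toy_dm(phi, region)
        thr = ThresholdSet({1: 1.0, 2: 0.1})
        cfg = PlanConfig(coverage_target=0.98, oar_regions=(2,),
                         oar_weights={2: 50.0})
        plan = optimize_powers(dm, thr, cfg)
        assert plan.coverage >= 0.98
        assert plan.tumor_weight_final > 1.0

    def test_unreachable_target_reports_infeasible(self):
        dm = _toy_dm([[0.5], [0.0]], [1, 1])  # second element gets no dose
        with pytest.raises(InfeasiblePlanError, match="unreachable"):
            optimize_powers(dm, ThresholdSet({1: 1.0}),
                            PlanConfig(coverage_target=1.0, oar_regions=(),
                                       max_escalations=3))

    def test_empty_tumor_rejected(self):
        dm = _toy_dm([[0.5]], [2])
        with pytest.raises(ValueError, match="empty"):
            optimize_powers(dm, ThresholdSet({1: 1.0, 2: 1.0}),
                            PlanConfig(oar_regions=(2,)))

    def test_oar_weight_monotonicity(self):
        rng = np.random.default_rng(52)
        phi = rng.uniform(0.1, 0.8, size=(16, 2))
        region = np.array([1] * 8 + [2] * 8, dtype=np.int32)
        dm = _toy_dm(phi, region)
        thr = ThresholdSet({1: 1.0, 2: 0.5})
        volumes = []
        for w in (0.1, 1.0, 10.0, 100.0):
            cfg = PlanConfig(coverage_target=0.9, oar_regions=(2,),
                             oar_weights={2: w})
            plan = optimize_powers(dm, thr, cfg)
            volumes.append(sum(plan.oar_overdose.values()))
        assert all(b <= a + 1e-9 for a, b in zip(volumes, volumes[1:]))

    def test_pruning_normalization_scales_thresholds(self):
        dm = _toy_dm([[0.25]], [1])
        cfg = PlanConfig(coverage_target=1.0, oar_regions=(),
                         pruning_normalization=2.0)
        plan = optimize_powers(dm, ThresholdSet({1: 1.0}), cfg)
        assert plan.powers[0] == pytest.approx(8.0, rel=1e-9)


class TestEnforceSurfaceLimit:
    def _plan(self, powers):
        return Plan(powers=np.asarray(powers, float), objective=0.0, coverage=1.0,
                    oar_overdose={})

    def test_scales_down_to_limit(self):
        out = enforce_surface_limit(self._plan([10.0, 20.0]),
                                    np.array([600.0, 100.0]), 300.0)
        assert np.allclose(out.powers, [5.0, 10.0])

    def test_below_limit_unchanged(self):
        plan = self._plan([10.0])
        out = enforce_surface_limit(plan, np.array([100.0]), 300.0)
        assert out is plan

    def test_zero_power_unchanged(self):
        plan = self._plan([0.0])
        out = enforce_surface_limit(plan, np.array([0.0]), 300.0)
        assert np.allclose(out.powers, 0.0)


@pytest.fixture(scope="module")
def mc_plan_setup():
    """Small tumour/OAR phantom with two interstitial sources (module-shared)."""
    mesh = td.generate_tumor_oar_phantom(6.0, 2.0, extents=(30, 30, 30),
                                         cells=(8, 8, 8))
    materials = {
        r: td.Material.from_reduced(r, f"r{r}", 0.02, 2.0, 0.0, 1.0)
        for r in (0, 1, 2)
    }
    sources = [
        td.PointSource(position=(13.0, 15.0, 15.0), power=1.0),
        td.PointSource(position=(17.0, 15.0, 15.0), power=1.0),
    ]
    thresholds = ThresholdSet({1: 20.0, 2: 20.0})
    return mesh, materials, sources, thresholds


class TestDoseMatrixMC:
    def test_column_equals_standalone_run(self, mc_plan_setup):
        mesh, materials, sources, _ = mc_plan_setup
        dm = build_dose_matrix(mesh, materials, sources, packets=3000, seed=60)
        from tetradose.dosimetry import fluence_from_score
        from tetradose.engine import SimConfig, run_mc

        j = 1
        unit = td.PointSource(position=sources[j].position, power=1.0)
        sc = run_mc(mesh, materials, [unit],
                    SimConfig(n_packets=3000, seed=sub_seed(60, j)))
        fld = fluence_from_score(sc, mesh, materials, 1.0, "track_length")
        assert np.array_equal(dm.phi[:, j], fld.phi)

    def test_compose_is_linear(self, mc_plan_setup):
        mesh, materials, sources, _ = mc_plan_setup
        dm = build_dose_matrix(mesh, materials, sources, packets=2000, seed=61)
        p = np.array([2.0, 5.0])
        fld = dm.compose(p)
        assert np.array_equal(fld.phi, dm.phi @ p)
        assert not dm.compose(np.zeros(2)).phi.any()

    def test_optimized_plan_meets_target_on_phantom(self, mc_plan_setup):
        mesh, materials, sources, thresholds = mc_plan_setup
        dm = build_dose_matrix(mesh, materials, sources, packets=20_000, seed=62)
        cfg = PlanConfig(coverage_target=0.98, oar_regions=(2,))
        plan = optimize_powers(dm, thresholds, cfg)
        assert plan.coverage >= 0.98
        assert (plan.powers >= 0).all()

    def test_evaluate_plan_consistent_with_compose(self, mc_plan_setup):
        mesh, materials, sources, thresholds = mc_plan_setup
        dm = build_dose_matrix(mesh, materials, sources, packets=20_000, seed=63)
        cfg = PlanConfig(coverage_target=0.95, oar_regions=(2,))
        plan = optimize_powers(dm, thresholds, cfg)
        report, dvh, fld = evaluate_plan(mesh, materials, plan, thresholds,
                                         packets=40_000, seed=64)
        # fresh simulation agrees with the dose-matrix composition within MC error
        assert report.tumor_coverage == pytest.approx(plan.coverage, abs=0.05)
        assert set(dvh.curves) == {1, 2}

    def test_zero_power_plan_zero_coverage(self, mc_plan_setup):
        mesh, materials, sources, thresholds = mc_plan_setup
        plan = Plan(powers=np.zeros(2), objective=0.0, coverage=0.0,
                    oar_overdose={},
                    sources=[td.PointSource(position=s.position, power=0.0)
                             for s in sources])
        report, _, fld = evaluate_plan(mesh, materials, plan, thresholds,
                                       packets=1000, seed=65)
        assert report.tumor_coverage == 0.0
        assert not fld.phi.any()


class TestAnnealing:
    def test_zero_iterations_returns_initial(self, mc_plan_setup):
        mesh, materials, sources, thresholds = mc_plan_setup
        cfg = PlanConfig(coverage_target=0.9, oar_regions=(2,))
        sched = AnnealSchedule(n_iters=0, t0=1.0, probe_moves=0)
        best, pos = anneal_placement(mesh, materials, sources, thresholds, cfg,
                                     sched, seed=70, packets=2000)
        assert np.allclose(pos[0], sources[0].position)
        assert np.allclose(pos[1], sources[1].position)

    def test_best_never_worse_than_initial(self, mc_plan_setup):
        mesh, materials, sources, thresholds = mc_plan_setup
        cfg = PlanConfig(coverage_target=0.9, oar_regions=(2,))
        sched = AnnealSchedule(n_iters=6, t0=1.0, probe_moves=0, sigma=2.0)
        best, _ = anneal_placement(mesh, materials, sources, thresholds, cfg,
                                   sched, seed=71, packets=2000)
        dm0 = build_dose_matrix(mesh, materials, sources, 2000, sub_seed(71, 1000))
        initial = optimize_powers(dm0, thresholds, cfg)
        assert best.objective <= initial.objective + 1e-9

    def test_recovers_symmetric_optimum(self):
        """Single source in a slab tumour flanked by OAR slabs: the annealer
        moves it toward the midline, where OAR overdose is minimal."""
        mesh = td.generate_phantom(
            td.PhantomSpec(kind="slab_stack", extents=(16, 16, 32), cells=(4, 4, 8),
                           layer_boundaries=(8.0, 24.0), layer_labels=(2, 1, 2))
        )
        materials = {r: td.Material.from_reduced(r, f"r{r}", 0.05, 2.0, 0.0, 1.0)
                     for r in (1, 2)}
        thresholds = ThresholdSet({1: 5.0, 2: 5.0})
        cfg = PlanConfig(coverage_target=0.9, tumor_region=1, oar_regions=(2,))
        start = [td.PointSource(position=(8.0, 8.0, 9.5), power=1.0)]
        sched = AnnealSchedule(n_iters=20, t0=None, probe_moves=5, sigma=4.0)
        best, pos = anneal_placement(mesh, materials, start, thresholds, cfg,
                                     sched, seed=72, packets=1500)
        # midline z = 16; one mesh cell is 4 mm
        assert abs(pos[0][2] - 16.0) <= 4.0 + 1e-9
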