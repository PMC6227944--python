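"""Sensitivity experiments: perturbation geometry, sweeps, estimators,
isolation classification and ranking."""

import math

import numpy as np
import pytest

from cranialink.sensitivity import (
    COORDINATED_NEUROCRANIUM,
    DEFAULT_PCT_RANGE,
    ExperimentRecord,
    ExperimentResult,
    ExperimentSpec,
    PerturbationInfeasible,
    central_differences,
    classify_isolation,
    delta_kt_average,
    delta_kt_instantaneous,
    enumerate_experiments,
    kt_surface,
    perturb_geometry,
    rank_sensitivity,
    run_experiment,
    summarize_experiment,
)
from cranialink.geometry import link_length

SHORT_RANGE = (99, 100, 101)


def _spec(**kw):
    defaults = dict(
        reference_link="lower_jaw",
        moved_joints=("JQ_L", "JQ_R"),
        axis="y",
        input_type="epaxial",
        pct_range=SHORT_RANGE,
    )
    defaults.update(kw)
    return ExperimentSpec(**defaults)


class TestSpecValidation:
    def test_default_range_is_75_to_125(self):
        assert DEFAULT_PCT_RANGE == tuple(range(75, 126))
        assert len(DEFAULT_PCT_RANGE) == 51

    def test_rejects_non_endpoint_joint(self):
        with pytest.raises(ValueError, match="not an endpoint"):
            _spec(moved_joints=("HS_L", "HS_R"))

    def test_rejects_range_without_default(self):
        with pytest.raises(ValueError, match="100"):
            _spec(pct_range=(98, 99, 101))

    def test_rejects_bad_axis(self):
        with pytest.raises(ValueError, match="axis"):
            _spec(axis="w")

    def test_labels(self):
        assert _spec().label == "lower_jaw:JQ:y:epaxial"
        coord = _spec(
            reference_link="anterior_suspensorium", moved_joints=COORDINATED_NEUROCRANIUM, axis="x"
        )
        assert coord.joints_label == "NV+NS"


class TestPerturbation:
    def test_analytic_root(self, default_geom):
        """Hand-derived oracle on a fabricated right-angle layout: with
        JQ_R=(0,0,0) and SYM=(4,-2,0), shifting SYM along y to make the jaw
        sqrt(20)*1.05 long solves s^2 - 4s + 20 - 22.05 = 0, i.e.
        s = 2 - sqrt(6.05) (branch through zero at 100%)."""
        geom = default_geom.with_positions({"JQ_R": [0, 0, 0], "JQ_L": [0, 0, 0.5], "SYM": [4, -2, 0]})
        spec = _spec(moved_joints=("SYM",), axis="y")
        perturbed, s = perturb_geometry(geom, spec, 105.0)
        assert s == pytest.approx(2.0 - math.sqrt(6.05), abs=1e-12)
        assert link_length(perturbed, "lower_jaw", "right") == pytest.approx(
            1.05 * math.sqrt(20.0), abs=1e-9
        )

    @pytest.mark.parametrize("pct", [75, 90, 100, 110, 125])
    def test_achieves_target_length_exactly(self, default_geom, pct):
        L0 = link_length(default_geom, "lower_jaw", "right")
        perturbed, s = perturb_geometry(default_geom, _spec(), float(pct))
        assert link_length(perturbed, "lower_jaw", "right") == pytest.approx(
            pct / 100.0 * L0, abs=1e-9
        )
        if pct == 100:
            assert s == pytest.approx(0.0, abs=1e-12)

    def test_branch_continuous_through_default(self, default_geom):
        """s(pct) must pass through 0 at 100% and vary continuously."""
        s_prev = None
        for pct in range(95, 106):
            _, s = perturb_geometry(default_geom, _spec(), float(pct))
            if s_prev is not None:
                assert abs(s - s_prev) < 1.0
            s_prev = s

    def test_pair_moved_mirror_symmetrically(self, default_geom):
        from cranialink.geometry import validate_symmetry

        for axis in ("x", "y", "z"):
            perturbed, _ = perturb_geometry(default_geom, _spec(axis=axis), 110.0)
            assert validate_symmetry(perturbed, 1e-9).passed

    def test_coordinated_set_preserves_neurocranium_link(self, default_geom):
        spec = _spec(
            reference_link="anterior_suspensorium", moved_joints=COORDINATED_NEUROCRANIUM, axis="x"
        )
        perturbed, _ = perturb_geometry(default_geom, spec, 115.0)
        assert link_length(perturbed, "neurocranium", "right") == pytest.approx(
            link_length(default_geom, "neurocranium", "right"), abs=1e-9
        )
        assert link_length(perturbed, "anterior_suspensorium", "right") == pytest.approx(
            1.15 * link_length(default_geom, "anterior_suspensorium", "right"), abs=1e-9
        )

    def test_unreachable_length_infeasible(self, default_geom):
        # shrinking a link below its off-axis offset is impossible along one axis
        geom = default_geom.with_positions({"JQ_R": [0, 0, 0], "JQ_L": [0, 0, 0.5], "SYM": [4, -2, 0]})
        spec = _spec(moved_joints=("SYM",), axis="y")
        # min reachable length is the x-distance 4 = 89.4% of sqrt(20)
        with pytest.raises(PerturbationInfeasible):
            perturb_geometry(geom, spec, 80.0)

    def test_only_listed_joints_move(self, default_geom):
        perturbed, _ = perturb_geometry(default_geom, _spec(), 90.0)
        for j in ("NV", "NS_L", "NS_R", "HS_L", "HS_R", "CH_L", "CH_R", "HYM", "SYM"):
            assert np.array_equal(perturbed.position(j), default_geom.position(j))


class TestEstimators:
    def test_central_difference_exact_on_quadratic(self):
        """Central differences are exact for quadratics at the midpoint of a
        symmetric stencil: y = L^2 on L = {1,2,3} gives slope 4 at L=2."""
        assert central_differences([1.0, 2.0, 3.0], [1.0, 4.0, 9.0]) == pytest.approx([4.0], abs=0)

    def test_central_difference_count(self):
        L = np.linspace(1, 2, 11)
        assert len(central_differences(L, L**2)) == 9

    def _fake_result(self, lengths, kts):
        records = tuple(
            ExperimentRecord(pct, L, 0.0, {"suspensorium": kt, "hyoid": 0.0, "lower_jaw": 0.0})
            for pct, L, kt in zip(range(98, 98 + len(lengths)), lengths, kts)
        )
        spec = ExperimentSpec(
            "posterior_suspensorium", ("HS_L", "HS_R"), "y", "epaxial",
            tuple(range(98, 98 + len(lengths))) if 100 in range(98, 98 + len(lengths)) else (100,),
        )
        return ExperimentResult(spec, records, ())

    def test_instantaneous_uses_99_and_101(self):
        res = self._fake_result([9.9, 10.0, 10.1, 10.2], [1.0, 1.5, 1.8, 2.0])
        # records carry pcts 98..101 -> 99% is L=10.0, 101% is L=10.2
        got = delta_kt_instantaneous(res, "suspensorium")
        assert got == pytest.approx((2.0 - 1.5) / (10.2 - 10.0), abs=1e-12)

    def test_average_linear_curve_binary_exact(self):
        """On a linear KT̄(L) curve every central difference equals the slope m,
        so dKT_avg = m * (a-2) / a exactly (binary-exact with power-of-two
        values: m = 0.5, a = 8 gives 0.375)."""
        L = [float(k) for k in range(8)]
        kt = [0.5 * x for x in L]
        res = self._fake_result(L, kt)
        assert delta_kt_average(res, "suspensorium") == 0.375
        assert delta_kt_average(res, "suspensorium", denominator="terms") == 0.5

    def test_average_is_nonnegative_and_uses_abs(self):
        res = self._fake_result([1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 0.0, 1.0])
        # slopes at interior points are 0 and 0 -> av 0; use a sign-flipping curve
        res2 = self._fake_result([1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 0.0, -1.0])
        assert delta_kt_average(res, "suspensorium") == 0.0
        assert delta_kt_average(res2, "suspensorium") == pytest.approx((0.0 + 1.0) / 4.0, abs=1e-15)

    def test_missing_interior_record_raises(self):
        res = self._fake_result([10.0, 10.1, 10.2], [1.0, 1.5, 2.0])  # pcts 98,99,100
        with pytest.raises(ValueError, match="99% and 101%"):
            delta_kt_instantaneous(res, "suspensorium")


class TestRunExperiment:
    def test_short_sweep_shapes(self, default_geom, config):
        res = run_experiment(default_geom, config, _spec())
        assert res.a == 3
        assert res.retained_range == (99, 101)
        assert [r.pct for r in res.records] == [99, 100, 101]
        lengths = [r.length_mm for r in res.records]
        assert lengths == sorted(lengths)
        assert res.record_at(100).displacement_mm == pytest.approx(0.0, abs=1e-12)

    def test_default_record_matches_direct_simulation(self, default_geom, config):
        from cranialink.kt import mean_kt
        from cranialink.solver import InputSpec, simulate

        res = run_experiment(default_geom, config, _spec())
        traj = simulate(default_geom, config, InputSpec.epaxial())
        rec = res.record_at(100)
        for out in ("suspensorium", "hyoid", "lower_jaw"):
            assert rec.kt_mean[out] == pytest.approx(mean_kt(traj, out), abs=1e-12)

    def test_structural_zero_jaw_perturbation(self, default_geom, config):
        """Moving JQ (and SYM with it downstream) cannot alter the suspensorium
        or hyoid KT: those outputs are solved before the jaw in the kinematic
        chain.  The KT̄ values must be bit-identical across the sweep."""
        res = run_experiment(default_geom, config, _spec())
        base = res.record_at(100)
        for rec in res.records:
            assert rec.kt_mean["suspensorium"] == base.kt_mean["suspensorium"]
            assert rec.kt_mean["hyoid"] == base.kt_mean["hyoid"]

    def test_structural_zero_ns_x(self, default_geom, config):
        """Shifting the NS pair along x (the suspensorium rotation axis)
        cancels analytically in the closure equations: the solved HS/JQ/SYM
        positions are unchanged, so hyoid and jaw KT respond only at
        floating-point rounding level while the suspensorium KT (whose
        direction vector starts at the moved NS) responds strongly."""
        spec = _spec(
            reference_link="anterior_suspensorium",
            moved_joints=("NS_L", "NS_R"),
            axis="x",
        )
        summary = summarize_experiment(run_experiment(default_geom, config, spec))
        for out in ("hyoid", "lower_jaw"):
            assert abs(summary[out].dkt_instantaneous) < 1e-12
            assert summary[out].dkt_average < 1e-12
        assert abs(summary["suspensorium"].dkt_instantaneous) > 1e-6

    def test_dropped_pcts_recorded_with_reason(self, default_geom, config):
        geom = default_geom.with_positions({"JQ_R": [0, 0, 0], "JQ_L": [0, 0, 0.5], "SYM": [4, -2, 0]})
        spec = _spec(moved_joints=("SYM",), axis="y", pct_range=(80, 99, 100, 101))
        res = run_experiment(geom, config, spec)
        assert (80, "infeasible-perturbation") in res.dropped

    def test_too_few_records_raises(self, default_geom, config):
        geom = default_geom.with_positions({"JQ_R": [0, 0, 0], "JQ_L": [0, 0, 0.5], "SYM": [4, -2, 0]})
        spec = _spec(moved_joints=("SYM",), axis="y", pct_range=(80, 85, 100))
        with pytest.raises(PerturbationInfeasible, match="retained"):
            run_experiment(geom, config, spec)


@pytest.fixture(scope="module")
def summaries(default_geom, config):
    specs = [
        _spec(),  # JQ y -> isolates lower_jaw (structural zeros elsewhere)
        _spec(moved_joints=("SYM",), axis="x"),  # SYM x -> also jaw-only
        _spec(
            reference_link="anterior_suspensorium",
            moved_joints=("NS_L", "NS_R"),
            axis="x",
        ),  # NS x -> isolates suspensorium
        _spec(reference_link="hyoid", moved_joints=("HS_L", "HS_R"), axis="x"),  # coupled
    ]
    return {s.label: summarize_experiment(run_experiment(default_geom, config, s)) for s in specs}


class TestClassifyAndRank:
    def test_isolation_verdicts(self, summaries):
        iso = classify_isolation(summaries)
        ex = iso["experiments"]
        assert ex["lower_jaw:JQ:y:epaxial"]["verdict"] == "isolates:lower_jaw"
        assert ex["lower_jaw:SYM:x:epaxial"]["verdict"] == "isolates:lower_jaw"
        assert ex["anterior_suspensorium:NS:x:epaxial"]["verdict"] == "isolates:suspensorium"
        assert ex["hyoid:HS:x:epaxial"]["verdict"] == "coupled"
        assert set(iso["isolating"]["lower_jaw"]) == {
            "lower_jaw:JQ:y:epaxial",
            "lower_jaw:SYM:x:epaxial",
        }

    def test_null_outputs_flagged(self, summaries):
        iso = classify_isolation(summaries)
        outputs = iso["experiments"]["lower_jaw:JQ:y:epaxial"]["outputs"]
        assert outputs == {"suspensorium": "null", "hyoid": "null", "lower_jaw": "active"}

    def test_ranking_orders_by_instantaneous_magnitude(self, summaries):
        df = rank_sensitivity(summaries)
        jaw = df[(df.reference_link == "lower_jaw") & (df.output == "lower_jaw")]
        assert set(jaw["rank_inst"]) == {1, 2}
        top = jaw[jaw.rank_inst == 1].iloc[0]
        bottom = jaw[jaw.rank_inst == 2].iloc[0]
        assert top.delta_kt_inst_abs >= bottom.delta_kt_inst_abs
        assert bool(top.is_max_inst) and not bool(bottom.is_max_inst)

    def test_ranking_deterministic_under_insertion_order(self, summaries):
        a = rank_sensitivity(summaries)
        b = rank_sensitivity(dict(reversed(list(summaries.items()))))
        assert a.equals(b)


class TestRosterAndSurface:
    def test_roster_enumeration(self, default_geom):
        specs = enumerate_experiments(default_geom)
        labels = [s.label for s in specs]
        assert len(labels) == len(set(labels)) == 52
        # 8 links x 2 endpoints x 3 axes = 48 sweeps minus duplicate-free
        # overlaps, plus 2 links x 2 axes of the coordinated neurocranium set
        assert sum(1 for s in specs if s.moved_joints == COORDINATED_NEUROCRANIUM) == 4
        assert all(s.input_type == "epaxial" for s in specs)

    def test_surface_grid(self, default_geom, config):
        s1 = _spec(axis="y", pct_range=(100,))
        s2 = _spec(moved_joints=("SYM",), axis="x", pct_range=(100,))
        df = kt_surface(default_geom, config, s1, s2, [-0.5, 0.0, 0.5], [0.0, 0.5])
        assert len(df) == 3 * 2 * 3  # grid1 x grid2 x outputs
        centre = df[(df.d1_mm == 0.0) & (df.d2_mm == 0.0) & (df.output == "lower_jaw")]
        from cranialink.kt import mean_kt
        from cranialink.solver import InputSpec, simulate

        expected = mean_kt(simulate(default_geom, config, InputSpec.epaxial()), "lower_jaw")
        assert centre["kt_mean"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_surface_infeasible_cells_are_nan(self, default_geom, config):
        s1 = _spec(reference_link="hyoid", moved_joints=("HS_L", "HS_R"), axis="y", pct_range=(100,))
        s2 = _spec(reference_link="hyoid", moved_joints=("CH_L", "CH_R"), axis="y", pct_range=(100,))
        df = kt_surface(default_geom, config, s1, s2, [0.0], [0.0, 15.0])
        broken = df[df.d2_mm == 15.0]
        assert broken["kt_mean"].isna().all()
        assert df[df.d2_mm == 0.0]["kt_mean"].notna().all()
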