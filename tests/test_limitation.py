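"""Critical-density analysis and station-level limitation assessment."""
import math

import numpy as np
import pytest

from tunaforage import (
    CLADOCERAN,
    COPEPOD,
    NAUPLIUS,
    LarvalStage,
    ModelParams,
    PreyType,
    Station,
    assess_stations,
    assessment_frame,
    calibrate_detection,
    critical_density,
    critical_density_table,
    default_stages,
    growth_budget,
    response_surface,
    sgr_max,
)
from tunaforage.limitation import DEFAULT_STATION_TEMP


def bisect_critical_density(stage, prey, temp, target, params, lo=1e-6, hi=1e12):
    """Numeric oracle: bisection on the growth budget's uncapped daily SGR."""
    goal = sgr_max(temp, params) if target == "max_growth" else 0.0

    def short(density):
        b = growth_budget(stage, [(prey, density)], temp, params)
        return b.daily_sgr_uncapped - goal

    assert short(lo) < 0 < short(hi)
    for _ in range(200):
        mid = math.sqrt(lo * hi)  # geometric: thresholds span many decades
        if short(mid) < 0:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


class TestCriticalDensity:
    def test_maintenance_below_max_growth(self, calibrated, stages):
        for stage in stages.values():
            nm = critical_density(stage, NAUPLIUS, 25.0, "maintenance", calibrated)
            ng = critical_density(stage, NAUPLIUS, 25.0, "max_growth", calibrated)
            assert 0 < nm < ng

    def test_closed_form_matches_bisection(self, full_capture):
        rng = np.random.default_rng(0)
        for _ in range(100):
            stage = LarvalStage("r", float(rng.uniform(3.5, 8.0)))
            prey = PreyType(
                "p",
                length=float(rng.uniform(0.1, 1.2)),
                dry_weight=float(rng.uniform(1e-4, 1.2e-2)),
                capture_mode="always_one",
            )
            temp = float(rng.uniform(22.0, 28.0))
            target = rng.choice(["maintenance", "max_growth"])
            closed = critical_density(stage, prey, temp, target, full_capture)
            numeric = bisect_critical_density(stage, prey, temp, target, full_capture)
            assert closed == pytest.approx(numeric, rel=1e-9)

    def test_zero_capture_probability_gives_infinity(self, calibrated):
        yolk = LarvalStage("pre", 2.8)  # below the capture ramp
        assert critical_density(yolk, COPEPOD, 24.0, "max_growth", calibrated) == math.inf

    def test_uncalibrated_params_raise(self, stages):
        from tunaforage import CalibrationError

        with pytest.raises(CalibrationError):
            critical_density(stages["F0"], NAUPLIUS, 22.0, "max_growth", ModelParams())


class TestCriticalDensityTable:
    def test_grid_shape_and_invariants(self, full_capture):
        table = critical_density_table(params=full_capture)
        assert len(table) == 4 * 3 * 3 * 2
        pivot = table.pivot_table(
            index=["prey", "stage"], columns=["target", "temperature_c"],
            values="critical_density_m3",
        )
        # max-growth threshold always above maintenance
        for temp in (22.0, 25.0, 28.0):
            assert (pivot[("max_growth", temp)] > pivot[("maintenance", temp)]).all()
        # monotone in temperature
        for target in ("maintenance", "max_growth"):
            assert (pivot[(target, 25.0)] > pivot[(target, 22.0)]).all()
            assert (pivot[(target, 28.0)] > pivot[(target, 25.0)]).all()
        # monotone in stage (weight) for fixed prey/temp/target
        for (prey, stage_group) in table.groupby("prey"):
            g = stage_group.sort_values("standard_length_mm")
            for (_, tgroup) in g.groupby(["temperature_c", "target"]):
                vals = tgroup.sort_values("standard_length_mm")["critical_density_m3"].to_numpy()
                assert (np.diff(vals) > 0).all()

    def test_cross_prey_ratio_column(self, full_capture, stages):
        naup = critical_density(stages["F1"], NAUPLIUS, 22.0, "max_growth", full_capture)
        clad = critical_density(stages["F1"], CLADOCERAN, 22.0, "max_growth", full_capture)
        expected = (CLADOCERAN.dry_weight * CLADOCERAN.length**2) / (
            NAUPLIUS.dry_weight * NAUPLIUS.length**2
        )
        assert naup / clad == pytest.approx(expected, rel=1e-12)


class TestResponseSurface:
    def test_curve_anatomy(self, calibrated, stages):
        stage, prey, temp = stages["F1"], NAUPLIUS, 25.0
        n_maint = critical_density(stage, prey, temp, "maintenance", calibrated)
        n_max = critical_density(stage, prey, temp, "max_growth", calibrated)
        dens = [0.0, n_maint, n_max, 2 * n_max]
        surf = response_surface(stage, prey, [temp], dens, calibrated)
        sgr = surf["daily_sgr"].to_numpy()
        assert sgr[0] < 0  # starvation at zero food
        assert sgr[1] == pytest.approx(0.0, abs=1e-12)  # zero crossing at maintenance
        assert sgr[2] == pytest.approx(sgr_max(temp), rel=1e-9)  # hits ceiling
        assert sgr[3] == sgr[2]  # saturated beyond the threshold
        assert (np.diff(sgr) >= -1e-15).all()

    def test_zero_crossing_by_root_finding(self, calibrated, stages):
        from scipy.optimize import brentq

        stage, prey, temp = stages["F2"], CLADOCERAN, 24.0

        def f(density):
            return growth_budget(stage, [(prey, density)], temp, calibrated).daily_sgr_uncapped

        root = brentq(f, 1e-6, 1e6, xtol=1e-12, rtol=1e-14)
        assert root == pytest.approx(
            critical_density(stage, prey, temp, "maintenance", calibrated), rel=1e-9
        )


class TestAssessStations:
    @pytest.fixture()
    def average_station(self):
        # survey-average prey field and mixed-layer temperature (2020)
        return Station(
            id="AVG", year=2020, longitude=2.0, latitude=39.5,
            temperature=24.4, nauplii=506.0, cladocera=653.0, copepods=258.0,
        )

    def test_average_station_scenarios(self, average_station, calibrated):
        (a,) = assess_stations([average_station], params=calibrated)
        for stage in ("F0", "F1", "F2", "F3"):
            assert a.result("nauplii_only", stage).limited
            assert not a.result("copepods_only", stage).limited
            assert a.result("copepods_only", stage).fli == 1.0
            assert not a.result("combined", stage).limited

    def test_empty_prey_field_starves_all_scenarios(self, calibrated):
        bare = Station("EMPTY", 2020, 2.0, 39.0, 24.0, 0.0, 0.0, 0.0)
        (a,) = assess_stations([bare], params=calibrated)
        assert all(r.fli < 0 and r.starving for r in a.results)

    def test_combined_at_least_single_prey(self, calibrated):
        rng = np.random.default_rng(3)
        stations = [
            Station(
                f"R{i}", 2020, 2.0, 39.0, float(rng.uniform(22, 28)),
                float(rng.uniform(0, 2000)), float(rng.uniform(0, 100)),
                float(rng.uniform(0, 50)),
            )
            for i in range(10)
        ]
        for a in assess_stations(stations, params=calibrated):
            for stage in ("F0", "F1", "F2", "F3"):
                combined = a.result("combined", stage).daily_sgr
                singles = [
                    a.result(s, stage).daily_sgr
                    for s in ("nauplii_only", "cladocera_only", "copepods_only")
                ]
                assert combined >= max(singles) - 1e-15

    def test_missing_temperature_falls_back_to_default(self, calibrated, caplog):
        st = Station("NOTEMP", 2020, 2.0, 39.0, None, 500.0, 10.0, 50.0)
        with caplog.at_level("WARNING", logger="tunaforage.limitation"):
            (a,) = assess_stations([st], params=calibrated)
        assert a.temperature_c == DEFAULT_STATION_TEMP
        assert "NOTEMP" in caplog.text

    def test_assessment_frame_shape(self, average_station, calibrated):
        frame = assessment_frame(assess_stations([average_station] * 3, params=calibrated))
        assert len(frame) == 3 * 4 * 4  # stations x scenarios x stages
        assert set(frame["scenario"]) == {
            "nauplii_only", "cladocera_only", "copepods_only", "combined",
        }

    def test_unknown_scenario_rejected(self, average_station, calibrated):
        with pytest.raises(ValueError):
            assess_stations([average_station], params=calibrated, scenarios=["krill_only"])
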