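"""RBED mathematics: survival, isoeffective dose, interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbedplan.radiobio import (
    LQParameters,
    SensitisationScenario,
    TissueResponseMap,
    equivalent_exposure_scaling,
    get_scenario,
    interpolate_lq,
    lq_survival,
    rbed,
    rbed_from_concentration,
    rbed_map,
    scenario_names,
)


def survival_oracle(dose, p):
    """Independent scalar evaluation of the LQ model."""
    import math

    return math.exp(-p.alpha * dose - p.beta * dose * dose)


def rbed_bisection_oracle(dose_a, p_a, p_b, tol=1e-13):
    """Solve the survival-equality equation by bisection (no closed form)."""
    target = survival_oracle(dose_a, p_a)
    lo, hi = 0.0, 1000.0
    while hi - lo > tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if survival_oracle(mid, p_b) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestLQSurvival:
    @pytest.mark.parametrize(
        "dose,params,expected",
        [
            (0.0, LQParameters(0.144, 0.109), 1.0),
            (2.0, LQParameters(0.144, 0.109), 0.4848091357673432),  # exp(-0.724)
            (2.0, LQParameters(0.002, 0.079), 0.7261490370736909),  # exp(-0.320)
        ],
    )
    def test_values(self, dose, params, expected):
        assert lq_survival(dose, params) == pytest.approx(expected, rel=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            lq_survival(-0.1, LQParameters(0.1, 0.05))

    def test_strictly_decreasing(self):
        p = LQParameters(0.024, 0.086)
        doses = np.linspace(0, 5, 101)
        sf = lq_survival(doses, p)
        assert np.all(np.diff(sf) < 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LQParameters(0.0, 0.0)
        with pytest.raises(ValueError):
            LQParameters(-0.1, 0.05)


class TestRBED:
    def test_identical_systems_identity(self):
        p = LQParameters(0.024, 0.086)
        assert rbed(2.0, p, p) == pytest.approx(2.0, rel=1e-12)

    def test_doped_to_undoped_maximum_scenario(self):
        # Maximum-scenario endpoints: doped (0.144, 0.109) vs undoped (0, 0.072).
        val = rbed(2.0, LQParameters(0.144, 0.109), LQParameters(0.0, 0.072))
        assert val == pytest.approx(3.1710495984067415, rel=1e-10)
        oracle = rbed_bisection_oracle(
            2.0, LQParameters(0.144, 0.109), LQParameters(0.0, 0.072)
        )
        assert val == pytest.approx(oracle, abs=1e-9)

    def test_tumour_wall_printed_value(self):
        # Printed tumour-wall mean: 2.241 Gy maps to 3.478 Gy.
        val = rbed(2.241, LQParameters(0.144, 0.109), LQParameters(0.0, 0.072))
        assert val == pytest.approx(3.478, rel=5e-3)

    def test_linear_reference_branch(self):
        p_a = LQParameters(0.144, 0.109)
        p_b0 = LQParameters(0.1, 0.0)
        effect = 0.144 * 2 + 0.109 * 4
        assert rbed(2.0, p_a, p_b0) == pytest.approx(effect / 0.1, rel=1e-12)

    def test_linear_branch_is_quadratic_limit(self):
        p_a = LQParameters(0.144, 0.109)
        lin = rbed(2.0, p_a, LQParameters(0.1, 0.0))
        quad = rbed(2.0, p_a, LQParameters(0.1, 1e-8))
        assert quad == pytest.approx(lin, rel=1e-5)

    def test_survival_equality_residual_random_draws(self, rng):
        """Closed form solves the isoeffect equation to 1e-10 in SF."""
        for _ in range(1000):
            p_a = LQParameters(rng.uniform(0.0, 0.2), rng.uniform(0.05, 0.15))
            p_b = LQParameters(rng.uniform(0.0, 0.1), rng.uniform(0.05, 0.15))
            d = rng.uniform(0.0, 5.0)
            d_b = rbed(d, p_a, p_b)
            assert abs(
                survival_oracle(d_b, p_b) - survival_oracle(d, p_a)
            ) < 1e-10


class TestInterpolation:
    @pytest.mark.parametrize(
        "conc,expected",
        [
            (0.0, (0.000, 0.072)),
            (500.0, (0.144, 0.109)),
            (250.0, (0.072, 0.0905)),
        ],
    )
    def test_maximum_scenario_endpoints_and_midpoint(self, conc, expected):
        p = interpolate_lq(get_scenario("maximum"), conc)
        assert (p.alpha, p.beta) == pytest.approx(expected, abs=1e-15)

    def test_endpoints_exact_all_scenarios(self):
        for name in ("minimum", "mean", "maximum"):
            s = get_scenario(name)
            assert interpolate_lq(s, 0.0) == s.params_undoped
            assert interpolate_lq(s, s.reference_concentration) == s.params_doped

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            interpolate_lq(get_scenario("mean"), -1.0)

    def test_scenario_deltas_positive(self):
        for name in ("minimum", "mean", "maximum"):
            s = get_scenario(name)
            assert s.delta_alpha > 0
            assert s.delta_beta >= 0


class TestRBEDFromConcentration:
    def test_tumour_inner_printed_value(self):
        # Printed tumour-inner mean: 2.258 Gy at 250 μg/ml maps to 2.945 Gy.
        val = rbed_from_concentration(2.258, 250.0, get_scenario("maximum"))
        assert val == pytest.approx(2.945, rel=5e-3)

    def test_zero_concentration_identity(self):
        for name in scenario_names():
            assert rbed_from_concentration(1.7, 0.0, get_scenario(name)) == pytest.approx(
                1.7, abs=1e-14
            )

    def test_mean_scenario_low_concentration(self):
        val = rbed_from_concentration(2.0, 25.0, get_scenario("mean"))
        assert val == pytest.approx(2.0435539042039585, rel=1e-10)
        p_a = interpolate_lq(get_scenario("mean"), 25.0)
        oracle = rbed_bisection_oracle(2.0, p_a, get_scenario("mean").params_undoped)
        assert val == pytest.approx(oracle, abs=1e-9)

    def test_monotone_in_dose_and_concentration(self):
        doses = np.linspace(0.0, 5.0, 51)
        concs = np.linspace(0.0, 500.0, 26)
        for name in ("minimum", "mean", "maximum"):
            s = get_scenario(name)
            by_dose = rbed_from_concentration(doses, 250.0, s)
            assert np.all(np.diff(by_dose) > 0)
            by_conc = rbed_from_concentration(2.0, concs, s)
            assert np.all(np.diff(by_conc) >= 0)

    @settings(derandomize=True, max_examples=200)
    @given(
        dose=st.floats(0.0, 6.0),
        conc=st.floats(0.0, 500.0),
        name=st.sampled_from(["minimum", "mean", "maximum"]),
    )
    def test_isoeffect_property(self, dose, conc, name):
        """RBED preserves the survival fraction across the doped/undoped pair."""
        s = get_scenario(name)
        d_b = rbed_from_concentration(dose, conc, s)
        sf_a = lq_survival(dose, interpolate_lq(s, conc))
        sf_b = lq_survival(d_b, s.params_undoped)
        assert abs(sf_a - sf_b) < 1e-10


class TestRBEDMap:
    def _phantom(self, labels, concentrations):
        from rbedplan.phantom import RegionSpec, VoxelPhantom

        labels = np.asarray(labels, dtype=np.int16).reshape(-1, 1, 1)
        regions = {
            int(lab): RegionSpec(int(lab), f"r{lab}", "breast_tissue", c)
            for lab, c in concentrations.items()
        }
        return VoxelPhantom(labels, (1, 1, 1), (0, 0, 0), regions)

    def test_non_responding_identity(self):
        ph = self._phantom([1, 1], {1: 500.0})
        dose = np.full(ph.shape, 2.0)
        tmap = TissueResponseMap({1: False})
        out = rbed_map(dose, ph, tmap, get_scenario("maximum"))
        np.testing.assert_array_equal(out, dose)

    def test_single_voxel_maximum(self):
        ph = self._phantom([1], {1: 500.0})
        out = rbed_map(np.full(ph.shape, 2.0), ph, TissueResponseMap({1: True}),
                       get_scenario("maximum"))
        assert out[0, 0, 0] == pytest.approx(3.1710495984067415, rel=1e-10)

    def test_two_voxel_composition(self):
        ph = self._phantom([1, 2], {1: 0.0, 2: 500.0})
        tmap = TissueResponseMap({1: True, 2: True})
        out = rbed_map(np.full(ph.shape, 2.0), ph, tmap, get_scenario("maximum"))
        assert out[0, 0, 0] == pytest.approx(2.0, abs=1e-12)
        assert out[1, 0, 0] == pytest.approx(3.1710495984067415, rel=1e-10)

    def test_lattice_mismatch_raises(self):
        ph = self._phantom([1], {1: 0.0})
        with pytest.raises(ValueError):
            rbed_map(np.zeros((2, 2, 2)), ph, TissueResponseMap({1: True}),
                     get_scenario("mean"))

    def test_missing_label_raises(self):
        ph = self._phantom([1], {1: 0.0})
        with pytest.raises(ValueError):
            rbed_map(np.zeros(ph.shape), ph, TissueResponseMap({}), get_scenario("mean"))


class TestEquivalentExposure:
    def test_undoped_region_gives_unity(self):
        f = equivalent_exposure_scaling([2.0, 2.0], 0.0, get_scenario("maximum"))
        assert f == pytest.approx(1.0, abs=1e-12)

    def test_uniform_dose_reduces_to_rbed_ratio(self):
        f = equivalent_exposure_scaling([2.0], 500.0, get_scenario("maximum"))
        assert f == pytest.approx(3.1710495984067415 / 2.0, rel=1e-8)

    def test_two_voxel_matches_dense_scan(self):
        s = get_scenario("maximum")
        doses = np.array([2.0, 2.2])
        f = equivalent_exposure_scaling(doses, 500.0, s)
        # Brute-force: densely scan f and pick the best mean-SF match.
        p_a = interpolate_lq(s, 500.0)
        target = np.mean([lq_survival(d, p_a) for d in doses])
        fs = np.linspace(1.0, 3.0, 2_000_001)
        scaled = fs[:, None] * doses[None, :]
        pb = s.params_undoped
        mean_sf = np.exp(-pb.alpha * scaled - pb.beta * scaled**2).mean(axis=1)
        best = fs[np.argmin(np.abs(mean_sf - target))]
        assert f == pytest.approx(best, abs=1e-6)

    def test_empty_and_zero_regions_rejected(self):
        with pytest.raises(ValueError):
            equivalent_exposure_scaling([], 0.0, get_scenario("mean"))
        with pytest.raises(ValueError):
            equivalent_exposure_scaling([0.0, 0.0], 250.0, get_scenario("mean"))


def test_registry_matches_published_parameters():
    expected = {
        "minimum": ((0.024, 0.086), (0.064, 0.087)),
        "mean": ((0.002, 0.079), (0.104, 0.098)),
        "maximum": ((0.000, 0.072), (0.144, 0.109)),
    }
    for name, (und, dop) in expected.items():
        s = get_scenario(name)
        assert (s.params_undoped.alpha, s.params_undoped.beta) == und
        assert (s.params_doped.alpha, s.params_doped.beta) == dop
        assert s.reference_concentration == 500.0
    assert get_scenario("conventional").is_identity


def test_scenario_invariants():
    with pytest.raises(ValueError):
        SensitisationScenario(
            "bad", LQParameters(0.1, 0.1), LQParameters(0.1, 0.1), -5.0
        )
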