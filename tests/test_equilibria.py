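import numpy as np
import pytest

from caregame import (
    classify_point,
    classify_regime,
    det_trace_at,
    interior_equilibrium,
    jacobian,
    replicator_field,
)
from caregame.equilibria import CORNERS

from _support import random_scenario_params, random_strict_params

# Expected stability pattern of the five candidate points in each of the
# four sign regimes with C(1,1) stable.  Scenario numbering follows the
# sign pair (U2+S2-P2, R2+S1p-C2): (-,-) -> 1, (-,+) -> 2, (+,-) -> 3,
# (+,+) -> 4.  The interior point exists only in scenario 1.
SCENARIO_PATTERNS = {
    1: {"O": "ESS", "A": "unstable", "B": "unstable", "C": "ESS", "E": "saddle"},
    2: {"O": "saddle", "A": "saddle", "B": "unstable", "C": "ESS", "E": None},
    3: {"O": "saddle", "A": "unstable", "B": "saddle", "C": "ESS", "E": None},
    4: {"O": "unstable", "A": "saddle", "B": "saddle", "C": "ESS", "E": None},
}


class TestInteriorEquilibrium:
    def test_baseline_point(self, baseline):
        eq = interior_equilibrium(baseline)
        assert eq.exists
        assert eq.point[0] == pytest.approx(0.2 / 0.63, abs=1e-12)
        assert eq.point[1] == pytest.approx(0.2 / 0.37, abs=1e-12)

    def test_baseline_field_residual(self, baseline):
        eq = interior_equilibrium(baseline)
        dxdt, dydt = replicator_field(baseline, eq.point)
        assert abs(dxdt) < 1e-10
        assert abs(dydt) < 1e-10

    def test_baseline_trace_zero(self, baseline):
        eq = interior_equilibrium(baseline)
        assert eq.tr == 0.0

    def test_boundary_point_does_not_exist(self, baseline):
        # C2 - R2 - S1p = 0 puts x* on the boundary, not inside
        params = baseline.replace(S1p=baseline.C2 - baseline.R2)
        eq = interior_equilibrium(params)
        assert not eq.exists
        assert eq.point[0] == pytest.approx(0.0, abs=1e-12)
        assert eq.stability == "indeterminate"

    def test_degenerate_denominator(self, baseline):
        # a = 0 when U1 drops by exactly a
        params = baseline.replace(U1=baseline.U1 - 0.37)
        assert not interior_equilibrium(params).exists

    def test_trace_zero_whenever_exists(self, rng):
        found = 0
        for _ in range(500):
            params = random_strict_params(rng)
            eq = interior_equilibrium(params)
            if eq.exists:
                found += 1
                assert eq.tr == 0.0
        assert found > 0


class TestJacobian:
    def test_baseline_origin_diagonal(self, baseline):
        J = jacobian(baseline, (0.0, 0.0))
        assert J == pytest.approx(np.diag([-0.2, -0.2]), abs=1e-12)

    def test_midpoint_kills_diagonal(self, rng):
        params = random_strict_params(rng)
        J = jacobian(params, (0.5, 0.5))
        assert J[0, 0] == 0.0
        assert J[1, 1] == 0.0

    def test_matches_finite_differences(self, baseline, rng):
        h = 1e-6
        for _ in range(25):
            x, y = rng.uniform(0.1, 0.9, size=2)
            J = jacobian(baseline, (x, y))
            fd = np.empty((2, 2))
            for j, (dx, dy) in enumerate(((h, 0.0), (0.0, h))):
                fp = replicator_field(baseline, (x + dx, y + dy))
                fm = replicator_field(baseline, (x - dx, y - dy))
                fd[0, j] = (fp[0] - fm[0]) / (2 * h)
                fd[1, j] = (fp[1] - fm[1]) / (2 * h)
            assert J == pytest.approx(fd, abs=1e-6)


class TestDetTraceClosedForms:
    def test_baseline_at_C(self, baseline):
        det, tr = det_trace_at(baseline, "C")
        assert det == pytest.approx(0.17 * 0.43, abs=1e-12)
        assert tr == pytest.approx(-0.6, abs=1e-12)

    def test_baseline_at_O(self, baseline):
        det, tr = det_trace_at(baseline, "O")
        assert det == pytest.approx(0.04, abs=1e-12)
        assert tr == pytest.approx(-0.4, abs=1e-12)

    def test_det_at_C_vanishing_factor(self, baseline):
        params = baseline.replace(S1=baseline.P1 - baseline.U1)  # U1 + S1 = P1
        det, _ = det_trace_at(params, "C")
        assert det == pytest.approx(0.0, abs=1e-12)

    def test_unknown_label(self, baseline):
        with pytest.raises(ValueError, match="unknown"):
            det_trace_at(baseline, "Z")

    def test_E_requires_existence(self, baseline):
        params = baseline.replace(S1p=baseline.C2 - baseline.R2)
        with pytest.raises(ValueError, match="does not exist"):
            det_trace_at(params, "E")

    def test_closed_forms_match_jacobian_on_random_sets(self, rng):
        for _ in range(1000):
            params = random_strict_params(rng)
            for name, point in CORNERS.items():
                det, tr = det_trace_at(params, name)
                J = jacobian(params, point)
                assert det == pytest.approx(np.linalg.det(J), abs=1e-10)
                assert tr == pytest.approx(np.trace(J), abs=1e-10)
            eq = interior_equilibrium(params)
            if eq.exists:
                det, tr = det_trace_at(params, "E")
                J = jacobian(params, eq.point)
                assert det == pytest.approx(np.linalg.det(J), abs=1e-10)
                assert tr == pytest.approx(np.trace(J), abs=1e-10)


class TestClassifyPoint:
    @pytest.mark.parametrize(
        ("det", "tr", "expected"),
        [
            (0.0731, -0.6, "ESS"),
            (-0.05, 0.0, "saddle"),
            (0.04, 0.4, "unstable"),
            (0.0, 0.3, "indeterminate"),
            (0.04, 0.0, "indeterminate"),
            (1e-14, -1.0, "indeterminate"),
        ],
    )
    def test_sign_patterns(self, det, tr, expected):
        assert classify_point(det, tr) == expected


class TestClassifyRegime:
    def test_baseline_is_scenario_1(self, baseline):
        regime = classify_regime(baseline)
        assert regime.scenario == 1
        assert set(regime.ess_points) == {"O", "C"}
        assert "bilateral" in regime.care_model_types
        assert regime.equilibrium("A").stability == "unstable"
        assert regime.equilibrium("B").stability == "unstable"
        assert regime.equilibrium("E").stability == "saddle"

    def test_health_led_regime(self, baseline):
        # U1 + S1 < P1 and R2 + S1p > C2
        params = baseline.replace(P1=2.5, S1p=2.0)
        regime = classify_regime(params)
        assert "health-led" in regime.care_model_types
        assert regime.equilibrium("A").stability == "ESS"

    def test_social_led_regime(self, baseline):
        # U2 + S2 > P2 and R1 + P1 < C1
        params = baseline.replace(P2=2.7, C1=4.5, C2=4.8)
        regime = classify_regime(params)
        assert "social-led" in regime.care_model_types
        assert regime.equilibrium("B").stability == "ESS"

    @pytest.mark.parametrize("scenario", [1, 2, 3, 4])
    def test_scenario_patterns_on_random_sets(self, scenario, rng):
        pattern = SCENARIO_PATTERNS[scenario]
        for _ in range(50):
            params = random_scenario_params(scenario, rng)
            regime = classify_regime(params)
            assert regime.scenario == scenario
            for name, expected in pattern.items():
                eq = regime.equilibrium(name)
                if expected is None:
                    assert not eq.exists
                else:
                    assert eq.stability == expected, (name, params)

    def test_corner_classification_depends_only_on_corner_expressions(self, baseline):
        # a pure (U1, S1) trade-off leaves every corner expression fixed
        shifted = baseline.replace(U1=baseline.U1 - 0.1, S1=baseline.S1 + 0.1)
        for name in CORNERS:
            assert det_trace_at(shifted, name) == pytest.approx(
                det_trace_at(baseline, name), abs=1e-12
            )
            r1 = classify_regime(baseline).equilibrium(name).stability
            r2 = classify_regime(shifted).equilibrium(name).stability
            assert r1 == r2
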