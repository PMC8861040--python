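"""Model definitions, fixed points, and linearization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twodelay import (
    FixedPoint,
    TwoDelayCubicModel,
    eval_rhs,
    fixed_points,
    linearize,
    numerical_jacobian,
)

finite = st.floats(min_value=-5, max_value=5, allow_nan=False)


@pytest.mark.parametrize(
    "model,state,expected",
    [
        (dict(a1=-1, a2=0), (0.0, 1.0, 0.0), -1.0),
        (dict(a1=3.7, a2=-2.2, b1=0.5, b2=-0.3, tau1=0.1, tau2=0.2),
         (0.0, 0.0, 0.0), 0.0),
        # equilibrium of the cubic feedback model at sqrt(2):
        # 0.3*sqrt2 - 2*(0.15*sqrt2) = 0
        (dict(a1=0.2, a2=0.1, b1=-1.0, b2=1.15),
         (math.sqrt(2),) * 3, 0.0),
    ],
)
def test_eval_rhs_examples(model, state, expected):
    m = TwoDelayCubicModel(**model)
    assert eval_rhs(m, *state) == pytest.approx(expected, abs=1e-14)


def test_eval_rhs_rejects_nonfinite_state():
    m = TwoDelayCubicModel(a1=1.0, a2=0.0)
    with pytest.raises(ValueError):
        eval_rhs(m, math.nan, 0.0, 0.0)


@settings(deadline=None, derandomize=True)
@given(a1=finite, a2=finite, b1=finite, b2=finite, v=finite)
def test_equilibrium_function_identity(a1, a2, b1, b2, v):
    """On the diagonal the RHS collapses to (a1+a2) v - (b1+b2) v^3."""
    m = TwoDelayCubicModel(a1=a1, a2=a2, b1=b1, b2=b2)
    expected = (a1 + a2) * v - (b1 + b2) * v ** 3
    assert eval_rhs(m, v, v, v) == pytest.approx(expected, abs=1e-10)


class TestFixedPoints:
    def test_vdp_special_case_has_only_zero(self):
        # b1 + b2 = 0: the Van der Pol form has only the origin
        m = TwoDelayCubicModel(a1=-1, a2=0, b1=-1, b2=1)
        assert [p.kind for p in fixed_points(m)] == ["zero"]

    def test_unit_ratio_gives_plus_minus_one(self):
        m = TwoDelayCubicModel(a1=1, a2=1, b1=1, b2=1)
        pts = {p.kind: p.value for p in fixed_points(m)}
        assert pts == {"zero": 0.0, "positive": 1.0, "negative": -1.0}

    def test_case8_mapping_ratio_ten(self):
        m = TwoDelayCubicModel(a1=3, a2=-4, b1=1, b2=-1.1)
        pts = {p.kind: p.value for p in fixed_points(m)}
        assert pts["positive"] == pytest.approx(math.sqrt(10), abs=1e-12)
        assert pts["negative"] == pytest.approx(-math.sqrt(10), abs=1e-12)

    def test_negative_ratio_gives_only_zero(self):
        m = TwoDelayCubicModel(a1=0.3, a2=0.0, b1=1.0, b2=-1.1)
        assert [p.kind for p in fixed_points(m)] == ["zero"]

    @pytest.mark.parametrize("seed", [0])
    def test_all_fixed_points_are_equilibria(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            a1, a2, b1, b2 = rng.uniform(-3, 3, 4)
            m = TwoDelayCubicModel(a1=a1, a2=a2, b1=b1, b2=b2)
            for p in fixed_points(m):
                assert abs(eval_rhs(m, p.value, p.value, p.value)) <= 1e-12


class TestLinearize:
    def test_symmetric_cubic_cancels_delta(self):
        m = TwoDelayCubicModel(a1=1, a2=1, b1=1, b2=1)
        lin = linearize(m, FixedPoint(1.0, "positive"))
        assert lin.c0 == pytest.approx(-4.0)
        assert lin.delta == pytest.approx(0.0)
        assert lin.c1 == 0.0 and lin.c2 == 0.0

    def test_delta_formula_nonzero_point(self):
        m = TwoDelayCubicModel(a1=1, a2=1, b1=-1, b2=2)
        lin = linearize(m, FixedPoint(math.sqrt(2), "positive"))
        assert lin.delta == pytest.approx(3.0)
        assert lin.c0 == pytest.approx(-4.0)
        assert lin.c1 == pytest.approx(3.0)
        assert lin.c2 == pytest.approx(-3.0)

    def test_linear_model_linearizes_to_itself(self):
        m = TwoDelayCubicModel(a1=-7, a2=3)
        lin = linearize(m, FixedPoint(0.0, "zero"))
        assert (lin.c0, lin.c1, lin.c2) == (0.0, -7.0, 3.0)

    def test_missing_nonzero_point_errors(self):
        m = TwoDelayCubicModel(a1=-1, a2=0, b1=-1, b2=1)
        with pytest.raises(ValueError):
            linearize(m, FixedPoint(1.0, "positive"))

    def test_agrees_with_finite_differences(self):
        """Analytic linearization vs central differences, 100 seeded models."""
        rng = np.random.default_rng(1234)
        checked = 0
        while checked < 100:
            a1, a2 = rng.uniform(-3, 3, 2)
            b1 = rng.uniform(0.2, 3)
            b2 = -rng.uniform(0.2, 3)
            if b1 + b2 == 0 or (a1 + a2) / (b1 + b2) <= 1e-3:
                continue
            m = TwoDelayCubicModel(a1=a1, a2=a2, b1=b1, b2=b2)
            p = [q for q in fixed_points(m) if q.kind == "positive"][0]
            lin = linearize(m, p)
            num = numerical_jacobian(m, p.value, step=1e-6)
            for analytic, fd in zip((lin.c0, lin.c1, lin.c2), num):
                assert analytic == pytest.approx(fd, rel=1e-6, abs=1e-6)
            checked += 1

    def test_delta_antisymmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a1, a2, b1, b2 = rng.uniform(-2, 2, 4)
            if b1 + b2 == 0:
                continue
            t1, t2 = rng.uniform(0, 1, 2)
            m = TwoDelayCubicModel(a1=a1, a2=a2, b1=b1, b2=b2, tau1=t1, tau2=t2)
            sw = TwoDelayCubicModel(a1=a2, a2=a1, b1=b2, b2=b1, tau1=t2, tau2=t1)
            d = (m.a1 * m.b2 - m.a2 * m.b1) / (m.b1 + m.b2)
            d_sw = (sw.a1 * sw.b2 - sw.a2 * sw.b1) / (sw.b1 + sw.b2)
            assert d_sw == pytest.approx(-d, abs=1e-12)


class TestNumericalJacobian:
    def test_linear_model(self):
        m = TwoDelayCubicModel(a1=2, a2=0)
        c0, c1, c2 = numerical_jacobian(m, 5.0, step=1e-6)
        assert c0 == pytest.approx(0.0, abs=1e-8)
        assert c1 == pytest.approx(2.0, abs=1e-8)
        assert c2 == pytest.approx(0.0, abs=1e-8)

    def test_origin_gradient_is_linear_part(self):
        m = TwoDelayCubicModel(a1=1.3, a2=-0.7, b1=2.0, b2=-1.0)
        c0, c1, c2 = numerical_jacobian(m, 0.0, step=1e-6)
        assert c0 == pytest.approx(0.0, abs=1e-9)
        assert c1 == pytest.approx(1.3, abs=1e-9)
        assert c2 == pytest.approx(-0.7, abs=1e-9)

    def test_zero_step_errors(self):
        with pytest.raises(ValueError):
            numerical_jacobian(TwoDelayCubicModel(a1=1, a2=0), 1.0, step=0.0)


def test_invalid_delays_rejected():
    with pytest.raises(ValueError):
        TwoDelayCubicModel(a1=1, a2=0, tau1=-0.1)
    with pytest.raises(ValueError):
        TwoDelayCubicModel(a1=math.inf, a2=0)


def test_three_delay_fixture_support():
    m = TwoDelayCubicModel(a1=-6, a2=4, b1=1, b2=-1.1, tau1=0.1, tau2=0.3,
                           cubic_tau1=0.1, cubic_tau2=5.0)
    assert set(m.delays()) == {0.1, 0.3, 5.0}
    assert not m.shared_delays
    with pytest.raises(ValueError):
        linearize(m, FixedPoint(0.0, "zero"))
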