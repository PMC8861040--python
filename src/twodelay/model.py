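"""Two-delay oscillator models: definitions, fixed points, linearization.

The model family implemented here is the scalar delay differential equation

    dx/dt = a1 x(t-tau1) + a2 x(t-tau2) - x(t)^2 [b2 x(t-tau2) + b1 x(t-tau1)]

which contains, as special cases,

* the linear two-delay model (b1 = b2 = 0), whose Taylor reduction for small
  delays is the damped harmonic oscillator;
* the two-delay Van der Pol form (b1 = -1, b2 = 1), whose reduction is the
  classical Van der Pol equation; and
* the generalized cubic model used to describe Parkinson's-disease tremor
  feedback, where a1, a2 encode negative/positive delayed feedback and the
  cubic coefficients satisfy b1*b2 < 0 with |b1| close to |b2|.

The cubic model has the zero fixed point always, and the pair
x* = ±sqrt((a1+a2)/(b1+b2)) whenever that ratio is positive.  Linearizing
about the non-zero fixed point yields

    dx/dt = delta x(t-tau1) - delta x(t-tau2) - 2(a1+a2) x(t)

with delta = (a1 b2 - a2 b1)/(b1 + b2).  (In the Van der Pol convention
b1 = -1 this denominator equals b2 - 1.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

__all__ = [
    "TwoDelayCubicModel",
    "History",
    "FixedPoint",
    "LinearizedModel",
    "eval_rhs",
    "fixed_points",
    "linearize",
    "numerical_jacobian",
]


@dataclass(frozen=True)
class TwoDelayCubicModel:
    """Parameters of the two-delay cubic model.

    Parameters
    ----------
    a1, a2 : float
        Linear feedback rates (1/time) on ``x(t-tau1)`` and ``x(t-tau2)``.
    b1, b2 : float
        Cubic coefficients (1/(amplitude^2 * time)) multiplying
        ``x(t)^2 * x(t-tau1)`` and ``x(t)^2 * x(t-tau2)``.
    tau1, tau2 : float
        Non-negative delays (time).
    cubic_tau1, cubic_tau2 : float or None
        Delays used inside the cubic term when they differ from the linear
        ones (``None`` means "same as tau1/tau2").  Two of the registered
        reference cases mix a short linear delay with a long cubic delay;
        this field lets those expressions be stored literally.
    """

    a1: float
    a2: float
    b1: float = 0.0
    b2: float = 0.0
    tau1: float = 0.0
    tau2: float = 0.0
    cubic_tau1: float | None = None
    cubic_tau2: float | None = None

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "b1", "b2", "tau1", "tau2"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        for name in ("tau1", "tau2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        for name in ("cubic_tau1", "cubic_tau2"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be a finite non-negative delay, got {v!r}")

    @property
    def is_linear(self) -> bool:
        return self.b1 == 0.0 and self.b2 == 0.0

    @property
    def ctau1(self) -> float:
        """Effective delay of the b1 cubic term."""
        return self.tau1 if self.cubic_tau1 is None else self.cubic_tau1

    @property
    def ctau2(self) -> float:
        """Effective delay of the b2 cubic term."""
        return self.tau2 if self.cubic_tau2 is None else self.cubic_tau2

    @property
    def shared_delays(self) -> bool:
        """True when the cubic term reads the state at the linear delays."""
        return self.ctau1 == self.tau1 and self.ctau2 == self.tau2

    def delays(self) -> tuple[float, ...]:
        """All distinct delays appearing in the right-hand side."""
        out: list[float] = []
        for tau in (self.tau1, self.tau2, self.ctau1, self.ctau2):
            if tau not in out:
                out.append(tau)
        return tuple(out)

    def cubic_imbalance(self) -> float:
        """Ratio |b1|/|b2| (reported, never enforced; inf if b2 == 0)."""
        if self.b2 == 0.0:
            return math.inf
        return abs(self.b1) / abs(self.b2)


@dataclass(frozen=True)
class History:
    """Pre-initial data x(t) for t <= 0; the DDE's initial condition.

    All registered reference cases use constant histories (x(t) = c for t <= 0);
    the closed-form solver tests use trigonometric ones.
    """

    func: Callable[[float], float]
    is_constant: bool = False

    def __call__(self, t: float) -> float:
        return float(self.func(t))

    @staticmethod
    def constant(value: float) -> "History":
        v = float(value)
        if not math.isfinite(v):
            raise ValueError("constant history must be finite")
        return History(func=lambda t: v, is_constant=True)

    @staticmethod
    def from_callable(func: Callable[[float], float]) -> "History":
        return History(func=func, is_constant=False)


# named histories accepted by the CLI and the config file
NAMED_HISTORIES: dict[str, Callable[[float], float]] = {
    "cos": math.cos,
    "sin": math.sin,
    "cos2pif": lambda t: math.cos(2.0 * math.pi * t),
}


@dataclass(frozen=True)
class FixedPoint:
    """A constant solution of the model; kind is 'zero', 'positive' or 'negative'."""

    value: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "positive", "negative"):
            raise ValueError(f"unknown fixed-point kind {self.kind!r}")


@dataclass(frozen=True)
class LinearizedModel:
    """dx/dt = c0 x(t) + c1 x(t-tau1) + c2 x(t-tau2), the linearization at a fixed point."""

    c0: float
    c1: float
    c2: float
    tau1: float
    tau2: float
    delta: float = 0.0
    point: FixedPoint | None = None

    def as_model(self) -> TwoDelayCubicModel:
        """The delayed part as a linear TwoDelayCubicModel (c0 handled separately).

        Only valid when c0 == 0; otherwise the instantaneous term has no
        representation in the two-delay family and a ValueError is raised.
        """
        if self.c0 != 0.0:
            raise ValueError("linearization has an instantaneous term; cannot drop c0")
        return TwoDelayCubicModel(a1=self.c1, a2=self.c2, tau1=self.tau1, tau2=self.tau2)


def eval_rhs(
    model: TwoDelayCubicModel,
    x: float,
    x1: float,
    x2: float,
    x1c: float | None = None,
    x2c: float | None = None,
) -> float:
    """Evaluate the right-hand side a1*x1 + a2*x2 - x^2*(b2*x2 + b1*x1).

    ``x1``/``x2`` are the delayed states at the linear delays; ``x1c``/``x2c``
    are the states at the cubic-term delays when those differ (default: same).
    """
    if x1c is None:
        x1c = x1
    if x2c is None:
        x2c = x2
    for v in (x, x1, x2, x1c, x2c):
        if not math.isfinite(v):
            raise ValueError(f"non-finite state passed to eval_rhs: {v!r}")
    return (
        model.a1 * x1
        + model.a2 * x2
        - x * x * (model.b2 * x2c + model.b1 * x1c)
    )


def fixed_points(model: TwoDelayCubicModel) -> list[FixedPoint]:
    """All constant solutions: zero always; ±sqrt((a1+a2)/(b1+b2)) when real.

    The positive and negative roots are both returned (the dynamics are
    odd-symmetric, so both are genuine equilibria) and tagged by kind.
    """
    pts = [FixedPoint(0.0, "zero")]
    bsum = model.b1 + model.b2
    asum = model.a1 + model.a2
    if bsum != 0.0:
        ratio = asum / bsum
        if ratio > 0.0:
            r = math.sqrt(ratio)
            pts.append(FixedPoint(r, "positive"))
            pts.append(FixedPoint(-r, "negative"))
    return pts


def linearize(model: TwoDelayCubicModel, point: FixedPoint) -> LinearizedModel:
    """Linearize the model about a fixed point.

    Zero point: (c0, c1, c2) = (0, a1, a2).  Non-zero point:
    c0 = -2(a1+a2), c1 = delta, c2 = -delta with
    delta = (a1 b2 - a2 b1)/(b1 + b2).

    Requires the cubic term to read the state at the linear delays (the
    two reference cases with a third delay are simulation-only fixtures).
    """
    if not model.shared_delays:
        raise ValueError(
            "linearize requires the cubic-term delays to equal the linear delays"
        )
    if point.kind == "zero":
        return LinearizedModel(
            c0=0.0, c1=model.a1, c2=model.a2,
            tau1=model.tau1, tau2=model.tau2, delta=0.0, point=point,
        )
    bsum = model.b1 + model.b2
    asum = model.a1 + model.a2
    if bsum == 0.0 or asum / bsum <= 0.0:
        raise ValueError("model has no non-zero fixed point to linearize about")
    expected = math.sqrt(asum / bsum)
    if not math.isclose(abs(point.value), expected, rel_tol=1e-9):
        raise ValueError(
            f"point {point.value!r} is not a fixed point of the model "
            f"(expected ±{expected!r})"
        )
    delta = (model.a1 * model.b2 - model.a2 * model.b1) / bsum
    return LinearizedModel(
        c0=-2.0 * asum, c1=delta, c2=-delta,
        tau1=model.tau1, tau2=model.tau2, delta=delta, point=point,
    )


def numerical_jacobian(
    model: TwoDelayCubicModel, x0: float, step: float = 1e-6
) -> tuple[float, float, float]:
    """Central finite differences of eval_rhs in (x, x1, x2) at (x0, x0, x0).

    Independent check on :func:`linearize`; with shared delays the partials
    at a fixed point are exactly (c0, c1, c2).
    """
    if step <= 0:
        raise ValueError("step must be > 0")

    def f(x: float, x1: float, x2: float) -> float:
        return eval_rhs(model, x, x1, x2)

    c0 = (f(x0 + step, x0, x0) - f(x0 - step, x0, x0)) / (2.0 * step)
    c1 = (f(x0, x0 + step, x0) - f(x0, x0 - step, x0)) / (2.0 * step)
    c2 = (f(x0, x0, x0 + step) - f(x0, x0, x0 - step)) / (2.0 * step)
    return (c0, c1, c2)
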