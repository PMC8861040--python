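"""Taylor reduction of the two-delay models to second-order ODEs.

Expanding the delayed states about zero delay to second order,

    x(t-tau) = x - tau x' + (tau^2/2) x'' + ...,

turns the linear two-delay model dx/dt = a1 x(t-tau1) + a2 x(t-tau2) into
the damped harmonic oscillator

    x'' + mu x' + beta x = 0,
    mu = -2 (1 + a1 tau1 + a2 tau2) / (a1 tau1^2 + a2 tau2^2),
    beta = 2 (a1 + a2) / (a1 tau1^2 + a2 tau2^2),

and the two-delay Van der Pol form (cubic coefficients b1 = -1, b2 = 1),
after collapsing x(t-tau2) - x(t-tau1) to (tau2-tau1) x' by the mean value
theorem, into the classical Van der Pol equation

    x'' + mu (x^2 - alpha) x' + beta x = 0,
    alpha = (1 + a1 tau1 + a2 tau2) / (tau2 - tau1),
    mu = 2 (tau2 - tau1) / (a1 tau1^2 + a2 tau2^2).

The series is truncated at second order exactly as in the derivation; no
remainder is estimated, and the reduction can disagree qualitatively with
the DDE outside the small-delay regime (the report surfaces both verdicts).

The RLC mapping encodes the quarter/three-quarter-period phase shifts of
capacitor and inductor currents as delays: for drive frequency f,
cos(2 pi f t) satisfies dI/dt = -2 pi f I(t - 1/(4f)) and sin(2 pi f t)
satisfies dI/dt = +2 pi f I(t - 3/(4f)), so tau1 = 1/(4f), tau2 = 3/(4f).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import BLOWUP_LIMIT, BlowUpError, Trajectory
from .model import TwoDelayCubicModel

__all__ = [
    "ReducedODECoeffs",
    "reduce_linear",
    "reduce_vdp",
    "rlc_delays",
    "simulate_ode",
    "rlc_identity_residual",
]


@dataclass(frozen=True)
class ReducedODECoeffs:
    """Coefficients of the reduced ODE x'' + mu (x^2 - alpha) x' + beta x = 0.

    ``alpha`` is ``None`` for the linear reduction (x'' + mu x' + beta x = 0).
    ``denom`` = a1 tau1^2 + a2 tau2^2 is kept as a diagnostic: its sign enters
    the reduced-ODE stability conditions and it must be non-zero for the
    reduction to exist.
    """

    mu: float
    beta: float
    alpha: float | None = None
    denom: float = 0.0

    def dominant_root(self) -> complex:
        """Root of lambda^2 + mu lambda + beta = 0 with the larger real part.

        For the nonlinear form this is the root of the linearization at the
        origin, where the effective damping is -mu*alpha.
        """
        mu_eff = self.mu if self.alpha is None else -self.mu * self.alpha
        disc = complex(mu_eff * mu_eff - 4.0 * self.beta)
        sq = np.sqrt(disc)
        r1 = (-mu_eff + sq) / 2.0
        r2 = (-mu_eff - sq) / 2.0
        return r1 if r1.real >= r2.real else r2


def _denom(model: TwoDelayCubicModel) -> float:
    return model.a1 * model.tau1 ** 2 + model.a2 * model.tau2 ** 2


def reduce_linear(model: TwoDelayCubicModel) -> ReducedODECoeffs:
    """Taylor-reduce the linear two-delay model to x'' + mu x' + beta x = 0."""
    if not model.is_linear:
        raise ValueError("reduce_linear applies to the linear model (b1 = b2 = 0)")
    denom = _denom(model)
    if denom == 0.0:
        raise ValueError("Taylor reduction degenerate: a1*tau1^2 + a2*tau2^2 = 0")
    one_plus = 1.0 + model.a1 * model.tau1 + model.a2 * model.tau2
    mu = -2.0 * one_plus / denom
    beta = 2.0 * (model.a1 + model.a2) / denom
    return ReducedODECoeffs(mu=mu, beta=beta, alpha=None, denom=denom)


def reduce_vdp(model: TwoDelayCubicModel) -> ReducedODECoeffs:
    """Taylor-reduce the two-delay Van der Pol form to x'' + mu(x^2-alpha)x' + beta x = 0.

    Requires the canonical cubic coefficients (b1, b2) = (-1, 1); the general
    cubic model has no reduced form here.
    """
    if (model.b1, model.b2) != (-1.0, 1.0):
        raise ValueError(
            "reduce_vdp requires the Van der Pol cubic (b1, b2) = (-1, 1); "
            f"got ({model.b1}, {model.b2})"
        )
    if not model.shared_delays:
        raise ValueError("reduce_vdp requires shared linear/cubic delays")
    if model.tau1 == model.tau2:
        raise ValueError("alpha undefined: tau1 = tau2")
    denom = _denom(model)
    if denom == 0.0:
        raise ValueError("Taylor reduction degenerate: a1*tau1^2 + a2*tau2^2 = 0")
    dtau = model.tau2 - model.tau1
    one_plus = 1.0 + model.a1 * model.tau1 + model.a2 * model.tau2
    return ReducedODECoeffs(
        mu=2.0 * dtau / denom,
        beta=2.0 * (model.a1 + model.a2) / denom,
        alpha=one_plus / dtau,
        denom=denom,
    )


def rlc_delays(f: float) -> tuple[float, float]:
    """Delays (1/(4f), 3/(4f)) encoding the RLC phase shifts at frequency f."""
    if f <= 0:
        raise ValueError("frequency must be > 0")
    return (1.0 / (4.0 * f), 3.0 / (4.0 * f))


def simulate_ode(
    coeffs: ReducedODECoeffs,
    x0: float,
    v0: float,
    t_end: float,
    h: float,
) -> Trajectory:
    """RK4-integrate the reduced second-order ODE as a first-order pair.

    Linear form (alpha is None): x'' + mu x' + beta x = 0.
    Nonlinear form: x'' + mu (x^2 - alpha) x' + beta x = 0.
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    mu, beta, alpha = coeffs.mu, coeffs.beta, coeffs.alpha

    if alpha is None:
        def acc(x: float, v: float) -> float:
            return -mu * v - beta * x
    else:
        def acc(x: float, v: float) -> float:
            return -mu * (x * x - alpha) * v - beta * x

    n = int(math.ceil(t_end / h - 1e-12))
    times = [0.0]
    xs = [float(x0)]
    vs = [float(v0)]
    t, x, v = 0.0, float(x0), float(v0)
    for _ in range(n):
        dt = min(h, t_end - t)
        k1x, k1v = v, acc(x, v)
        k2x, k2v = v + 0.5 * dt * k1v, acc(x + 0.5 * dt * k1x, v + 0.5 * dt * k1v)
        k3x, k3v = v + 0.5 * dt * k2v, acc(x + 0.5 * dt * k2x, v + 0.5 * dt * k2v)
        k4x, k4v = v + dt * k3v, acc(x + dt * k3x, v + dt * k3v)
        x = x + (dt / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
        v = v + (dt / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
        t = t + dt
        if not math.isfinite(x) or abs(x) > BLOWUP_LIMIT:
            raise BlowUpError(t)
        times.append(t)
        xs.append(x)
        vs.append(v)
    return Trajectory(
        times=np.asarray(times), values=np.asarray(xs), derivs=np.asarray(vs), h=h
    )


def rlc_identity_residual(f: float, t_grid=None) -> float:
    """Max residual of the delay identities satisfied by the AC current curves.

    For I = cos(2 pi f t):  dI/dt + 2 pi f I(t - 1/(4f)) = 0.
    For I = sin(2 pi f t):  dI/dt - 2 pi f I(t - 3/(4f)) = 0.
    Both are exact trigonometric identities at any frequency; the returned
    maximum over the grid is rounding noise.
    """
    if f <= 0:
        raise ValueError("frequency must be > 0")
    if t_grid is None:
        t_grid = np.arange(0.0, 2.0 / f + 1e-12, 0.01 / f)
    t = np.asarray(t_grid, dtype=float)
    w = 2.0 * math.pi * f
    tau1, tau2 = rlc_delays(f)
    res_cos = np.abs(-w * np.sin(w * t) + w * np.cos(w * (t - tau1)))
    res_sin = np.abs(w * np.cos(w * t) - w * np.sin(w * (t - tau2)))
    return float(max(res_cos.max(), res_sin.max()))
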