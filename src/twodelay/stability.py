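"""Characteristic equations and rightmost-root stability analysis.

Substituting x = e^(lambda t) into the linear(ized) two-delay model

    dx/dt = c0 x(t) + c1 x(t-tau1) + c2 x(t-tau2)

gives the transcendental characteristic equation

    lambda = c0 + c1 e^(-lambda tau1) + c2 e^(-lambda tau2).

Its roots come in conjugate pairs and accumulate to the left; the root with
maximal real part (the rightmost root) sets the asymptotic growth/decay rate
of the linearized dynamics.  The rightmost root is located by Newton
iteration from a grid of seeds over a search box, which is reliable here
because all models of interest have their dominant roots well inside a
moderate box.

Small-delay sign conditions complement the root computation: for the zero
fixed point of the linear model the origin is asymptotically stable for
tau1, tau2 << 1 iff a1 + a2 < 0, while for the non-zero fixed point of the
cubic feedback model the approximate real root is lambda = -2 (a1 + a2), so
stability requires a1 + a2 > 0.  The reduced-ODE conditions (sign of
a1 tau1^2 + a2 tau2^2 and of 1 + a1 tau1 + a2 tau2) are reported alongside.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

from .model import (
    FixedPoint,
    LinearizedModel,
    TwoDelayCubicModel,
    fixed_points,
    linearize,
)

__all__ = [
    "CharRoot",
    "StabilityVerdict",
    "char_residual",
    "rightmost_root",
    "small_delay_verdict",
    "approx_root_parkinson",
    "hopf_scan",
]

ROOT_RESIDUAL_TOL = 1e-9
MARGINAL_BAND = 1e-6


@dataclass(frozen=True)
class CharRoot:
    """A characteristic root lambda = mu_r + i*omega with its residual |g(lambda)|."""

    lam: complex
    residual: float

    @property
    def growth_rate(self) -> float:
        return self.lam.real

    @property
    def omega(self) -> float:
        return self.lam.imag


@dataclass(frozen=True)
class StabilityVerdict:
    """Per-condition stability report for a fixed point.

    ``small_delay_stable`` is the sign condition appropriate to the point
    (a1+a2 < 0 at zero, a1+a2 > 0 at the non-zero point);
    ``reduced_ode_conditions`` are the three sign conditions under which the
    Taylor-reduced oscillator is a stable spiral; ``verdict`` follows the
    rightmost root's real part with a ±1e-6 marginal band (exact Hopf points
    must classify as marginal, not by floating-point luck).
    """

    point: FixedPoint
    small_delay_stable: bool
    reduced_ode_conditions: dict[str, bool]
    rightmost: CharRoot
    verdict: str


def char_residual(lin: LinearizedModel, lam: complex) -> complex:
    """g(lambda) = lambda - c0 - c1 e^(-lambda tau1) - c2 e^(-lambda tau2)."""
    lam = complex(lam)
    return (
        lam
        - lin.c0
        - lin.c1 * cmath.exp(-lam * lin.tau1)
        - lin.c2 * cmath.exp(-lam * lin.tau2)
    )


def _char_deriv(lin: LinearizedModel, lam: complex) -> complex:
    return (
        1.0
        + lin.c1 * lin.tau1 * cmath.exp(-lam * lin.tau1)
        + lin.c2 * lin.tau2 * cmath.exp(-lam * lin.tau2)
    )


def _newton(lin: LinearizedModel, seed: complex, maxit: int = 60) -> complex | None:
    lam = complex(seed)
    for _ in range(maxit):
        # e^{-lam*tau} overflows for strongly negative Re(lam); such iterates
        # have wandered far left of any rightmost root and can be abandoned
        if -lam.real * max(lin.tau1, lin.tau2) > 500.0:
            return None
        g = char_residual(lin, lam)
        if abs(g) < 1e-13 * max(1.0, abs(lam)):
            return lam
        gp = _char_deriv(lin, lam)
        if gp == 0:
            return None
        step = g / gp
        lam = lam - step
        if not (math.isfinite(lam.real) and math.isfinite(lam.imag)):
            return None
        if abs(step) < 1e-14 * max(1.0, abs(lam)):
            return lam
    return lam if abs(char_residual(lin, lam)) < ROOT_RESIDUAL_TOL else None


def rightmost_root(
    lin: LinearizedModel,
    search_real: tuple[float, float] = (-20.0, 5.0),
    search_imag: tuple[float, float] = (0.0, 50.0),
    n_real: int = 12,
    n_imag: int = 26,
) -> CharRoot:
    """Rightmost characteristic root via grid-seeded Newton iteration.

    Conjugate pairs are reported with omega >= 0.  With both delays zero the
    equation is affine and the root c0 + c1 + c2 is returned exactly.
    """
    if lin.tau1 == 0.0 and lin.tau2 == 0.0:
        lam = complex(lin.c0 + lin.c1 + lin.c2)
        return CharRoot(lam=lam, residual=abs(char_residual(lin, lam)))

    roots: list[complex] = []
    re_seeds = np.linspace(search_real[0], search_real[1], n_real)
    im_seeds = np.linspace(search_imag[0], search_imag[1], n_imag)
    for re in re_seeds:
        for im in im_seeds:
            lam = _newton(lin, complex(re, im))
            if lam is None:
                continue
            if abs(char_residual(lin, lam)) > ROOT_RESIDUAL_TOL:
                continue
            lam = complex(lam.real, abs(lam.imag))
            if not any(abs(lam - r) < 1e-6 * max(1.0, abs(r)) for r in roots):
                roots.append(lam)
    if not roots:
        raise RuntimeError("no characteristic root located in the search box")
    best = max(roots, key=lambda r: r.real)
    return CharRoot(lam=best, residual=abs(char_residual(lin, best)))


def _classify(re_lam: float) -> str:
    if abs(re_lam) <= MARGINAL_BAND:
        return "marginal"
    return "stable" if re_lam < 0 else "unstable"


def small_delay_verdict(
    model: TwoDelayCubicModel, point: FixedPoint
) -> StabilityVerdict:
    """Evaluate the small-delay sign conditions and the rightmost root at a fixed point."""
    lin = linearize(model, point)
    asum = model.a1 + model.a2
    denom = model.a1 * model.tau1 ** 2 + model.a2 * model.tau2 ** 2
    one_plus = 1.0 + model.a1 * model.tau1 + model.a2 * model.tau2
    if point.kind == "zero":
        small = asum < 0.0
    else:
        small = asum > 0.0
    conditions = {
        "denom_negative": denom < 0.0,
        "one_plus_positive": one_plus > 0.0,
        "a_sum_negative": asum < 0.0,
    }
    rm = rightmost_root(lin)
    return StabilityVerdict(
        point=point,
        small_delay_stable=small,
        reduced_ode_conditions=conditions,
        rightmost=rm,
        verdict=_classify(rm.lam.real),
    )


def approx_root_parkinson(model: TwoDelayCubicModel) -> tuple[float, float]:
    """Small-delay approximate real root -2(a1+a2) at the non-zero fixed point.

    Valid for tau2 > tau1 (the delta terms of the characteristic equation
    nearly cancel for a real root when both delays are small).  Returns the
    approximation together with the residual of the full characteristic
    equation at that value as a quality diagnostic — this is an
    approximation, never a substitute for the true rightmost root.
    """
    if model.tau2 <= model.tau1:
        raise ValueError("approximation requires tau2 > tau1")
    bsum = model.b1 + model.b2
    if bsum == 0.0:
        raise ValueError("delta undefined: b1 + b2 = 0")
    asum = model.a1 + model.a2
    delta = (model.a1 * model.b2 - model.a2 * model.b1) / bsum
    lin = LinearizedModel(c0=-2.0 * asum, c1=delta, c2=-delta,
                          tau1=model.tau1, tau2=model.tau2, delta=delta)
    lam = -2.0 * asum
    residual = abs(char_residual(lin, complex(lam)))
    return lam, residual


def hopf_scan(
    lin: LinearizedModel, omega_max: float, n_grid: int = 4000
) -> list[CharRoot]:
    """Locate pure-imaginary characteristic roots i*omega with omega in (0, omega_max].

    Scans |g(i omega)| on a grid for local minima, refines each candidate by
    complex Newton, and keeps refined roots that converged onto the imaginary
    axis with residual <= 1e-9.  An empty list is a valid outcome (strictly
    stable or unstable spectra have no imaginary-axis roots).
    """
    if omega_max <= 0:
        raise ValueError("omega_max must be > 0")
    omegas = np.linspace(0.0, omega_max, n_grid + 1)[1:]
    mags = np.array([abs(char_residual(lin, complex(0.0, w))) for w in omegas])
    roots: list[complex] = []
    for k in range(len(omegas)):
        if 0 < k < len(omegas) - 1 and not (mags[k] <= mags[k - 1] and mags[k] <= mags[k + 1]):
            continue
        if k == 0 and mags[0] > mags[1]:
            continue
        if k == len(omegas) - 1 and mags[-1] > mags[-2]:
            continue
        scale = max(1.0, abs(lin.c1) + abs(lin.c2) + abs(lin.c0))
        if mags[k] > 0.5 * scale:
            continue
        lam = _newton(lin, complex(0.0, omegas[k]))
        if lam is None:
            continue
        if abs(lam.real) > 1e-8:
            continue
        lam = complex(0.0, abs(lam.imag))
        res = abs(char_residual(lin, lam))
        if res > ROOT_RESIDUAL_TOL:
            continue
        if lam.imag <= 1e-12 or lam.imag > omega_max * (1 + 1e-9):
            continue
        if not any(abs(lam.imag - r.imag) < 1e-6 * max(1.0, abs(r.imag)) for r in roots):
            roots.append(lam)
    roots.sort(key=lambda r: r.imag)
    return [CharRoot(lam=r, residual=abs(char_residual(lin, r))) for r in roots]
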