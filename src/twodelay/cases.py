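"""Registry of the ten reference cases and a trajectory classifier.

The cases cover the whole model family: damped two-delay linear dynamics
(cases 1-2), a linear system sitting exactly on a Hopf point (case 3), the
two-delay Van der Pol form with comparable and with widely separated delays
(cases 4-7), relaxation oscillation in the generalized cubic model (case 8),
and the Parkinson's-disease feedback regimes where symptoms decay to zero
(case 9) or, with net positive feedback, settle at a non-zero level
(case 10).

Sign convention for entering the case expressions: the model's cubic term
is -x(t)^2 [b2 x(t-tau2) + b1 x(t-tau1)], so a case term written as
+x^2 [p x(t-taub) + q x(t-taua)] maps to b2 = -p, b1 = -q.  Cases 9 and 10
use a cubic delay of 5 that does not occur in their linear parts; the
registry stores the expressions literally via the model's separate
cubic-term delays rather than "correcting" them.

As written, case 10 has (a1+a2)/(b1+b2) = -3 < 0 and hence no real non-zero
fixed point, so its literal dynamics cannot settle at one; its expected
label is therefore "unspecified" here (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import Trajectory, integrate
from .model import History, TwoDelayCubicModel

__all__ = [
    "CaseSpec",
    "TrajectoryLabel",
    "case_registry",
    "classify_trajectory",
    "run_case",
]


@dataclass(frozen=True)
class CaseSpec:
    name: str
    model: TwoDelayCubicModel
    history_value: float
    t_end: float
    expected: str  # a TrajectoryLabel.label value or "unspecified"

    @property
    def history(self) -> History:
        return History.constant(self.history_value)


@dataclass(frozen=True)
class TrajectoryLabel:
    """Qualitative classification of a trajectory's long-time behavior."""

    label: str  # decays_to_zero | converges_to_constant | sustained_oscillation | growing
    tail_mean: float
    tail_amplitude: float
    period: float | None = None
    relaxation_flag: bool = False


def _default_horizon(model: TwoDelayCubicModel) -> float:
    dmax = max(model.delays())
    # covers every registered case's transient
    return 40.0 if dmax < 1.0 else 30.0 * dmax


_PI = math.pi


def _registry() -> dict[str, CaseSpec]:
    specs = [
        # name, a1, tau1, a2, tau2, b1, b2, ct1, ct2, history, expected
        ("case1", -10.0, 0.2, 3.0, 0.3, 0.0, 0.0, None, None, 2.0, "decays_to_zero"),
        ("case2", -3.0, 0.1, -5.0, 0.3, 0.0, 0.0, None, None, 2.0, "decays_to_zero"),
        ("case3", -7.0, _PI / 20, 3.0, 3 * _PI / 20, 0.0, 0.0, None, None, 2.0,
         "sustained_oscillation"),
        ("case4", -0.9, _PI / 2, 0.2, 3 * _PI / 2, -1.0, 1.0, None, None, 0.4,
         "unspecified"),
        # -x^2[1.55 x(t-3pi/2) - x(t-pi)] -> b2 = 1.55, b1 = -1
        ("case5", -1.95, _PI, 2.5, 3 * _PI / 2, -1.0, 1.55, None, None, 1.1,
         "unspecified"),
        ("case6", -8.0, 0.1, 4.0, 5.0, -1.0, 1.0, None, None, 2.0, "unspecified"),
        ("case7", -14.0, 0.1, 2.0, 5.0, -1.0, 1.0, None, None, 2.0, "unspecified"),
        # +x^2[1.1 x(t-5) - x(t-0.1)] -> b2 = -1.1, b1 = 1
        ("case8", 3.0, 0.1, -4.0, 5.0, 1.0, -1.1, None, None, 2.0,
         "sustained_oscillation"),
        # linear delays 0.1, 0.3; cubic term keeps its own delays 0.1 and 5
        ("case9", -6.0, 0.1, 4.0, 0.3, 1.0, -1.1, 0.1, 5.0, 2.0, "decays_to_zero"),
        ("case10", 0.2, 0.1, 0.1, 0.3, 1.0, -1.1, 0.1, 5.0, 1.0, "unspecified"),
    ]
    out: dict[str, CaseSpec] = {}
    for name, a1, t1, a2, t2, b1, b2, ct1, ct2, hist, expected in specs:
        model = TwoDelayCubicModel(
            a1=a1, a2=a2, b1=b1, b2=b2, tau1=t1, tau2=t2,
            cubic_tau1=ct1, cubic_tau2=ct2,
        )
        out[name] = CaseSpec(
            name=name, model=model, history_value=hist,
            t_end=_default_horizon(model), expected=expected,
        )
    return out


_REGISTRY = _registry()


def case_registry() -> dict[str, CaseSpec]:
    """The ten registered reference cases, keyed case1..case10."""
    return dict(_REGISTRY)


def classify_trajectory(
    traj: Trajectory, tail_fraction: float = 0.5, tol: float | None = None
) -> TrajectoryLabel:
    """Label a trajectory from its tail statistics.

    The tail (last ``tail_fraction`` of the span) yields a mean and a
    half peak-to-peak amplitude.  Flat tails classify as decayed or
    constant-limit depending on the mean; oscillating tails are labelled
    sustained when the amplitude is steady across the last two half-windows
    (ratio within [0.9, 1.1]), growing above that band, and decaying below.
    The period comes from mean spacing of upward crossings of the tail mean,
    and the relaxation flag marks fast-slow waveforms whose derivative crest
    factor max|x'| / (2 pi * amplitude / period) exceeds 2.
    """
    if not 0.0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5]")
    span = traj.t_end - traj.t0
    if len(traj) < 16:
        raise ValueError("trajectory too short to classify")
    if tol is None:
        x0 = abs(traj.values[0])
        tol = 0.02 * (x0 if x0 > 0 else 1.0)

    t_tail = traj.t_end - tail_fraction * span
    mask = traj.times >= t_tail
    tt = traj.times[mask]
    xt = traj.values[mask]
    dt_ = traj.derivs[mask]
    tail_mean = float(np.mean(xt))
    tail_amp = float((np.max(xt) - np.min(xt)) / 2.0)

    # amplitude in the last two half-windows of the tail
    mid = tt[0] + (tt[-1] - tt[0]) / 2.0
    first, second = xt[tt < mid], xt[tt >= mid]
    amp1 = float((np.max(first) - np.min(first)) / 2.0) if len(first) else 0.0
    amp2 = float((np.max(second) - np.min(second)) / 2.0) if len(second) else 0.0

    if tail_amp < tol:
        if abs(tail_mean) < tol:
            return TrajectoryLabel("decays_to_zero", tail_mean, tail_amp)
        return TrajectoryLabel("converges_to_constant", tail_mean, tail_amp)

    # oscillating tail: period from upward crossings of the tail mean
    y = xt - tail_mean
    up = np.flatnonzero((y[:-1] < 0) & (y[1:] >= 0))
    period: float | None = None
    if len(up) >= 2:
        crossings = tt[up] + (tt[up + 1] - tt[up]) * (-y[up]) / (y[up + 1] - y[up])
        period = float(np.mean(np.diff(crossings)))

    ratio = amp2 / amp1 if amp1 > 0 else math.inf
    relax = False
    if period is not None and period > 0 and tail_amp > 0:
        crest = float(np.max(np.abs(dt_))) / (2.0 * math.pi * tail_amp / period)
        relax = crest > 2.0

    if ratio > 1.1:
        return TrajectoryLabel("growing", tail_mean, tail_amp, period, relax)
    if ratio < 0.9:
        # still decaying; the limit decides which quiescent label applies
        label = "decays_to_zero" if abs(tail_mean) < tol else "converges_to_constant"
        return TrajectoryLabel(label, tail_mean, tail_amp, period, relax)
    return TrajectoryLabel("sustained_oscillation", tail_mean, tail_amp, period, relax)


def run_case(
    name: str, h: float = 0.01, t_end: float | None = None
) -> tuple[Trajectory, TrajectoryLabel]:
    """Integrate a registered case and classify the result."""
    reg = case_registry()
    if name not in reg:
        raise KeyError(f"unknown case {name!r}; valid names: {sorted(reg)}")
    spec = reg[name]
    horizon = spec.t_end if t_end is None else t_end
    traj = integrate(spec.model, spec.history, horizon, h)
    tol = 0.02 * max(abs(spec.history_value), 1e-12)
    return traj, classify_trajectory(traj, tail_fraction=0.5, tol=tol)
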