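"""Run configuration: flat key=value config files and CLI flag merging.

The grammar is deliberately tiny: one ``key = value`` pair per line, ``#``
comments, blank lines ignored.  Keys are the model parameters (a1, a2, b1,
b2, tau1, tau2), the history (a constant, or one of the named signals
``cos``, ``sin``, ``cos2pif``), and solver settings (h, t_end).  Unknown
keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .model import History, NAMED_HISTORIES, TwoDelayCubicModel

__all__ = ["RunConfig", "parse_config", "parse_config_file", "config_to_text"]

_MODEL_KEYS = ("a1", "a2", "b1", "b2", "tau1", "tau2", "cubic_tau1", "cubic_tau2")
_SOLVER_KEYS = ("h", "t_end")
_DEFAULTS = {"b1": 0.0, "b2": 0.0, "tau1": 0.0, "tau2": 0.0,
             "h": 0.01, "t_end": 40.0, "history": "1.0"}
_REQUIRED = ("a1", "a2")


@dataclass(frozen=True)
class RunConfig:
    """Validated model + solver settings for one run."""

    a1: float
    a2: float
    b1: float
    b2: float
    tau1: float
    tau2: float
    cubic_tau1: float | None
    cubic_tau2: float | None
    history: str  # numeric literal or named signal
    h: float
    t_end: float

    def model(self) -> TwoDelayCubicModel:
        return TwoDelayCubicModel(
            a1=self.a1, a2=self.a2, b1=self.b1, b2=self.b2,
            tau1=self.tau1, tau2=self.tau2,
            cubic_tau1=self.cubic_tau1, cubic_tau2=self.cubic_tau2,
        )

    def history_func(self) -> History:
        if self.history in NAMED_HISTORIES:
            return History.from_callable(NAMED_HISTORIES[self.history])
        return History.constant(float(self.history))


def _parse_number(key: str, raw: str) -> float:
    try:
        v = float(raw)
    except ValueError as exc:
        raise ValueError(f"config key {key!r}: non-numeric value {raw!r}") from exc
    if not math.isfinite(v):
        raise ValueError(f"config key {key!r}: value must be finite, got {raw!r}")
    return v


def parse_config(entries: dict[str, str | float | None]) -> RunConfig:
    """Validate a flat mapping of settings into a RunConfig.

    Missing optional keys get defaults; missing required keys (a1, a2) and
    unknown keys raise ValueError naming the key.
    """
    entries = {k: v for k, v in entries.items() if v is not None}
    known = set(_MODEL_KEYS) | set(_SOLVER_KEYS) | {"history"}
    unknown = sorted(set(entries) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    missing = sorted(set(_REQUIRED) - set(entries))
    if missing:
        raise ValueError(f"missing required config keys: {', '.join(missing)}")

    vals: dict[str, float | str | None] = dict(_DEFAULTS)
    vals["cubic_tau1"] = None
    vals["cubic_tau2"] = None
    for k, v in entries.items():
        if k == "history":
            s = str(v).strip()
            if s not in NAMED_HISTORIES:
                _parse_number("history", s)  # must be numeric if not named
            vals["history"] = s
        else:
            vals[k] = _parse_number(k, str(v)) if isinstance(v, str) else float(v)

    if vals["h"] <= 0:
        raise ValueError("h must be positive")
    if vals["t_end"] <= 0:
        raise ValueError("t_end must be positive")
    cfg = RunConfig(**vals)  # type: ignore[arg-type]
    cfg.model()  # validates delays etc.
    return cfg


def parse_config_file(path) -> RunConfig:
    """Parse a key=value config file into a RunConfig."""
    entries: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value', got {line!r}")
            key, _, raw = line.partition("=")
            entries[key.strip()] = raw.strip()
    return parse_config(entries)


def config_to_text(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to the key=value grammar (round-trips)."""
    lines = []
    for k, v in asdict(cfg).items():
        if v is None:
            continue
        lines.append(f"{k} = {v!r}" if isinstance(v, float) else f"{k} = {v}")
    return "\n".join(lines) + "\n"
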