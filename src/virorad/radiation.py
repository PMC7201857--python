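"""Time-dependent radiation dose-rate schedules R(t).

Three clinically motivated delivery modes are supported:

* ``constant`` — temporary brachytherapy: a source emits a fixed dose
  rate until withdrawn, R(t) = R.
* ``decay`` — permanent brachytherapy: an implanted source whose output
  decays, R(t) = beta1 * exp(-alpha1 * (t - t0)).
* ``periodic`` — external-beam delivery, R(t) = beta2 + alpha2 *
  sin(omega * (t - t0)).
* ``off`` — no radiation (the virotherapy-only control arm).

Schedule clocks are measured from ``t0``, the time radiotherapy starts,
since no radiation exists before then.  Default amplitudes give R = 2
(constant), 2 e^{-0.01 (t-t0)} (decay) and 1 + sin 2(t-t0) (periodic),
with rates per hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RadiationSchedule", "evaluate", "MODES"]

MODES = ("constant", "decay", "periodic", "off")


@dataclass(frozen=True)
class RadiationSchedule:
    mode: str = "constant"
    R_const: float = 2.0
    beta1: float = 2.0
    alpha1: float = 0.01
    beta2: float = 1.0
    alpha2: float = 1.0
    omega: float = 2.0
    t0: float = 120.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown radiation mode {self.mode!r}; expected one of {MODES}")
        if self.mode == "constant" and self.R_const < 0:
            raise ValueError("constant dose rate must be nonnegative")
        if self.mode == "decay" and (self.beta1 < 0 or self.alpha1 < 0):
            raise ValueError("decay schedule requires beta1 >= 0 and alpha1 >= 0")
        if self.mode == "periodic" and self.beta2 < abs(self.alpha2):
            raise ValueError(
                "periodic schedule requires beta2 >= |alpha2| so R(t) stays nonnegative"
            )

    def evaluate(self, t: float) -> float:
        """Dose rate at time ``t`` (hours, absolute clock; t >= t0)."""
        if t < self.t0:
            raise ValueError(f"schedule starts at t0={self.t0} h; got t={t} h")
        s = t - self.t0
        if self.mode == "constant":
            return self.R_const
        if self.mode == "decay":
            return self.beta1 * float(np.exp(-self.alpha1 * s))
        if self.mode == "periodic":
            return self.beta2 + self.alpha2 * float(np.sin(self.omega * s))
        return 0.0


def evaluate(schedule: RadiationSchedule, t: float) -> float:
    """Functional form of :meth:`RadiationSchedule.evaluate`."""
    return schedule.evaluate(t)
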