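"""Antigen exposure forcing and the transit-compartment delay chain.

Antigen exposure after immunization is represented by an empirical pulse
(``Antigen0``) feeding a chain of six identical first-order transit stages.
The chain converts the exposure curve into a gamma-distributed delayed signal
(terminal state ``Antigen``) that drives ASC generation; the mean delay is
``n_transit / ktr`` (18 days by default, matching the observed lag between
peak exposure and peak ASC counts).

The pulse is a Bateman (difference-of-exponentials) form

    A0(t) = amplitude * (exp(-decay*(t-onset)) - exp(-rise*(t-onset)))

for t >= onset, zero before.  The absolute amplitude is arbitrary — only the
product amplitude × ASC generation rate × precursor pool is observable — so
it is a configuration value (default 10 signal units).  The pulse is
integrated in differential form inside the ODE system purely for numerical
convenience; :func:`forcing` is the closed form it must reproduce.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["AntigenSchedule", "mtt_to_ktr", "forcing", "forcing_derivative"]


def mtt_to_ktr(mtt: float, n_transit: int = 6) -> float:
    """Transit rate (1/day) giving a mean chain delay of ``mtt`` days.

    A chain of ``n_transit`` identical first-order stages at rate ``ktr``
    has mean residence time ``n_transit/ktr``; hence ``ktr = n_transit/mtt``.
    """
    if mtt <= 0:
        raise ValueError(f"mean transit time must be positive, got {mtt}")
    if n_transit < 1:
        raise ValueError(f"need at least one transit stage, got {n_transit}")
    return n_transit / mtt


@dataclass(frozen=True)
class AntigenSchedule:
    """Parametric antigen pulse plus transit-chain configuration.

    amplitude : signal units — pulse scale (arbitrary units, default 10)
    rise, decay : 1/day — Bateman rise/decay rates; rise > decay > 0
    onset : days — time of exposure
    n_transit : number of transit stages (6)
    mtt : days — mean transit time of the chain (18)
    """

    amplitude: float = 10.0
    rise: float = 1.5
    decay: float = 0.35
    onset: float = 0.0
    n_transit: int = 6
    mtt: float = 18.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not (self.rise > self.decay > 0):
            raise ValueError(
                f"need rise > decay > 0 for a well-formed pulse, got "
                f"rise={self.rise}, decay={self.decay}"
            )
        if self.mtt <= 0 or self.n_transit < 1:
            raise ValueError("mtt must be positive and n_transit >= 1")

    @property
    def ktr(self) -> float:
        return mtt_to_ktr(self.mtt, self.n_transit)

    @property
    def peak_time(self) -> float:
        """Time of the pulse maximum: onset + ln(rise/decay)/(rise - decay)."""
        return self.onset + math.log(self.rise / self.decay) / (
            self.rise - self.decay
        )

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def zero(cls) -> "AntigenSchedule":
        """No antigen exposure (homeostasis-only simulation)."""
        return cls(amplitude=0.0)


def forcing(t, schedule: AntigenSchedule):
    """Closed-form exposure curve ``Antigen0(t)`` (vectorized over ``t``)."""
    t = np.asarray(t, dtype=float)
    tau = t - schedule.onset
    out = schedule.amplitude * (
        np.exp(-schedule.decay * tau) - np.exp(-schedule.rise * tau)
    )
    out = np.where(tau >= 0, out, 0.0)
    return out if out.ndim else float(out)


def forcing_derivative(t, schedule: AntigenSchedule):
    """Time derivative of :func:`forcing`, used as the ODE representation."""
    t = np.asarray(t, dtype=float)
    tau = t - schedule.onset
    out = schedule.amplitude * (
        schedule.rise * np.exp(-schedule.rise * tau)
        - schedule.decay * np.exp(-schedule.decay * tau)
    )
    out = np.where(tau >= 0, out, 0.0)
    return out if out.ndim else float(out)
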