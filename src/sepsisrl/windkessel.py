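"""Two-element Windkessel arterial pressure model.

The arterial circulation is lumped into a resistance ``R`` (systemic
vascular resistance, mmHg·s/mL) and a capacitance ``C`` (arterial
elastance, mL/mmHg).  Cardiac ejection is modelled as an impulse of volume
``SV`` (stroke volume, mL) at the start of each cardiac cycle of length
``T`` (filling time, s); between ejections pressure decays exponentially
with time constant ``R·C``:

    dP/dt = -P/(R·C) + Q(t)/C,      Q(t) = SV·δ(t)

Integrating over one cycle on the periodic steady state gives closed forms
for the systolic, diastolic and mean arterial pressures:

    P_sys  = (SV/C) / (1 - e^{-T/RC})
    P_dias = (SV/C) · e^{-T/RC} / (1 - e^{-T/RC})
    P_MAP  = SV·R/T = SV·F·R/60

Heart rate ``F`` (beats/min) and ``T`` satisfy F·T = 60 and both are
carried as latent states.  This map from {R, C, SV, F, T} to
{P_sys, P_dias, P_MAP, F} is the fixed, parameter-free decoder of the
physiology-driven autoencoder; only combinations RC, SV/C, SV·R (and hence
cardiac output CO = SV·F) are identifiable from the four observables, and
one scale degree of freedom on {R, C, SV} remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CardioState",
    "VitalsPrediction",
    "IdentifiableCombos",
    "BASELINE",
    "decode",
    "decode_arrays",
    "simulate_ode",
    "steady_cycle",
    "invert_observables",
    "cardiac_output",
]

#: Fixed baseline cardiovascular state used for deviation parameterization:
#: textbook resting-adult values (R mmHg·s/mL, C mL/mmHg, SV mL, F bpm).
BASELINE = {"R": 1.0, "C": 2.0, "SV": 70.0, "F": 75.0}


@dataclass(frozen=True)
class CardioState:
    """Latent cardiovascular parameters. F and T are redundant (F·T = 60)."""

    R: float
    C: float
    SV: float
    F: float
    T: float

    def __post_init__(self):
        for name in ("R", "C", "SV", "F", "T"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"CardioState.{name} must be positive and finite")
        if abs(self.F * self.T - 60.0) > 1e-6 * 60.0:
            raise ValueError(
                f"inconsistent heart rate and filling time: F*T = {self.F * self.T}"
            )

    @classmethod
    def from_rate(cls, R: float, C: float, SV: float, F: float) -> "CardioState":
        return cls(R=R, C=C, SV=SV, F=F, T=60.0 / F)

    @classmethod
    def from_period(cls, R: float, C: float, SV: float, T: float) -> "CardioState":
        return cls(R=R, C=C, SV=SV, F=60.0 / T, T=T)


@dataclass(frozen=True)
class VitalsPrediction:
    """Observable output of the decoder: pressures in mmHg, F in bpm."""

    Psys: float
    Pdias: float
    Pmap: float
    F: float


@dataclass(frozen=True)
class IdentifiableCombos:
    """The maximal set of state combinations recoverable from the vitals."""

    RC: float          # decay time constant, s
    SV_over_C: float   # pulse pressure, mmHg
    SV_times_R: float  # mmHg·s
    CO: float | None = None  # cardiac output mL/min, known only with SV


def decode(state: CardioState) -> VitalsPrediction:
    """Closed-form periodic steady-state pressures for a cardiovascular state."""
    x = state.T / (state.R * state.C)
    pulse = state.SV / state.C
    # limit form for large T/RC: e^-x underflows to 0, Psys -> SV/C, Pdias -> 0
    emx = np.exp(-x) if x < 700 else 0.0
    denom = 1.0 - emx
    psys = pulse / denom
    pdias = pulse * emx / denom
    pmap = state.SV * state.R / state.T
    return VitalsPrediction(Psys=psys, Pdias=pdias, Pmap=pmap, F=state.F)


def decode_arrays(R, C, SV, T):
    """Vectorized decoder on arrays; returns (Psys, Pdias, Pmap, F)."""
    R, C, SV, T = (np.asarray(a, dtype=float) for a in (R, C, SV, T))
    if np.any(R <= 0) or np.any(C <= 0) or np.any(SV <= 0) or np.any(T <= 0):
        raise ValueError("all Windkessel parameters must be positive")
    x = T / (R * C)
    emx = np.where(x < 700, np.exp(-np.minimum(x, 700)), 0.0)
    denom = 1.0 - emx
    pulse = SV / C
    return pulse / denom, pulse * emx / denom, SV * R / T, 60.0 / T


def simulate_ode(
    state: CardioState, n_cycles: int = 50, dt: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the pressure ODE with impulse ejection over ``n_cycles``.

    Within each cycle the solution is the exact exponential decay
    P(t) = P0·e^{-t/RC}; the ejection impulse adds SV/C to the pressure at
    the cycle start.  Using the per-cycle analytic solution avoids
    discretizing the delta function.  Returns (t, P) sampled every ``dt``.
    This is the numerical oracle for :func:`decode`.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if dt >= state.T:
        raise ValueError("dt must resolve the cardiac cycle (dt < T)")
    rc = state.R * state.C
    jump = state.SV / state.C
    n_per = int(np.ceil(state.T / dt))
    tau = np.arange(n_per) * dt  # within-cycle sample times
    pressures = []
    p0 = 0.0
    for _ in range(n_cycles):
        p0 += jump
        pressures.append(p0 * np.exp(-tau / rc))
        p0 *= np.exp(-state.T / rc)
    p = np.concatenate(pressures)
    t = np.arange(p.size) * dt
    return t, p


def steady_cycle(state: CardioState, n_samples: int = 4096) -> np.ndarray:
    """One periodic steady-state cycle of P(t), sampled uniformly on [0, T)."""
    v = decode(state)
    tau = np.linspace(0.0, state.T, n_samples, endpoint=False)
    return v.Psys * np.exp(-tau / (state.R * state.C))


def invert_observables(v: VitalsPrediction) -> IdentifiableCombos:
    """Recover the identifiable state combinations from observed vitals.

    A scale degree of freedom remains: (SV, C) -> (k·SV, k·C), R -> R/k
    leaves all four observables unchanged, so only RC, SV/C and SV·R are
    returned.
    """
    if not (v.Psys > v.Pdias > 0.0):
        raise ValueError("require Psys > Pdias > 0")
    if v.F <= 0:
        raise ValueError("require F > 0")
    T = 60.0 / v.F
    rc = -T / np.log(v.Pdias / v.Psys)
    return IdentifiableCombos(
        RC=rc,
        SV_over_C=v.Psys - v.Pdias,
        SV_times_R=v.Pmap * T,
    )


def cardiac_output(state: CardioState) -> float:
    """Cardiac output CO = SV·F in mL/min."""
    return state.SV * state.F
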