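"""After-spike update rules: Monod interpolant, positivity, and firing block.

Between spikes the A-GLIF state evolves by the closed form; everything the
model "learns" about a neuron's firing pattern lives in the rules that
re-initialize the state after each spike:

* the membrane potential resets to ``V_r``;
* the depolarizing current resets to the constant ``I_dep0``;
* the adaptation current resets to a value drawn from a Monod-type
  saturating function of the time since stimulation onset and the
  stimulation current::

      I_adap0(chi, I) = c + a e^{b I} chi / (d + chi),

  with ``chi = t_spk^+ - t_start`` in ms and ``I`` in pA; the returned value
  is the nondimensional adaptation current.  ``a > 0`` gives lengthening
  inter-spike intervals (spike-frequency adaptation), ``a < 0`` shortening
  ones; ``b`` sets how the effect scales with current; ``c`` is the value at
  stimulation onset and ``c + a e^{b I}`` the late-time plateau.

Firing block — a neuron that stops firing long before the stimulus ends and
never recovers — is handled by declaring the Monod function undefined after a
cutoff time that depends linearly on the stimulation current.  The lines are
fitted from the spike raster: a current is classified as blocking when the
train ends more than two final inter-spike intervals before the stimulus
does, blocking currents are grouped into intervals, and the line through the
interval's anchor points (last spike time plus half the final ISI) gives the
cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import DimensionalParameters, NondimensionalParameters

__all__ = [
    "MonodCoefficients",
    "MonodPropertyReport",
    "BlockLine",
    "BlockRule",
    "InitialConditions",
    "SpikeRaster",
    "monod_value",
    "monod_properties",
    "threshold_H",
    "adjust_monod_out_of_range",
    "first_spike_conditions",
    "after_spike_conditions",
    "detect_firing_block",
    "build_block_rule",
    "block_cutoff",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MonodCoefficients:
    """Coefficients (a, b, c, d) of the after-spike adaptation update."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.a != 0.0 and not self.d > 0.0:
            raise ValueError("d must be > 0 whenever a != 0")

    def plateau(self, I_stim: float) -> float:
        """Late-time limit c + a e^{b I} of the update value."""
        return self.c + self.a * math.exp(self.b * I_stim)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d}


@dataclass(frozen=True)
class MonodPropertyReport:
    monotone_in_chi: str  # "increasing" | "decreasing" | "constant"
    monotone_in_I: str
    positivity_verdict: str  # "global" | "range_restricted" | "fails"


@dataclass(frozen=True)
class BlockLine:
    """One cutoff line t = A_coef * I + B_coef with a one-sided validity region."""

    A_coef: float
    B_coef: float
    side: str  # "le" (valid for I <= threshold) | "ge" (valid for I >= threshold)
    threshold: float  # validity threshold current (pA)
    P1: tuple[float, float]
    P2: tuple[float, float]

    def valid_for(self, I_stim: float) -> bool:
        return I_stim <= self.threshold if self.side == "le" else I_stim >= self.threshold

    def cutoff(self, I_stim: float) -> float:
        return self.A_coef * I_stim + self.B_coef

    def to_dict(self) -> dict:
        return {
            "A": self.A_coef, "B": self.B_coef, "side": self.side,
            "threshold": self.threshold, "P1": list(self.P1), "P2": list(self.P2),
        }


@dataclass(frozen=True)
class BlockRule:
    lines: tuple[BlockLine, ...]
    block_intervals: tuple[tuple[float, float], ...] = ()
    I_fire: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "lines": [ln.to_dict() for ln in self.lines],
            "block_intervals": [list(b) for b in self.block_intervals],
            "I_fire": list(self.I_fire),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockRule":
        lines = tuple(
            BlockLine(
                A_coef=ln["A"], B_coef=ln["B"], side=ln["side"],
                threshold=ln["threshold"], P1=tuple(ln["P1"]), P2=tuple(ln["P2"]),
            )
            for ln in d.get("lines", [])
        )
        return cls(
            lines=lines,
            block_intervals=tuple(tuple(b) for b in d.get("block_intervals", [])),
            I_fire=tuple(d.get("I_fire", [])),
        )


@dataclass(frozen=True)
class InitialConditions:
    """Nondimensional Cauchy data for one inter-spike integration leg."""

    V0: float
    I_adap0: float
    I_dep0: float
    t0: float  # nondimensional start time
    provenance: str  # "first_spike" | "after_spike" | "discontinuity"
    H_exceeded: bool = False


@dataclass
class SpikeRaster:
    """Spike times (ms) per stimulation current (pA), for one cell."""

    trains: dict[float, np.ndarray] = field(default_factory=dict)
    cell_id: str = "cell"
    T: float = 400.0
    t_start: float = 0.0

    def currents(self) -> list[float]:
        return sorted(self.trains)

    def spikes(self, I_stim: float) -> np.ndarray:
        return self.trains[I_stim]


def monod_value(m: MonodCoefficients, chi: float, I_stim: float) -> float:
    """Evaluate the Monod update c + a e^{b I} chi / (d + chi)."""
    if chi < 0:
        raise ValueError("chi must be >= 0")
    if m.d + chi == 0:
        raise ZeroDivisionError("Monod function undefined at d + chi = 0")
    return m.c + m.a * math.exp(m.b * I_stim) * chi / (m.d + chi)


def monod_properties(m: MonodCoefficients) -> MonodPropertyReport:
    """Monotonicity and positivity classification of the update function.

    Positivity is ``global`` when the sufficient conditions hold for every
    positive current and elapsed time (either ``a > 0, c >= 0`` or
    ``a < 0, b < 0, c >= -a``); ``range_restricted`` when only the necessary
    conditions hold (``a > 0`` with a positive plateau, or ``a < 0`` with
    ``c > 0``), so positivity is guaranteed only on the fitted current range;
    ``fails`` otherwise.
    """
    if m.a == 0.0:
        pos = "global" if m.c >= 0 else "fails"
        return MonodPropertyReport("constant", "constant", pos)
    mono_chi = "increasing" if m.a > 0 else "decreasing"
    ab = m.a * m.b
    mono_I = "increasing" if ab > 0 else ("decreasing" if ab < 0 else "constant")
    if (m.a > 0 and m.c >= 0) or (m.a < 0 and m.b < 0 and m.c >= -m.a):
        pos = "global"
    elif (m.a > 0 and m.b > 0) or (m.a < 0 and m.b < 0 and m.c > 0):
        # necessary conditions only: a>0 with an eventually positive plateau,
        # or a<0, b<0 with positive intercept; positivity then holds on a
        # restricted current/time range, not for every chi and current
        pos = "range_restricted"
    elif m.a > 0 and m.b <= 0 and m.c + m.a > 0:
        pos = "range_restricted"
    else:
        # includes a<0 with b>0, whose plateau diverges to -infinity
        pos = "fails"
    return MonodPropertyReport(mono_chi, mono_I, pos)


def threshold_H(n: NondimensionalParameters, I_dep0: float, V0: float) -> float:
    """Upper bound H on the after-spike adaptation value.

    ``H = alpha/beta + I_dep0 + (delta/beta)(1 + V0)``; keeping
    ``I_adap0 < H`` guarantees the membrane potential rises immediately after
    the reset.  All quantities are nondimensional.
    """
    if n.beta == 0:
        raise ZeroDivisionError("beta must be nonzero")
    return n.alpha / n.beta + I_dep0 + (n.delta / n.beta) * (1.0 + V0)


def adjust_monod_out_of_range(
    m: MonodCoefficients,
    n: NondimensionalParameters,
    I_stim: float,
    I_dep0: float = 0.0,
    V0: float = -1.0,
    chi_first: float | None = None,
    eta_grid: int = 101,
) -> MonodCoefficients:
    """Vertical translation of the Monod function restoring positivity.

    Intended for currents outside the fitted range, where the interpolated
    update value may go negative (the main fitted case here is ``a > 0``).
    The intercept is replaced by::

        c* = alpha/beta + eta I_dep0 + (delta/beta)(1 + V0) - a e^{b I}

    choosing ``eta`` on a uniform grid in [0, 1] to minimize ``|c* - c|``
    subject to the positivity of the translated function.  If no grid value
    qualifies, the fallback subtracts the (negative) value at the first spike
    time: ``c* = c - L`` with ``L = I_adap0(chi_first, I)``, which zeroes the
    update there.  Returns the original coefficients when no adjustment is
    needed.
    """
    chi_probe = chi_first if chi_first is not None else 1e-6
    if monod_value(m, chi_probe, I_stim) >= 0 and min(m.c, m.plateau(I_stim)) >= 0:
        return m
    aebi = m.a * math.exp(m.b * I_stim)
    base = n.alpha / n.beta + (n.delta / n.beta) * (1.0 + V0) - aebi
    best = None
    for eta in np.linspace(0.0, 1.0, eta_grid):
        c_star = base + eta * I_dep0
        # positivity of the translated function for chi > 0
        if min(c_star, c_star + aebi) >= 0:
            dist = abs(c_star - m.c)
            if best is None or dist < best[0]:
                best = (dist, c_star)
    if best is not None:
        return MonodCoefficients(a=m.a, b=m.b, c=best[1], d=m.d)
    L = monod_value(m, chi_probe, I_stim)
    if L < 0:
        return MonodCoefficients(a=m.a, b=m.b, c=m.c - L, d=m.d)
    return m


def first_spike_conditions(
    p: DimensionalParameters, n: NondimensionalParameters, I_stim: float, t0: float = 0.0
) -> InitialConditions:
    """Cauchy data at stimulation onset from rest.

    The depolarizing current receives a kick proportional to the
    suprathreshold current excess: ``I_dep = I_dep_start (I - I_th)`` (pA)
    when ``I > I_th``, zero otherwise; it is converted to nondimensional
    units with the standard current scaling.
    """
    excess = I_stim - p.I_th
    I_dep_pA = p.I_dep_start * excess if excess > 0 else 0.0
    cur = -p.k_2 / (p.E_L * p.k_adap)
    return InitialConditions(
        V0=-1.0, I_adap0=0.0, I_dep0=I_dep_pA * cur, t0=t0, provenance="first_spike"
    )


def after_spike_conditions(
    p: DimensionalParameters,
    n: NondimensionalParameters,
    m: MonodCoefficients,
    t_spk_plus_ms: float,
    t_start_ms: float,
    I_stim: float,
) -> InitialConditions:
    """Cauchy data after a spike (applied at the end of the refractory gap).

    ``I_adap0`` comes from the Monod update at ``chi = t_spk^+ - t_start``
    (ms) and is clipped at zero: positivity of the adaptation current is
    prioritized over the voltage-rise bound H, which is only advisory (the
    ``H_exceeded`` flag) since outside the fitted current range enforcing it
    would be overly restrictive.
    """
    chi = t_spk_plus_ms - t_start_ms
    cur = -p.k_2 / (p.E_L * p.k_adap)
    I_dep0 = p.I_dep0 * cur
    raw = monod_value(m, max(chi, 0.0), I_stim)
    I_adap0 = max(0.0, raw)
    H = threshold_H(n, I_dep0, n.Vr_tilde)
    return InitialConditions(
        V0=n.Vr_tilde,
        I_adap0=I_adap0,
        I_dep0=I_dep0,
        t0=t_spk_plus_ms / p.tau,
        provenance="after_spike",
        H_exceeded=bool(I_adap0 >= H),
    )


def detect_firing_block(spikes, T: float) -> tuple[bool, bool]:
    """Classify one spike train: (blocked, never_fired).

    A train is blocked when the last spike plus twice the final inter-spike
    interval still falls short of the stimulation end ``T`` — the neuron went
    silent early and never recovered.  Trains with fewer than two spikes
    cannot define a final ISI and are reported as not blocked; an empty train
    additionally sets ``never_fired``.
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size == 0:
        return False, True
    if spikes.size == 1:
        return False, False
    isi_last = spikes[-1] - spikes[-2]
    return bool(spikes[-1] + 2.0 * isi_last < T), False


def _anchor(spikes: np.ndarray) -> float:
    """Anchor time t_last + ISI_last/2 of a train with >= 2 spikes."""
    return float(spikes[-1] + 0.5 * (spikes[-1] - spikes[-2]))


def build_block_rule(raster: SpikeRaster, T: float | None = None) -> BlockRule:
    """Derive the firing-block cutoff lines from a spike raster.

    Blocking currents are grouped into maximal runs over the tested current
    grid; for each run, ``I_fire`` is the nearest tested current outside the
    run at which the neuron fires without blocking.  The cutoff line passes
    through the anchor points (current, last spike + half final ISI) at the
    interval endpoints; for a run of a single blocking current the interval
    is extended to ``I_fire`` and the anchor at ``I_fire`` is used as the
    second point.  The validity threshold is the midpoint between ``I_fire``
    and the actual blocking current adjacent to it, which reproduces the
    reference worked examples exactly.
    """
    if T is None:
        T = raster.T
    currents = raster.currents()
    info: dict[float, tuple[bool, bool]] = {}
    for I in currents:
        spikes = raster.spikes(I)
        if 0 < len(spikes) < 2:
            logger.warning(
                "current %.0f pA has a single spike; excluded from block detection", I
            )
        info[I] = detect_firing_block(spikes, T)

    blocking = [I for I in currents if info[I][0]]
    firing_ok = [I for I in currents if not info[I][0] and not info[I][1] and len(raster.spikes(I)) >= 2]
    if not blocking:
        return BlockRule(lines=())
    if not firing_ok:
        raise ValueError("no non-blocking firing current available to serve as I_fire")

    # group blocking currents into maximal runs of consecutive tested currents
    runs: list[list[float]] = [[blocking[0]]]
    for I in blocking[1:]:
        idx_prev = currents.index(runs[-1][-1])
        if currents.index(I) == idx_prev + 1:
            runs[-1].append(I)
        else:
            runs.append([I])

    lines: list[BlockLine] = []
    intervals: list[tuple[float, float]] = []
    fires: list[float] = []
    for run in runs:
        above = [I for I in firing_ok if I > run[-1]]
        below = [I for I in firing_ok if I < run[0]]
        cand = []
        if above:
            cand.append(above[0])
        if below:
            cand.append(below[-1])
        if not cand:
            raise ValueError("no non-blocking firing current adjacent to a block interval")
        I_fire = min(cand, key=lambda I: min(abs(I - run[0]), abs(I - run[-1])))

        if len(run) >= 2:
            lo, hi = run[0], run[-1]
        else:  # degenerate single-block extension
            lo, hi = (run[0], I_fire) if I_fire > run[0] else (I_fire, run[0])
        P1 = (lo, _anchor(raster.spikes(lo)))
        P2 = (hi, _anchor(raster.spikes(hi)))
        A = (P2[1] - P1[1]) / (P2[0] - P1[0])
        B = P1[1] - A * P1[0]
        # validity: midpoint between I_fire and the blocking current nearest it
        adjacent_block = min(run, key=lambda I: abs(I - I_fire))
        thr = 0.5 * (I_fire + adjacent_block)
        side = "le" if I_fire >= hi else "ge"
        lines.append(BlockLine(A_coef=A, B_coef=B, side=side, threshold=thr, P1=P1, P2=P2))
        intervals.append((lo, hi))
        fires.append(I_fire)
    return BlockRule(lines=tuple(lines), block_intervals=tuple(intervals), I_fire=tuple(fires))


def block_cutoff(rule: BlockRule | None, I_stim: float) -> float | None:
    """Time (ms) after which the Monod update is undefined, if any.

    Returns the cutoff from the first line whose validity region contains
    ``I_stim`` (the smallest cutoff if several apply), or ``None`` when the
    neuron keeps firing at this current.
    """
    if rule is None:
        return None
    cuts = [ln.cutoff(I_stim) for ln in rule.lines if ln.valid_for(I_stim)]
    return min(cuts) if cuts else None
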