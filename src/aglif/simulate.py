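"""Event-driven forward simulation on the closed-form trajectories.

The simulator never integrates the ODEs numerically: within each inter-spike
leg the state is evaluated exactly from the general integral, the first
upward threshold crossing is bracketed on a coarse time grid (default 0.05 ms)
and refined by bisection to 1e-9 ms.  A spike is the threshold-crossing
instant (the model has no spike shape); the fixed refractory gap ``dt_ref``
separates the crossing from the after-spike re-initialization.

Piecewise-constant protocols apply extra rules at each current discontinuity:

* a downward step that stays above the rheobase keeps V and I_adap continuous
  and re-seeds the depolarizing current so that the membrane keeps rising
  (the Theta* correction estimated from the two most recent voltage samples);
* an upward step carries the full state and dilates the Monod clock origin
  ``t_start`` by the relative suprathreshold excess of the previous segment,
  which reproduces the reduced spike counts seen after a step;
* a step to or below the rheobase (or to negative current) lets the state
  relax toward the (possibly clamped) equilibrium; stimulation onset rules
  apply afresh at the next suprathreshold segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import DimensionalParameters, NondimensionalParameters, nondimensionalize
from .solution import clamped_equilibrium, trajectory
from .update_rules import (
    BlockRule,
    InitialConditions,
    MonodCoefficients,
    after_spike_conditions,
    block_cutoff,
    first_spike_conditions,
)

__all__ = [
    "StimulusProtocol",
    "SpikeTrain",
    "TraceRecord",
    "CellModel",
    "solve_to_threshold",
    "simulate_constant",
    "simulate_piecewise",
    "theta_star",
    "updated_t_start",
]

#: coarse scan step (ms) for threshold bracketing
SCAN_STEP_MS = 0.05
#: bisection tolerance (ms)
BISECT_TOL_MS = 1e-9
#: points evaluated per vectorized scan chunk
_CHUNK = 4096


@dataclass(frozen=True)
class StimulusProtocol:
    """Contiguous, ordered piecewise-constant current segments (ms, pA)."""

    segments: tuple[tuple[float, float, float], ...]  # (t_begin, t_end, I)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        prev_end = None
        for t0, t1, _ in self.segments:
            if t1 <= t0:
                raise ValueError(f"segment ({t0}, {t1}) is empty or reversed")
            if prev_end is not None and not math.isclose(t0, prev_end, abs_tol=1e-9):
                raise ValueError("segments must be contiguous and ordered")
            prev_end = t1

    @property
    def t_end(self) -> float:
        return self.segments[-1][1]

    @classmethod
    def constant(cls, I_stim: float, T: float, t0: float = 0.0) -> "StimulusProtocol":
        return cls(segments=((t0, T, I_stim),))


@dataclass(frozen=True)
class SpikeTrain:
    I_stim: float
    spike_times: tuple[float, ...]
    blocked_at: float | None = None
    never_fired: bool = False

    @property
    def isis(self) -> np.ndarray:
        return np.diff(np.asarray(self.spike_times))


@dataclass
class TraceRecord:
    """Sampled dimensional trace (t ms, V mV, I_adap pA, I_dep pA)."""

    t: np.ndarray = field(default_factory=lambda: np.empty(0))
    V: np.ndarray = field(default_factory=lambda: np.empty(0))
    I_adap: np.ndarray = field(default_factory=lambda: np.empty(0))
    I_dep: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass(frozen=True)
class CellModel:
    """Everything needed to simulate one cell."""

    p: DimensionalParameters
    monod: MonodCoefficients
    block_rule: BlockRule | None = None


def solve_to_threshold(
    n: NondimensionalParameters,
    init: InitialConditions,
    t0: float,
    t_max: float,
    Vth_tilde: float | None = None,
    scan_step: float | None = None,
    bisect_tol: float | None = None,
) -> float | None:
    """First upward crossing of the threshold, in nondimensional time.

    Scans V(t) on a coarse grid, brackets the first up-crossing and refines
    it by bisection.  Returns ``None`` when V stays below threshold up to
    ``t_max``.  Grid and tolerance are fixed in dimensional ms and converted
    with the cell's time scale, so behavior is independent of ``tau``.
    """
    if t_max <= t0:
        raise ValueError("t_max must exceed t0")
    vth = n.Vth_tilde if Vth_tilde is None else Vth_tilde
    step = (SCAN_STEP_MS if scan_step is None else scan_step) / n.tau
    tol = (BISECT_TOL_MS if bisect_tol is None else bisect_tol) / n.tau

    if init.V0 >= vth:
        return t0
    lo = t0
    v_lo = init.V0
    pos = t0
    while pos < t_max:
        grid = pos + step * np.arange(1, _CHUNK + 1)
        grid = grid[grid <= t_max + step]
        grid = np.minimum(grid, t_max)
        if grid.size == 0:
            break
        V, _, _ = trajectory(n, init.V0, init.I_adap0, init.I_dep0, t0, grid)
        above = np.nonzero(V >= vth)[0]
        if above.size:
            i = above[0]
            hi = grid[i]
            lo = grid[i - 1] if i > 0 else lo
            # bisection refinement
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                vm, _, _ = trajectory(n, init.V0, init.I_adap0, init.I_dep0, t0, mid)
                if vm >= vth:
                    hi = mid
                else:
                    lo = mid
            return float(0.5 * (lo + hi))
        pos = float(grid[-1])
        if math.isclose(pos, t_max):
            break
        lo = pos
        v_lo = float(V[-1])
    _ = v_lo
    return None


def _sample_leg(
    n: NondimensionalParameters,
    init: InitialConditions,
    t0_nd: float,
    t1_nd: float,
    p: DimensionalParameters,
    trace_step_ms: float,
):
    """Sample one inter-event leg into dimensional trace arrays."""
    tau = n.tau
    t0_ms, t1_ms = t0_nd * tau, t1_nd * tau
    if t1_ms <= t0_ms:
        return None
    ts_ms = np.arange(t0_ms, t1_ms, trace_step_ms)
    if ts_ms.size == 0:
        ts_ms = np.array([t0_ms])
    V, Ia, Id = trajectory(n, init.V0, init.I_adap0, init.I_dep0, t0_nd, ts_ms / tau)
    cur = -p.k_2 / (p.E_L * p.k_adap)
    return ts_ms, -np.asarray(V) * p.E_L, np.asarray(Ia) / cur, np.asarray(Id) / cur


class _TraceBuilder:
    def __init__(self, enabled: bool):
        self.enabled = enabled
        self.parts: list[tuple] = []

    def add(self, part) -> None:
        if self.enabled and part is not None:
            self.parts.append(part)

    def build(self) -> TraceRecord:
        if not self.parts:
            return TraceRecord()
        t = np.concatenate([p[0] for p in self.parts])
        return TraceRecord(
            t=t,
            V=np.concatenate([p[1] for p in self.parts]),
            I_adap=np.concatenate([p[2] for p in self.parts]),
            I_dep=np.concatenate([p[3] for p in self.parts]),
        )


def _relaxation_alpha(I_stim: float, p: DimensionalParameters, n: NondimensionalParameters) -> float:
    """Effective alpha whose equilibrium matches the clamped value for I <= 0."""
    if I_stim > 0:
        return I_stim / p.K
    V_star, _ = clamped_equilibrium(I_stim, p, n.with_alpha(I_stim / p.K))
    return (V_star + 1.0) * (n.beta - n.delta)


def updated_t_start(t_start: float, I_prev: float, I_th: float) -> float:
    """Monod-clock dilation applied at an upward current step.

    ``t_start -> t_start (1 + (I_prev - I_th)/I_prev)``: the longer and
    stronger the previous suprathreshold drive, the further the adaptation
    clock advances, reducing the spike count after the step.
    """
    if I_prev <= 0:
        raise ValueError("I_prev must be positive")
    return t_start * (1.0 + (I_prev - I_th) / I_prev)


def theta_star(
    V_prev: float, V_prev2: float, dt: float, delta: float, alpha_bb: float
) -> float:
    """Nonnegative part of the voltage-slope correction Theta at a down-step.

    ``Theta = (V_prev/alpha_bb)(1/dt - delta) - V_prev2/(alpha_bb dt)
    - delta/alpha_bb - 1`` estimated from the last two voltage samples
    (nondimensional, sample spacing ``dt``); ``alpha_bb`` is the scaled
    current of the segment being left.  Clipped at zero.
    """
    if alpha_bb == 0:
        raise ZeroDivisionError("alpha_bb must be nonzero")
    if dt <= 0:
        raise ValueError("dt must be positive")
    theta = (
        (V_prev / alpha_bb) * (1.0 / dt - delta)
        - V_prev2 / (alpha_bb * dt)
        - delta / alpha_bb
        - 1.0
    )
    return max(theta, 0.0)


def _run_suprathreshold_segment(
    p: DimensionalParameters,
    n: NondimensionalParameters,
    monod: MonodCoefficients,
    init: InitialConditions,
    seg_start_ms: float,
    seg_end_ms: float,
    t_start_ms: float,
    I_stim: float,
    cutoff_ms: float | None,
    spikes: list[float],
    tracer: _TraceBuilder,
    trace_step_ms: float,
):
    """Run the spike loop inside one suprathreshold segment.

    Returns (end_init, end_time_ms, blocked_at, pending_refractory_end_ms).
    ``end_init`` holds the Cauchy data valid at ``end_time_ms``; when the
    segment ends inside a refractory gap, ``pending_refractory_end_ms`` is
    the instant at which the after-spike data take effect.
    """
    tau = p.tau
    cur = init
    t0_ms = seg_start_ms
    blocked_at = None
    while t0_ms < seg_end_ms:
        t_cross_nd = solve_to_threshold(n, cur, t0_ms / tau, seg_end_ms / tau)
        if t_cross_nd is None:
            tracer.add(_sample_leg(n, cur, t0_ms / tau, seg_end_ms / tau, p, trace_step_ms))
            return cur, t0_ms, blocked_at, None
        t_spk = t_cross_nd * tau
        if cutoff_ms is not None and t_spk >= cutoff_ms:
            # firing block: discard the crossing, terminate the train
            tracer.add(_sample_leg(n, cur, t0_ms / tau, cutoff_ms / tau, p, trace_step_ms))
            return cur, t0_ms, cutoff_ms, None
        tracer.add(_sample_leg(n, cur, t0_ms / tau, t_spk / tau, p, trace_step_ms))
        spikes.append(t_spk)
        t_plus = t_spk + p.dt_ref
        nxt = after_spike_conditions(p, n, monod, t_plus, t_start_ms, I_stim)
        if t_plus >= seg_end_ms:
            return nxt, t_spk, blocked_at, t_plus
        cur = nxt
        t0_ms = t_plus
    return cur, seg_end_ms, blocked_at, None


def simulate_constant(
    cell: CellModel,
    I_stim: float,
    T: float,
    trace_step_ms: float = 0.1,
    record_trace: bool = True,
) -> tuple[SpikeTrain, TraceRecord]:
    """Simulate a constant current step on [0, T] from rest.

    Subthreshold and negative currents produce no spikes: the state relaxes
    exactly toward the (clamped) equilibrium.  Suprathreshold currents run
    the event loop, with the firing-block cutoff applied if the cell's block
    rule covers ``I_stim``.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    p = cell.p
    n = nondimensionalize(p, I_stim)
    tracer = _TraceBuilder(record_trace)
    tau = p.tau

    if I_stim <= p.I_th:
        n_eff = n.with_alpha(_relaxation_alpha(I_stim, p, n))
        init = InitialConditions(V0=-1.0, I_adap0=0.0, I_dep0=0.0, t0=0.0,
                                 provenance="first_spike")
        tracer.add(_sample_leg(n_eff, init, 0.0, T / tau, p, trace_step_ms))
        return SpikeTrain(I_stim=I_stim, spike_times=(), never_fired=True), tracer.build()

    cutoff = block_cutoff(cell.block_rule, I_stim)
    init = first_spike_conditions(p, n, I_stim)
    spikes: list[float] = []
    _, _, blocked_at, _ = _run_suprathreshold_segment(
        p, n, cell.monod, init, 0.0, T, 0.0, I_stim, cutoff, spikes, tracer, trace_step_ms
    )
    return (
        SpikeTrain(
            I_stim=I_stim,
            spike_times=tuple(spikes),
            blocked_at=blocked_at,
            never_fired=not spikes,
        ),
        tracer.build(),
    )


def simulate_piecewise(
    cell: CellModel,
    protocol: StimulusProtocol,
    trace_step_ms: float = 0.1,
    record_trace: bool = True,
) -> tuple[SpikeTrain, TraceRecord]:
    """Simulate a piecewise-constant protocol with the discontinuity rules."""
    p = cell.p
    tau = p.tau
    tracer = _TraceBuilder(record_trace)
    spikes: list[float] = []
    blocked_at = None

    seg0 = protocol.segments[0]
    t_start_ms = seg0[0]
    state: InitialConditions | None = None  # carried Cauchy data
    state_t_ms = seg0[0]
    pending_reset_ms: float | None = None
    prev_I: float | None = None
    prev_supra = False

    for t_begin, t_end, I in protocol.segments:
        n = nondimensionalize(p, I)
        supra = I > p.I_th

        if not supra:
            # relax toward (clamped) equilibrium; reset the Monod clock to the
            # end of this subthreshold epoch
            n_eff = n.with_alpha(_relaxation_alpha(I, p, n))
            if state is None:
                state = InitialConditions(V0=-1.0, I_adap0=0.0, I_dep0=0.0,
                                          t0=t_begin / tau, provenance="first_spike")
                state_t_ms = t_begin
            if pending_reset_ms is not None and pending_reset_ms > t_begin:
                # refractory tail crosses into a subthreshold segment: hold the
                # reset data until the gap ends, then relax
                state_t_ms = min(pending_reset_ms, t_end)
                pending_reset_ms = None
            V, Ia, Id = trajectory(
                n_eff, state.V0, state.I_adap0, state.I_dep0, state_t_ms / tau, t_end / tau
            )
            tracer.add(_sample_leg(n_eff, state, state_t_ms / tau, t_end / tau, p, trace_step_ms))
            state = InitialConditions(V0=float(V), I_adap0=float(Ia), I_dep0=float(Id),
                                      t0=t_end / tau, provenance="discontinuity")
            state_t_ms = t_end
            t_start_ms = t_end
            prev_I, prev_supra = I, False
            continue

        # suprathreshold segment
        if state is None or not prev_supra:
            # onset from rest or after a subthreshold epoch
            state = first_spike_conditions(p, n, I, t0=t_begin / tau)
            state_t_ms = t_begin
        elif pending_reset_ms is not None:
            # boundary fell inside the refractory gap: after-spike data apply
            # at the gap's end, no extra boundary update
            state_t_ms = pending_reset_ms
        elif prev_I is not None and I < prev_I:
            # downward step above rheobase: V, I_adap continuous, I_dep re-seeded
            dt_nd = trace_step_ms / tau
            tb_nd = t_begin / tau
            base_nd = state.t0
            v1_t = max(tb_nd - dt_nd, base_nd)
            v2_t = max(tb_nd - 2.0 * dt_nd, base_nd)
            Vb, Iab, _ = trajectory(n_prev_eff, state.V0, state.I_adap0, state.I_dep0, base_nd, tb_nd)
            V1, _, _ = trajectory(n_prev_eff, state.V0, state.I_adap0, state.I_dep0, base_nd, v1_t)
            V2, _, _ = trajectory(n_prev_eff, state.V0, state.I_adap0, state.I_dep0, base_nd, v2_t)
            alpha_bb = prev_I / p.K
            th = theta_star(float(V1), float(V2), dt_nd, n.delta, alpha_bb)
            alpha_bar = I / p.K
            state = InitialConditions(
                V0=float(Vb), I_adap0=float(Iab),
                I_dep0=float(Iab) + th * alpha_bar / n.beta,
                t0=tb_nd, provenance="discontinuity",
            )
            state_t_ms = t_begin
        else:
            # upward (or equal) step: carry state, dilate the Monod clock
            Vb, Iab, Idb = trajectory(
                n_prev_eff, state.V0, state.I_adap0, state.I_dep0, state.t0, t_begin / tau
            )
            state = InitialConditions(V0=float(Vb), I_adap0=float(Iab), I_dep0=float(Idb),
                                      t0=t_begin / tau, provenance="discontinuity")
            state_t_ms = t_begin
            if prev_I is not None and prev_I > p.I_th:
                t_start_ms = updated_t_start(t_start_ms, prev_I, p.I_th)
        pending_reset_ms = None

        cutoff = block_cutoff(cell.block_rule, I)
        state, state_t_ms, seg_block, pending_reset_ms = _run_suprathreshold_segment(
            p, n, cell.monod, state, state_t_ms, t_end, t_start_ms, I,
            cutoff, spikes, tracer, trace_step_ms,
        )
        if seg_block is not None:
            blocked_at = seg_block
            break
        if pending_reset_ms is None:
            # state holds data at state_t_ms; advance it to the segment end
            Ve, Iae, Ide = trajectory(
                n, state.V0, state.I_adap0, state.I_dep0, state_t_ms / tau, t_end / tau
            )
            state = InitialConditions(V0=float(Ve), I_adap0=float(Iae), I_dep0=float(Ide),
                                      t0=t_end / tau, provenance="discontinuity")
            state_t_ms = t_end
        prev_I, prev_supra = I, True
        n_prev_eff = n

    label_I = protocol.segments[0][2] if len(protocol.segments) == 1 else math.nan
    return (
        SpikeTrain(
            I_stim=label_I,
            spike_times=tuple(spikes),
            blocked_at=blocked_at,
            never_fired=not spikes,
        ),
        tracer.build(),
    )
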