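"""Ground-truth synthetic cells and spike rasters.

Real CA1 recordings are not distributed with this package; this module
generates fully specified A-GLIF cells and the rasters they produce under
the standard constant-step protocol (200 to 1000 pA in 200 pA increments,
400 ms steps), so that every fitting and validation routine can be exercised
against a known ground truth.

Cells are drawn directly in constraint space: the generator picks ``delta``
inside (0, 1), then the threshold current ratio ``alpha_th`` as a fraction
of its admissible maximum ``(1 + Vth_tilde)(1 - delta)^2 / 4`` and ``beta``
as a fraction of its admissible band, so the subthreshold-silence
constraints hold by construction for every draw.  The Monod update
coefficients are scaled to the cell's own voltage-rise bound H (evaluated at
the middle protocol current): intercept and plateau are fixed fractions of
H, which yields inter-spike intervals in the physiological range of tens of
milliseconds rather than arbitrary firing rates.

Phenotypes differ in their Monod update coefficients:

* ``adapting`` — ``a > 0, b > 0``: intervals lengthen within a train and the
  effect strengthens with current (continuous accommodating);
* ``adapting_bneg`` — ``a > 0, b < 0``: adaptation weakens with current;
* ``non_adapting`` — tiny ``a``: near-constant intervals (continuous
  non-accommodating);
* ``blocking`` — adapting plus a firing-block rule synthesized from two
  chosen block currents (600 and 800 pA);
* ``high_threshold`` — elevated rheobase, so the lowest protocol current
  stays silent.

What these fixtures do not emulate: channel noise, spike-shape details, the
subthreshold waveform of biophysical models, and trial-to-trial variability
beyond optional Gaussian spike-time jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    DimensionalParameters,
    check_constraints,
    complete_parameters,
    nondimensionalize,
)
from .simulate import (
    CellModel,
    SpikeTrain,
    StimulusProtocol,
    simulate_constant,
    simulate_piecewise,
)
from .update_rules import BlockLine, BlockRule, MonodCoefficients, SpikeRaster, threshold_H

__all__ = [
    "ReferenceCell",
    "PHENOTYPES",
    "PROTOCOL_CURRENTS",
    "PROTOCOL_T_MS",
    "DRAW_RANGES",
    "make_reference_cell",
    "generate_constant_raster",
    "generate_piecewise_fixture",
]

#: the constant-step stimulation protocol emulated by all fixtures
PROTOCOL_CURRENTS: tuple[float, ...] = (200.0, 400.0, 600.0, 800.0, 1000.0)
PROTOCOL_T_MS: float = 400.0

#: documented parameter draw ranges, kept in one place so fixtures are
#: stable across versions.  Potentials in mV, currents in pA, C_m in pF;
#: *_frac entries are fractions of the admissible constraint intervals and
#: of the voltage-rise bound H.
DRAW_RANGES = {
    "E_L": (-78.0, -72.0),
    "V_r_offset": (10.0, 14.0),      # V_r = E_L + offset
    "V_th_offset": (26.0, 30.0),     # V_th = E_L + offset
    "C_m": (200.0, 320.0),
    "I_th": (90.0, 160.0),
    "I_th_high": (320.0, 380.0),
    "delta": (0.06, 0.2),
    "alpha_th_frac": (0.55, 0.8),
    "beta_frac": (0.4, 0.8),
    "I_dep_start": (0.9, 1.6),
    "I_dep0": (20.0, 60.0),
    # Monod scaling, as fractions of H at the middle protocol current
    "c_frac": (0.25, 0.4),
    "plateau_frac": (0.65, 0.85),
    "b_pos": (1.5e-3, 3e-3),
    "b_neg": (2e-4, 6e-4),
    "d_ms": (25.0, 60.0),
}

PHENOTYPES = ("adapting", "adapting_bneg", "non_adapting", "blocking", "high_threshold")


@dataclass(frozen=True)
class ReferenceCell:
    params: DimensionalParameters
    monod: MonodCoefficients
    block_rule: BlockRule | None
    phenotype: str

    def cell(self) -> CellModel:
        return CellModel(p=self.params, monod=self.monod, block_rule=self.block_rule)


def _draw(rng: np.random.Generator, key: str) -> float:
    lo, hi = DRAW_RANGES[key]
    return float(rng.uniform(lo, hi))


def _draw_parameters(rng: np.random.Generator, high_threshold: bool) -> DimensionalParameters:
    """Draw a parameter set satisfying the stability constraints by construction."""
    E_L = _draw(rng, "E_L")
    V_r = E_L + _draw(rng, "V_r_offset")
    V_th = E_L + _draw(rng, "V_th_offset")
    C_m = _draw(rng, "C_m")
    I_th = _draw(rng, "I_th_high" if high_threshold else "I_th")
    delta = _draw(rng, "delta")
    one_plus = 1.0 - V_th / E_L
    alpha_th = _draw(rng, "alpha_th_frac") * one_plus * (1.0 - delta) ** 2 / 4.0
    K = I_th / alpha_th
    beta_lo = alpha_th / one_plus + delta
    beta_hi = (1.0 + delta) ** 2 / 4.0
    beta = beta_lo + _draw(rng, "beta_frac") * (beta_hi - beta_lo)
    k_2 = -K / (C_m * E_L)
    p = complete_parameters(
        dict(
            E_L=E_L, V_r=V_r, V_th=V_th, C_m=C_m, tau_m=1.0 / (k_2 * delta),
            I_th=I_th, K=K, k_1=beta * k_2,
            I_dep_start=_draw(rng, "I_dep_start"), I_dep0=_draw(rng, "I_dep0"),
        )
    )
    report = check_constraints(nondimensionalize(p, I_th), p)
    assert report.passed, "constraint-space draw must be feasible"
    return p


def _monod_for(
    rng: np.random.Generator, phenotype: str, p: DimensionalParameters
) -> MonodCoefficients:
    """Monod coefficients scaled to the cell's voltage-rise bound H.

    The intercept ``c`` and the plateau are fixed fractions of H evaluated
    at the lowest suprathreshold protocol current, where the bound is
    tightest (H grows linearly with current).  Keeping the update below H at
    every protocol current — the model's own requirement inside the fitted
    range — guarantees the membrane rises after each reset, and yields
    intervals of tens of milliseconds as in the reference recordings.
    """
    cur = -p.k_2 / (p.E_L * p.k_adap)
    firing = [I for I in PROTOCOL_CURRENTS if I > p.I_th]

    def H_at(I: float) -> float:
        n = nondimensionalize(p, I)
        return threshold_H(n, p.I_dep0 * cur, n.Vr_tilde)

    H_low = H_at(firing[0])
    c_frac = _draw(rng, "c_frac")
    plateau_frac = _draw(rng, "plateau_frac")
    d = _draw(rng, "d_ms")
    if phenotype == "non_adapting":
        m = MonodCoefficients(a=float(0.03 * H_low), b=1e-4, c=float(0.55 * H_low), d=float(d))
    else:
        c = c_frac * H_low
        rise = plateau_frac * H_low - c
        b = _draw(rng, "b_pos") if phenotype != "adapting_bneg" else -_draw(rng, "b_neg")
        m = MonodCoefficients(a=float(rise / math.exp(b * firing[0])), b=float(b), c=float(c), d=float(d))
    # enforce the bound across the whole protocol range: with b > 0 the
    # plateau grows exponentially in current while H grows only linearly
    shrink = min(
        (0.95 * H_at(I) - m.c) / (m.a * math.exp(m.b * I))
        for I in firing
        if m.a * math.exp(m.b * I) > 0
    )
    if shrink < 1.0:
        m = MonodCoefficients(a=float(m.a * max(shrink, 0.0)), b=m.b, c=m.c, d=m.d)
    return m


def _block_rule_for(rng: np.random.Generator) -> BlockRule:
    """Synthesize a block rule from two chosen blocking currents (600, 800 pA).

    The cutoff line slopes gently downward with current, as observed for
    depolarization-blocking interneurons.
    """
    t1 = float(rng.uniform(240.0, 300.0))
    t2 = t1 - float(rng.uniform(20.0, 50.0))
    P1, P2 = (600.0, t1), (800.0, t2)
    A = (P2[1] - P1[1]) / (P2[0] - P1[0])
    B = P1[1] - A * P1[0]
    line = BlockLine(A_coef=A, B_coef=B, side="ge", threshold=500.0, P1=P1, P2=P2)
    return BlockRule(lines=(line,), block_intervals=((600.0, 800.0),), I_fire=(400.0,))


def make_reference_cell(phenotype: str, seed: int) -> ReferenceCell:
    """Deterministically construct one ground-truth cell of a phenotype."""
    if phenotype not in PHENOTYPES:
        raise ValueError(f"phenotype must be one of {PHENOTYPES}")
    rng = np.random.default_rng([seed, PHENOTYPES.index(phenotype)])
    p = _draw_parameters(rng, high_threshold=(phenotype == "high_threshold"))
    monod = _monod_for(rng, phenotype, p)
    block = _block_rule_for(rng) if phenotype == "blocking" else None
    return ReferenceCell(params=p, monod=monod, block_rule=block, phenotype=phenotype)


def generate_constant_raster(
    cell: ReferenceCell | CellModel,
    currents=PROTOCOL_CURRENTS,
    T: float = PROTOCOL_T_MS,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> SpikeRaster:
    """Simulate the constant-step protocol, optionally jittering spike times.

    Jitter is truncated Gaussian (clipped at 3 sd) applied per spike,
    preserving ordering and the refractory separation so the raster stays
    physically valid, and never changing spike counts.
    """
    model = cell.cell() if isinstance(cell, ReferenceCell) else cell
    rng = np.random.default_rng(seed)
    trains: dict[float, np.ndarray] = {}
    for I in currents:
        if I <= 0:
            raise ValueError("protocol currents must be positive")
        train, _ = simulate_constant(model, I, T, record_trace=False)
        ts = np.asarray(train.spike_times, dtype=float)
        if jitter_sd > 0 and ts.size:
            jit = np.clip(rng.normal(0.0, jitter_sd, size=ts.size), -3 * jitter_sd, 3 * jitter_sd)
            ts = np.sort(ts + jit)
            # re-impose refractory separation and the stimulation window
            gap = model.p.dt_ref + 1e-6
            for k in range(1, ts.size):
                if ts[k] - ts[k - 1] < gap:
                    ts[k] = ts[k - 1] + gap
            ts = np.clip(ts, 0.0, T)
        trains[float(I)] = ts
    return SpikeRaster(
        trains=trains,
        cell_id=f"synthetic_{getattr(cell, 'phenotype', 'cell')}",
        T=T,
        t_start=0.0,
    )


def generate_piecewise_fixture(
    cell: ReferenceCell | CellModel, n_segments: int, seed: int
) -> tuple[StimulusProtocol, SpikeTrain]:
    """Random step protocol (up, down, zero and subthreshold segments) plus
    the simulated ground-truth spike train."""
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    model = cell.cell() if isinstance(cell, ReferenceCell) else cell
    rng = np.random.default_rng(seed)
    choices = [0.0, 0.5 * model.p.I_th] + list(PROTOCOL_CURRENTS)
    segs = []
    t = 0.0
    seg_len = 200.0
    prev = None
    for _ in range(n_segments):
        I = float(rng.choice(choices))
        if prev is not None and I == prev:
            I = float(rng.choice([c for c in choices if c != prev]))
        segs.append((t, t + seg_len, I))
        t += seg_len
        prev = I
    protocol = StimulusProtocol(segments=tuple(segs))
    train, _ = simulate_piecewise(model, protocol, record_trace=False)
    return protocol, train
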