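"""Domain types and unit conventions for the A-GLIF point-neuron model.

The adaptive generalized leaky integrate-and-fire (A-GLIF) model describes a
membrane potential ``V`` coupled to two intrinsic currents: a hyperpolarizing
adaptation current ``I_adap`` and a depolarizing current ``I_dep``::

    dV/dt      = (1/C_m) [ (C_m/tau_m)(V - E_L) - I_adap + I_dep + I_stim ]
    dI_adap/dt = k_adap (V - E_L) - k_2 I_adap
    dI_dep/dt  = -k_1 I_dep

Dimensional units are fixed throughout the package: time in ms, potentials in
mV, currents in pA, capacitance in pF.  Rates ``k_1``, ``k_2`` are in 1/ms and
the adaptation constant ``k_adap`` in pA / (mV ms), the unit that makes the
``I_adap`` equation dimensionally consistent.

Two structural identities tie the rate constants together:

* ``k_adap = C_m k_1 k_2`` — equates the decay-rate ratio of the two currents
  (``beta``) with the coupling ratio (``gamma``), collapsing the
  nondimensional system to three parameters;
* ``k_2 = -K / (C_m E_L)`` — introduces the current scale ``K`` (pA) so that
  the scaled injected current is simply ``alpha = I_stim / K``.

Both are treated as hard constraints: parameter sets violating them are
rejected, never silently adjusted.

Rescaling ``t -> t/tau`` (``tau = 1/k_2``), ``V -> -V/E_L`` and
``I -> -k_2 I / (E_L k_adap)`` yields the nondimensional system::

    dV/dt      = alpha + beta (I_dep - I_adap) + delta (1 + V)
    dI_adap/dt = 1 - I_adap + V
    dI_dep/dt  = -beta I_dep

with ``alpha = I_stim/K``, ``beta = k_1/k_2`` and ``delta = 1/(k_2 tau_m)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Literal

__all__ = [
    "DimensionalParameters",
    "NondimensionalParameters",
    "ModelState",
    "ConstraintReport",
    "ConstraintViolation",
    "ParameterError",
    "complete_parameters",
    "nondimensionalize",
    "convert_state",
    "check_constraints",
]

#: relative tolerance for the structural identities (closed-form arithmetic)
STRUCTURAL_RTOL = 1e-9
#: relative tolerance for unit round-trips
ROUNDTRIP_RTOL = 1e-12


class ParameterError(ValueError):
    """Raised when a parameter set is incomplete, inconsistent, or unphysical."""


@dataclass(frozen=True)
class DimensionalParameters:
    """Physiological constants of one model cell (ms / mV / pA / pF units).

    ``I_dep_start`` is the dimensionless multiplier converting the
    suprathreshold current excess ``I_stim - I_th`` (pA) into the
    depolarizing current injected at stimulation onset; ``I_dep0`` is the
    constant depolarizing current (pA) re-injected after every spike.
    ``I_stim_neg`` is the hyperpolarizing current at which the membrane
    relaxes to the floor potential ``V_min``.
    """

    E_L: float
    V_r: float
    V_th: float
    C_m: float
    tau_m: float
    I_th: float
    K: float
    k_1: float
    k_2: float
    k_adap: float
    I_dep_start: float = 0.0
    I_dep0: float = 0.0
    dt_ref: float = 2.0
    V_min: float = -90.0
    I_stim_neg: float = -185.0

    def __post_init__(self) -> None:
        for name in ("k_1", "k_2", "k_adap", "C_m", "tau_m", "K", "I_th"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.E_L < 0:
            raise ParameterError(f"E_L must be negative, got {self.E_L}")
        for name in ("V_r", "V_th"):
            v = getattr(self, name)
            if not (self.V_min < v < 0):
                raise ParameterError(f"{name}={v} must lie strictly between V_min={self.V_min} and 0")
        if not self.V_th > self.E_L:
            raise ParameterError(f"V_th={self.V_th} must exceed E_L={self.E_L}")
        if not math.isclose(self.k_adap, self.C_m * self.k_1 * self.k_2, rel_tol=STRUCTURAL_RTOL):
            raise ParameterError(
                f"k_adap={self.k_adap} violates k_adap = C_m k_1 k_2 = "
                f"{self.C_m * self.k_1 * self.k_2}"
            )
        if not math.isclose(self.k_2, -self.K / (self.C_m * self.E_L), rel_tol=STRUCTURAL_RTOL):
            raise ParameterError(
                f"k_2={self.k_2} violates k_2 = -K/(C_m E_L) = "
                f"{-self.K / (self.C_m * self.E_L)}"
            )

    @property
    def tau(self) -> float:
        """Nondimensionalization time scale 1/k_2 (ms)."""
        return 1.0 / self.k_2

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class NondimensionalParameters:
    """Parameters (alpha, beta, delta) of the rescaled system plus scales.

    ``gamma`` equals ``beta`` by construction (consequence of the structural
    identity ``k_adap = C_m k_1 k_2``) and is exposed as a read-only property,
    never stored independently.
    """

    alpha: float
    beta: float
    delta: float
    tau: float
    Vth_tilde: float
    Vr_tilde: float
    alpha_th: float

    def __post_init__(self) -> None:
        for name in ("beta", "delta", "tau"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def gamma(self) -> float:
        return self.beta

    def with_alpha(self, alpha: float) -> "NondimensionalParameters":
        return replace(self, alpha=alpha)


UnitsFlag = Literal["dimensional", "nondimensional"]


@dataclass(frozen=True)
class ModelState:
    """State (V, I_adap, I_dep) at time t, in either unit system."""

    t: float
    V: float
    I_adap: float
    I_dep: float
    units_flag: UnitsFlag = "dimensional"


@dataclass(frozen=True)
class ConstraintViolation:
    name: str
    margin: float
    detail: str = ""


@dataclass(frozen=True)
class ConstraintReport:
    """Outcome of the subthreshold-silence constraint check.

    ``margins`` holds the signed margin of every condition (positive =
    satisfied); ``violated`` lists the failed ones.  ``dimensional_agree``
    records whether the redundant dimensional-form cross-checks gave the same
    pass/fail verdict as the nondimensional conditions.
    """

    passed: bool
    violated: tuple[ConstraintViolation, ...]
    margins: dict = field(default_factory=dict)
    dimensional_agree: bool | None = None

    def __post_init__(self) -> None:
        assert self.passed == (len(self.violated) == 0)


def complete_parameters(raw: dict) -> DimensionalParameters:
    """Build a consistent :class:`DimensionalParameters` from a partial dict.

    ``k_2`` is derived from the scaling identity ``k_2 = -K/(C_m E_L)`` and
    ``k_adap`` from ``k_adap = C_m k_1 k_2``.  If either was supplied it is
    checked against the derived value (relative tolerance 1e-9) and a
    :class:`ParameterError` is raised on mismatch.
    """
    required = {"E_L", "C_m", "tau_m", "K", "k_1", "V_r", "V_th", "I_th"}
    missing = required - set(k for k, v in raw.items() if v is not None)
    if missing:
        raise ParameterError(f"missing required parameters: {sorted(missing)}")
    for name in ("C_m", "tau_m", "K", "k_1", "I_th"):
        if not raw[name] > 0:
            raise ParameterError(f"{name} must be > 0, got {raw[name]}")
    if not raw["E_L"] < 0:
        raise ParameterError(f"E_L must be negative, got {raw['E_L']}")

    k_2 = -raw["K"] / (raw["C_m"] * raw["E_L"])
    k_adap = raw["C_m"] * raw["k_1"] * k_2
    for name, derived in (("k_2", k_2), ("k_adap", k_adap)):
        supplied = raw.get(name)
        if supplied is not None and not math.isclose(supplied, derived, rel_tol=STRUCTURAL_RTOL):
            raise ParameterError(
                f"supplied {name}={supplied} contradicts the derived value {derived}"
            )

    known = {f.name for f in fields(DimensionalParameters)}
    extra = {k: v for k, v in raw.items() if k in known and v is not None}
    extra["k_2"] = k_2
    extra["k_adap"] = k_adap
    return DimensionalParameters(**extra)


def nondimensionalize(p: DimensionalParameters, I_stim: float) -> NondimensionalParameters:
    """Rescale a dimensional parameter set at stimulation current ``I_stim`` (pA)."""
    return NondimensionalParameters(
        alpha=I_stim / p.K,
        beta=p.k_1 / p.k_2,
        delta=1.0 / (p.k_2 * p.tau_m),
        tau=1.0 / p.k_2,
        Vth_tilde=-p.V_th / p.E_L,
        Vr_tilde=-p.V_r / p.E_L,
        alpha_th=p.I_th / p.K,
    )


def convert_state(s: ModelState, p: DimensionalParameters, direction: str) -> ModelState:
    """Convert a state between unit systems.

    ``to_nondimensional`` applies t -> t/tau, V -> -V/E_L and
    I -> -k_2 I / (E_L k_adap); ``to_dimensional`` inverts it.  The round trip
    is the identity to 1e-12 relative.
    """
    cur = -p.k_2 / (p.E_L * p.k_adap)  # pA -> nondimensional current factor
    if direction == "to_nondimensional":
        if s.units_flag != "dimensional":
            raise ValueError("state is already nondimensional")
        return ModelState(
            t=s.t / p.tau,
            V=-s.V / p.E_L,
            I_adap=s.I_adap * cur,
            I_dep=s.I_dep * cur,
            units_flag="nondimensional",
        )
    if direction == "to_dimensional":
        if s.units_flag != "nondimensional":
            raise ValueError("state is already dimensional")
        return ModelState(
            t=s.t * p.tau,
            V=-s.V * p.E_L,
            I_adap=s.I_adap / cur,
            I_dep=s.I_dep / cur,
            units_flag="dimensional",
        )
    raise ValueError(f"unknown direction {direction!r}")


def _dimensional_constraints(p: DimensionalParameters) -> tuple[float, float, float]:
    """Signed margins of the dimensional-form constraints (positive = pass).

    These are the dimensional equivalents of the nondimensional region: a
    lower bound on the current scale K and a two-sided band on k_adap.
    """
    E_L, V_th, C_m, tau_m, I_th, K = p.E_L, p.V_th, p.C_m, p.tau_m, p.I_th, p.K
    rad = I_th**2 - I_th * C_m * (V_th - E_L) / tau_m
    K_lower = -C_m * E_L / tau_m + 2 * E_L / (E_L - V_th) * (I_th + math.sqrt(max(rad, 0.0)))
    k_adap_lower = K / (E_L * tau_m) * (I_th * tau_m / (C_m * (E_L - V_th)) - 1.0)
    k_adap_upper = (C_m * E_L - K * tau_m) ** 2 / (4 * C_m * E_L**2 * tau_m**2)
    return K - K_lower, p.k_adap - k_adap_lower, k_adap_upper - p.k_adap


def check_constraints(
    n: NondimensionalParameters, p: DimensionalParameters | None = None
) -> ConstraintReport:
    """Check the parameter constraints guaranteeing subthreshold silence.

    The conditions ensure that for any ``0 < I_stim < I_th`` the stable
    equilibrium of the membrane potential stays below threshold, so the cell
    can never fire below its rheobase:

    * ``0 < delta < 1``;
    * ``alpha_th < (1 + Vth_tilde)(delta - 1)^2 / 4``;
    * ``alpha_th/(1 + Vth_tilde) + delta < beta <= (1 + delta)^2 / 4``.

    Failures are reported with signed margins, not raised.  When ``p`` is
    given, the redundant dimensional-form checks are evaluated as well and
    their agreement recorded in ``dimensional_agree``.
    """
    b, d = n.beta, n.delta
    one_plus_vth = 1.0 + n.Vth_tilde
    margins = {
        "delta_open_unit_interval": min(d, 1.0 - d),
        "alpha_th_bound": one_plus_vth * (d - 1.0) ** 2 / 4.0 - n.alpha_th,
        "beta_lower": b - (n.alpha_th / one_plus_vth + d),
        "beta_upper": (1.0 + d) ** 2 / 4.0 - b,
    }
    descriptions = {
        "delta_open_unit_interval": "0 < delta < 1",
        "alpha_th_bound": "alpha_th < (1+Vth_tilde)(delta-1)^2/4",
        "beta_lower": "alpha_th/(1+Vth_tilde) + delta < beta",
        "beta_upper": "beta <= (1+delta)^2/4",
    }
    strict = {"delta_open_unit_interval", "alpha_th_bound", "beta_lower"}
    violated = tuple(
        ConstraintViolation(name=k, margin=m, detail=descriptions[k])
        for k, m in margins.items()
        if (m <= 0 if k in strict else m < 0)
    )
    dimensional_agree = None
    if p is not None:
        dm = _dimensional_constraints(p)
        dim_pass = all(m > 0 for m in dm[:2]) and dm[2] >= 0
        nond_sub = (
            margins["alpha_th_bound"] > 0
            and margins["beta_lower"] > 0
            and margins["beta_upper"] >= 0
        )
        dimensional_agree = dim_pass == nond_sub
        margins["dim_K_lower"], margins["dim_k_adap_lower"], margins["dim_k_adap_upper"] = dm
    return ConstraintReport(
        passed=len(violated) == 0, violated=violated, margins=margins,
        dimensional_agree=dimensional_agree,
    )
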