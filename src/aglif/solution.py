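"""Exact trajectories, equilibria and stability of the nondimensional system.

The rescaled A-GLIF equations form a constant-coefficient linear system, so
between spikes the state has a closed form built from two combined
exponential terms::

    A  = (delta + 1)^2 - 4 beta
    H1 = e^B (e^C - 1) / sqrt(A),   H2 = e^B (e^C + 1)

with ``B = -(sqrt(A) - delta + 1) dt / 2`` and ``C = sqrt(A) dt``.  Writing
``r = (delta - 1)/2`` and ``nu = sqrt(A)/2`` these reduce to the numerically
friendly real forms ``H1 = e^{r dt} sinh(nu dt)/nu`` and
``H2 = 2 e^{r dt} cosh(nu dt)``; for ``A < 0`` the hyperbolic functions become
trigonometric ones and for ``A -> 0`` the analytic limits
``H1 -> dt e^{r dt}``, ``H2 -> 2 e^{r dt}`` apply.  All trajectory evaluation
in this package goes through these expressions — no numerical ODE integration
is ever performed.

The closed form has removable singularities at ``beta = delta`` (the alpha
terms) and on the resonance curve ``beta^2 + (beta - 1) delta = 0`` (the
I_dep terms), where the depolarizing decay rate coincides with a membrane
eigenvalue.  Near those surfaces the analytic limits, obtained by
l'Hopital differentiation of H1 and H2 with respect to beta
(``dH2/dbeta = -dt H1`` and ``dH1/dbeta = (2 H1 - dt H2)/A``), are used
instead of the raw quotients.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

from .core import DimensionalParameters, ModelState, NondimensionalParameters

__all__ = [
    "AuxiliaryTerms",
    "Equilibrium",
    "StabilityReport",
    "auxiliary_terms",
    "general_integral",
    "trajectory",
    "equilibria",
    "eigenvalues",
    "classify_stability",
    "voltage_sensitivities",
    "clamped_equilibrium",
]

#: below this |A| the series limit of H1 replaces the sinh/sin quotient
_A_SERIES_TOL = 1e-10
#: below this distance from a removable singularity the analytic limit is used
_SINGULAR_TOL = 1e-9


@dataclass(frozen=True)
class AuxiliaryTerms:
    """The exponent arguments and combined exponentials at elapsed time dt.

    ``B_cal`` and ``C_cal`` are complex when ``A_cal < 0``; ``H1`` and ``H2``
    are always real.
    """

    A_cal: float
    B_cal: complex
    C_cal: complex
    H1: float
    H2: float


def _h12(beta: float, delta: float, dt):
    """Vectorized (H1, H2) over elapsed nondimensional time ``dt >= 0``."""
    dt = np.asarray(dt, dtype=float)
    A = (delta + 1.0) ** 2 - 4.0 * beta
    r = 0.5 * (delta - 1.0)
    ert = np.exp(r * dt)
    if A > _A_SERIES_TOL:
        nu = 0.5 * math.sqrt(A)
        H1 = ert * np.sinh(nu * dt) / nu
        H2 = 2.0 * ert * np.cosh(nu * dt)
    elif A < -_A_SERIES_TOL:
        w = 0.5 * math.sqrt(-A)
        H1 = ert * np.sin(w * dt) / w
        H2 = 2.0 * ert * np.cos(w * dt)
    else:
        # analytic limit at the degenerate-eigenvalue parabola, with the
        # leading series correction (mu2 = A/4)
        mu2 = 0.25 * A
        H1 = ert * dt * (1.0 + mu2 * dt * dt / 6.0)
        H2 = 2.0 * ert * (1.0 + 0.5 * mu2 * dt * dt)
    return H1, H2


def _dh12_dbeta(beta: float, delta: float, dt):
    """Analytic derivatives of (H1, H2) with respect to beta."""
    dt = np.asarray(dt, dtype=float)
    A = (delta + 1.0) ** 2 - 4.0 * beta
    H1, H2 = _h12(beta, delta, dt)
    dH2 = -dt * H1
    if abs(A) > 1e-8:
        dH1 = (2.0 * H1 - dt * H2) / A
    else:
        r = 0.5 * (delta - 1.0)
        dH1 = -np.exp(r * dt) * (dt**3 / 6.0 + A * dt**5 / 240.0)
    return dH1, dH2


def auxiliary_terms(beta: float, delta: float, elapsed: float) -> AuxiliaryTerms:
    """Evaluate the exponential building blocks at one elapsed time."""
    if beta <= 0 or delta <= 0:
        raise ValueError("beta and delta must be positive")
    if elapsed < 0:
        raise ValueError("elapsed time must be >= 0")
    A = (delta + 1.0) ** 2 - 4.0 * beta
    sA = cmath.sqrt(A)
    B = -0.5 * (sA - delta + 1.0) * elapsed
    C = sA * elapsed
    if B.imag == 0:
        B = B.real
    if C.imag == 0:
        C = C.real
    H1, H2 = _h12(beta, delta, elapsed)
    return AuxiliaryTerms(A_cal=A, B_cal=B, C_cal=C, H1=float(H1), H2=float(H2))


def trajectory(
    n: NondimensionalParameters,
    V0: float,
    I_adap0: float,
    I_dep0: float,
    t0: float,
    t,
):
    """Closed-form (V, I_adap, I_dep) at nondimensional time(s) ``t >= t0``.

    Vectorized over ``t``.  Removable singularities of the printed closed form
    (``beta = delta`` and ``beta^2 + (beta-1) delta = 0``) are evaluated by
    their analytic limits.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < t0 - 1e-12):
        raise ValueError("t must be >= t0")
    dt = np.maximum(t - t0, 0.0)
    a, b, d = n.alpha, n.beta, n.delta
    H1, H2 = _h12(b, d, dt)
    e = np.exp(-b * dt)
    scale = max(1.0, abs(b), abs(d))

    # I_dep^0 coefficient terms (resonance curve D = 0)
    D = b * b + (b - 1.0) * d
    NV2 = (b - 1.0) * (H2 - 2.0 * e) + H1 * ((b - 1.0) * (d + 1.0) + 2.0 * b)
    NI = 2.0 * e + H1 * (2.0 * b + d - 1.0) - H2
    if abs(D) > _SINGULAR_TOL * scale:
        cV_dep = b * NV2 / (2.0 * D)
        cI_dep = 0.5 * b * NI / D
    else:
        dH1, dH2 = _dh12_dbeta(b, d, dt)
        dNV2 = (
            (H2 - 2.0 * e)
            + (b - 1.0) * (dH2 + 2.0 * dt * e)
            + dH1 * ((b - 1.0) * (d + 1.0) + 2.0 * b)
            + H1 * (d + 3.0)
        )
        dNI = -2.0 * dt * e + dH1 * (2.0 * b + d - 1.0) + 2.0 * H1 - dH2
        dD = 2.0 * b + d
        cV_dep = (NV2 + b * dNV2) / (2.0 * dD)
        cI_dep = 0.5 * (NI + b * dNI) / dD

    # alpha-dependent terms (removable singularity at beta = delta)
    if abs(b - d) > _SINGULAR_TOL * scale:
        V_alpha = H1 / 2.0 * (a * (b - 1.0) / (b - d) + a + d + 1.0) - (H2 - 2.0) * (
            a - b + d
        ) / (2.0 * (b - d))
        I_alpha = -a / 2.0 * ((1.0 - d) * H1 + H2 - 2.0) / (b - d)
    else:
        dH1, dH2 = _dh12_dbeta(b, d, dt)
        V_alpha = (
            a / 2.0 * (H1 + (b - 1.0) * dH1 - dH2)
            + H1 / 2.0 * (a + d + 1.0)
            + (H2 - 2.0) / 2.0
        )
        I_alpha = -a / 2.0 * ((1.0 - d) * dH1 + dH2)

    V = -I_adap0 * b * H1 + I_dep0 * cV_dep + V0 / 2.0 * ((d + 1.0) * H1 + H2) + V_alpha
    I_adap = (
        0.5 * I_adap0 * (H2 - (d + 1.0) * H1)
        + I_dep0 * cI_dep
        + V0 * H1
        + I_alpha
        + H1
    )
    I_dep = I_dep0 * e
    return V, I_adap, I_dep


def general_integral(
    n: NondimensionalParameters, init: ModelState, t0: float, t: float
) -> ModelState:
    """Evaluate the general integral from a nondimensional initial state."""
    if init.units_flag != "nondimensional":
        raise ValueError("general_integral expects a nondimensional initial state")
    if t < t0:
        raise ValueError("t must be >= t0")
    V, I_adap, I_dep = trajectory(n, init.V, init.I_adap, init.I_dep, t0, t)
    return ModelState(
        t=t, V=float(V), I_adap=float(I_adap), I_dep=float(I_dep),
        units_flag="nondimensional",
    )


@dataclass(frozen=True)
class Equilibrium:
    """A steady state of the nondimensional system.

    ``E0_family`` is the line of equilibria (V, 1+V, 0) that exists only for
    ``alpha = 0`` and ``beta = delta``; ``E1`` is the generic unique
    equilibrium (alpha/(beta-delta) - 1, alpha/(beta-delta), 0).
    """

    kind: str  # "E0_family" | "E1"
    V_star: float
    I_adap_star: float
    I_dep_star: float
    stability_label: str


@dataclass(frozen=True)
class StabilityReport:
    eigenvalues: tuple[complex, complex, complex]
    label: str
    region_conditions: tuple[str, ...]


def eigenvalues(beta: float, delta: float) -> tuple[complex, complex, complex]:
    """Eigenvalues of the Jacobian: -beta and ((delta-1) +/- sqrt(D))/2.

    ``D = (1+delta)^2 - 4 beta``; the pair is returned as complex conjugates
    when ``D < 0``.  The spectrum does not depend on the injected current.
    """
    if beta <= 0 or delta <= 0:
        raise ValueError("beta and delta must be positive")
    disc = (1.0 + delta) ** 2 - 4.0 * beta
    sq = cmath.sqrt(disc)
    l2 = 0.5 * ((delta - 1.0) + sq)
    l3 = 0.5 * ((delta - 1.0) - sq)
    if disc >= 0:
        l2, l3 = complex(l2.real), complex(l3.real)
    return (complex(-beta), l2, l3)


def classify_stability(beta: float, delta: float) -> StabilityReport:
    """Classify the generic equilibrium by region of the (beta, delta) plane.

    * ``stable_node_real``: delta < beta <= (1+delta)^2/4 with 0 < delta < 1
      (real negative pair; monotone approach);
    * ``stable_focus_damped``: beta > (1+delta)^2/4 with 0 < delta < 1
      (damped subthreshold oscillations);
    * ``center_sustained``: beta > 1 and delta = 1 (sustained oscillations);
    * ``unstable``: beta < delta with delta <= 1, or any beta with delta > 1
      (the rebound-spiking regime falls here);
    * ``boundary_degenerate``: the measure-zero boundaries (beta = delta with
      delta < 1; beta <= 1 with delta = 1 at equality cases).
    """
    if beta <= 0 or delta <= 0:
        raise ValueError("beta and delta must be positive")
    parab = (1.0 + delta) ** 2 / 4.0
    conds: list[str] = []
    if delta > 1.0:
        label = "unstable"
        conds.append("real_positive_branch" if beta <= parab else "focus_positive_real_part")
    elif delta == 1.0:
        if beta > 1.0:
            label = "center_sustained"
            conds.append("pure_imaginary_pair")
        elif beta < 1.0:
            label = "unstable"
            conds.append("real_positive_branch")
        else:
            label = "boundary_degenerate"
            conds.append("double_zero_eigenvalue")
    else:  # 0 < delta < 1
        if beta > parab:
            label = "stable_focus_damped"
            conds.append("complex_pair_negative_real_part")
        elif beta > delta:
            label = "stable_node_real"
            conds.append("real_negative_pair")
        elif beta < delta:
            label = "unstable"
            conds.append("real_positive_branch")
        else:
            label = "boundary_degenerate"
            conds.append("zero_eigenvalue_on_beta_equals_delta")
    evs = eigenvalues(beta, delta)
    return StabilityReport(eigenvalues=evs, label=label, region_conditions=tuple(conds))


def equilibria(n: NondimensionalParameters) -> list[Equilibrium]:
    """Steady states of the nondimensional system at the stored alpha."""
    a, b, d = n.alpha, n.beta, n.delta
    if a == 0.0 and b == d:
        # line of equilibria (Vbar, 1+Vbar, 0); report the resting member
        label = "stable" if d <= 1.0 else "unstable"
        return [
            Equilibrium(
                kind="E0_family", V_star=-1.0, I_adap_star=0.0, I_dep_star=0.0,
                stability_label=label,
            )
        ]
    V_star = a / (b - d) - 1.0
    return [
        Equilibrium(
            kind="E1", V_star=V_star, I_adap_star=a / (b - d), I_dep_star=0.0,
            stability_label=classify_stability(b, d).label,
        )
    ]


def voltage_sensitivities(
    n: NondimensionalParameters, init: ModelState, t0: float, t: float
) -> tuple[float, float]:
    """Sensitivities of V(t) to the after-spike initial currents.

    The derivative with respect to ``I_adap0`` is the exact closed form
    ``-beta H1``, strictly negative for t > t0 in the real-eigenvalue stable
    region: raising the after-spike adaptation current always delays the next
    threshold crossing, which is what makes inter-spike intervals monotone in
    the update sequence.  The derivative with respect to ``I_dep0`` is
    computed by central finite difference on the closed form and is positive.
    """
    dt = t - t0
    if dt < 0:
        raise ValueError("t must be >= t0")
    H1, _ = _h12(n.beta, n.delta, dt)
    dV_dIadap = float(-n.beta * H1)
    h = 1e-6
    Vp, _, _ = trajectory(n, init.V, init.I_adap, init.I_dep + h, t0, t)
    Vm, _, _ = trajectory(n, init.V, init.I_adap, init.I_dep - h, t0, t)
    dV_dIdep = float((Vp - Vm) / (2.0 * h))
    return dV_dIadap, dV_dIdep


def clamped_equilibrium(
    I_stim: float, p: DimensionalParameters, n: NondimensionalParameters | None = None
) -> tuple[float, float]:
    """Long-time membrane potential for subthreshold or negative currents.

    Returns ``(V_star_nondimensional, V_star_mV)``.  For
    ``I_stim_neg <= I_stim <= 0`` the equilibrium is clamped to interpolate
    linearly between the resting potential (at zero current) and the floor
    potential ``V_min`` (reached at ``I_stim_neg``, the potassium reversal
    regime); below ``I_stim_neg`` it saturates at ``V_min``.  For
    ``0 < I_stim < I_th`` the unclamped equilibrium applies.
    """
    if n is None:
        from .core import nondimensionalize

        n = nondimensionalize(p, I_stim)
    if I_stim >= p.I_th:
        raise ValueError("clamped_equilibrium requires a subthreshold or negative current")
    if I_stim > 0:
        V_star = n.alpha / (n.beta - n.delta) - 1.0
    else:
        alpha = I_stim / p.K
        alpha_neg = p.I_stim_neg / p.K
        V_min_star = -p.V_min / p.E_L
        if I_stim >= p.I_stim_neg:
            V_star = -1.0 + (1.0 + V_min_star) * alpha / alpha_neg
        else:
            V_star = V_min_star
    return V_star, -V_star * p.E_L
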