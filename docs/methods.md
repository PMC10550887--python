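# Methods

## The model

`aglif` implements an adaptive generalized leaky integrate-and-fire (A-GLIF)
point-neuron model for spike-time prediction in hippocampal CA1 pyramidal
cells and interneurons.  Between spikes the state
(V, I_adap, I_dep) obeys a linear three-variable system:

    dV/dt      = (1/C_m) [ (C_m/τ_m)(V − E_L) − I_adap + I_dep + I_stim ]
    dI_adap/dt = k_adap (V − E_L) − k_2 I_adap
    dI_dep/dt  = −k_1 I_dep

with spikes declared when V reaches the threshold V_th, followed by a fixed
refractory gap Δt_ref and a state reset.  Two structural identities,
k_adap = C_m k_1 k_2 and k_2 = −K/(C_m E_L), reduce the rescaled system
(t → t/τ with τ = 1/k_2, V → −V/E_L, I → −k_2 I/(E_L k_adap)) to three
parameters: the scaled current α = I_stim/K, the decay-rate ratio
β = k_1/k_2, and δ = 1/(k_2 τ_m).  They are enforced as hard constraints:
parameter files violating them are rejected, never adjusted.

All nonlinearity of real firing dynamics lives in the after-spike update of
the adaptation current, a Monod-type saturating function of the time χ
elapsed since stimulation onset (ms) and the stimulation current (pA):

    I_adap0(χ, I) = c + a e^{bI} χ/(d + χ)

returning the nondimensional adaptation value.  a > 0 produces
spike-frequency adaptation (lengthening inter-spike intervals), a < 0 the
reverse; the product a·b sets whether adaptation strengthens or weakens with
current; c is the value at onset and c + a e^{bI} the late-time plateau.

## Exact trajectories and their degenerate limits

The linear system is solved in closed form through two combined
exponentials, written in overflow-safe real form with r = (δ−1)/2 and
ν = √((δ+1)² − 4β)/2:

    H1 = e^{rΔt} sinh(νΔt)/ν,   H2 = 2 e^{rΔt} cosh(νΔt)

(trigonometric for complex ν, the analytic limit H1 → Δt e^{rΔt} within
10⁻¹⁰ of ν = 0, with the leading series correction retained).  No numerical
ODE integration is performed anywhere in the package; the simulator's test
suite uses fixed-step fourth-order Runge-Kutta integration purely as an
independent oracle.

The printed closed form has removable singularities at β = δ (the α terms)
and on the resonance curve β² + (β−1)δ = 0, where the depolarizing decay
rate −β coincides with a membrane eigenvalue.  Within 10⁻⁹ (scaled) of
either surface the implementation evaluates the analytic limit via
l'Hôpital's rule using the exact derivatives dH2/dβ = −Δt·H1 and
dH1/dβ = (2H1 − Δt·H2)/𝒜; the threshold balances the cancellation error of
the raw quotient (≈ machine-ε/distance) against the linearization error of
the limit (≈ distance), keeping both below 10⁻⁶ absolute.  Doubly
degenerate points (e.g. β = δ = 1/2, which lies on both surfaces) apply
both limits independently, which is exact because they act on disjoint
groups of terms.

## Stability constraints and the feasible region

The Jacobian eigenvalues are −β and ((δ−1) ± √((1+δ)² − 4β))/2,
independent of the injected current.  The package classifies the
(β, δ) plane into a real-eigenvalue stable node region
(δ < β ≤ (1+δ)²/4, 0 < δ < 1), a damped-focus region (β above the
parabola, δ < 1), a sustained-oscillation line (δ = 1, β > 1), and the
unstable remainder, with measure-zero boundaries reported as degenerate
rather than force-fitted.  The rebound-spiking regime (unstable, δ > 1) is
excluded from all fitting.

Requiring the subthreshold equilibrium to sit below threshold for every
current under the rheobase I_th yields the working constraints

    0 < δ < 1,
    α_th < (1 + Ṽ_th)(δ−1)²/4,
    α_th/(1 + Ṽ_th) + δ < β ≤ (1+δ)²/4,

with α_th = I_th/K and Ṽ_th = −V_th/E_L.  The equivalent dimensional
inequalities (a lower bound on K and a band on k_adap) are evaluated as
redundant cross-checks and agree in verdict on 10⁴ random draws in the test
suite.  These constraints are narrow: they force K ≳ 14·I_th for typical
CA1 potentials, hence a short nondimensional time scale; the slow
physiological inter-spike intervals emerge from adaptation values close to
the voltage-rise bound H = α/β + I_dep⁰ + (δ/β)(1 + V⁰), not from slow
membrane dynamics.

The bound H is advisory during simulation: the after-spike update enforces
positivity (values clipped at zero) and only flags H violations, because
outside the fitted current range enforcing H would be overly restrictive.
Out-of-range corrections translate the Monod function vertically, choosing
the mixing weight η on a 101-point grid in [0, 1] to stay closest to the
original coefficients subject to positivity, with the fallback c → c − L
(L the negative value at the first spike time) when no grid value
qualifies.

## Simulation

The event loop evaluates V on a 0.05 ms grid (vectorized over the closed
form), brackets the first upward threshold crossing, and refines it by
bisection to 10⁻⁹ ms; spike times are therefore grid-independent up to
bracketing, which a test verifies by halving the scan step.  Spike time is
the crossing instant; re-initialization happens Δt_ref = 2 ms later.

Firing block: a train is classified as blocked when the last spike plus
twice the final inter-spike interval precedes the stimulation end.  Blocking
currents are grouped into maximal runs on the tested grid; each run yields a
cutoff line through the anchor points (I, t_last + ISI_last/2) at its
endpoints, extended through the nearest non-blocking firing current for
single-current runs.  The line's validity threshold is the midpoint between
that firing current and the blocking current adjacent to it — the rule that
reproduces all three published worked thresholds (300, 500, 700 pA) where
the simpler midpoint-of-interval prose rule fails for degenerate runs.
During simulation a crossing at or beyond the applicable cutoff is
discarded and the train terminated.

Piecewise-constant protocols: at a downward step that stays above rheobase,
V and I_adap are continuous and I_dep is re-seeded as
I_adap(t̄) + Θ*·ᾱ/β, where Θ* ≥ 0 is estimated from the two most recent
voltage samples (spacing = trace step, default 0.1 ms, recomputed from the
closed form so the correction does not depend on trace recording); at an
upward step the state carries over and the Monod clock origin dilates,
t_start → t_start(1 + (I_prev − I_th)/I_prev); a step to or below rheobase
relaxes the state toward the (clamped) equilibrium and resets the onset
rules.  A boundary falling inside a refractory gap defers to the after-spike
re-initialization at the gap's end.  Negative currents use a clamped
equilibrium interpolating linearly between E_L at zero current and the
potassium floor V_min = −90 mV at the calibration current I_stim_neg
(−185 pA for the reference cell), saturating below it.

## Fitting

The cost is spike-time only: the absolute first-spike error per current plus
hinge penalties for experimental inter-spike intervals outside the
attainable band [ISI at I_adap⁰ = H, ISI at I_adap⁰ = 0], both ends
computed with the exact threshold solver (during the search the solver uses
a 0.1 ms bracketing grid and 10⁻⁵ ms bisection — far below any difference
the search can exploit).  A real-coded genetic algorithm (tournament size 3,
blend crossover, Gaussian mutation whose width anneals by a factor of ten
over the run, elitism of one, seeded and bit-reproducible) searches a
genome expressed in constraint-space coordinates — I_th, C_m, K, the
fraction of the admissible δ interval, the fraction of the admissible β
band, I_dep_start, I_dep⁰ — so every individual satisfies the stability
constraints by construction.  Because the cost landscape has many
near-optimal basins and a single population collapses into one of them
early, the population is split into independent islands (default two, no
migration) sharing the same total evaluation budget; basin diversity is
what the downstream model selection feeds on.  Defaults follow the
published procedure (population 200, 250 generations, stop when the best
cost improves by ≤ 2% between consecutive generations, checked after a
burn-in of 10 generations); the recovery benchmark disables the stop rule
to realize its stated generation budget.

Between spikes V(t) is affine in I_adap⁰ with slope −βH1, so each
experimental ISI inside the band inverts in closed form into the unique
after-spike value that places the crossing at the observed interval,
verified by one forward threshold solve (with a bisection fallback for the
rare case of an earlier crossing); the cost is blind to these values, so
they are recovered deterministically rather than searched.  The Monod
coefficients are fitted by bounded multi-start nonlinear least squares
(trust-region reflective, starts around moment-based guesses, both
admissible sign regimes), with near-constant sequences flagged as the
degenerate a ≈ 0 case.

The spike-time cost is degenerate — many parameter sets zero it — yet
candidates differ in how faithfully the complete fitted model (parameters
plus interpolated updates) reproduces the raster: interpolation residuals
of order 10⁻³ in the update value accumulate over dense trains into
end-of-window spike-count drift, especially near rheobase where the
interval's sensitivity to the update diverges.  The tie is therefore
resolved by model selection on the training raster itself: the best
individuals of each island (within 2 ms total cost of the overall best) are
taken through the full pipeline — inversion, Monod interpolation,
simulation of every training current — and the fit with the fewest
spike-count mismatches is returned, tie-broken by the Monod interpolation
residual, which measures consistency with the model's own assumption of
Monod-shaped updates, then by cost.  The selected candidate is finally
polished by a short seeded hill climb (default 12 small genome
perturbations, accepted only when the pipeline score improves).  Model and reference rasters are compared with the univariate
Mann-Whitney U test with continuity correction, per current and pooled; the
bivariate spatial-rank variant and Hotelling t² fallback used for two-sided
spike-time/current samples are out of scope here and replaced by this
per-current + pooled scheme.

## Synthetic ground truth

No raw recordings ship with the package; the `synth` module generates fully
specified cells and the rasters they produce under the standard protocol
(200–1000 pA in 200 pA steps, 400 ms).  Draws are made directly in
constraint space (δ, then α_th and β as fractions of their admissible
intervals) and the Monod coefficients are scaled to the cell's own H bound
at the lowest suprathreshold protocol current, with the plateau capped at
0.95·H at every protocol current — mirroring the fitting requirement that
the update stay below H inside the fitted range.  This yields 8–70 spikes
per 400 ms train and inter-spike intervals of roughly 8–50 ms, matching the
order of magnitude of CA1 responses.  Five phenotypes cover adapting
(a > 0, b > 0), inverse-current adapting (a > 0, b < 0), near-constant-ISI,
blocking (with a synthesized cutoff rule on 600/800 pA), and high-rheobase
cells.  Optional spike-time jitter is truncated Gaussian, re-spaced to
preserve refractory separation and counts.  The fixtures do not emulate
channel noise, spike shapes, or the subthreshold waveform of biophysical
models, so passing tests certify the fitting machinery, not its behavior on
raw voltage traces.

## Problem sizes and numerical choices

The test suite verifies the closed form against vectorized RK4 (step 10⁻³,
horizon 50 time units) on 200 stable draws at 10⁻⁶ absolute tolerance; the
stability map on a 200×200 grid against batched numeric eigendecomposition;
subthreshold silence on 50 random constraint-satisfying cells over 10⁴ ms;
and ground-truth recovery on the five phenotype cells at a reduced GA budget
(population 40, 60 generations) — exact spike counts at every current and
first-spike times within 2 ms.  Structural identities are checked at 10⁻⁹
relative, unit round-trips at 10⁻¹²; both reflect closed-form arithmetic
with no integration error.  Monod-fit noiseless recovery reaches 10⁻⁶ RMS
in fitted values; coefficient identifiability in (a, b) is poorer than value
identifiability, which is why recovery is asserted on fitted values.

## Known limitations

Only spike times are fitted; subthreshold voltage waveforms are reproduced
qualitatively at best.  Continuous time-varying stimuli (ramps, noise,
synaptic conductances) are outside the protocol model.  The Θ* correction
depends on the chosen sample spacing Δt, which the source procedure leaves
unspecified; it is configurable with a 0.1 ms default.  Near-rheobase
currents make inter-spike intervals extremely sensitive to the adaptation
value (dISI/dI_adap⁰ diverges as I_adap⁰ → H), so small interpolation
errors there translate into large timing errors — the Monod-consistency
tie-break mitigates but cannot eliminate this.
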