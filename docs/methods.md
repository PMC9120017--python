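# Methods

## Kinetic schemes and rate matrices

A mechanism is declared as a list of directed transitions between
integer-labelled states. Each transition carries a named rate constant
(s⁻¹ unimolecular, M⁻¹ s⁻¹ when multiplied by a ligand concentration),
an optional ligand dependence (Ca²⁺ or blocker, molar), and an optional
voltage partitioning: the rate is multiplied by *v*^(δ/2) with
*v* = e^(−zVF/RT) for the forward direction and its reciprocal for the
backward one, so the equilibrium constant of the step carries the full
apparent valence δ·z. Constants: F = 96485.332 C/mol,
R = 8.314462 J/(mol·K); the default temperature is 293.15 K (20 °C,
the recording temperature), overridable everywhere. Voltages are volts
and concentrations molar internally; mV and µM appear only at the CSV
and CLI boundary.

Two schemes ship with the package. The **open-block** scheme has eight
states: a seven-state Ca²⁺-gating core (state 0 open; Ca²⁺-accelerated
steps 4→2, 5→3, 6→5 whose reverses and the 3→5, 5→6 steps carry the
Ca²⁺ voltage factor) plus a dead-end blocked state 7 reached from the
open state with rate b·k07·v₀₇^(δᵇ/2). The **closed-antagonism**
scheme has ten states: the same core with blocker binding instead on
closed states 3, 5 and 6 (dead-end states 7, 8, 9). In the transcribed
open-block scheme the 2→4 step carries no voltage factor even though
its reverse (4→2) does, and 4↔5 is voltage-independent while its
parallel pathway steps are not; the scheme is reproduced exactly as
such, with an opt-in `k24_voltage=True` flag that attaches the
symmetric forward factor for users who consider the asymmetry a
transcription artifact. Microscopic reversibility is deliberately not
enforced on the Ca²⁺-binding cycle.

## Spectral solvers

Equilibrium occupancy uses the rank-1 projector of the zero eigenvalue
of **Q**; time courses use the full modal sum. Numerical policy:

- the zero eigenvalue is the unique λ with |λ| < 10⁻⁹·max(1, max|λ|);
  zero or several qualifying eigenvalues raise an error (a reducible
  chain has no unique stationary distribution);
- the decomposition must reconstruct **Q** to a relative Frobenius
  error below 10⁻⁸, else the matrix is treated as defective;
- complex eigenpairs (possible without detailed balance) are kept
  through the algebra; results are cast to real only after the
  imaginary residue is verified below 10⁻⁹;
- returned occupancies have tiny negative entries (> −10⁻⁹) clamped to
  zero and are renormalized; larger violations raise.

Concentration jumps are piecewise-constant conditions: each segment
builds a new generator at its own conditions and relaxes the occupancy
reached at the end of the previous segment; the first segment starts at
its own equilibrium. Continuously ramped stimuli and stiff-ODE
integration are out of scope — the spectral form is exact for constant
conditions.

## Dose–response analysis

Block curves are ratios of equilibrium open probabilities
P_open(b)/P_open(0) (steady-state block, not kinetic endpoints); Ca²⁺
activation curves are absolute P_open(x), not renormalized, so the
saturating plateau below 1 set by the distal equilibria is visible.
Hill fits initialize IC₅₀ at the log-interpolated half-response
crossing with h = 1, bound IC₅₀ two decades beyond the sampled grid and
h in (0, 10], optimize IC₅₀ on a log scale, and let h float per curve.
Curves spanning less than 0.2 in response are fitted but flagged
poorly determined. Responses are never clipped to [0, 1]; noisy
observations may exceed the bounds and the fits tolerate that.

For the open-block topology the identity IC₅₀ = K_d(V)/P_open(V, x)
with Hill slope exactly 1 follows from dead-end-state algebra; the
package nonetheless always computes curves through the full equilibrium
solve, so arbitrary schemes are handled identically, and the identity
serves as a cross-check in the test suite.

## Permeation model

The barrier model is evaluated with u = zFV/RT. Its middle term has a
removable singularity at u = 0; for |u| < 10⁻⁴ it is computed from a
third-order series (limit (n−2)/σ_h), keeping the current continuous
across the branch switch to better than 10⁻¹⁰ relative, and the exact
branch uses `expm1` to stay accurate at small |u|. The barrier count
is fixed by configuration (default n = 3, the minimal scheme: outer,
middle, inner); the amplitude A is a single fitted scale because its
two physical factors are not separately identifiable. The packaged
default condition is symmetric 150 mM Cl⁻. I–V fits require at least
six distinct voltages covering both polarities.

## Estimation engine

All fits use bound-constrained least squares (trust-region reflective)
on named parameters with per-parameter transforms: rate constants,
IC₅₀, σ values and amplitudes are optimized in log space for
positivity; electrical distances linearly in [0, 1]. The composite
objective is the unweighted sum of squared deviations over all blocks
(inhibition, Ca²⁺ activation, I–V) of a dataset, as fitted in the
original analysis; an optional per-block SEM weighting exists but is
off by default. A solver failure inside the objective contributes a
large constant residual per observation and a flag instead of aborting,
which keeps optimizers alive near degenerate corners.

Confidence intervals are linearized: with J the Jacobian at the
optimum, s² = ssq/(n_obs − n_free) and Cov = s²(JᵀJ)⁻¹, each parameter
gets estimate ± t₀.₉₇₅,dof·stderr, formed on the internal
(possibly log) scale and mapped back — intervals of positive
parameters therefore stay positive and always contain the estimate.
The t quantile (rather than a plain normal) is a package choice that
behaves sensibly at small n_obs; the original analysis states only
that Jacobian-based 95 % intervals were used. A condition number of
JᵀJ above 10¹² marks parameters unidentifiable: the result is flagged
and the interval reported unbounded. Standard errors propagate through
sums/differences in absolute quadrature and through products/quotients
in relative quadrature.

Blocker fits hold the gating rates fixed by default (two-stage logic:
gating characterised separately, block parameters estimated on top);
passing rate names in `free` unlocks joint fitting. Optional seeded
random restarts jitter the initial point and keep the best optimum;
everything is deterministic given identical inputs.

## Synthetic data and the packaged calibration

The generators emulate inside-out patch experiments: per replicate,
each observation is the mechanism-derived mean response plus additive
Gaussian noise (default σ = 0.03 on the normalized current with
6 replicates, giving SEM ≈ 0.012, comparable to published error bars;
the true per-point noise of the recordings is not recoverable from
printed SEMs, so σ is a package choice recorded in provenance).
Optional rundown multiplies the mean by (1 − r)^sweep before noise;
correction fits a per-replicate geometric drift to interleaved
blocker-free reference sweeps and divides it out (the published
reference-sweep protocol itself is not reproduced). The default design
mirrors the measured one: Ca²⁺ ∈ {400 nM, 800 nM, 2 µM}, ±80 mV,
12 log-spaced blocker concentrations 0.1–100 µM. Every generator is a
pure function of (inputs, seed), and generated tables carry a
provenance record (seed, truth parameters, design, noise).

The gating rate constants of the activation core are not published as
numbers, so the package ships its own calibration, chosen once: the
Ca²⁺ activation midpoint sits near 0.3 µM at 0 mV with pronounced
voltage dependence (δ_Ca = 0.30, z_Ca = +2), in the physiological
range for this channel, and the closed→open rate k10 is solved exactly
from closed-subchain flux balance so that P_open(2 µM Ca²⁺, 0 mV) =
0.90 — the value forced by consistency of the reported
K_d(0 mV) = 3.6 µM with the observed IC₅₀ ≈ 4 µM through
IC₅₀ = K_d/P_open. The planted blocker truth for recovery benchmarks
is K_d(0 mV) = 3.6 µM, δ_b = 0.27, z_b = −1 (the blocker binds
deprotonated); both valences are parameters, not constants, so the
sign convention can be flipped. Under this calibration the Ca²⁺-free
chain is trapped in the distal closed state (no basal activity), so
blocker-free normalization at zero Ca²⁺ is reported as a degenerate
condition rather than a curve.

What passing tests show — and what they do not: synthetic data are
generated by the same model family that is fitted, with homoscedastic
Gaussian noise and exactly geometric rundown. Recovery and coverage
results therefore validate the correctness of the solvers, objectives
and interval construction, not robustness to model misspecification,
capacitance or series-resistance artifacts, single-channel noise, or
non-exponential rundown, none of which the generator emulates.

## Problem sizes

The default benchmark fits 432 observations (3 Ca²⁺ × 2 voltages ×
12 concentrations × 6 replicates) with two free parameters; property
tests use randomized generators up to 10 states and batches of 100
draws for the solver-oracle and IC₅₀-identity checks, 100 seeded
refits for coverage, and 50 seeds for noisy I–V recovery — sizes at
which the full suite completes in well under a minute.

## Known limitations

- No stochastic single-channel simulation; all observables are
  ensemble occupancies.
- No enforcement of microscopic reversibility; user-declared schemes
  violating detailed balance are solved as given (complex eigenmodes
  are handled, but physically questionable schemes are not diagnosed).
- The closed-antagonism parameter set used in tests is illustrative:
  its blocker affinities are not constrained by published estimates.
- Unweighted least squares treats all blocks equally; heteroscedastic
  designs should enable SEM weighting explicitly.
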