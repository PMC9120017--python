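# gatekit

Markov-state analysis of ion-channel gating, open-channel block, and
permeation from patch-clamp dose–response data.

## The problem

Small-molecule blockers of the calcium-activated chloride channel
TMEM16A, such as the compound 1PBC, inhibit current in a way that
depends on membrane voltage and on the intracellular Ca²⁺ concentration
that gates the channel. Distinguishing *open-channel block* (the
blocker binds only the conducting conformation) from *closed-state
antagonism* (it binds resting states) requires quantitative modelling:
both hypotheses predict sigmoidal concentration–response curves, but
they predict opposite Ca²⁺ dependence of the apparent potency.

`gatekit` is for electrophysiologists and modellers who want to encode
such hypotheses as continuous-time Markov schemes, solve them exactly,
and fit them to normalized current measurements.

## The models

**Gating and block.** A kinetic scheme is a generator matrix **Q**
whose off-diagonal entries are transition rates; ligand-binding steps
are multiplied by the molar Ca²⁺ (*x*) or blocker (*b*) concentration,
and voltage-partitioned steps by *v*^(δ/2) with
*v* = e^(∓*zVF*/*RT*), where δ is the fraction of the membrane field
the charge *z* traverses. Equilibrium occupancies come from the
eigendecomposition **Q** = **V Λ V**⁻¹ by projecting onto the zero
mode, P(∞) = P(0)·(**V**₍λ₌₀₎**V**⁻¹₍λ₌₀₎), and concentration-jump
relaxations from P(t) = P(0)·Σᵢ **A**ᵢ e^(λᵢt). The packaged
8-state open-block scheme appends a dead-end blocked state to the open
state; for that topology the normalized current is exactly
I/I₀ = 1/(1 + b·P_open/K_d(V)), so IC₅₀ = K_d(V)/P_open(V, x) with
Hill slope 1 and K_d(V) = K_d(0)·e^(δ_b z_b VF/RT). A 10-state
closed-antagonism scheme is packaged as the contrast model.

**Dose–response.** Curves are fitted to the Hill equation
I/I_max = 1/(1 + (IC₅₀/b)^h) (or its falling mirror for inhibition)
with Jacobian-based 95 % confidence intervals.

**Permeation.** Instantaneous I–V relations follow a minimal barrier
model with relative crossing rates σ_h (middle barrier) and σ_β
(innermost barrier); ΔE_a = −RT ln σ converts them to activation-energy
differences relative to the outermost barrier.

**Estimation.** All fits go through one bound-constrained least-squares
engine (rates log-parameterized, electrical distances in [0, 1]) with
95 % intervals from the linearized covariance σ²(JᵀJ)⁻¹ and a
t-quantile, plus closed-form propagation of standard errors through
sums, differences, products and quotients.

Because raw recordings behind the published figures are not available
as numeric tables, a seeded synthetic-data module generates
replicate-structured dose–response, Ca²⁺-activation, I–V and
concentration-jump datasets (Gaussian noise on the normalized response,
optional multiplicative rundown drift) for every pipeline stage.

## Worked example

```sh
gatekit recover-benchmark --seed 1
```

generates the default synthetic study — blocker concentration–response
at Ca²⁺ ∈ {400 nM, 800 nM, 2 µM} and ±80 mV, 12 concentrations from
0.1 to 100 µM, 6 replicates, noise σ = 0.03 — at the planted truth
(K_d(0 mV) = 3.6 µM, δ_b = 0.27), refits the blocker parameters with
gating held at the packaged calibration, and prints

```
K_d(0 mV) = 3.599 uM  (95% CI 3.534 - 3.665)
delta_b   = 0.2739  (95% CI 0.2682 - 0.2797)
```

i.e. the dissociation constant of the blocker at 0 mV and the fraction
of the membrane field its charge senses, both recovered within their
confidence intervals. The same pipeline is available in Python:

```python
import gatekit as gk

spec = gk.packaged_mechanism("open_block")
params = gk.default_calibration()
data = gk.generate_block_dataset(spec, params,
                                 gk.BlockDesign(), gk.NoiseModel(seed=1))
result = gk.fit_block_mechanism(data, spec, params)
print(result.estimates)   # {'kd_1pbc': 3.5986e-06, 'delta_b': 0.27395}
```

Other subcommands: `simulate-block`, `simulate-iv`, `simulate-jump`,
`fit-hill`, `fit-block`, `fit-iv` (see `gatekit --help`).

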