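# Methods

## Generative model

Each source is a canonical microcircuit of four populations (spiny stellate,
superficial pyramidal, inhibitory interneuron, deep pyramidal).  Every
population carries a voltage/conductance pair obeying a damped second-order
synaptic convolution

    v̇ = g,
    ġ = κ (afferent) − 2 κ g − κ² v,

with per-population rate constants κ.  In the 1-based subscript convention
odd state subscripts are voltages and even ones conductances; the flat state
vector has 8 entries per source (40 for the five-source network).  The zero
state with zero input is an exact equilibrium, and at prior-mean parameters
the Jacobian there has all eigenvalues in the left half-plane (max Re
≈ −22 s⁻¹ for the default network; asserted in the test suite).

**Presynaptic transform.** Afferent drive sums presynaptic firing rates
through connection gains.  The firing transform is a centred sigmoid
implemented as `f(v) = B·tanh(gain·v/B)` with `gain = 1`, `B = 4` (mV-scale
units): odd, monotone, bounded, `f(0) = 0` so the resting fixed point is
preserved, and with unit slope at the origin so linearised gains equal the
connection templates.  The element-wise (Hadamard) structure of the dynamics
is the firm constraint; the specific sigmoid is a design choice consistent
with convolution-based neural mass practice.

**Rate constants.** Template κ = (256, 128, 64, 32) s⁻¹ for (ss, sp, ii,
dp), i.e. time constants of 4–31 ms.  With the 60 ms input latency these
place simulated response peaks at ≈70–100 ms after the event, matching the
latency regime of the evoked responses this model targets.

**Intrinsic wiring.** Within a source (rows = target, columns = source, in
mV per unit presynaptic rate):

|        | ss    | sp   | ii   | dp   |
|--------|-------|------|------|------|
| **ss** | −128  |      |      |      |
| **sp** | +128  | −64  | −64  |      |
| **ii** | +64   |      | −32  |      |
| **dp** | +32   |      | −16  | −16  |

i.e. recurrent self-inhibition on every population, stellate excitation of
both pyramidal populations and of interneurons, and interneuron inhibition
of both pyramidal populations.  Ignoring self-loops this intrinsic graph is
feed-forward, which keeps each source unconditionally stable at template
parameters.  The nonzero entries fall into three classes (self, excitatory,
inhibitory), each carrying one intrinsic log-scaling `g`.

**Extrinsic wiring.** Forward (ascending) connections from superficial
pyramidal cells target spiny stellate (A1, template 256) and deep pyramidal
(A2, template 64) populations of the higher source; backward (descending)
connections from deep pyramidal cells inhibit superficial pyramidal (A3,
template 64) and interneuron (A4, template 32) populations of the lower
source.  Each network edge carries one log-scaling shared by its two
sub-pathways.  Template magnitudes were chosen so that per-stage DC transfer
is of order one (activity propagates across the hierarchy), the
forward×backward loop gain stays below one (stability margin), and the
defining qualitative effect of the study — reduced backward inhibition
raising the late-condition rTPJ superficial-pyramidal amplitude — holds
under the plain peak-amplitude metric.

**Network.** Five sources: lFEF, rFEF, lIPS, rIPS, rTPJ.  Forward edges
rTPJ→lFEF, rTPJ→rFEF, lIPS→lFEF, rIPS→rFEF with matching backward edges.
The rTPJ sits lower in the visual hierarchy than the FEFs, so rTPJ→FEF is
forward; IPS→FEF is treated the same way within the dorsal network (FEF
highest).  Interhemispheric FEF–FEF and IPS–IPS edges are excluded by
default.  Exogenous input drives the spiny stellate populations of rTPJ and
both IPS (the lower sources); conduction delays are omitted so the flow
remains an ODE.  Condition-specific effects are log-slopes `b` on the four
rTPJ↔FEF edges (numbered 1: rTPJ→lFEF, 2: rTPJ→rFEF, 3: lFEF→rTPJ,
4: rFEF→rTPJ), multiplying the per-condition design covariate; with the
parametric design `[0..15]` a constant slope is a monoexponential coupling
trajectory `100·exp(k·b)` percent of baseline.

## Forward simulation and observation

The input is a Gaussian bump (default onset 60 ms, dispersion 16 ms,
amplitude 1).  Integration uses fixed-step classical RK4 at the 600 Hz
sampling rate with internal sub-stepping (4 sub-steps by default; 2 inside
the inversion loop), from the zero state over 0–250 ms (150 samples).  A
fixed-step scheme makes every output bit-reproducible across platforms; the
step is ~25× inside the RK4 stability bound of the fastest mode, and halving
it changes the solution by far less than 0.5% (asserted).  Any state
exceeding 10⁶ raises an explicit blow-up error.  Sensors (4 channels by
default, standing in for the few spatial modes retained after dimensionality
reduction of real recordings) see the superficial-pyramidal voltage of each
source through a fixed, documented lead-field matrix; the observation stage
is strictly linear.

## Inversion (variational Laplace)

Free parameters (22 by default): extrinsic log-scalings `a` (8), modulatory
log-slopes `b` (4), input log-gains `c` (3), intrinsic class log-scalings
`g` (3), rate-constant log-scalings `κ` (4).  Prior means are zero ("no
change from template"); prior variances 1/16 for a, b, g; 1 for c; 1/128
for κ.  Lead-field gains (unit prior variance) and input timing are held at
their known synthetic values by default: freeing the lead gain introduces a
pure scale degeneracy with the input gain; it can be freed via the `free=`
argument.  Observation noise is white with a single log-precision λ,
Gaussian prior N(4, 16).

The free energy is `F = accuracy − KL(q‖p)`: the expected Gaussian
log-likelihood of the residuals under the posterior (via local
linearisation, including the trace term) minus the Gaussian KL complexity,
plus the corresponding λ terms when the noise is estimated.  Ascent is
Gauss–Newton with Levenberg–Marquardt regularisation: a trial step solves
`(H + ν·diag H) δ = ∇F` with `H = e^λ JᵀJ + Π₀`; steps that would lower F
are rejected and ν increased (×8), accepted steps decay ν (÷2), so the
free-energy trace over accepted iterations is non-decreasing by
construction.  Ties (|ΔF| below numerical tolerance) are accepted and count
toward convergence.  λ is updated by damped Newton steps interleaved with
the parameter updates (coordinate ascent, for stability over joint updates).
Convergence is declared after 4 successive accepted steps with gain below
0.01 nats (max 128 iterations; `max_iter = 0` returns the prior with its
free energy).  Jacobians are central finite differences (ε = 10⁻³ on the
log-scalings), evaluated in one vectorised batch integration.  The posterior
covariance is the inverse curvature at the optimum, symmetrised with a
relative eigenvalue floor of 10⁻¹².  On linear-Gaussian problems the scheme
reproduces the conjugate posterior and the exact log evidence to machine
precision (asserted at 10⁻⁶).

A deliberate asymmetry avoids the inverse crime in recovery studies:
datasets are generated with 4 RK4 sub-steps while the inversion model uses
2, so the fitted model is never bit-identical to the generator.  The
resulting discretisation mismatch (~0.2% of signal) only matters at
noiseless SNR, where it acts as a small effective noise floor.

## Model comparison and averaging

Reduced models share the likelihood and differ only in priors: switching an
effect off means a reduced prior with mean 0 and variance 10⁻⁸ (a
numerically stable stand-in for the zero-variance limit).  The evidence
change and reduced posterior follow the standard Gaussian identities (see
`compare.py`); the identity reduction returns exactly ΔF = 0.  All 2ᵏ
keep/remove patterns are enumerated in binary-counting order (effect 1 =
least significant bit; model 1 removes everything, model 2ᵏ is the full
model — this package's numbering is its own convention and is not assumed
to match any external report's model indices).  Posterior model
probabilities are a max-subtracted softmax of the free energies under a
uniform model prior (configurable), and the Bayesian model average is the
moment-matched Gaussian of the probability-weighted mixture over all
models, not only the winner.  On linear-Gaussian fixtures BMR agrees with
brute-force re-inversion to 10⁻⁶; on nonlinear CMC fixtures agreement
within 0.5 nats is asserted.

## Synthetic data and recovery studies

`generate_dataset` adds white Gaussian sensor noise to the noise-free
predictions, scaled so that 10·log₁₀(signal power / noise power) equals the
requested SNR over the whole epoch (insensitive to window choice); an
optional channel-correlated component exists for robustness testing.  All
randomness flows through one seeded generator; a stored `GroundTruth` (spec,
parameters, seed) regenerates any dataset bit-identically.  The default SNR
of 10 dB is a fixture convention — the realised SNR of grand averages over
thousands of real events is not knowable from published material.

The default scenario fixes true modulations (0, +0.1, −0.4, −0.4) on edges
1–4: the sign pattern mirrors the reported phenomenon (backward
disinhibition plus a modest right-forward increase), while the magnitudes
are fixture choices sized to be detectable at desk scale.  What the
generator deliberately does not emulate: real MEG noise is neither white
nor channel-independent, real lead fields are unknown and estimated, real
grand averages mix subjects with heterogeneous anatomy, and the "true
model" never lies inside the fitted family.  Passing recovery tests
therefore demonstrates internal consistency of the pipeline, not field
performance on real recordings.

`recovery_experiment` runs generate → invert → BMR → BMA per replicate
(default 20 replicates, max 64 iterations each; ~1.5–3 s per replicate, a
problem size chosen so the full study completes in about a minute).
Metrics use the full-model posterior: per-edge bias, RMSE, 90%
credible-interval coverage, sign accuracy (for truly-zero effects: the
fraction of intervals covering zero), and the exact-pattern hit rate of the
BMR winner.  The parameter-recovery study runs at 10 dB; the
model-selection study cycles SNR over (∞, 30, 25, 20, 15, 10) dB — an even
ladder over the noiseless-to-10 dB range.

## Known limitations

- **Detection of small effects at low SNR.** At 10–15 dB the marginal
  posterior sd of a forward modulation is ≈0.04–0.08, so a true effect of
  +0.1 sits at the boundary where BMR's complexity saving for removing the
  effect matches its accuracy cost: the keep/remove contest is near even
  odds, and the exact-pattern hit rate of the model-selection study is
  ≈20–30% at flat 10 dB and ≈70–80% over the SNR ladder.  This is a
  property of the study conditions (effect size vs prior sd 0.25, four
  channels, 150 samples, two conditions), not of the estimator: the same
  contest computed in closed form on the linearised model gives the same
  rates, and fully converged fits do not change the outcome.
- **Left/right backward collinearity.** With a symmetric network and
  symmetric truth, the two FEF deep-pyramidal traces are nearly identical,
  so the two backward modulations are individually weakly determined
  (posterior correlation ≈ −0.9; their sum is sharp).  Sign accuracy and
  coverage are unaffected, but individual backward magnitudes carry wide
  intervals even at high SNR.
- **BMR on nonlinear models** is exact only to the extent the Gaussian
  posterior approximation holds; the 0.5-nat agreement bound with direct
  re-inversion is an empirical, fixture-level statement.
- **Single noise group.** One log-precision is shared by all channels;
  per-channel-group precisions would be a modest extension.
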