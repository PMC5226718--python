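# Model and methods

## The network

Five populations, all-to-all connected, no synaptic delays, no
plasticity. Of N = 1000 leaky integrate-and-fire neurons, 800 are
excitatory — three selective pools of f·N_E = 160 cells coding the
left, right and sure targets, plus 320 nonspecific cells — and 200 are
inhibitory. Membrane dynamics of each cell:

    C_m dV/dt = −g_L (V − V_L) − I_AMPA,ext − I_AMPA,rec − I_NMDA − I_GABA

with conductance-based synaptic currents. AMPA and GABA gating
variables jump by 1 on a presynaptic spike and decay exponentially
(τ_AMPA = 2 ms, τ_GABA = 10 ms); NMDA channels rise through an
auxiliary variable x (τ_rise = 2 ms) and saturate,
ds/dt = −s/τ_decay + α·x·(1 − s) with α = 0.5 ms⁻¹ and
τ_decay = 100 ms, and carry the magnesium block
1/(1 + [Mg²⁺] e^(−0.062 V)/3.57). A spike is emitted when V ≥ −50 mV
outside the refractory period (2 ms excitatory, 1 ms inhibitory); V
then resets to −55 mV.

Structured weights implement competition: w₊ = 1.5 inside a selective
pool, w₋ = 0.878 from every other excitatory pool onto a selective
pool, weight 1 everywhere else (including all inhibitory connections;
the inhibitory-to-inhibitory weight, not fixed by the published
parameter set, is taken as 1). Autapses are excluded.

The leak conductances are not part of the published parameter table;
we use the standard values of this model family, 25 nS (excitatory)
and 20 nS (inhibitory), giving membrane time constants of 20 ms and
10 ms. The attractor structure is extremely sensitive to this choice —
a 1 nS change in either class destroys the spontaneous state — which
is itself evidence that these are the intended values: the published
landscape only exists in their immediate neighborhood.

Every neuron receives an independent external Poisson drive through
AMPA synapses. The 800 sources × 3 Hz background is realized as one
aggregated Poisson process of 2400 Hz per neuron (statistically
identical, much cheaper). Stimulus-related inputs add to this
aggregate rate.

## Stimulation protocol

A trial is: 500 ms spontaneous activity; direction targets on (input
to L and R); 500 ms later the motion stimulus (λ + Δλ to L, λ − Δλ to
R, for 100–500 ms); a delay; the sure target to pool S 500 ms after
motion offset (free-choice trials only, sustained to trial end); and
an 80 Hz / 100 ms saccade-related signal to L, R and S at the end of
the trial. The trial ends 1000 ms after sure-target onset; the go cue
is the onset of the saccade signal.

Target inputs are double exponentials,
A_fast·e^(−t/τ_fast) + A_slow·e^(−t/τ_slow) + asymptote. The
amplitudes are not published and are the model's calibrated elements
(the original study likewise tuned its target inputs to match the
monkeys' sure-choice proportions). Defaults:

| input | A_fast | τ_fast | A_slow | τ_slow | asymptote |
|---|---|---|---|---|---|
| direction targets (L, R) | 120 Hz | 80 ms | 55 Hz | 5000 ms | 0 Hz |
| sure target (S) | 185 Hz | 80 ms | 68 Hz | 5000 ms | 5 Hz |

The slow component represents the sustained visibility of the targets
on the screen until the saccade. It was calibrated — once, against
reduced pilot ensembles at λ = 50 Hz — so that (i) both direction
pools sit at comparably elevated rates (~10–15 Hz) at motion onset,
(ii) the winning pool can sustain rates near the 28 Hz decision
threshold through the delay, (iii) fewer than roughly 5–10% of trials
remain undecided at the go cue, and (iv) sure-choice fractions at
λ = 50 Hz are in the experimentally observed range (~0.5 at zero
coherence). The sure-target input ended up needing a peak comparable
to the direction targets': pool S ignites from a suppressed state
against established competitors, which demands a stronger kick than
the "lower stakes" ordering of the inputs would suggest.

## Mean-field reduction

Each population x is described by the mean μ_x and fluctuation σ_x of
its membrane potential and an effective time constant τ_x = τ_m/S_x,
where S_x is the total effective conductance in units of the leak:

    S_x  = 1 + T_ext ν_ext + T_AMPA n_x^AMPA + (ρ1 + ρ2) n_x^NMDA + T_I n_x^GABA
    μ_x  = [ (T_ext ν_ext + T_AMPA n^AMPA + ρ1 n^NMDA) V_E
             + ρ2 n^NMDA ⟨V_x⟩ + T_I n^GABA V_I + V_L ] / S_x
    σ_x² = g_ext² (⟨V_x⟩ − V_E)² ν_ext τ_AMPA² τ_x / (g_m² τ_m²)

(the division of μ_x by S_x makes the leak-only limit μ = V_L exact).
Drives are population-fraction- and weight-weighted sums of rates
(AMPA, GABA) or of the stationary NMDA activation ψ(ν) (NMDA). The
NMDA linearization constants use β = 0.062 mV⁻¹ and γ = [Mg²⁺]/3.57,
evaluated at the self-consistent mean potential
⟨V_x⟩ = μ_x − (V_thr − V_reset) ν_x τ_x.

ψ(ν) is an alternating series in the rise-time coupling. Its textbook
form contains binomial sums that cancel catastrophically in floating
point from n ≈ 20; we evaluate the algebraically identical product
form T_n/(n+1)! = 1/[(n+1)·Π_{j=1..n}(x+j)] with
x = τ_rise(1 + ν τ_NMDA)/τ_decay, summed to n = 64 with an early stop
at |term| < 1e−12. A unit test checks it against an exact-rational
direct evaluation of the binomial form.

The output rate is the first-passage-time transfer function

    φ = 1000 / ( τ_rp + τ_x √π ∫_β^α erfcx(−u) du ) Hz

with the coloured-noise-corrected bound
α = (V_thr − μ)/σ·(1 + 0.5k) + 1.03√k − 0.5k, k = τ_AMPA/τ_x, and
β = (V_reset − μ)/σ. The integral uses a fixed 160-point
Gauss–Legendre rule (checked against adaptive quadrature at 1e−6
relative); α is cut off at 12 (the rate is then numerically zero) and
α ≤ β returns the refractory ceiling 1/τ_rp.

Fixed points are found by relaxing τ_x dν_x/dt = −ν_x + φ with forward
Euler at 0.1 ms. The stopping rule is a rate-of-change criterion —
max |Δν| < 1e−6 Hz per 0.1 ms reference step, rescaled proportionally
with dt — because a fixed per-step tolerance stops earlier in physical
time when dt shrinks and flips classifications near bifurcations.
Non-convergence within 10⁶ steps is flagged, never returned as a fixed
point. Stability is operational (convergence of the flow); there is
no eigenvalue analysis.

**Transverse perturbation.** Symmetric states (spontaneous, mixed) are
probed from seeds carrying a 0.1 Hz L/R asymmetry — the same precision
as the basin bisection. The instability that removes these states is
transverse to the ν_L = ν_R diagonal, and an exactly symmetric
relaxation can never leave the diagonal, so unperturbed seeds
overstate their stability by several Hz of λ.

**Stationary conditions.** The landscape conditions are: *stimulus*
(λ ± Δλ to L/R), *delay* (no stimulus), *sure* (5 Hz sustained input
to S). All three include a small residual drive to L and R (3.08 Hz
during stimulus, 2.21 Hz in delay/sure) standing in for the slowly
decaying target input. These residuals are mean-field configuration
constants: with them the reduction's bifurcation sequence matches the
published landscape analysis (spontaneous state lost just above
λ = 1 Hz; decision attractors lost near λ = 60 Hz; the mixed state
stabilizing in the low 20s). They are deliberately *not* computed from
the spiking protocol's target input — see *Where the two tiers part
ways* below.

**Attractor bookkeeping.** Converged states are classified by their
selective-pool pattern (spontaneous: all < 10 Hz; decision: one pool
> 20 Hz, others < 10 Hz; mixed: ν_L, ν_R ∈ [10, 40] Hz within 2 Hz of
each other; thresholds configurable). Two fixed points are the same
attractor when all five rates agree within 0.1 Hz. Basin boundaries
are located along rays from each attractor by bisection to 0.1 Hz,
with non-probed pools initialized at their in-attractor rates; a
returned point is verified by probing both sides.

## Trials and analyses

Population rates are estimated in a trailing 50 ms window stepped at
5 ms. A decision is the first time a selective pool's rate reaches
ϑ and stays there for the following 50 ms; ϑ = 28 Hz at λ = 50 Hz,
24 Hz in the bistable preset at λ = 15 Hz, and a calibration helper
picks ϑ for other regimes by the original criterion (largest threshold
leaving < 5% of trials undecided at the go cue). Decision times count
from motion onset. The choice reported at the go cue is the pool
dominating in the 50 ms before it; a trial whose go-cue direction
winner differs from its first threshold-crossing winner is a change of
mind (a sure choice supersedes rather than reverses the direction
decision and is not counted). The (ν_L, ν_R) snapshot is the spike
count in the single 50 ms window before sure-target onset — evaluated
in forced-choice trials too, at the time the sure target would have
appeared.

Derived statistics follow the published procedures: 1 Hz square bins
for P(S | ν_L, ν_R) with bins under 30 trials masked; decision-time
histograms in 10 ms bins smoothed with a 3-bin moving average, the
fast/slow split at the histogram minimum within [100, 1500] ms (the
minimum must separate at least 5% of the mass on each side, otherwise
an empty tail inside the search range masquerades as a dip; a
boundary minimum or missing shoulder raises the "no interior dip"
flag); bootstrap comparison of fast-vs-slow error counts with 10000
resamples and a t-test on the bootstrap distributions; Wilson score
intervals on all proportions; sure-target value w_S = 0.8 in the
reward P(correct) + P(S)·w_S.

The closed-form sure-choice conditionals assume only that presenting
the sure target leaves the overall probability of a correct decision
unchanged:

    P(S|C) = [P(C) − P(C|S̄) + P(S)·P(C|S̄)] / P(C)
    P(S|E) = 1 − P(E|S̄)·P(S̄) / P(E)

and satisfy the law of total probability to machine precision.

## Numerical choices

Spiking integration: forward Euler for V at dt = 0.05 ms
(configurable; halving dt moves pool rates by a few percent at most),
exact exponential decay factors for the AMPA/GABA/NMDA-rise gating
variables, Euler for the saturating NMDA equation. Spikes take effect
on the next step (no delay within the 0.05 ms grid). Because weights
depend only on the (pre-pool, post-pool) pair, recurrent input is
accumulated per pool and the step cost is O(N). One RNG stream per
trial, seeded per trial (base seed + trial index), makes every
ensemble bit-reproducible. External Poisson counts use the
inverse-product method with a per-pool cached threshold.

## What the generator emulates, and what it does not

Simulated ensembles reproduce the task's *structure*: the condition
grid (λ = 50 Hz; Δλ from 0 to 30 Hz; durations 100–500 ms; forced and
free trials), the published decision rule, and trial-to-trial
stochasticity arising solely from the Poisson input and network
dynamics. They do not emulate: non-decision time (reaction times are
decision times only), variable go-cue timing (the trial end is fixed),
coherence-dependent input to pool S, or any learning or session
structure. Passing tests therefore show that the mechanism produces
the qualitative phenomenology — they say nothing about fits to any
individual animal's data.

## Where the two tiers part ways

A faithful transcription of both tiers from the same parameter table
does not make them quantitatively interchangeable, and we document the
gap rather than hide it:

* At the spontaneous state the spiking network runs ≈ 1 Hz below the
  reduction (≈ 1.6 vs 2.5 Hz) — within the usual accuracy of this
  approximation.
* At high-rate attractors the gap widens: the reduction puts the
  delay-period decision-memory attractor at ≈ 33 Hz, while the
  finite-size spiking network (160-neuron pools, fully shared
  recurrent input) sustains ≈ 10 Hz without input support. The
  published behavior (decisions crossing a 28 Hz threshold in the
  delay, < 5% undecided) therefore requires the sustained component of
  the target input in the spiking tier; the mean-field tier, which
  linearizes away exactly the correlations responsible, needs only the
  small residuals quoted above.

Consequences visible in the shipped statistics, at the default
calibration and reduced ensemble sizes: the undecided fraction at
λ = 50 Hz sits near 5–10% rather than strictly below 5%, and the
change-of-mind fraction near 15–20% rather than 10 ± 2% — the delay
attractor being shallower than in the reduction makes late reversals
easier. Strengthening the sustained input removes undecided trials
but raises reversals further, and vice versa; the default sits at the
balance point. A second consequence is the *timing* of resolution:
with the sustained input holding the symmetric state together through
the stimulus, much of the competition resolves in the delay rather
than during the stimulus. P(S) therefore falls cleanly with evidence
(≈ 0.36 → 0.09 over Δλ = 0 → 16 Hz at λ = 50) but *rises* with
stimulus duration instead of falling, and early errors are mostly
fully resolved wrong decisions rather than near-diagonal states — so
the error branch of the X-pattern (sure choices increasing with
evidence in error trials) does not emerge at this calibration.

## Reduced scales

The shipped presets and the test suite run deliberately reduced
problem sizes chosen as the smallest that still expose each effect:
ensembles of ~100–200 trials at λ = 50 Hz (the publication scale of
1000 trials per condition is available as the `full-psychophysics` preset),
a 200-neuron rescaled network for pure plumbing tests (it does not
sustain decisions and is never used for behavioral statistics), basin
boundaries at 8 rays, and bifurcation scans over targeted λ windows at
the stated 1 Hz resolution.
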