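# Methods

## The model

`cbgt` simulates decision making in a closed cortex–basal-ganglia–thalamus
(CBGT) circuit solving a two-armed bandit with dissociated cognitive and
motor choices.  Twelve rate-coded populations (72 neural assemblies) form
three segregated loops:

* a **cognitive** loop (cortex, striatum, STN, GPi, thalamus; 4 assemblies
  per structure, one per cue),
* a **motor** loop (same five structures; one assembly per screen location),
* an **associative** loop (cortex and striatum only; a 4×4 sheet indexed by
  cue × location) that binds cue identity to position and couples the two
  competitions.

Each assembly follows

    τ dV/dt = −V + I_syn + I_ext + h,      U = f(V + V·n),

with τ = 10 ms everywhere, `I_syn = Σ G·w·U_pre` the gain- and
weight-weighted presynaptic drive, `I_ext` the stimulus current, `h` the
population baseline and `n` a fresh zero-mean Gaussian drawn per assembly
per step (multiplicative output noise; cortex 1 %, striatum/STN/thalamus
0.1 %, GPi 3 %).  All transfer functions are threshold-linear ramps except
the striatum, which uses a Boltzmann sigmoid
(`v_min = 1`, `v_max = 20`, `v_h = 16`, `v_c = 3` spikes/s): silent at rest
(~1 spike/s), rising steeply above ~10 spikes/s of input and saturating near
20.  Integration is forward Euler at dt = 1 ms (τ/10); trajectories at
dt = 1 and dt = 1/16 agree to < 2 % over a settle, and the test suite checks
this refinement property.

Two competitions coexist:

* **BG competition** — the direct pathway
  (cortex → striatum → GPi ⊣ thalamus → cortex) is net positive through
  double inhibition, channel-specific; the hyperdirect pathway
  (cortex → STN → GPi, with STN diverging onto *all* GPi assemblies of its
  loop) is net negative and shared, a common-mode brake.  Together they
  implement an off-center/on-surround race.
* **Cortical competition** — lateral connectivity inside each cortical
  population: +0.5 to self, −0.5 to every other assembly.

A decision is read from motor cortex alone: the first time the two
stimulated motor assemblies differ by 40 spikes/s, the leader's location is
chosen.  A non-stimulated assembly dominating everything by the same margin
is an *illegal* choice (failed trial), as is a 2500 ms timeout.

## Operating point

The circuit only works as a disinhibition gate if the pallidum is tonically
active and the thalamus sits balanced at its firing threshold beneath that
tonic inhibition.  The default baselines implement exactly this: GPi
`h = +39` spikes/s (tonically firing, as pallidal cells do in vivo) and
thalamus `h = +40`, so that at rest the ~40 spikes/s of pallidal inhibition
(gain −1.5) cancels the thalamic drive.  Striatal activity then
*disinhibits* the corresponding thalamic channel and closes a positive loop
with cortex.  The cortico-thalamic gain is 0.05: large enough to let the
loop ignite once a channel leads, small enough that the settle-phase noise
is not amplified into a premature choice when the pallidal brake is absent.
The cortico-striatal base gain is 2.0, so that with synaptic weights
initialized at 0.5 the *effective* coupling is 1 and a cortical activation
of 30 spikes/s produces a striatal output of 20 spikes/s — the anchor that
defines the sigmoid's operating range.  This operating point was calibrated
against the circuit's qualitative regime behaviour (below), then frozen; the
balance is deliberate and fairly tight (the GPi baseline tolerates roughly
±1 spike/s before one of the regimes degrades), which mirrors how finely the
real circuit must poise excitation against inhibition.

With these defaults the three regimes behave as intended (medians over 100
noise-seeded naive trials):

| configuration | selects? | median decision time | settle transient |
| --- | --- | --- | --- |
| lateral gains zeroed (BG alone) | yes | ≈ 450 ms | damped overshoot |
| GPi output cut (cortex alone) | yes | ≈ 630 ms | monotone |
| intact, congruent | yes | ≈ 210 ms | damped overshoot |

The damped settle transient is the signature of the delayed STN/striatal
feedback through GPi and thalamus; cutting the GPi output removes both the
delay loop and the oscillation.

## Task and protocol

A trial presents two of the cues at two of four locations; cognitive-cortex
assemblies of the two cues, motor-cortex assemblies of the two locations and
the two *veridical* associative (cue, location) cells each receive a
7 spikes/s external current (the binding input resolves the cue↔location
ambiguity).  Reward is Bernoulli in the chosen cue's probability; failed
trials yield no reward at all.  Performance is the fraction of trials on
which the cue with the higher reward probability was (motorically) chosen,
failed trials counting against.

The covert-learning experiment runs 12 independently seeded model instances
through three 60-trial conditions: C0 (intact, stimulus set 1), C1
(GPi→thalamus gains zeroed — the muscimol analogue — fresh weights and
critic for stimulus set 2) and C2 (output restored, *keeping* C1's weights
and critic).  Both stimulus sets use P = (0.75, 0.25).  Each session draws
its three condition streams from one spawned seed sequence, so a master
seed reproduces the whole experiment bit-exactly.

## Learning

Plasticity is restricted to the cognitive channel.  Weights are initialized
at 0.5 (SD 0.005), multiply their pathway gain, and every change passes
through the soft-bounding map `W ← W + ΔW (W_max − W)(W − W_min)` with
bounds [0.25, 0.75], whose fixed points at the bounds keep weights in range
under arbitrary deltas.

* **Critic**: one value per cue, `V_i ← V_i + α·RPE` with `RPE = R − V_i`
  and α = 0.025; updated only on rewarded-or-unrewarded (not failed) trials.
* **Cortico-striatal (actor)**: `ΔW = LTP_RL·RPE·U_B` for positive RPE,
  `LTD_RL·RPE·U_B` for negative, with the asymmetric rates 0.050/0.030,
  applied to the chosen cue's synapse; `U_B` is the striatal assembly's
  output at decision time.
* **Cortico-cortical (Hebbian)**: `ΔW = LTP_HL·U_A·U_B` (0.005), reward
  independent, applied to the cognitive→associative cortical synapses on
  every decided trial.

Decision-time activities enter these rules in units of a reference rate of
8 spikes/s (`LEARNING_ACTIVITY_REF`).  The rules above are scale-free on
paper but not in practice: raw decision-time rates (20–60 spikes/s) would
drive every weight to its bound within a couple of trials, erasing both the
gradual weight trajectories a 60-trial session is supposed to show and the
covert cortico-striatal differentiation that C2 reveals.  The reference was
calibrated once so that one 60-trial session of random sampling produces a
cortico-striatal advantage for the richer cue of ≈ 0.1 weight units — the
regime in which learning is gradual, expressible and does not saturate —
and then frozen.

Why this produces covert learning: in C1 the cortex alone decides, choices
are random, and the striatum — disconnected from behaviour but not from
dopamine — samples both cues roughly equally.  The critic's values converge
toward the two reward probabilities and the asymmetric actor rule converts
the value difference into a cortico-striatal weight difference.  None of
this can influence behaviour while the pallido-thalamic gains are zero.
When C2 restores them, the biased direct pathway tilts the race toward the
richer cue from the first trial.  Resetting the weights between C1 and C2
(the `carry_c1_to_c2=False` control) abolishes the head start.

## Statistics

The behavioural analysis pools, per condition, the first and last 10 trials
of the 12 sessions into six samples of 120 binary success indicators, then
runs a Kruskal–Wallis rank-sum test across the six samples and Dunn's
pairwise post hoc z-tests on the pooled tie-corrected ranks, adjusting the
p values over all 15 pairs with the Benjamini–Hochberg step-up procedure;
significance is declared at adjusted p < 0.01.  The three planned
comparisons reported are C0-start = C2-start, C1-start = C2-start and
C1-end = C2-start.  Kruskal–Wallis is delegated to `scipy.stats.kruskal`
and the BH step to `statsmodels`; Dunn's test is implemented here and
cross-checked in the test suite against brute-force rank arithmetic to
1e-8, alongside a type-I-error check on chance-level Bernoulli fixtures
(`make_fixture`).

## What the synthetic conditions do and do not show

All inputs are generated by the task environment; there is no recorded
data in the loop.  The Bernoulli fixture generator emulates only the
*shape* of the six behavioural samples (independent coin flips at chosen
success rates) — it has none of the within-session nonstationarity that
learning produces, so it validates the statistics stage, not the model.
Likewise, passing the protocol reproduction says the simulated circuit
under these study conditions behaves like the published simulation; the
primate experiments (muscimol microinjection, 0.433/0.492/0.667) are
biological context, not something this artifact can or does reproduce.

## Numerical choices and degenerate inputs

dt must satisfy dt ≤ τ/5 (enforced); noise is redrawn per step and per
assembly, uncorrelated — the correlation structure of the biological noise
is unknown, and a correlated hook is deliberately not exposed until there
is something to calibrate it against.  Between trials all activations are
reset to zero and the circuit re-settles for 500 ms; weights and critic
persist.  Boltzmann exponents are clipped at ±500 to avoid overflow; ties
in the decision race (exactly equal activities) yield no decision rather
than an arbitrary pick; an empty record list has no defined performance and
raises.  The lesion operators zero gains without touching structure and are
idempotent; rebuilding the table restores the intact model.

## Known limitations

* The operating point is a re-derivation, not a transcription: four
  baseline/gain values and the learning activity reference are this
  package's own calibration (see the narrow GPi-baseline window above).
* Between-session variability in C1 is slightly larger than the published
  ±0.16 because Hebbian habit formation can transiently lock single
  sessions onto one cue.
* The statistical significance of all three planned comparisons at
  p < 0.01 holds for most but not all master seeds (the C0-start sample
  occasionally draws high); the covert-learning effect itself (C2 start
  above both C1 windows) is robust across every seed tried.
* No GPe/indirect pathway, no dopamine-neuron dynamics (the critic is
  algorithmic), no eligibility traces, no plasticity outside the cognitive
  channel.
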