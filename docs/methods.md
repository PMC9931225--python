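# Methods

This note documents the models implemented in `sepsisrl`, the choices
behind them, and what the synthetic test-bed does and does not establish.

## Problem setting

Hourly ICU trajectories of septic patients are treated as a partially
observed Markov decision process.  Observations are demographics, seven
vitals, five organ-dysfunction (SOFA) scores and twelve labs; actions are
the joint choice of intravenous-fluid volume and norepinephrine-equivalent
vasopressor rate for the next hour, each discretized to {none, low, high}
with cutoffs 500 mL/h and 0.15 mcg/kg/min (9 joint actions).  Rewards are
SOFA-based shaping terms plus ±15 on terminal survival/death:

    r(s_t, a, s_{t+1}) = −0.025·1[SOFA_{t+1} = SOFA_t > 0]
                         − 0.125·(SOFA_{t+1} − SOFA_t)        (non-terminal)

The printed form of this reward in the source literature wraps the SOFA
difference in an indicator with unbalanced parentheses; we implement the
linear-difference reading, which matches the coefficient pattern and the
SOFA-shaping reward it descends from.

## Cardiovascular latent state (two-element Windkessel)

The arterial tree is lumped into a resistance R (mmHg·s/mL) and a
capacitance C (mL/mmHg).  With ejection idealized as an impulse of volume
SV at the start of each cardiac cycle of length T = 60/F,

    dP/dt = −P/(RC) + Q(t)/C,  Q(t) = SV·δ(t)

has the periodic steady state

    P_sys  = (SV/C)/(1 − e^{−T/RC})
    P_dias = (SV/C)·e^{−T/RC}/(1 − e^{−T/RC})
    P_MAP  = SV·R/T.

Only the combinations RC, SV/C (pulse pressure), SV·R (= P_MAP·T) and T
are identifiable from (P_sys, P_dias, P_MAP, F): scaling (SV, C) by k and
R by 1/k changes nothing.  A further consequence used by the tests: the
decoder's image is a 3-manifold in the 4-dim observable space — P_MAP is
algebraically pinned by the other observables — so observations carrying
independent noise on all three pressures cannot be reconstructed exactly,
and reconstruction error has a noise-dependent floor.

The ODE oracle for the closed forms steps cycle-by-cycle with the exact
per-cycle exponential decay and an SV/C jump, avoiding δ-function
discretization artifacts.

## Physiology-driven denoising recurrent autoencoder

The encoder g is three networks: a patient encoder (2-layer tanh MLP,
width 64) mapping demographics to an initial state estimate; a one-layer
GRU (hidden 64) over the vitals+scores history up to and including the
current hour; and a transition network (2-layer MLP, width 64) mapping
(previous state estimate, current action one-hot, history summary) to the
new estimate.  The decoder f is the fixed Windkessel map above — it has
no trainable parameters.  Latents are kept positive by a softplus
transform of (baseline + learned deviation) with textbook resting
baselines R₀ = 1.0, C₀ = 2.0, SV₀ = 70, F₀ = 75 (configurable); a zero
deviation decodes exactly to the baseline vitals.

Training minimizes the unnormalized squared reconstruction error of
(P_sys, P_dias, P_MAP, F) summed over the four outputs and averaged per
observed hour, with input elements independently zeroed at a probability
drawn uniformly from 10–25% per batch.  Corruption is applied to the
vitals/scores channels only (not actions or demographics): the point of
the denoising scheme is that the current observation cannot simply be
memorized and inverted, so the network must integrate history and
treatments.  Inference uses uncorrupted input.  Defaults: Adam at 3e-3
with a single ×0.3 step decay after ⅔ of 45 epochs, batches of 64
patients, an 80/20 patient-level train/validation split, seeded.

## Lab-history autoencoder

Labs arrive ~12-hourly and are forward-filled, so hourly lab rows are
highly redundant.  Three stacked GRU layers with strictly decreasing
widths (default 64→32→10) encode the 12-channel lab history; the final
10-dim hidden state is the representation, and a linear head reconstructs
the standardized 12-channel input at every hour.  The corruption
probability ramps linearly from 0 to 50% across epochs ("gradually
increased" is otherwise unquantified; linear-in-epoch is our choice).  We
reconstruct the full input window, and the representation at inference is
a deterministic function of the uncorrupted input.

## State assembly

Each hour yields a 41-dim state: demographics (3) + vitals (7) + scores
(5) + labs (12) + cardiovascular latents (R, C, SV, T) + lab
representation (10).  Features are z-scored with moments fitted on the
training split only (gender enters as 0/1 before scaling).  A patient
with L recorded hours contributes L transitions: L−1 shaped non-terminal
transitions and one terminal transition rewarded ±15.  Terminal rows
never serve as bootstrap targets.  The action index convention is
vaso-major: index = 3·vaso_bin + fluid_bin.

## Distributional Q-learning (C51)

Return distributions are categorical over 51 equally spaced atoms on
[−16, 16] — the terminal rewards ±15 plus bounded discounted shaping
terms; γ = 0.99.  The distributional Bellman target shifts atoms by
r + γz, clips to the support and splits mass linearly between the two
nearest atoms (this projection conserves mass exactly and preserves the
mean whenever nothing clips); the loss is the cross-entropy to the
projected target.  Backups are double-DQN style (online-net argmax,
target-net distribution) with a hard target copy every 1000 steps.  The
value net is an MLP (2×128 tanh) with a 9×51 head and per-action softmax.

Experience replay is weighted: terminal death, terminal survival, and
"near-death" transitions (non-survivors within 24 h of death) are
upweighted, with the terminal class masses calibrated so a batch of 100
contains on average exactly one terminal survival and one terminal death
record; near-death transitions get 5× the base-class weight.  On a toy
tabular MDP the weighting provably changes only the sampling
distribution, not the fixed point, and the test suite checks convergence
to tabular value iteration both with and without it.

## Model uncertainty

Epistemic uncertainty is estimated with a bootstrap ensemble: patient-
level resamples (all of a patient's transitions travel together —
transition-level resampling would leak trajectories across members) of
30% of patients, drawn with replacement, each training an identical C51
agent from a different seed.  For a state-action pair,

    u(s, a) = (1/M) Σ_m KL(θ_m(s,a) ‖ θ̄(s,a))        [nats]

with θ̄ either the ensemble mean distribution (default) or the
full-data model, and a 1e-8 probability floor before the KL.  The
production-scale default is 25 members; the bundled study runs 5 at desk
scale.  Derived agents: a patient-weighted mixture (weights ∝ number of
distinct patients a member trained on) and a voting agent that prescribes
vasopressors only if at least p% of members' greedy actions contain one.

## Preference score

    P(s, a) = β·softmax(Q̃(s, ·))_a + (1 − β)·G(s, a) − λ·u(s, a)

with Q̃ from the ensembled distributions (softmax temperature 1), G the
behavior-cloner probabilities (2×128 MLP classifier, weight decay 1e-4),
and β ∈ [0, 1], λ ≥ 0 user-chosen.  β = 1, λ = 0 recovers the
expected-value criterion; β = 0, λ = 0 the pure cloner.  The printed form
of this score in the source literature has unbalanced parentheses; the
implemented reading is the one consistent with those two limits.  u
enters unrescaled; λ absorbs its scale.

## Synthetic cohort

Real credentialed ICU data is out of scope, so the package ships a
seeded simulator whose hidden state is exactly the Windkessel state the
encoder is supposed to recover.  Default study conditions: 2000 patients,
72-h horizon, ~20% ICU mortality, observation noise 3 mmHg on each
pressure and 2 bpm on heart rate, ~5% missingness, 12-hourly labs.

Per patient: baselines are drawn around the population baseline (SDs
0.10/0.25/10/6 for R/C/SV/F); a latent severity z follows a random walk
with a patient-specific drift (mean −0.05/h) and maps through a logistic
to sev ∈ (0, 1).  Severity acts like vasoplegic sepsis: at full severity
R falls 50%, SV falls 25%, F rises 20% (multiplicative OU noise on top).
Vasopressors add ΔR ∈ {0, 0.2, 0.4} and a small ΔF within the hour;
fluids add ΔSV ∈ {0, 4, 8} mL.  Treatment feeds back on severity in
proportion to the perfusion deficit (MAP below 65 mmHg) it removes that
hour — so treating a normotensive patient confers no benefit, and in deep
shock vasopressors (which restore R directly) are causally the right
tool while fluids help modestly.  Six SOFA components follow biased
integer random walks (the cardiovascular one on perfusion deficit, the
others on severity).  Death fires from a per-hour logistic hazard
dominated by perfusion deficit (0.30/mmHg vs 0.05 per SOFA point);
discharge after 4 consecutive well hours.  The behavior policy gives
vasopressors with probability increasing in SOFA with strong hour-to-hour
persistence, mimicking clinician treatment patterns; hazard parameters
were calibrated during generator construction to the ~20% mortality
target and to perfusion-dominant death, and then frozen.

What the simulator does *not* emulate: pharmacokinetics, ventilation and
other organ support, measurement artifacts beyond i.i.d. Gaussian noise
and random missingness, informative (missing-not-at-random) sampling,
inter-current events, and any real covariance structure between labs and
hemodynamics beyond the shared severity driver.  Passing tests therefore
establish that the pipeline recovers structure *that is in the generator*
— identifiable Windkessel combinations, hypotension-linked risk, the
value of vasopressors in vasoplegia — not that it would do so on real
patients.

## Numerical choices and degenerate inputs

* Windkessel decode guards T/RC overflow with the limit form
  (P_sys → SV/C, P_dias → 0); non-positive parameters are rejected at
  construction, and F·T = 60 is enforced to 1e-6 relative.
* The C51 projection is exact for atoms landing on grid points (no mass
  is split); ties in greedy actions resolve to the lowest action index.
* Bootstrap resamples missing a terminal class are redrawn with a
  warning (up to 20 attempts).
* Gaussian-mixture density fits retry with a stronger covariance ridge
  (1e-6 → 1e-3 → 1e-1) on singular fits.
* Leading missing values that forward-fill cannot reach fall back to the
  column median.
* All training is float64 on a small numpy autodiff core whose gradients
  are finite-difference-checked in the test suite.

## Problem sizes used in the bundled study

The reproduction script and the end-to-end tests run: 2000 simulated
patients (~55k patient-hours); physiology autoencoder 45 epochs (GRU
hidden 64); lab autoencoder 10 epochs at widths 32→16→10; C51 agent 10k
batches of 100; 5-member ensemble at 2.5k batches per member; toy-MDP
checks at 4k batches.  These sizes were chosen so the full study runs on
a single CPU in well under half an hour while leaving every qualitative
check comfortably resolved; all are config parameters.

A consequence of the generator's strong, causal treatment effect is that
the *optimal* value of near-death states is not low: most hypotensive
states are rescuable by high-dose vasopressors, so V* under the learned
policy separates survivors from non-survivors overall but does not fall
sharply in the final hours before death.  Real septic deaths are far
less preventable, and value distributions on real data shift toward the
death outcome as it approaches; reproducing that requires a generator in
which deterioration is partly irreversible, which this one deliberately
is not (the treatment-policy trends tested here need treatment to
matter).

## Known limitations

* The behavior policy's confounding by indication is mild compared with
  real clinical data; offline RL pathologies (extrapolation error on
  unsupported actions) are correspondingly milder here.
* Off-policy evaluation is deliberately out of scope; no claim about
  policy value on real patients is made or testable here.
* The quartile-regression distributional variant and alternative
  imitation learners (e.g. nearest-neighbor) are not implemented.
* With 5 ensemble members the uncertainty estimator is noisy; ordering
  comparisons (in- vs out-of-distribution) are meaningful, absolute
  magnitudes are not.
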