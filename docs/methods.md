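# Methods

## Gating model

The simulator represents one channel population by a Hodgkin–Huxley-style
scheme deliberately kept as small as the measurements it must support:

* **Activation.** A single first-order gate `m` with Boltzmann steady
  state `m_inf(V) = 1/(1 + exp(-(V - V_1/2)/k))`.  A power-1 gate (rather
  than the classical m⁴) is used so that the conductance–voltage curve
  equals the Boltzmann exactly; tail-current analysis fits a single
  Boltzmann to normalized tails, and a power-4 gate would make the
  generative curve and the fitted form systematically disagree.
* **Activation/deactivation kinetics.** `tau_m(V) = tau_V1/2 ·
  exp((V - V_1/2)/k_tau)` with *signed* `k_tau`, so the data determine
  whether tau rises or falls with voltage.  Separate laws govern
  depolarized and hyperpolarized relaxations, crossing over at −40 mV:
  depolarizing steps (≥ −40 mV) use the activation law (`k_tau` < 0, tau
  shrinks with depolarization), hyperpolarizing post-steps use the
  deactivation law (`k_tau` > 0).  The generative slope magnitude defaults
  to 25 mV per e-fold for both laws — a mid-range value for Kv1 channels
  that keeps the fastest time constants in the protocol families (~0.4 ms
  at +60 mV) well above the 20 µs sampling interval.
* **C-type inactivation.** Two parallel first-order availability gates
  `h_f`, `h_s` with weights `A%` and `1-A%` produce the observed
  bi-exponential decay.  At depolarized potentials (≥ 0 mV) they relax
  with `tau_fast` and `tau_slow`; at hyperpolarized potentials (≤ −60 mV)
  both recover with a common `tau_recovery` (which is why the double-pulse
  recovery curve is single-exponential); in between, time constants
  interpolate log-linearly.  Steady-state availability is coupled to
  activation, `h_inf = 1 - m_inf`: C-type inactivation proceeds from the
  open state, so closed channels at subthreshold potentials do not
  inactivate.  The two regimes the experiments constrain (complete decay
  at +40 mV, complete recovery at −80 mV) are reproduced exactly; the
  coupling is the simplest interpolation between them that does not
  introduce availability drift during subthreshold activation steps.
* **Current.** `I = g_max · m · (A%·h_f + (1-A%)·h_s) · (V - E_K)`, with
  `E_K` from the Nernst equation for the recording solutions (2.8 mM K⁺
  out, 132 mM in, 293.15 K → −97.3 mV).  Published current amplitudes
  carry no absolute unit, so `g_max` is expressed in display units per mV
  and calibrated per species so that the steady IV current at +20 mV
  equals the reference amplitude (2.1 wild type, 0.4 mutant, 0.55
  heteromer).  Calibration simulates the actual +20 mV sweep and applies
  the same baseline-subtracted measure as the analysis, so the anchor is
  exact by construction.
* **`A%` (fast fraction).** Not published; the generative default is 0.3,
  configurable per species.

Because commands are piecewise-constant, every gate relaxes in closed form
within a segment (`x(t) = x_inf - (x_inf - x_0)·exp(-t/tau)`); the
simulator evaluates these expressions per segment and carries exact gate
values across boundaries.  No ODE solver is involved; an independent
adaptive Runge–Kutta integration of the same gating equations exists in
the test suite and agrees with the closed forms to better than 10⁻⁶ of
peak current on every protocol.  Gates start each sweep at their holding
steady state (long inter-sweep rests are assumed; cumulative inter-sweep
inactivation is not modeled).

## Dominant-negative co-expression

Subunits are assumed to assemble into tetramers independently, so a WT
cDNA fraction p gives a Binomial(4, p) composition.  Under the
mutant-dominant rule, any tetramer with ≥ 1 mutant subunit gates like the
mutant homomer; at 1:1 this leaves p⁴ = 6.25% wild-type channels and
predicts a co-expression amplitude of 0.0625·2.1 + 0.9375·0.4 ≈ 0.506 at
+20 mV.  Because the observed heteromeric *gating* (midpoint between WT
and mutant) is not mutant-like, the mixture model is used only for the
amplitude prediction; the characterization of co-expressed channels uses
a single effective species with the measured heteromeric parameters.

## Protocols

The five protocol builders reproduce the standard characterization
battery: 200 ms IV steps from −80 to +60 mV (10 mV spacing, holding
−80 mV); the same prepulse family followed by a 150 ms tail at −50 mV
(WT convention) or −30 mV (mutant/heteromer convention, where −50 mV
would sit near threshold); 200 ms deactivation post-steps from −80 to
+20 mV after a +20 mV conditioning pulse; a single 90 s pulse at +40 mV;
and a double-pulse recovery protocol (20 s conditioning, 100 ms probe,
interpulse intervals 0.1–17.1 s in 1 s increments — the published range
with a uniform grid, since only the range is stated).  Every sweep opens
with 10 ms at holding so fitters always have a baseline window.  Command
voltages are nominal; no liquid-junction or series-resistance correction
is applied.  Sampling defaults to 50 kHz; the two multi-second protocols
(inactivation, recovery) default to 10 kHz since nothing in them is
faster than a few milliseconds and the full rate would produce
needlessly large arrays.

## Analysis pipeline and numerical choices

* **IV table:** steady current = mean over the last 10% of the step,
  baseline-subtracted using the pre-step holding window.
* **Tail amplitudes:** extremum of baseline-subtracted current in a
  window starting 0.5 ms after the step (capacitive-artifact skip) and
  extending 5 ms.  The short window matters: after subthreshold
  prepulses the current at the tail potential slowly *rises* toward its
  steady state, and a long search window would report that re-activation
  instead of the instantaneous tail, lifting the foot of the activation
  curve and biasing the fitted midpoint.
* **Boltzmann fit:** nonlinear least squares on the normalized curve;
  requires ≥ 4 points bracketing the midpoint, flags non-convergence.
* **Single-exponential fits:** `A·exp(-t/tau) + C`, tau initialized from
  the 63.2% settling time, fit restricted to ≈ 8 time constants and
  refined once.  The windowing keeps slow secondary drifts (creeping
  inactivation during an activation step) from biasing the fast
  relaxation.  Residual structure beyond 1% of the amplitude raises a
  non-mono-exponential flag rather than failing.
* **tau(V) law:** linear least squares on log tau versus V (exactly
  linear under the model), evaluated at the *fitted* midpoint of the same
  cell.  Activation fits use steps ≥ −30 mV (channels measurably open);
  deactivation fits use post-steps ≤ −50 mV, safely inside the
  deactivation regime of the simulator's −40 mV crossover.
* **Double-exponential fit:** starts at the current maximum; initialized
  by peeling (slow component from the late 60%, fast from the early
  residual); components ordered fast < slow, with a collapse flag when
  they agree within 5% or one amplitude vanishes.
* **Recovery:** probe/conditioning peak ratios are normalized by the
  ratio at the longest interval (capped at 1) and fitted with a rising
  exponential with free asymptote, `A - (A - R0)·exp(-dt/tau)`.  The free
  asymptote is deliberate: the longest interval (17.1 s ≈ 5 recovery time
  constants) is not complete recovery, so the normalized asymptote sits
  slightly above 1 and pinning it at 1 biases tau low by ~2%.
* **Cohort statistics:** mean ± SEM (n−1 denominator); two-sample,
  two-tailed pooled-variance Student's t-test with p < 0.05 significance.
* Convergence failures are never silent: every fit result carries RSS,
  a convergence flag and warning flags, and pipeline errors name their
  stage.

## Synthetic cohorts

Inter-cell variability is multiplicative mean-one log-normal jitter (CV
`jitter_cv`, default 0.1) on positive-definite parameters and additive
normal jitter (SD = `jitter_cv`·10 mV) on the midpoint, which is not
positive-definite.  Recording noise is additive Gaussian (default in the
CLI examples: 1–2% of the WT peak; the published recordings' noise level
is not quantified), optionally shaped by a 4-pole Bessel low-pass
emulating the 2 kHz acquisition filter — off by default so noise-free
traces are exact.  What the generator does *not* emulate: leak and
capacitive transients (an optional ohmic leak can be enabled), series
resistance, cumulative inter-sweep inactivation, temperature effects, and
single-channel stochasticity.  Passing tests therefore demonstrate that
the pipeline is unbiased for data satisfying the model's assumptions,
not that it is robust to every artifact of real recordings.

## Trajectory geometry

* **Containers:** multi-model PDB is the only trajectory dialect (convert
  DCD/XTC with e.g. `mdconvert` first).  Frame times ride in
  `REMARK 250 FRAME TIMES (NS)` records, with a uniform-grid fallback.
  In-memory frames keep float64 coordinates; file precision (10⁻³ Å)
  applies only at the boundary.  Residue numbers must follow Kv1.1
  author numbering (P403, G385); the CLI offers `--residue-offset` for
  shifted files.
* **Helix axis:** the Cα trace is smoothed with a one-turn kernel whose
  half-weights `a = -cos(50°)/cos(150°)` cancel the 100°-per-residue
  helical wheel exactly for any phase, then the principal component of
  the smoothed points is taken, oriented N→C.  Plain PCA of raw Cα
  positions of a 13-residue segment carries an axis tilt of over a degree
  from the unbalanced partial turn; the smoothing removes it exactly for
  an ideal helix and keeps noisy-axis errors well under 2° at 0.3 Å
  coordinate noise.
* **Kink angle:** angle between the axes of the S6 windows above
  (389–401) and below (405–417) the PVP motif, excluding the motif
  itself.  The window boundaries are a package default (the exact
  published windows are not stated) and configurable per call.
* **Symmetry angles:** interior angles of the quadrilateral of G385 Cα
  atoms, neighbors identified by azimuthal order about the bundle axis
  rather than chain label (chain naming varies between files).  90° each
  for exact C₄ symmetry.
* **Windowed statistics:** observables evaluated on the frame nearest
  each sample time of an inclusive grid over the final window (default
  50 ns every 0.1 ns → 501 samples), reported as mean ± SD (n−1).
* **Synthetic bundles:** ideal α-helices (1.5 Å rise, 100° twist, 2.3 Å
  radius) with exact C_n symmetry, kinked at residue 403.  The segment
  N-terminal to the kink pivots; an optionally larger kink on one subunit
  therefore displaces that subunit's S6 top and spreads the symmetry
  angles, emulating the asymmetric conformational change of a
  destabilized mutant subunit.

## Problem sizes used in the checks

Single-cell recovery checks run one noise-free cell per species through
the full five-protocol battery (≈ 10⁷ samples per cell).  Cohort-level
checks use 29 jittered cells for the SEM-scale comparison and 20
replicate draws for the significance-pattern check.  Synthetic
trajectories in the tests use tens to hundreds of frames; the statistics
window convention (501 samples at 50 ns/0.1 ns) is checked on a 601-frame
trajectory.

## Known limitations

* The gating scheme is phenomenological; it reproduces the measured
  steady-state and kinetic laws by construction but is not a mechanistic
  Markov model, and mixed-stoichiometry tetramers are either fully
  mutant-like (amplitude prediction) or a single effective species
  (gating) — intermediate per-stoichiometry gating is not modeled.
* Inactivation voltage dependence between −60 and 0 mV is an
  interpolation; the experiments only constrain the extremes.
* The activation-curve foot retains a small bias (≤ 0.4 mV on the
  recovered midpoint for the broadest curve) from availability and
  driving-force variation across prepulses; it is within the tolerance
  of every published comparison but not exactly zero.
* Geometry analysis assumes one Cα per residue in the analyzed windows
  and ≥ 4 chains; discontinuous numbering raises a named error rather
  than a guess.
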