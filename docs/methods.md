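# Methods

This note documents the models implemented in `gaitmtu`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about behavior on real gait data.

## Overview

The package estimates the morphological parameters of the muscle-tendon
units (MTUs) of the human leg from gait data. The pipeline is:

1. **EMG → activation.** Raw EMG is preprocessed, a neural drive x(t) is
   inferred with a recursive Bayesian filter, and first-order activation
   dynamics turn the drive into an active state a(t).
2. **Forward mechanics.** Twelve lumped Hill-type MTUs (plus a passive
   hip flexor ligament) are simulated over prescribed joint kinematics:
   given a(t) and the MTU length l_MTC(t), the fascicle length l_CE(t) is
   integrated and tendon forces follow; joint moments are moment-arm
   weighted force sums.
3. **Energetics.** An Umberger-family metabolic model converts muscle
   state into per-muscle metabolic rate; whole-body cost and the cost of
   transport (MCOT) follow under bilateral symmetry.
4. **Identification.** A dual-objective evolutionary search over 50
   morphological parameters (per muscle: maximal isometric force F_max, a
   joint (l_sl, l_opt) length scale, tendon shape factor K_sh, tendon
   reference strain lambda_ref; plus ligament stiffness and engagement
   angle) minimizes metabolic cost C_met and kinetic misfit
   C_kin = 1 − mean R² simultaneously.
5. **Selection.** One solution is chosen from the Pareto front by the
   vastus metabolic-budget statistic Delta_VAS with cutoff 0.63.

## EMG drive estimation

The rectified EMG sample e is modeled as exponentially distributed given
the hidden drive x: P(e|x) = exp(−e/x)/x. The drive evolves as a
jump-diffusion (Brownian motion of rate alpha, rare jumps to a uniform
level at rate beta). The filter discretizes x on 100 uniform levels on
[1e−3, 1] and per sample applies (i) a three-point diffusion kernel
[alpha, 1−2·alpha, alpha] with reflecting ends, (ii) an additive uniform
mass beta, (iii) the likelihood, and renormalizes; the output is the
posterior mode.

Discrete semantics of the tuning constants: **alpha is the kernel weight
in grid-cell units at the reference 100-level grid**; the tuned default
0.5 is the maximal-diffusion kernel [0.5, 0, 0.5]. On other grid sizes
the weight is rescaled by (cells/99)² and split into stable sub-steps, so
the diffusion per sample is resolution independent and the estimate
converges under grid refinement (verified: 64 vs 256 levels differ by
< 0.02 RMS). The default beta = 5e−31 effectively disables jumps but
keeps the posterior from developing absorbing states; both are
configurable (`SangerConfig`).

The filter's known properties, reproduced by the tests: sharp on/off
transitions, decay to the grid floor in silence, and an onset lag of a
few tens of milliseconds (≈30 ms on synthetic steps) — within the 10–100
ms electromechanical-delay range between EMG and force production, which
is why this estimator feeds the mechanics better than a bandpass
envelope.

Preprocessing removes the DC offset, clips at ±5 SD (artifact guard),
normalizes to the resulting maximum, and rectifies. MVC normalization
divides by the average of the strongest suprathreshold burst of ≥ 1 s in
a calibration trial, renormalizing to 1 if the walking trial exceeds it.
Without MVC trials the absolute drive scale is unidentifiable; the
identification stage absorbs it into F_max, so the pipeline leaves
estimated drives on the filter's own scale in that case.

Activation dynamics: da/dt = (x−a)(x/tau_act + (1−x)/tau_deact) for
x ≥ a, (x−a)/tau_deact otherwise, integrated with an exact exponential
step per sample (unconditionally stable; matches the closed-form step
responses to 1e−9 when the drive is constant per interval). Defaults:
tau_act 12 ms (18 ms for the slow-dominant soleus), tau_deact = 4 ×
tau_act; sub-threshold drive (default 0.05) is treated as silence.

Gait-cycle averaging resamples heel-strike-anchored cycles to a percent-
gait-cycle grid and discards outlier cycles whose RMS distance to the
pointwise median exceeds median + 3·1.4826·MAD (plus a tiny absolute
floor so float jitter never flags identical cycles). The exact discard
rule is not prescribed by the underlying method; this robust rule
discards ~5–10% of cycles on realistically noisy input.

## Muscle-tendon mechanics

Constitutive curves (all constants per muscle via `MTUParams`):

* active force-length: f_l = exp(ln(0.05)·|(l_CE−l_opt)/(l_opt·w)|³) —
  a bell of half-width w (0.5–0.56 by muscle) decaying to 0.05 at the
  edges;
* force-velocity: concentric Hill hyperbola
  f_v = (v_max−|v|)/(v_max+K|v|) with K = 5; eccentric branch
  f_v = N − (N−1)(v_max+v)/(7.56·K·v+v_max), saturating at N = 1.5;
  v_CE > 0 is lengthening;
* parallel element: quadratic above l_opt, reaching F_max at l_opt(1+w);
* tendon: F_SE = F_max·(exp(K_sh·lambda/lambda_ref)−1)/(exp(K_sh)−1) for
  positive strain lambda, zero when slack; F_SE(lambda_ref) = F_max by
  construction;
* pennation: constant muscle width, theta = arcsin(l_opt·sin(theta0)/l_CE),
  clamped just below 90° (with a warning) if the fascicle falls below the
  geometric minimum;
* v_max = (6 + 6·FT) l_opt/s from the fast-twitch fraction FT.

Two closed-form consequences used as oracles: the shortening speed
maximizing CE power is (√(1+K)−1)/K ≈ 0.29 v_max for K = 5 (0.28–0.32
across K ∈ [4, 5]), and the metabolic model's efficiency peaks at a
slower speed (≈0.18 v_max in this calibration) — the classic ordering of
the low-energy, maximum-efficiency, and maximum-power operating speeds.

**Damped equilibrium.** The single state per muscle is l_CE; velocity
comes from the series force balance. The classical (undamped) balance
F_SE = (a·F_max·f_l·f_v + F_PE)·cos(theta) has no solution when a
passive stretched muscle over-balances a slack tendon or when the load
exceeds the eccentric plateau, and regularizing by velocity clamping
produces chatter. The simulator therefore solves the damped balance

    F_SE/cos(theta) = a·F_max·f_l·f_v(v) + F_PE + c·v,

with a light damper c = 0.1·F_max/v_max in parallel with the CE. Each
force-velocity branch then yields a quadratic in v with a unique
admissible root (closed form, verified against bisection to 4e−15), the
velocity is defined for any activation including zero, and force-balance
residuals at output samples are machine zero. Velocities are capped at
[−v_max, +2·v_max]; cap hits are counted in `MTUTrace.clamped` (zero on
all synthetic truth subjects). `solve_ce_velocity` separately exposes the
classical undamped inversion (with an activation floor and a no-root
error) for isolated-state analysis.

Integration: two gait cycles from a quasi-static initial condition
(static equilibrium at t = 0; PE rest length if the tendon is slack),
with the second cycle reported. Two paths: a compiled fixed-step Heun
scheme at 8 substeps per 125 Hz mechanics sample (1 ms; refined
automatically for reference strains below 0.02), and SciPy's LSODA as a
variable-step stiff reference. They agree to a few 1e−3 l_opt on walking
inputs and the fast path costs ~0.5 ms per muscle-cycle, which is what
makes the evolutionary identification tractable on one CPU.

The rigid-tendon limit (lambda_ref → 0.002) reproduces
l_CE = (l_MTC − l_sl)/cos(theta) within 1% of l_opt when checked on a
loaded short-tendon muscle (TA): the residual deviation is the tendon's
own elastic stretch, which scales with l_sl/l_opt, and a slack tendon at
low activation legitimately leaves the fascicle untracked.

Joint moments are tau_j = Σ_i F_MTC,i·r_ij(theta_j), biarticular muscles
contributing at both joints. The hip flexor ligament is a linear rotary
spring engaging in extension beyond theta0_HFL (flexion positive), adding
a pure flexion moment at zero metabolic cost.

## Energetics

Per-muscle metabolic rate (W per kg of muscle) is the sum of activation
heat, maintenance heat, shortening/lengthening heat, and positive CE work
rate. Calibration (`UmbergerCoefficients`, all overridable): combined
activation+maintenance heat 128·FT + 25 W/kg split 40/60, the maintenance
part scaled by f_l above optimal length; shortening coefficients
alpha_S(ST) = 100/ṽ_max(ST), alpha_S(FT) = 153/ṽ_max(FT) with
ṽ_max(ST) = ṽ_max(FT)/2.5 (velocities in l_opt/s); lengthening
coefficient alpha_L = 4·alpha_S(ST); excitation/activation factor
A = u if u > a else (u+a)/2, entering as A^0.6 (activation/maintenance),
A² (shortening), A (lengthening); aerobic scale S = 1.5; negative CE work
excluded (work-rate term floored at zero), so every component is
nonnegative and total ≥ work rate. The exact printed coefficient set of
the source model could not be consulted offline; this is the widely
reproduced calibration and is carried as named, documented constants.

Muscle mass is M_i = rho·F_max·l_opt/sigma with rho = 1059.7 kg/m³ and
sigma = 0.25 MPa. Whole-body cost over a window T doubles one leg's
muscle energies (bilateral symmetry) and bills the remaining body mass at
the measured basal rate; MCOT = C_met/(M·g·v·T) is gross (basal
included), with a dimensionless value ≈ 0.12 for the basal-only limit at
1.25 m/s. Phase fractions integrate summed muscle rates over the
double-support, single-support, and swing partitions defined by both
legs' events. Positive-work efficiency divides total positive CE work by
total muscle metabolic energy (muscle-only denominator — whether basal
cost belongs in that denominator is not prescribed; the muscle-only
variant is implemented and documented).

## Identification

`MorphologyVector` fixes the parameter ordering: muscles in the canonical
registry order, each contributing (F_max, length_scale, K_sh,
lambda_ref), then (K_HFL, theta0_HFL) — 50 values for the full leg.
Bounds: F_max in [0.5, 3.0] × a reference strength; K_sh in [2, 5];
lambda_ref in [0.02, 0.09]; the length-scale interval is computed per
muscle in closed form so a rigid-tendon fascicle sweep over the cycle
stays inside [l_opt(1−w), l_opt(1+w)]; the ligament may engage up to 10°
of flexion with stiffness up to twice the peak hip moment per radian of
peak extension.

The search is an elitist NSGA-II: uniform full-space initialization (no
seeding), binary tournament on (rank, crowding), SBX crossover
(eta = 15) for 80% of offspring with light per-gene Gaussian refinement
(probability 1/n, SD 2% of range), all-gene Gaussian mutation (SD 2% of
range, resampled into bounds) for the rest, and nondominated-sort +
crowding survivor selection. Failed simulations receive dominated penalty
costs (10 × basal-only cost, C_kin = 2) instead of raising. The returned
front is the nondominated archive of *every* candidate evaluated, which
is denser than the final population and makes front quality monotone
over generations by construction. Presets: `PAPER_SCALE` (population
1000 × 100 generations, the production setting) and `DESK_SCALE`
(64 × 20, minutes on one CPU).

**Local refinement of the best-fit corner.** At desk-scale budgets
(~4·10³ evaluations vs ~10⁵ at production scale) the genetic search
reaches C_kin ~1e−3, while discriminating ~15% strength errors requires
~1e−4: the objective landscape has long curved valleys in which a muscle
compensates a wrong F_max with re-tuned tendon parameters. After the
generational loop the best-kinetic-fit corner is therefore polished by
multi-start Levenberg–Marquardt on the standardized joint-moment
residuals (starts: mutually distant low-C_kin archive points), including
one *mirror trial* per muscle: the symmetric force-length bell admits a
paired solution with the operating range reflected about l_opt, which
forms a separate local basin no local step crosses; the mirror start
reflects the length scale accordingly. This is the analog of the hybrid
local-solver option in the optimizer family the production setting used,
is deterministic, and is configurable (`polish_starts = 0` disables). On
the noiseless 3-muscle benchmark it takes recovery from ~35% strength
errors to < 3% at C_kin < 2e−6 in 5/5 seeds.

## Selection

Along the front, each muscle's fraction of whole-body metabolic cost
(both legs, basal included) is fit as a fifth-order polynomial of mean
R² (degree reduced with a warning on small fronts). The vastus fraction
F_VAS — the largest consumer, and the one that ramps as the optimizer
overfits — defines Delta_VAS(R²) = (F_VAS(R²) − F_VAS(min R²)) /
(F_VAS(max R²) − F_VAS(min R²)), evaluated on the fitted curve. The
chosen solution is the maximum-mean-R² front member with Delta_VAS
strictly below the cutoff (default 0.63); ties break toward lower
metabolic cost. Strict inequality is a choice (the boundary convention is
not prescribed); raising the cutoff never lowers the selected fit.

## Synthetic data: what it emulates and what it does not

The generator produces one averaged mechanics cycle at 125 Hz (joint
angles as ≤ 5-harmonic Fourier series shaped like sagittal walking, with
the hip passing vertical before toe-off so the ligament can engage),
several cycles of 1000 Hz EMG drawn from the exponential observation
model around periodic drive templates, heel-strike/toe-off events for
both legs (toe-off at 62% GC, half-cycle contralateral shift), and joint
moments forward-simulated from a known morphology plus Gaussian noise
(SD 2% of the per-joint range — keeping truth R² near 0.99). Moment arms
are linear in joint angle with anatomical signs, and MTU lengths are the
exact excursion integrals of those moment arms, so geometry consistency
(l̇_MTC = −Σ r θ̇) holds analytically. Drive templates follow the
qualitative on/off timing of walking (dorsiflexor around heel strike and
swing; soleus early-and-broad in stance vs gastrocnemius concentrated at
push-off — a separation that real EMG shows and that makes the two
plantarflexors' strengths identifiable; knee extensors in early stance;
hip flexors around toe-off; hamstrings in terminal swing) without
claiming subject-level amplitude fidelity. Default subject: 70.4 kg,
1.77 m, 1.25 m/s, basal 1.5 W/kg, 1.1 s cycle.

Passing the recovery tests therefore shows that the estimator chain is
correct and well-conditioned *under the model's own assumptions*; it
does not validate the Hill curves, the metabolic calibration, or the
lumped-muscle geometry against a living subject, and real data adds
motion artifacts, electrode variability, marker noise, and out-of-
sagittal-plane mechanics that the generator deliberately omits. Ground-
truth morphologies are drawn uniformly from the inner 70% of the bounds
box, which skews strong relative to anatomy (MCOT on synthetic truth
subjects lands near 0.8 vs ≈ 0.35 for real walking); recovery, not
physiological realism of the draw, is the purpose.

A separate front generator plants the overfit-tail geometry (vastus
share rising promptly at the tail onset, metabolic cost blowing up deep
in the tail) to exercise the selection stage with a known ground-truth
cost.

## Numerical choices and degenerate inputs

* Mechanics grid 125 Hz, EMG 1000 Hz; fixed-step integrator at 1 ms with
  automatic refinement for ultra-stiff tendons.
* Quasi-static initialization; the first of the two simulated cycles is
  discarded (contraction transients are tens of ms against a 1.1 s
  cycle).
* Degenerate parameter intervals (lower == upper) pin a parameter; zero
  moment arms yield constant MTU length; constant EMG is rejected (zero
  variance); fronts with indistinguishable R² refuse budget fitting.
* Bit-level determinism: every stochastic stage takes an explicit seed;
  identical seeds reproduce datasets, fronts, and reports exactly.
* Test problem sizes: the recovery benchmark uses the 3-muscle ankle
  subsystem (population 96 × 40 generations, 5 seeds) and the full
  12-muscle model at the desk preset; both chosen so the whole suite
  runs in minutes on one CPU.

## Known limitations

* No activation-dependent optimal length, force enhancement/depression
  history effects, or tendon damping; the CE damper is a numerical
  regularization, not a fitted tissue property.
* The metabolic coefficient set is literature-standard but not verified
  against the original source tables; all constants are configurable.
* Hip-adjacent muscles in the sagittal model carry small effective
  moment arms; their parameters are weakly identifiable from sagittal
  moments alone (true of the method, not just the implementation).
* MVC-free operation leaves drive scale inside F_max, so identified
  strengths are interpretable only up to that calibration when no MVC
  trial is supplied.
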