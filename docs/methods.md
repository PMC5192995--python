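# Methods

## Structural model

Two coupled states describe one animal: tumor volume T (mm³) and the
vessel-dependent carrying capacity V (mm³), the maximum tumor volume the
current vasculature can support.

- Untreated: dT/dt = α_T·T·(1 − T/V); dV/dt = α_V·T^β·V^γ with β = 2/3,
  γ = 1/3 fixed.  The capacity is stimulated by the hypoxic tumor rim
  (∝ surface area, hence T^{2/3}); γ = 1 − β makes vessel growth
  asymptotically exponential.  β and γ are not identifiable from size data
  and are never estimated.
- Antiangiogenic treatment adds vessel kill −δ_V·V and the normalization
  window: the effective capacity in the tumor equation becomes N(t)·V with
  N(t) = N_max ≥ 1 strictly inside (t_norm1, t_norm2) and 1 outside (the
  boundaries belong to the outer branch).  The *monotonic* model variant is
  the same system with N ≡ 1.
- Combination therapy adds a kill term −δ_T·C·T·e^{−λ(t−t_C_on)} with the
  algebraic intratumoral concentration C = α̃_C·N·V·e^{−k·mod(t,1)} inside
  the daily dosing window (t_C_on, t_C_off) and 0 outside.  C is evaluated
  inside the right-hand side; it is not a third state.

Two interpretation choices in the combination model deserve note, both made
so that the model reproduces the documented qualitative behavior of the
system rather than degenerate dynamics: (i) the resistance clock starts at
chemotherapy onset (t − t_C_on), expressing resistance acquired under drug
exposure — with a clock anchored at inoculation, a long course dosing a
superset of days can never do worse than a short one, contradicting the
window-timing effect the experiment is about; (ii) the capacity volume
enters the delivery term in milliliters (1 mm³ = 10⁻³ ml), keeping C at a
fraction of a mg/ml; per-mm³ delivery would give concentrations of
hundreds of mg/ml and instant eradication under any regimen.

Default parameter values (population-typical): α_T = 0.109/day,
α_V = 0.119/day, K = 1.14, δ_V = 0.113/day (bevacizumab) or 0.115/day
(vanucizumab), N_max = 6.7, window 53.4–59.2 days, T0 = 70 mm³; chemo
constants α̃_C = 1, k = 0.9/day, δ_T = 0.12, λ = 0.08/day.

## Numerics

The public simulator (`simulate_individual`) integrates with LSODA at
rtol 1e-8, restarted at every discontinuity of the right-hand side (window
edges, dosing switches, each integer day inside the dosing window), with
the piecewise branches frozen per segment so no adaptive step straddles a
jump.  The estimation machinery uses a fixed-step RK4 on the same
segment-snapped grid (`_ode.integrate`); at its default step of 0.5 days
the two agree to ~3·10⁻⁸ relative, and the test suite cross-checks them.
States are floored at 10⁻¹² mm³ under the fractional powers; trajectories
that undershoot zero by more than 10⁻⁶ raise instead of being clipped.

## Synthetic trials

`simulate_trial` emulates the reference study design: arms
(control/bevacizumab/vanucizumab) × 10 animals, measurement days
38, 42, 45, 49, 52, 56, 59, 63, 66, 70 (the published schedule gives only
"twice per week for 5 weeks"; these ten days include the days named in the
diagnostic discussion), T0 log-normal with mean 70 mm³ and CV 30% (only
the mean is published), individual parameters φ_i = θ·exp(η_i) with
η_i ~ N(0, ω²) and the window draws redrawn to keep t_norm1 < t_norm2,
proportional noise y = f·(1 + b·ε) with redraws of non-positive values.  A
single master seed spawns independent per-animal streams.  What the
generator does **not** emulate: caliper-geometry measurement error
structure, dropout/sacrifice, inter-occasion variability, or any
model-misspecification — so passing recovery tests demonstrate estimator
correctness under the assumed model, not robustness to real-data
violations of it.

## Estimation

SAEM with an MCMC E-step: per animal, a prior-independence Metropolis
kernel plus componentwise random walks (3 passes/iteration) whose step
sizes adapt per animal and component toward ~30% acceptance.  Burn-in
(500 iterations, stochastic-approximation step 1) is followed by 500
smoothing iterations with a 1/k schedule.  The M-step is the closed-form
conjugate update.  Stability machinery that proved necessary on this
model's likelihood surface:

- η-recentering: when the M-step moves μ, individual η are shifted so each
  animal's φ is continuous across the update; without it one badly-mixed
  iteration after a large μ jump can inflate the residual statistic,
  explode b, flatten the likelihood and destroy the fit;
- growth caps during burn-in (ω² at most ×1.05/iteration, b² at most
  ×1.3) plus the usual simulated-annealing floors, and a 100-iteration
  freeze of the IIV while the fixed effects find their basin;
- truncated individual priors on a physiological box (rates < 5/day,
  K ∈ [10⁻³, 100], window start within the observation horizon, window
  length 0.25–35 days, window end within the horizon, T0 ∈ [1, 10⁴] mm³);
  without the box, burn-in can escape along the N_max → ∞ ridge.

Internal parametrization: all individual parameters are log-normal, with
three estimated on transformed scales — T0 as a latent individual
parameter (the day-38 record is an ordinary noisy observation; conditioning
the initial state on the observed value would be inconsistent with the
generative model and biases α_T upward by tens of percent), the window
amplitude as N_max − 1 (the window can only enhance the capacity), and the
window end through the window *length*.  Ordered-window truncation of two
independent log-normals was tried and rejected: it removes ~23% of the
joint prior mass, the naive M-step then ratchets the window wider every
iteration, and the truncation-corrected M-step is flat along the gap
direction.  Reported estimates are always on the natural scale (N_max,
t_norm2 in days), with delta-method standard errors.

Initialization defaults to neutral heuristics (growth rates ~0.1–0.15/day,
K = 2, window at the 45%/70% points of the observation span, T0 at the
geometric mean of the first observations); for refits of the published
model the examples and the acceptance script initialize at the published
population values, the standard practice when a literature model is
re-estimated.

After convergence: empirical Bayes modes per animal (L-BFGS-B +
Nelder-Mead polish), marginal log-likelihood by *defensive* importance
sampling (half the draws from a Gaussian at the MAP with inflated
inverse-Hessian covariance, half from the population prior; the mixture
bounds the weights, guaranteeing finite variance), BIC = −2LL + ln(n)·d
with n the number of observations and d the number of estimated typical
values + estimated IIVs + 1 error parameter, RSE from the linearized
(first-order) Fisher information, and shrinkage 1 − Var(η̂)/ω̂².  An
optional iterated maximum-simulated-likelihood refinement of (θ, ω, b)
with re-anchored defensive draws per round is available
(`SaemSettings.polish`) but off by default: on this model's flat ridge it
did not measurably improve placement for its cost.

## Identifiability — what these data can and cannot say

With K ≈ 1.1 the tumor starts at ~90% of its capacity, so the logistic
relaxation rate α_T is barely expressed; and α_V and δ_V enter the
capacity equation through a near-cancelling difference (V starts close to
equilibrium).  The linearized Fisher information of the default design at
the default population values gives RSE ≈ 3% for the window times, ~5% for
b, ~6% for T0, ~27% for K — but ~85% for α_T, ~98% for α_V, ~113% for δ_V
and ~367% for N_max, and direct likelihood evaluation confirms that
coordinated ±40% displacements of the weakly identified block change the
marginal log-likelihood by only a few nats.  Consequences: (i) recovery
experiments reproduce the window times, b, T0 and K tightly, while the
vessel-turnover block scatters widely with a modest downward median bias —
that is the information content of the design, not an estimator defect;
(ii) model comparison and the window location, the analysis' scientific
conclusions, are unaffected; (iii) denser sampling (daily measurements)
visibly tightens the weak block, which `richness_study` demonstrates.

## Diagnostics

CWRES by FOCE-style linearization around each animal's EBE (whitened with
the Cholesky factor of FΩF′ + R).  Under the generating model the pooled
residuals are calibrated to mean ≈ 0 with variance ≈ 1.15 — slightly above
1 because the linearization understates the spread of this strongly
nonlinear model.  The VPC simulates replicate trials from the fitted
population law (including the fitted T0 law), bins at the nominal
measurement days (the design is balanced; no binning algorithm), and draws
90% bands on the 10/50/90% quantiles; within one dataset the quantile
curves share the same 30 animals, so band exceedances are strongly
correlated and coverage should be judged pooled over datasets.  Structural
misfit of the no-window model shows up as an ordered
positive-then-negative excursion of the treated-arm mean CWRES (volumes
underestimated during the growth burst, overestimated after the window
closes); which calendar days carry the signs depends on how the
measurement grid aligns with the window.

## Model selection

`select_model` encodes the explicit rule set: lower BIC wins; ties
(|ΔBIC| < 2) go to fewer parameters; and a diagnostics override — if the
BIC-preferred model alone shows the transient residual signature (or gross
arm-mean misfit), the competitor is selected and the override is logged.
The override exists because the parameter penalty of the BIC does not see
*structured* residuals, which are direct evidence of missing dynamics.
Error models (proportional vs constant) are compared by −2ΔLL and a Wald
statistic on the error coefficient.

## Chemotherapy scheduling

The scheduling experiment integrates the population-typical
vanucizumab-treated animal (no IIV) from day 38 to day 73 under three
regimens — daily dosing on days 42–49 (before the window), 54–61 (inside
it), and 38–59 (a three-week course from treatment start) — plus the
monotherapy reference.  Daily dosing is realized entirely through the
mod(t, 1) intra-day decay; there are no separate bolus events.  Final
volumes order in-window < three-week < pre-window < monotherapy: dosing
inside the window wins because normalized vessels deliver more drug
(C ∝ N·V), and the long course loses to the targeted week because
resistance has eroded its effect by the time the window opens.  The
ordering is unchanged under λ ± 20% and under solver-tolerance halving.

## Known limitations

- Antibody pharmacokinetics are not modeled (saturating exposure assumed),
  and there is no spatial or agent-based vasculature.
- The weakly identified block (α_T, α_V, δ_V, N_max) should be read as a
  coupled complex on this design; single-parameter point estimates from
  10-point-per-animal data are not individually meaningful.
- The sampler does not reach the exactly-noiseless limit: at b → 0 the
  individual posteriors become points and recovery saturates at the ~5–10%
  level rather than machine precision.
- CWRES relies on first-order linearization; its variance calibration is
  ~15% above unity under strong nonlinearity.
- The IIV matrix is diagonal (no correlations, no covariates, no
  inter-occasion variability), matching the reference analysis.
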