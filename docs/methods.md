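# Methods

## The labelling model

Each memory subset (central or effector memory CD4 T cells) is treated as
a population in quasi-equilibrium over the 35-day assay: a constant influx
Φ (cells/day) of newly generated memory cells enters, cells divide at
rate α and are lost (death plus onward differentiation) at rate δ, and
the balance Φ = Σ (δᵢ − αᵢ) Nᵢ holds. The state tracks, per cell,

* subpopulation A/B (the kinetic structure),
* Ki67 status — high for a mean duration T = 1/β after division, modelled
  as a single exponential stage by default with optional Erlang stages
  (`ki67_stages`),
* BrdU content (labelled/unlabelled),
* lineage (host/donor in a busulfan chimera).

Division removes the parent and creates two Ki67-high daughters. During
the pulse, both daughters of an unlabelled parent become labelled with
probability ε (expectation-level fluxes 2εαU and 2(1−ε)αU); daughters of
a labelled parent inherit the label; label dilution below detection is
neglected (pulse ≤ 21 d). The chase is the same system with ε = 0 and the
source labelling on its decay branch. Influx enters Ki67-high, split
host/donor by the influx donor fraction f_d, and carries a labelled
fraction s(t); by default s(t) = s_max (1 − e^(−r_s t)) during the pulse
and exponential decay (rate r_decay) afterwards, with defaults
s_max = 0.3, r_s = 0.1/d, r_decay = 0.05/d — a saturating imprint of
labelling in the precursor pool. The exact mechanistic form of the source
labelling is not identifiable from the target population alone, so the
parametric form is a stated modelling choice, exposed in
`LabellingSchedule` and replaceable by any callable.

Structures and their conventions (fixed throughout):

| structure | A | B | transitions | influx enters |
|---|---|---|---|---|
| branched | slow | fast | none | ψ into A, 1−ψ into B |
| linear | fast entry state | slow descendant | A→B at γ (Ki67/BrdU preserved) | A |
| burst | quiescent | burst | A→B at ω, B→A at ρ | B |
| temporal | single pool | – | – | A |

Burst-model influx entering the burst state reflects the assumption that
new memory cells have recently divided; this placement is a documented
choice, not data-driven.

The system is linear in the state, so: steady states are direct linear
solves restricted to the subpopulations actually fed by influx or
transitions (an unreachable subpopulation is structurally empty, and its
inert block would otherwise make the equations singular); Φ = 0 requires
exact birth–death balance and a supplied pool size N0, otherwise a
`NoEquilibriumError` is raised — never silent clipping. Trajectories use
LSODA (`rtol 1e-8`, `atol 1e-10·N0`) split at the pulse→chase switch; an
exact semi-analytic path (eigendecomposition of the augmented
constant-plus-exponential-forcing system, with a dense `expm` fallback
when the eigenbasis is ill-conditioned) provides the same solution ~50×
faster for inference. The two paths agree to 1e-6 in the tests, and an
independent Gillespie simulation of the same reaction scheme (pool size
1e4, 10-day horizon and 10 replicates, scaled for CPU budget) reproduces
the ODE observables within Monte-Carlo error.

## Inference

Each fit describes one timecourse (subset × lineage × cohort).
Quasi-equilibrium is enforced by construction: the initial condition is
the steady state implied by (Φ, rates), so the pool size N0 is a derived
quantity constrained through the count likelihood. Free parameters are
the natural rates — for the branched structure α_A, λ_A = δ_A − α_A, α_B,
λ_B, ψ, Φ, β, ε — plus five observation-noise scales. Net-loss
parametrisation keeps δ > α automatic where an equilibrium requires it;
for burst/temporal the steady state is solved and non-physical
combinations are rejected. The convention "A is the slow/quiescent
subpopulation" (α_A ≤ α_B for branched and burst) is an identification
constraint that removes the relabelling symmetry of the posterior, not a
prior belief.

**Likelihood.** Fractions enter on the logit scale with normal errors and
per-observable scales; counts on the log scale. Boundary values (0 or 1)
are moved inward by the continuity correction 1/(2·n_cells), applied to
both observation and model prediction so that an exactly-zero prediction
matching an exactly-zero observation contributes a zero residual.
Undefined observations (NaN — empty denominator in the gate) contribute
zero and are counted.

**Priors.** Defaults: log-normal on rates (median 0.03/d, broad),
Beta(2,2) on fractions, half-normal(0.3) on noise scales, and a broad
log-normal on Φ centred at 3% of the observed pool size per day. For real
analyses the Φ prior should come from the chimerism module
(`influx_prior_from_estimate`). All priors are overridable and
YAML-serialisable.

**Sampler.** An ensemble sampler mixing differential-evolution moves
(proposals along the difference of two complementary walkers, step
2.38/√(2d) adapted toward 25% acceptance during burn-in only) with
stretch moves. The posterior can be multimodal — a slow-division /
high-labelling-efficiency basin competes with the dominant one — so
initialisation is a multi-start Nelder-Mead refinement of the best prior
draws, with the ensemble started around the best mode found and
re-inflated by the DE kernel during burn-in. Convergence is summarised by
split-R̂ and bulk ESS (arviz, walkers as chains); fits exceeding R̂ 1.01
are flagged `valid=False`. At the reduced draw counts used in the test
suite (≈1,200 steps × 32 walkers) R̂ typically remains above that gate;
the flag reports this honestly, and parameter-recovery coverage is
checked across replicates rather than through the gate. Production fits
should raise `n_steps` severalfold.

**Model comparison.** PSIS-LOO on the per-row pointwise log-likelihood of
thinned draws; models within |ΔELPD| < 4 are reported indistinguishable;
fractions of Pareto-k̂ above 0.7 raise a reliability warning.

**Identifiability.** Refitting model-generated noisy data exposes the
structural confound between the influx and the net loss of its direct
descendants. Because the branched influx splits over two descendants, the
flag is the multiple correlation of log Φ on the descendants' log
net-loss rates (threshold 0.9) rather than a single pairwise correlation;
pairwise |r| > 0.9 pairs are reported alongside. An informative influx
prior clears the flag.

## Chimerism

The donor fraction F of a quasi-equilibrium population fed at per-capita
rate φ from a source of chimerism χ_src(t) follows
dF/dt = φ (a·χ_src(t) − F), F = 0 at transplant. The scaling a ∈ (0, 1]
lets a population saturate below its source — the signature of older
(host) cells surviving better than newer (donor) ones — and is the
pragmatic stand-in for explicitly age-structured loss; `model="simple"`
pins a = 1. The fitted f_d(t) = a·χ_src(t) is the chimerism of the
influx: it feeds the labelling fits as a prior and, compared with the
observed chimerism of candidate upstream populations (thymic DP1, naive,
central memory), orders the differentiation pathway by distance of
medians.

## Derived quantities

All posterior-derived quantities are computed per draw and summarised
afterwards. Subset mean loss rates weight δ of fast and slow cells of
both lineages by subpopulation sizes; the aggregate over subsets weights
the *loss rates* by abundance (EM:CM ≈ 7.5) and inverts — lifespans are
inverse rates, and rate-weighting is the canonical aggregation; the
lifespan-weighted alternative is reported alongside.

The two quick estimators are approximations with known error structure:

* 2ε/p (upslope): exact only for the initial slope. Over the default
  0–4 d window the fast subpopulation already saturates and the influx
  labelling still lags, biasing the estimate upward — ~60% in the default
  synthetic world, shrinking below 30% for a densely sampled 0–1 d
  window. The 0–4 d default matches realistic sampling density; treat the
  output as an upper bound.
* −T/ln(1 − k/2) (Ki67): with the printed inputs (k = 0.4/0.2, T = 3.1 d,
  EM:CM = 7.5) gives 26.0 d rate-weighted (27.6 lifespan-weighted). The
  Ki67-high duration is exponential in the ODEs while the estimator
  treats it as a fixed duration T; the discrepancy is part of the
  estimator's approximation, not of the model.

## Predictions

Both fate-reporter simulations reuse the labelling machinery with the
label axis reinterpreted as a heritable reporter (ε = 0, label moved only
by influx composition). Cohort transfer: the steady state with all
Ki67-high cells YFP-labelled evolves 3 days in the donor animal before
transfer, then with or without influx; the uniform-rate null (homogeneous,
δ = α, Φ = 0) preserves the cohort's Ki67 level exactly, which is the
falsification logic for constant rates. Reporter dilution: the
central-memory source is the fitted naive curve
g(t) = f_∞ + (f_0 − f_∞)e^(−rt) (non-increasing by construction); the
effector-memory source is the predicted central-memory trajectory, or
optionally the naive curve for the pathway comparison; bands are 2.5–97.5
percentiles over posterior draws.

## Synthetic world

The generator emulates the study design: 21-day pulse + 14-day chase,
observation days (1, 2, 4, 7, 10, 14, 17, 21 | 24, 28, 31, 35), 2 mice
per timepoint per lineage, two age cohorts, logit-normal noise (SD 0.25)
on fractions — which keeps them strictly inside (0, 1) — and log-normal
noise (SD 0.2) on counts. Default ground truth (branched): fast cells
α = 0.25/d, δ = 0.265/d; slow cells α = 0.007/d, δ = 0.013/d; T = 3.1 d;
ε = 0.5; influx at equilibrium, a few percent of the pool per day; the
influx split ψ differs between host and donor so that donor cells are
fast-enriched, reproducing the higher donor Ki67 and the ~0.44 / ~0.2
Ki67-high fractions of central/effector memory. These values are stated
once and are not tuned against test outcomes.

What a green test does not establish: the generator shares its
observation model with the likelihood (logit-normal), so recovery tests
validate the inference machinery, not robustness to misspecified noise;
real flow-cytometry data add gating drift, mouse-level random effects and
non-exchangeable timepoints that the generator does not emulate.

## Known limitations

* Reproduction of the original study's fitted values requires the study's
  data workbook, which is not redistributable; the corresponding test
  fails with an explanatory message unless `data/S1_data.xlsx` is
  supplied.
* The ensemble sampler at test-suite draw counts does not reach R̂ ≤ 1.01;
  see Inference above.
* Intracellular BrdU pharmacokinetics, deuterium labelling, spatial
  effects and explicit cell-age-structured survival are out of scope; the
  asymptote scaling in the chimerism module is a reduced-form surrogate
  for the latter.
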