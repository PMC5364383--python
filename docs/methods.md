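# Methods

## Model

The core of the package is an integrated population model (IPM) for an
age-structured, two-sex songbird population censused just before breeding.
Three data streams are modelled jointly, sharing one set of vital rates:

**State process.** Stages are local recruits *R* (1-year-olds hatched in the
study area), surviving adults *S* (≥2-year-olds that bred there the previous
year) and immigrants *I* (unbanded arrivals, treated as 1-year-olds);
breeders are B = R + S + I per sex and year.  Transitions are binomial
(recruitment out of the fledgling pool, adult survival out of the breeder
pool, a 50:50 binomial fledgling sex split) or Poisson (total fledglings
with mean ρ·B_f, immigrant arrivals with mean ι).  Demographic
stochasticity is therefore explicit and the latent abundances are integers.

**Observation processes.** Sex-specific counts are lognormal around the true
breeder numbers with one shared σ_obs (the field counts are nearly exact, so
σ_obs is small and mainly guards against rounding and the occasional missed
bird).  Capture-recapture data enter as age/sex-specific m-arrays under a
Cormack–Jolly–Seber (CJS) likelihood; annual fledgling totals enter as
J_t ~ Poisson(ρ_t · C_f,t) with C_f,t the surveyed females.

**Vital-rate structure.** Each of the seven rate series (juvenile and adult
apparent survival by sex, fecundity, expected immigrants by sex) is modelled
on its link scale (logit for probabilities, log for positive rates) as
mean + Σ β·X_t + ε_t with standardized annual covariates X and temporal
residuals ε_t ~ MVN(0, Σ) joint across the seven rates.  Detection
probabilities have the same logit structure but independent normal residuals
per age-sex group.  Apparent survival confounds death with permanent
emigration; nothing in the model attempts to separate them.

**Derived quantities.** λ_t = B_{t+1}/B_t (sexes pooled) and the
combined-sex immigration rate ω_t = (I_{f,t+1}+I_{m,t+1})/(B_{f,t}+B_{m,t})
are computed per retained draw, so all downstream summaries carry posterior
uncertainty.

### Indexing conventions

Residual row t carries: survival over the interval t→t+1, fecundity of year
t, and the expected immigrants *arriving* in year t+1.  The winter weather
window (01 Nov–31 Mar, spanning the calendar boundary) is indexed to the
year in which it starts.  Both conventions together align a winter with the
mortality interval it acts on and with the immigration pulse it drives.
The survival and immigration components of the final residual row touch no
data; they remain in the MVN prior and the Σ update, which is equivalent to
marginalizing them.

### Age-structured detection

Birds banded as nestlings are released as juveniles; their first interval
uses juvenile survival and their first possible re-encounter (age 1) uses
the juvenile detection probability; at age ≥2 they use adult survival and
detection.  Birds first captured as adults (immigrants, birds of unknown
origin) use adult parameters throughout.  The m-array builder routes a
juvenile's first transition to the juvenile m-array of its sex and all later
transitions to the adult m-array.  This "age at occasion" convention keeps
all four detection parameters identifiable from the m-arrays.

### Priors

Survival and detection means: uniform on the probability scale (logistic on
the logit scale).  Log-scale means (fecundity, immigration) and all slope
coefficients: Normal(0, 10).  Σ: inverse-Wishart(I, df = 9), with an
independent half-normal(1) diagonal alternative behind a config switch.
Detection-residual SDs: Uniform(0, 10).  σ_obs: Uniform(0.001, 10).
Initial stage abundances: discrete uniform on [0, 300].  These are standard
vague choices for this model family; the package's validation rests on
parameter recovery from synthetic data, not on replicating any particular
prior.  σ_obs is time-constant by default (a per-year option exists but the
single-σ observation model is the default reading).

## Sampler

One chain is one compiled (numba) Metropolis-within-Gibbs sweep:

- discrete latents (R, S, I, F, F_f per sex-year): ±k integer random walks
  with adaptive k, plus composition-preserving pair moves (R↔I, S↔I, R↔S at
  fixed B) so the stage split keeps mixing when σ_obs is small and B is
  pinned to the counts;
- continuous scalars (means, slopes, residuals, detection block, σ_obs):
  adaptive Gaussian random walks targeting ≈0.44 acceptance, adapted every
  50 iterations during burn-in only (scales frozen afterwards, so the
  retained chain is a valid Markov chain);
- Σ: conjugate inverse-Wishart draw given the residual matrix (Bartlett
  construction).

Every update evaluates only the likelihood terms it can change; m-array
rows are recomputed only for release cohorts whose cell probabilities
involve the perturbed parameter.  A numpy reference implementation of every
likelihood block lives in `fullcycle.model`, and the compiled and reference
densities are held equal (≤1e-8) by test.  The m-array multinomial constant
is omitted throughout: it cancels in MCMC and its omission makes the
likelihood exactly equal to the product of per-individual history
probabilities, which is how the enumeration oracle checks it.

Support violations (e.g. a proposed R_{t+1} exceeding the fledgling pool)
evaluate to −∞ and are rejected; they never raise.  Chains start from
jittered prior medians and count-derived stage splits (gap years
interpolated); each chain's seed is spawned deterministically from the run
seed.  The study-scale schedule (3 × 1,000,000 iterations, 500,000 burn-in,
thin 100 → 15,000 draws) is the default config; tests and screening fits
use a reduced schedule (3 × 20,000, burn-in 10,000, thin 10), which recovery
tests show is enough for nominal interval coverage of the survival and
fecundity parameters at this data size.  Convergence is monitored with the
classic Gelman–Rubin statistic (flag threshold 1.005); constant chains
report 1 by convention with a warning.

## Covariate screening and the path model

Candidate covariates are screened one at a time: the full IPM is refit with
a single slope active, and "the 90% CI overlaps 0 least" is operationalized
as minimal two-sided tail mass 2·min(P(β>0), P(β<0)).  One winner is kept
per vital rate from the breeding-ground weather set and one from the
wintering set; every candidate whose 90% CI excludes 0 is carried forward.
Ties break to the larger |posterior mean|, then to candidate order.
Breeding density always enters the final model (de-trended — OLS residuals
on year — for fecundity, to avoid reading a shared long-term trend as
density dependence); winter density enters everywhere except the
immigration sub-model.  The density × winter-temperature interaction on
survival uses the product of the standardized main effects, not itself
re-standardized.

The path model is seven normal linear regressions refit to every retained
draw: λ on the six vital rates (four survivals, fecundity, ω), and each
vital rate on its covariate roster.  Gap-affected transition years (a
transition starting or ending in an unmonitored year) are removed listwise;
all series are then re-standardized within each draw (population SD), so
coefficients are standardized effects.  The indirect effect of covariate X
via vital rate V is β(X→V)·β(V→λ); cumulative effects sum over vital rates,
an identity that holds to machine precision by construction and by test.
The batched fit solves the per-draw normal equations for all draws at once
and is tested against per-draw `lstsq`.

## Synthetic data

The generator is individual-based: every fledgling, breeder and immigrant
is tracked, so the aggregated stage counts follow the state equations
*exactly*, and the encounter histories refer to the same individuals that
are counted — reproducing the real data's overlap between census and
capture-recapture streams.  Defaults emulate the study system the model
targets: 26 annual occasions; ~50–115 breeding adults; juvenile/adult
survival 0.2/0.5; fecundity 3 fledglings per female; ~8 immigrants per sex
and year; detection 0.93 (juvenile) / 0.96 (adult); count SD 0.05 on the
log scale; a 3-year monitoring gap at occasions 18–20; residual SDs
0.25/0.2/0.12 (juvenile survival & immigration / adult survival /
fecundity) with exchangeable correlation 0.3, which yields annual growth
rates spanning roughly 0.5–1.7.  Default covariate effects encode the
limitation-vs-regulation structure of interest: winter temperature +0.3 to
+0.35 (link scale, per SD) on survival and immigration; breeding density
−0.25 to −0.35 on fecundity, juvenile survival and adult male survival.
Covariate series are stationary Gaussian (iid by default; an AR(1) option
exists), with means/SDs chosen to look like coastal mid-Atlantic winters, a
Bay-of-Fundy breeding season, and a winter abundance index of ~0.84
birds·h⁻¹.

Monitoring rules in gap years: counts and productivity are missing (not
zero), detection is structurally zero, and gap-year fledglings are never
banded — if they recruit they are later first-captured as adults of unknown
age, exactly like immigrants.  Immigrants are detected with the adult
probability from arrival (their age-1 year), because the juvenile detection
parameter reflects natal-return behaviour of locally hatched birds; this is
the one place the generator and the CJS age convention had to be reconciled
by choice.

What the generator does *not* emulate: mis-sexing/mis-aging, transience or
trap response, sex-biased detection beyond the age split, spatial structure,
observation error in the covariates, and any carry-over of individual
condition.  Passing tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness to their
violation in real field data.

Because the breeding-density covariate is the population's own size, its
slope is endogenous: in-sample standardization and the feedback loop bias
single-replicate slope estimates away from the generating value.  Recovery
experiments therefore use exogenous (weather) covariates, where coverage is
nominal; density effects are validated by sign and by the end-to-end path
decomposition instead.  The same phenomenon — regression-to-the-mean in
density-dependence estimation — is why fecundity is screened against
*de-trended* density.

## Goodness of fit

Posterior-predictive checks cover the two blocks where they are standard:
the Freeman–Tukey statistic Σ(√m − √E)² over m-array cells, and the
chi-square discrepancy Σ(J−E)²/(E+10⁻⁶) for productivity, each compared
with replicates drawn at the draw's parameters conditional on the observed
release totals (CJS) and surveyed females (productivity).  Zero-release
rows contribute nothing.  No omnibus state-space check is attempted.  Note
that the model class is flexible enough to absorb a pure rescaling of the
fledgling counts into its fecundity mean and residual variance when
*refit*; the misfit sensitivity of the chi-square check is therefore
demonstrated by scoring perturbed data against a posterior fit to clean
data, which is the standard cross-data posterior-predictive construction.

## Problem sizes

The test suite fits at reduced scales chosen to exercise every claim on one
CPU: recovery coverage uses 20 replicate 26-year data sets at the reduced
schedule; GOF calibration uses 20 replicate 18-year data sets at a short
single-chain schedule; sign recovery uses 10 replicate 26-year pipelines;
the grid-oracle comparison uses a 3-occasion toy with 120 releases and a
160×160 grid coarsened to 16×16 bins for the total-variation comparison.

## Known limitations

- Immigration parameters are the information-poorest block (no direct data);
  they mix slowest and their slopes can be biased at short schedules.
- σ_obs can drift to its lower prior bound when the latent B can match the
  counts exactly; this is a known behaviour of state-space models with
  near-exact counts and is why the pair moves exist.
- The two-sex projection assumes female-limited reproduction (Poisson mean
  ρ·B_f) and no unmated birds.
- The CJS block conditions on first capture; banding effort is not modelled.
- Data streams overlap (counted birds are also in the m-arrays); the joint
  likelihood treats them as independent, following the established
  robustness results for IPMs of this form.
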