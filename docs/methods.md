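# Methods

## Model structure and assumptions

The consumer is a strict C:N homeostat: body composition is fixed at
θ_Z mol C (mol N)⁻¹, so growth G (day⁻¹, carbon-specific) consumes carbon
and nitrogen in that ratio, nitrogen exclusively via protein (C:N θ_V).
Lipid and carbohydrate are folded into one non-nitrogenous carbon currency;
the model does not resolve them separately, because digestibility data for
carbohydrate are rarely available in crustacean trials.  All rates are
biomass-specific (mol C (mol C)⁻¹ day⁻¹), which removes body-size scaling
from the model; temperature and allometric effects are out of scope, as is
any multi-day dynamics — each evaluation is a steady-state budget.

Energetic demand is

    C_E = sigma_SDA * (I_V + I_H) + xi_basal

by default charged on ingested carbon.  Whether specific dynamic action
scales with ingested or absorbed material is genuinely open physiology, so
`sda_base="absorbed"` switches the base to β_V I_V + β_H I_H consistently
in both modes; all invariants (conservation, inverse consistency) hold
under either choice.

The protein pathway must supply growth and turnover nitrogen, inflated by
1/k_N for synthesis overhead, plus the protein-fuelled share of energy
with its penalty surcharge:

    beta_V * I_V = theta_V (G + r_B) / (theta_Z k_N) + f_V (1 + phi) C_E

The non-protein pathway carries the remaining carbon balance:

    beta_H * I_H = (1 - theta_V/theta_Z)(G + r_B) + (1 - f_V) C_E

Design choices embedded here, made where the published description leaves
the functional forms open:

* **Penalty form** — a multiplicative surcharge (1 + phi) on protein carbon
  routed to energy; the surcharge carbon is respired.  The penalty is
  structurally inert when f_V = 0 (a tested invariant).
* **Turnover accounting** — replaced biomass is synthesised at the same
  1/k_N cost as growth; the displaced biomass carbon is respired and its
  nitrogen excreted, so r_B raises demand without adding retained biomass.
* **Synthesis overhead** — the (1/k_N − 1) share of protein routed to
  synthesis is respired as carbon and excreted as nitrogen.  These flows
  are not tracked term by term: the ledger closes respiration and excretion
  as exact residuals of the two conservation identities, which is both
  simpler and numerically exact (closure to machine precision, asserted to
  1e-10 relative in the tests).
* **theta_Z < theta_V is rejected** rather than silently crediting protein
  carbon surplus; a consumer more N-rich than protein is outside the scope
  the lobster application needs.
* **Forward-mode growth floor** — growth is the Liebig minimum of the two
  pathway-supportable rates, clamped at zero with a maintenance-deficit
  flag instead of returning negative growth; the waste ledger is still
  reported (starvation produces faeces and excretion, not an exception).

Reverse mode solves the 2×2 linear system in closed form (Cramer's rule);
an infeasible regime (singular system from excessive SDA, or a negative
required intake when one pathway oversupplies the other) raises a typed
error naming the cause.  An independent `numpy.linalg.solve` oracle checks
the closed form to 1e-12 in the acceptance tests.

## Parameters, units, defaults

| parameter | meaning | unit | default | rationale |
|---|---|---|---|---|
| theta_V | protein C:N | mol C (mol N)⁻¹ | 3.7 | framework default for body/model protein |
| theta_Z | consumer body C:N | mol C (mol N)⁻¹ | 4.5 | placeholder in the crustacean range |
| sigma_SDA | SDA fraction of intake C | – | 0.1 | placeholder; decapod SDA order of magnitude |
| r_B | biomass turnover | day⁻¹ | 0.001 | placeholder, small relative to observed growth |
| xi_basal | other basal costs | mol C (mol C)⁻¹ day⁻¹ | 0.002 | placeholder |
| f_V | protein share of energy | – | 0 | calibrated per feed |
| k_N | net protein synthesis efficiency | – | 1 | calibrated per feed |
| phi | penalty on protein fuel | – | 0 | calibrated per feed, only active when f_V > 0 |
| beta_V, beta_H | absorption efficiencies | – | 0.69 | framework default where unmeasured |

The four study-level constants (theta_Z, sigma_SDA, r_B, xi_basal) were not
printed with the trial tables; they are configuration, logged on every
pipeline run and overridable in `RunConfig.model`.  Per-feed parameter
estimates are sensitive to them; the structural results (conservation,
fit r², the 3.87/3.7 waste wedge, experiment contrasts) are not or only
weakly so.  The feed-protein C:N used for unit conversion and for the
conventional waste estimator is 3.87; the physiological budget keeps the
model protein C:N 3.7.  This deliberate split means the stoichiometric
faecal-N estimate sits 100·(3.87/3.7 − 1) ≈ 4.6% above the conventional
one whenever both use the same measured digestibility — the two estimators
differ by consumer-demand accounting *and* by protein C:N basis, and the
basis effect dominates for the protein-source experiment.

## Calibration

Per feed, the objective is the sum of squared *relative* intake errors at
the observed growth rate; relative errors keep protein and lipid intakes
(an order of magnitude apart) comparable, and growth enters as a hard
constraint rather than a third residual.  The search is deterministic:

1. vectorised coarse grid — step 0.01 for ≤ 2 free parameters, 0.02 for 3,
   0.05 for ≥ 4 (a 0.01 grid in five dimensions would be ~10¹⁰ points);
2. tie-break on the grid's flat set (objective within 1e-9 of the
   minimum): smallest f_V, then smallest phi, then largest k_N, then
   largest beta_V/beta_H;
3. cyclic per-coordinate golden-section refinement that accepts only
   strict improvements (so flat directions cannot drift);
4. when the refined fit is numerically exact and under-determined (≥ 3
   free parameters against 2 observations), a lexicographic polish pushes
   each parameter to its tie-break extreme as far as the remaining ones can
   re-absorb, by bisection.  The result is flagged `nonunique`: the point
   is the documented representative of a flat manifold, not an identified
   estimate.

Estimation is staged: phi stays at zero until the stage-1 fit (f_V, k_N,
and betas where free) leaves misfit above 1e-6 *and* f_V > 0, because the
penalty only acts through protein fuelling and freeing it earlier would
manufacture values from nothing.  Bounds: f_V ∈ [0,1], k_N ∈ [0.3,1]
(physiologically broad floor), phi ∈ [0,1], betas ∈ [0.3,1]; all
configurable.  Measured digestibilities always override estimation.
Experiments that measured no digestibility at all get beta_V and beta_H
added to the estimate set; an experiment missing only protein digestibility
uses the framework default beta_V = 0.69 instead, mirroring standard
practice for such trials.

## Waste analysis

"N waste" is faecal (egested) N only; metabolic excretion U_N is reported
separately and never folded in, so the model estimate and the conventional
I_V(1 − AD_N)/3.87 measure the same stream.  Experiment contrasts are
percent differences of per-experiment mean faecal N and are always printed
in both directions (percent change is asymmetric); the summary quantities
report each contrast with the larger experiment mean in the denominator,
i.e. how far the smaller experiment sits below the larger one, which is the
form in which such contrasts are quoted for these data.  Feed C:N from the
tabulated intakes alone, (I_V + I_H)·3.87/I_V, omits non-lipid carbohydrate
carbon and carries an explicit "approximate" flag.

## Synthetic trials

The generator emulates the packaged table's schema: truth parameters drawn
uniformly from intervals bracketing the per-feed estimates these data
support (f_V 0–0.2, k_N 0.65–0.95, phi 0–0.7, beta_V 0.6–0.95, beta_H
0.5–0.9), growth uniform on the observed 0.004–0.033 day⁻¹ range, exact
intakes from reverse mode, then multiplicative lognormal noise with mean
exactly 1 and CV 0.05 (proportional assay error; intakes stay positive).
Uniform draws (not Gaussian) exercise recovery across the whole admissible
box.  What the generator does *not* emulate: tank-level replication,
mortality, time-resolved growth, digestibility measurement error, or any
model misspecification — synthetic recovery therefore demonstrates that the
calibration machinery inverts the model correctly under its own
assumptions, not that the model is correct for real lobsters.

## Numerical choices and problem sizes

Flat-set tolerance 1e-9 on the squared-relative objective (≈ 3e-5 relative
intake error); refinement convergence at 1e-15 absolute improvement per
cycle, 60-cycle cap; bisection depth 30 in the tie-break polish.  The test
suite sweeps 1000 random parameter sets for conservation and inverse
consistency, 100 for the linear-solve oracle, 50 noise-free and 200 noisy
synthetic feeds for recovery; the full 17-feed reproduction runs in about
two seconds on one CPU.  Phi recovery is exercised with truth f_V ≥ 0.05
because the penalty is unidentifiable as f_V → 0.

## Known limitations

* The exact functional forms of the original supplement are not published
  with the trial table; this package's budget equations are an explicit,
  documented reconstruction, and per-feed parameter estimates (f_V, k_N,
  phi) can differ substantially from the originally reported ones while
  the structural statistics agree.  The reproduction report surfaces the
  deviations rather than asserting agreement.
* Two observations per feed cannot identify three or more parameters; the
  tie-break point is a convention, and `nonunique` must be checked before
  interpreting such estimates.
* Single-currency non-N pool, steady state, no temperature or size
  scaling, no dissolved-nutrient fate downstream of the animal.
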