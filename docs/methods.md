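# Methods

This note documents the models behind `dairygap`, the parameters that
matter, the synthetic-data generators used for testing, and the design
choices made where the design was genuinely open.

## 1. Top-decile benchmarking

For each agricultural zone the attainable yield is the mean milk yield
(kg per head per lactation) of the ⌈n/10⌉ most productive farms; the
relative yield gap is reported absolutely and as a percent increase over the
zone mean. Choices:

* **Decile size ⌈n/10⌉** guarantees a non-empty benchmark for small zones
  (a 10-farm zone benchmarks against its single best farm).
* **Ties at the cutoff** are resolved by taking earlier-indexed records, so
  the benchmark set always has exactly ⌈n/10⌉ members and results are
  permutation-invariant in the values (the tie rule only selects among
  equal values).
* **Rounding**: the displayed percent column rounds half away from zero to
  an integer; the unrounded value is retained on the result object. Two
  cells of the published regional table do not recompute exactly from its
  printed means (an absolute gap of 1666 where the printed means give 1665,
  and a percentage of 219 where they give 218.47); this implementation
  always reports its own arithmetic and the discrepancy is flagged in the
  acceptance test's comment rather than imitated.
* Ranking is by per-head yield with no breed stratification, matching the
  survey data the method is designed for.

## 2. Stochastic frontier analysis

A Cobb-Douglas output distance function with M outputs and K inputs is made
estimable by normalising with one output, giving the regression stated in
the README with composed error ε = v + u (v ~ N(0, σ_v²) noise, u ≥ 0
half-normal inefficiency). Because the regressand is −ln y_M, inefficiency
*adds* to ε, so the marginal density is f(ε) = (2/σ)·φ(ε/σ)·Φ(λε/σ) with
σ² = σ_v² + σ_u² and λ = σ_u/σ_v.

* **Parameterisation**: (σ², γ) with γ = σ_u²/σ² ∈ [0, 1), the convention
  of the classic frontier-estimation packages. Internally σ² is optimised
  on a log scale and γ on a logit scale, making the problem unconstrained.
* **Starting values**: corrected OLS — slopes from least squares, σ_u from
  the third central moment of the residuals
  (m₃ = σ_u³ √(2/π)(4/π − 1) for the half-normal), intercept shifted by
  E[u] = σ_u√(2/π); γ is floored at 0.05 to stay off the boundary, and two
  extra starts at γ ∈ {0.3, 0.7} guard against local optima. The best
  log-likelihood wins.
* **Optimiser**: BFGS with gtol 1e-8; convergence is declared on optimiser
  success *or* a near-zero gradient (BFGS occasionally stops with a
  precision-loss status at a genuine optimum).
* **Standard errors**: inverse observed information, with the Hessian
  computed numerically in the natural (coefficients, σ², γ) space at the
  optimum.
* **Efficiency scores**: u | ε is N(γε, γ(1−γ)σ²) truncated at zero; the
  default point estimator is the conditional expectation
  E[e^{−u}|ε] (Battese–Coelli form), with exp(−E[u|ε]) available behind
  `estimator="jlms"`. Φ ratios are floored at 1e-300 before dividing.
* **Inefficiency test**: z = γ̂/SE(γ̂) with one-sided normal tail
  probability, banded at {0.001, 0.01, 0.05, 0.1}. The mapping is applied
  as defined; a published table marks z = 1.13 as significant at 10% even
  though the one-sided p is ≈ 0.129 — that mark is documented, not
  reproduced.
* **Gap conversion**: gap% = (1/TE̅ − 1)·100 from the mean of individual
  scores. Published gap columns are not always a deterministic function of
  the printed mean TE (farm-wise conversion before averaging is the likely
  cause), so both conventions can be computed from the score list.

The likelihood is verified against numerical convolution quadrature
(≤ 1e-6 on small samples), the γ = 0 limit against the Gaussian regression
likelihood, and the whole estimator against simulation recovery (n = 500,
γ = 0.8, 10 seeds: median coefficient error and mean-TE error ≤ 0.05).

## 3. Herd simulation

A deterministic expected-value cohort model advanced monthly; a seeded
integer-stochastic mode (Poisson/binomial event draws) exists for realism
but all shipped analyses use the deterministic mode for exact
reproducibility.

**State.** The breeder pool carries a mean liveweight plus two stage
pipelines — months of gestation (9 bins) and months of lactation (L bins) —
rather than per-cow records; a cow may appear in both, which is exactly the
information the energy and calving accounting needs. Young stock are
age-indexed arrays (count, weight) per sex; classes are female/male calf
(< 6 months), heifer and growing male.

**Feeding.** Feeds are offered per head per day (never ad libitum), drawn
from on-farm stocks first; storable feeds (residues, hays, concentrates)
stockpile across months at harvest pulses, standing pasture and cut green
feed do not. Purchasable feeds are bought at the shortfall; non-purchasable
shortfalls truncate intake proportionally across classes. Mass balance
(opening + supply + purchases − consumption = closing) holds exactly per
feed per month and is asserted in the acceptance suite.

**Energy and protein (simplified feeding-standards forms).** All constants
are fixed model choices, flagged for sensitivity analysis:

| quantity | form | value/units |
| --- | --- | --- |
| maintenance | 0.26·W^0.75 / k_m | k_m = 0.7, MJ ME/day |
| pregnancy | linear ramp over last 3 gestation months | 0 → 12 MJ/day |
| lactation efficiency | k_l | 0.6 |
| milk energy | 38.6·fat + 1.69 | MJ/kg milk |
| protein-allowable milk | CP·0.6 / 0.033 | kg/day |
| growth cost | 35 MJ/kg gain / k_g | k_g = 0.43 |
| tissue mobilisation | 28 MJ/kg, ≤ 20% of the milk-energy deficit, floor 0.75·SRW | |
| rumen protein coupling | usable ME × min(1, CP%/7%), floored at 0.6 | |

The last row is a deliberate model addition: microbial fermentation is
nitrogen-limited below ≈ 7% dietary crude protein, so low-protein diets
extract less energy. It is what gives protein-only interventions (legume
reseeding of pasture, urea treatment of straw) a production pathway; at or
above 7% CP the energy balance is the pure feeding-standards form.

Realised milk per lactating cow is min(lactation-curve potential scaled by
W/SRW, energy-allowable, protein-allowable); the curve rises linearly over
month 1, plateaus, and declines linearly over the last third of lactation.
Milk energy output never exceeds k_l·(usable ME − maintenance − pregnancy)
plus mobilised tissue energy, an inequality asserted cohort-month by
cohort-month in tests.

**Reproduction and mortality.** Monthly conception probability of an open,
cycling breeder is logistic in body condition c = W/SRW:
p = 0.35 / (1 + e^{−12(c − 0.8)}), with 9-month gestation, 2-month
post-partum anoestrus and a 50:50 calf sex ratio — at sustained high
condition the implied calving interval is ≈ 14 months. Monthly mortality is
base/12 + 0.02·max(0, 0.75 − c) for every cohort (young stock conditions
are weight relative to an age-appropriate target).

**Management.** Males sell at the configured age/weight rule (with an
age-only failsafe 24 months later); female weaners beyond a replacement
pipeline of 1.5 × the maximum breeder bound are sold; heifers promote into
the pool at age of first mating; culling at cull age is implemented as the
equivalent steady-state monthly fraction 1/(cull_age − age_first_mating) of
the pool (the cohort model does not track per-cow age) and is suspended at
the minimum breeder bound; the maximum bound is enforced by selling the
excess, scaling the stage pipelines proportionally. Head-count conservation
(opening + births − deaths − sales = closing) holds exactly every month.

**Economics.** Annual profit = milk × price + Σ sales × class prices −
purchased-feed cost − health/mating cost × mean herd size. On-farm feed and
labour carry no cost. Currencies stay native (ETB/INR); the reporting
conversion constant is 1 USD = 22 ETB = 66 INR.

**Horizon and summaries.** 240 months with a 5-year burn-in; summaries
average the final 15 years. Calving interval = 12 / (calvings per
breeder-year); milk per cow per lactation = total milk / total calvings.

## 4. Scenario library and calibration

The five regional baselines and 22 interventions are encoded verbatim where
the published household descriptions give quantities (noug cake 0.4 →
0.8 kg/head/day, bran to 5 kg/head/day, straw +1 MJ ME/kg DM and 5 →
5.8 INR/kg, pasture nitrogen +0.5% with the seasonal decline halved, breed
swaps with their herd bounds, male sale rules, baseline mortalities). All
values live in the shipped YAML files (`data/library.yaml`,
`data/scenarios/*.yaml`), not in code, so they can be audited in one place.

Everything the source descriptions do *not* print — feed compositions and
prices, animal prices, milk prices, breed lactation potentials, grazing
offers and monthly feed supplies — is a fixture assumption chosen once and
calibrated so that each regional baseline lands in the reported band of
baseline outcomes (lowland zebu a few hundred kg per lactation with a long
calving interval; the urban all-purchased-fodder baseline loss-making;
irrigated buffalo around 2–3 kg/day) and so that the qualitative structure
of the reported intervention table is reproduced: within every region the
simulated ranking of scenarios by annual farm milk matches the published
row order. Notable calibration points:

* Breed peak potentials: zebu 3.0, Ethiopian crossbred 8.0, Indian local
  3.5, Indian crossbred 9.0, buffalo 7.0 kg/day. The zebu and local values
  sit above the naive 1.5–2 kg/day reading of baseline yields because the
  published concentrate scenarios reach 3.7+ kg/day from the same animals —
  the baseline is feed-limited, not potential-limited.
* Milk prices 15 ETB/kg, 28 INR/kg (cow), 42 INR/kg (buffalo); the buffalo
  premium reflects fat content. Cattle male calves carry zero sale value in
  India (slaughter restrictions), buffalo male calves do not — this is what
  makes buffalo more profitable than crossbred cattle at equal or lower
  milk volume.
* Concentrate prices (noug 4, wheat bran 3 ETB/kg; brans 10–12 INR/kg) are
  set so concentrate supplementation is profitable when the milk response
  is realised, consistent with the reported scenario economics.

These are calibrations, not ground truth: the spreadsheet model behind the
published simulation table is closed and its internal equations are
unpublished, so the published numeric outputs are treated as qualitative
targets (orderings, signs, bands) rather than values to reproduce.

## 5. Synthetic data

* **Benchmark populations**: log-normal yields (median, log-sd shape). The
  top-decile/overall-mean ratio has the closed form Φ(σ − z₀.₉)/0.1, used
  as the generator's calibration oracle (±5% at n = 10⁴). Log-normality
  matches the strong right skew of smallholder yield surveys but carries no
  zone covariance or reporting error.
* **Frontier populations**: log-normal inputs and an exogenous log-normal
  output mix ln(y_m/y_M); the normalising output is solved from the
  frontier identity with freshly drawn v and u. Drawing the *mix* rather
  than the secondary outputs keeps the normalised-output regressors
  independent of the composed error — the estimator's own maintained
  assumption; real farm data offer no such guarantee, so passing recovery
  tests demonstrate estimator correctness, not robustness to endogenous
  output mixes.
* **Fixtures**: `gen_fixtures(region)` materialises the feed/price tables
  and scenario files; regeneration is byte-identical (no randomness).

All generators are pure functions of (parameters, seed).

## 6. Problem sizes

The default test suite and the acceptance script use: 10-farm zones for the
benchmarking arithmetic (exact by construction), n = 500 × 10 seeds for
frontier recovery, n = 10⁴ for the distributional checks, and the full
5-region × 27-scenario sweep at 240 months (a few seconds in total). These
sizes make every check exact or tightly converged while keeping the whole
pipeline fast enough to run routinely.

## 7. Known limitations

* The herd model's constants are plausible simplified forms, not a fitted
  feeding standard; absolute simulated yields and profits should be read as
  scenario-relative, not predictive.
* Breeder age is pooled; culling is a steady-state fraction and "oldest
  first" sales are proportional pipeline scaling.
* Lactating cows are milked fully; calf suckling, manure/draught value,
  labour, crop growth and weather variability are out of scope.
* The SFA assumes a Cobb-Douglas kernel, half-normal inefficiency and
  exogenous regressors; no panel structure or inefficiency covariates.
* Benchmark and modelled yields for a zone may aggregate different survey
  states; the gap report labels this caveat rather than resolving it.
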