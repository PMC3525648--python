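# Methods

`twinrisk` implements a probabilistic twin-study framework that converts
directly observable epidemiology — disease prevalence, MZ/DZ-twin and
sibling concordance, subgroup frequencies in cases and controls — into
quantities that cannot be observed directly: the fraction of the population
that is genetically susceptible, the fraction of cases that require
susceptibility, penetrance decompositions of the susceptible set, the
mechanism by which a risk allele is enriched among cases, and
gender-specific environmental response curves.  The worked configuration
bundled with the package is multiple sclerosis (MS) with the DRB1\*1501
carrier partition, but every operation takes its inputs as parameters.

## Model and assumptions

Genetic susceptibility is binary: a genotype either can (`G`) or cannot
(`G−`) produce the disease, and each susceptible genotype `G_i` carries its
own penetrance `z_i = P(D|G_i)`.  Write `z = E[z_i]` for the expected
penetrance of the susceptible set and `σ² = Var(z_i)` for its variance.
The key identities the package relies on:

- **Twins are representative.**  MZ twinning carries no genetic
  predilection, so the genotype distribution among twins matches the
  population.  This is the load-bearing assumption; if it fails the whole
  chain is invalid.
- **Size-biased concordance.**  The MZ co-twin of a case shares the case's
  genotype, and case probands over-sample high-penetrance genotypes in
  proportion to `z_i`.  The genotype-sharing concordance among susceptible
  individuals is therefore `b′ = E[z_i²]/E[z_i] = z + σ²/z`, not `z`.
- **Shared gestation is removable by the sibling/DZ contrast.**  DZ twins
  and full siblings share genes to the same degree; the DZ excess is
  attributed to the shared intra-uterine environment (the shared childhood
  environment is assumed inert, which adoption and half-sibling studies
  support for MS but not, e.g., for Parkinson's disease).  Multiplying an
  MZ rate by `sib/DZ` strips the gestational excess.
- **Conservation.**  `z · P(G) = g · P(D)` where `g = P(G|case)`: the
  genetic case mass can be produced either by many weakly penetrant
  susceptibles or few strongly penetrant ones.

## The adjustment chain

1. **Ascertainment.**  Registries print proband-wise rates but not the
   double-ascertainment probability `π`.  `calibrate_ascertainment` solves
   `f·C/(f·C+D) = rate` for `f = 1+π` on the registry's total counts and
   applies the single study-wide factor to every subgroup of the same
   study.  Calibrating on the whole study (24 concordant / 109 discordant
   MZ pairs at the registry's overall proband-wise rate 0.253, `f ≈ 1.538`)
   reproduces every printed subgroup proband-wise rate; per-table
   calibration is also supported but misses one subgroup cell by one unit
   of printed precision.
2. **Gestational correction.**  The pooled `sib/DZ = 0.029/0.054 ≈ 0.537`
   is applied uniformly: per-gender ratios exist in the inputs but only the
   pooled factor reproduces all published adjusted values, so the pooled
   factor is the default and per-subgroup factors are deliberately not
   used.  This yields the headline `b = 0.25 × 0.537 = 0.134`.
3. **Subgroup renormalization.**  Carrier/non-carrier adjusted rates are
   rescaled by one common factor so the cohort-level rate equals `b`.  The
   anchor is the *pooled adjusted rate of the same table* (`0.297 × 0.537`),
   which is how the published values (t = 0.139, s = 0.129) are
   constructed; an explicit case-weighted mixture anchor is also available
   and is the route used by the mixture-consistency property tests.  A
   single common factor preserves the subgroup ratio, so mechanism
   diagnostics are unaffected by the anchoring choice.

## Bounds on P(G) and g

- **Upper bound** `P(G) ≤ 2·P(D)/b`.  Because `b` estimates `g·b′` and
  `b′ = z + σ²/z ≤ 2z` whenever the two-point decomposition of the
  susceptible set is admissible (`σ ≤ z`), the conservation identity forces
  the susceptible fraction below `2·P(D)/b`.  For MS this is 2.2% of the
  population; the same expression reproduces all regional upper bounds and
  the cross-disease table.
- **Lower bound** `P(G) ≥ g·P(D)/z_max` for any ceiling `z_max` on the
  susceptible-set penetrance.  The regional-table convention takes
  `z_max = b` for the region; a tighter user-supplied ceiling is accepted.
- **Lower bound on g** (`estimate_g`).  Each two-way partition of the
  population by a susceptibility-associated trait `Gx` (carrier status,
  gender) contributes an admissible interval for `g` from the joint
  feasibility of four relations:

  1. carrier balance: cases that are *not* genetically susceptible carry
     `Gx` at the population frequency, so `A(1−g₁) = (1−g)A₀` and
     `(1−A)(1−g₂) = (1−g)(1−A₀)`, where `A₀ = P(Gx+)`, `A = P(Gx+|case)`
     and `g₁, g₂` are the susceptible-case fractions inside each subgroup;
  2. subgroup penetrances: `t = g₁·t′`, `s = g₂·s′` with the
     susceptible-only analogues `t′, s′` constrained to `[0, 1]`;
  3. penetrance ordering: the case-enriched subgroup is at least as
     penetrant among susceptibles, `t′ ≥ s′` (dropped with a warning when
     the observed subgroup ordering contradicts it).

  All constraints relax monotonically as `g → 1`, so the admissible set is
  an interval `[g_min, 1]`; a grid scan (step 1e-4) with bisection
  refinement finds the boundary, and a closed-form solution of the linear
  boundary condition is used as an independent cross-check in the tests.
  The estimate is the intersection over partitions.  With the bundled MS
  inputs the gender partition admits `[0.43, 1]`, the carrier partition
  `[0.945, 1]`, hence `g ≥ 94%`.  Internally consistent: at that `g` the
  carrier partition's `s′/b′ ≈ 1.0` (carrier status does not touch
  penetrance) while the gender partition's is ≈ 0.28 (it does).

## Penetrance decomposition and the "purely genetic" ceiling

Given `g`, `b′ = b/g` and a `P(G)` bound, conservation fixes
`z = g·P(D)/P(G)` and the size-biased identity yields `σ² = z(b′ − z)`.
The raw lower boundary `g·P(D)/P(G)_upper` can be incoherent with the
two-subset decomposition (below `z = b′/2` the implied variance exceeds
`z²` and the low-penetrance subset would need a negative expectation); the
lower boundary is raised, minimally, to `b′/2`.  For MS this moves the
lower end from 0.064 to 0.071 — a minor correction, but potentially large
for other diseases.  The high/low subset expectations default to the
symmetric two-point representation `x = z+σ`, `y = z−σ` (`p = 0.5`).

`purely_genetic_bound` caps the mass of near-deterministic genotypes
(penetrance ≥ a threshold τ, default 0.9): maximizing `P(z_i ≥ τ)` over
all distributions on [0, 1] with the given mean and variance gives a
two-point extremal distribution, with bound `σ²/(σ²+(τ−z)²)` when
`σ² ≤ z(τ−z)` and `z²/(z²+σ²)` otherwise.  For the MS ranges this is below
0.01 at τ = 0.9 — effectively no purely genetic disease.  The test-suite
oracle is an exhaustive search over discretized two-point distributions,
independent of the closed form.

## Environmental response curves

`P(D, E|G)` as a function of a dimensionless exposure coordinate `x`
(monotone in the likelihood of a sufficient exposure; explicitly *not* a
time axis) is modelled as zero below a gender-specific threshold λ and a
constant-hazard exponential rise to a gender-specific plateau (0.28 for
women, 0.06 for men in the bundled configuration).  The exponential is the
minimal constant-hazard form consistent with the proportional-hazard
assumption; the curve is parameterized through `ResponseCurveParams` so an
alternative form can replace it without changing the fitting interface.
`fit_gender_curves` anchors the female curve (threshold 0, unit hazard)
and solves the male threshold offset, the hazard ratio `r`, or a geometric
split of both, so that both genders reproduce their current-epoch adjusted
penetrances at the same calibration exposure.  `exposure_sufficiency`
reports the saturation fraction `z/plateau` as a lower bound on `P(E|G)`
(≈ 0.65 for women with the bundled inputs); the minimum number of distinct
environmental events is carried as a configured constant (default 3, from
prior sequential-exposure modelling, not derived here).  Two related
historical claims — the population-level exposure floor and the implied
prevalence increase — require external gender-ratio trajectory data and
are provided as documented stubs that compute only from user-supplied
inputs.

## Synthetic cohorts

The simulator draws twin cohorts under exactly the generative assumptions
above: a susceptible fraction `p_g`, genotype penetrances from a point,
two-point, or Beta distribution, an optional diallelic marker (allele
frequency `maf`) coupled to susceptibility either through carrier
susceptibility odds (`susceptibility_multiplier`, the allele-frequency
mechanism) or through carrier penetrance (`penetrance_multiplier`, the
penetrance mechanism).  MZ co-twins share genotypes exactly; DZ/sibling
co-twins share the susceptibility *status* with a configurable probability
(default 0.5) and redraw their own penetrance class — the estimators
consume only concordance rates, so a single sharing probability replaces
explicit multilocus genetics.  Co-gestated pairs (MZ, DZ) multiply the
co-twin's penetrance by `iu_effect` when the index twin is affected;
sibling pairs do not, which is precisely the asymmetry the `sib/DZ`
correction removes.  Concordant pairs are doubly ascertained with
probability `π`.

What the simulator does *not* emulate: age structure, mortality,
zygosity misclassification, diagnostic drift, or realistic pedigrees.
Passing the recovery tests therefore shows the estimators are correct
*under the model*, not that the model describes any particular registry.

### Problem sizes used by the stochastic checks

Sizes are chosen so sampling noise sits well inside the claimed margins:

- size-biased oracle: 200,000 MZ pairs, all susceptible, two-point
  penetrances {0.1, 0.5} — relative error of the proband-wise rate ≪ 2%;
- interval coverage: 200 seeds × 50,000 pairs per zygosity, `p_g = 0.05` —
  the lower/upper margins (`z/b′ ≈ 0.69`, `2z/b′ ≈ 1.39` of the truth) are
  3.5–4.5 standard errors of the dominant noise term (the sibling/DZ
  ratio), so ≥ 99% coverage holds with slack;
- mechanism separation: 60 seeds × 100,000 pairs, `p_g = 0.1` — about
  4,000 affected MZ pairs per cohort keep the `s/b` noise (σ ≈ 0.02–0.03)
  well inside the classifier's 0.10 tolerance.

## Numerical conventions

- Published-value comparisons round half-up at the printed number of
  decimals, with a 1e-9 nudge for floating-point representations of exact
  ties.
- Eight published cells land one unit of printed precision away from the
  full-precision recomputation (the publication rounded intermediates
  before final steps; a few regional lower bounds appear floor-rounded).
  These are listed in `data/printed_values.yaml` under
  `known_discrepancies`, reported as `known_discrepancy` by the
  reproduction harness, and asserted in the tests to be within exactly one
  ulp — never silently passed off as matches.
- `estimate_g` grid step 1e-4, bisection to 1e-10; all feasibility
  tolerances 1e-12.
- Degenerate inputs: zero concordant pairs cannot calibrate ascertainment;
  sibling concordance above DZ clamps the gestational factor to 1 with a
  warning; a case-depleted marker (A < A₀) returns zero allele
  contribution with a warning rather than extrapolating a protective
  model.

## Known limitations

- The carrier-balance relations assume the marker is neutral in
  non-genetic cases; a marker that also modulates purely environmental
  disease would bias `estimate_g`.
- The mechanism classifier uses `s/b` as a proxy for the susceptible-only
  ratio `s′/b′`; this is tight only because `g ≈ 1` for the bundled
  inputs (the exact `s′/b′` at the estimated `g` is also reported).
- Confidence intervals on concordance are out of scope (the source tables
  publish none); all bounds are deterministic functions of point inputs,
  with a sensitivity sweep (`sensitivity_sweep`) in place of interval
  arithmetic.
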