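# Methods

## The hybrid liability model

All quantities live on the standardized liability scale: a disorder's
latent liability has unit variance, and a person is affected when their
liability exceeds `τ = Φ⁻¹(1 − K)` for population prevalence `K`.
Variance components are therefore dimensionless fractions.

The hybrid model posits that a fraction `x` (0 < x < 1) of the
couple-shared environmental variance `E_P` is transmitted from parents to
offspring by non-genetic means, contributing to cross-generation
resemblance exactly as additive genetic variance `G_A` does. To first
order (direct genetic and environmental variances only, no dominance,
epistasis, assortative mating or gene–environment covariance) the
broad-sense heritability a family design reports is

    H² = (G_A + x·E_P) / (G_A + E),
    E  = E_P + E_F + E_S + E_U,

with `E_F`, `E_S`, `E_U` the shared-familial, shared-sibling and unique
environmental components (`E_F` defaults to 0 when a source decomposition
names only couple, sibling and unique terms). Solving for the additive
variance gives the unique algebraic inversion

    G_A = (H²·E − x·E_P) / (1 − H²),

verified throughout by back-substitution and against brute-force
bisection. Feasibility requires `H²·E ≥ x·E_P`; a violation means the
transmitted environment alone would exceed the heritability budget, and
the solver raises instead of clamping — a negative variance signals
inconsistent inputs, and silent clamping would mask it.

Two modes exist because summary sources do not always print the total
environmental variance: `solved` mode inverts the equation from
`(H², E, E_P, x)`; `reproduced` mode assembles `G = G_A + x·E_P` from an
externally supplied `G_A`, keeping the bundled-table computations
independent of unpublished `E` values. For the same reason the package
never assumes `E = 1 − H²`: back-solving published decompositions implies
component sums slightly above 1, so `E` is always treated as a supplied
total.

The transmission fraction is evaluated on the grid
`x ∈ {0.25, 0.5, 0.6, 0.667}` by convention, with `x = 0.5` the headline
model used in the bundled decomposition.

### Bundled data and known discrepancy

`epiherit.datasets.load_neuropsych_five` ships liability-scale summary
statistics for five high-heritability neuropsychiatric disorders (ASD
0.924, ADHD 0.763, bipolar disorder 0.676, depression 0.579,
schizophrenia 0.562), their SNP/CNV-measured genetic variance, the
additive variance implied by the hybrid model at `x = 0.5`, and
`E_P` (stored as twice the published `0.5·E_P` term, so every fixture
number traces to a printed value).

Depression's source decomposition prints a hybrid residual of 0.207
(explained 64.2%, residual 35.8%) where its own printed components give
`0.579 − 0.373 = 0.206` (64.4%, 35.6%) — an artifact of unrounded source
arithmetic. The package reports the internally consistent 0.206 and
propagates a provenance note on that row rather than forcing the printed
value; the aggregate ranges are unaffected either way.

Aggregates: the measured-genetics explained range covers all disorders
with a SNP estimate; the hybrid explained and residual ranges exclude
outliers with `E_P = 0` (ASD), for which the hybrid model is degenerate
(it trivially explains all of H²). The exclusion rule is data-driven, not
a hard-coded name, and can be overridden. Report formatting rounds
variances to 3 decimals and percentages to 1 decimal, ties half away from
zero, with range endpoints additionally reported as integer percent; raw
values are retained in all machine-readable outputs.

## Family simulator

`simulate_families` realizes the model generatively for nuclear families
(2 parents, `n_offspring` children, default 2), all deviates independent
standard normals scaled as stated:

- couple deviate `C ~ N(0, E_P)`, carried by both spouses with loading 1
  (spouse latent correlation = `E_P`; no assortative mating, no genetic
  spouse correlation);
- parent liability `L_p = G_p + C + U_p`, `G_p ~ N(0, G_A)`,
  `U_p ~ N(0, 1 − G_A − E_P)`;
- offspring genetics `G_o = (G_f + G_m)/2 + M_o`, Mendelian segregation
  `M_o ~ N(0, G_A/2)` (infinitesimal model, no dominance);
- transmitted environment `T_o = x·C + δ_o`,
  `δ_o ~ N(0, x(1−x)·E_P)` per child;
- sibling-shared `S ~ N(0, E_S)` (one draw per family) and unique
  environment filling each child's variance to 1, so parent and offspring
  liabilities are both standardized although composed differently;
- affected ⇔ liability > `Φ⁻¹(1 − K)`; prevalence defaults to `K = 0.1`,
  a realistic order for common psychiatric disorders and high enough to
  keep concordance cells well populated at simulated sample sizes.

**Transmission loading convention.** The generative text underdetermines
how "a fraction x of E_P is transmitted": loading the couple deviate by
`x` (with variance top-up) gives transmitted variance `x·E_P` *and*
parent–offspring environmental covariance `x·E_P`; loading by `√x` would
give the same variance but covariance `√x·E_P`. The covariance-x
convention is adopted because it makes `x·E_P` enter cross-generation
resemblance exactly as the model's numerator intends, and the estimators
are derived under the same convention, so the pair is internally
consistent. Under it the latent correlations are

    r_spouse           = E_P
    r_parent_offspring = G_A/2 + x·E_P
    r_sibling          = G_A/2 + x²·E_P + E_S

and the naive parent–offspring estimator `2·r_po = G_A + 2x·E_P` exceeds
`G_A` whenever `x·E_P > 0` — the confounding thesis stated at the level
where it is literally true. Variance budgets (`G_A + E_P ≤ 1` for
parents, `G_A + x·E_P + E_S ≤ 1` for offspring) are validated before any
sampling. `x = 0` is permitted in simulation (no transmission) though the
analytic solver requires `0 < x < 1`. All draws flow through one
`numpy.random.Generator` seeded from `SimulationParams.seed`, in a fixed
order, so identical parameters give bit-identical tables.

What the simulator does *not* emulate: assortative mating, dominance and
epistasis, gene–environment covariance, diagnostic misclassification,
ascertainment through clinics, multi-generation (grandparent) structure,
and cohort trends in prevalence. Passing recovery tests therefore shows
the estimators are correct *under the model's own assumptions*, not that
real register data are free of these additional structures.

## Estimation

**Tetrachoric correlations.** Affection concordance for spouse,
parent–offspring (each parent × each child) and sibling (all unordered
child pairs) relations is tabulated as 2×2 counts. The latent model is a
standard bivariate normal dichotomized at thresholds fixed at the
inverse-normal of each margin's affected proportion (standard two-step
practice; prevalence is a design constant in simulations, and joint
threshold estimation buys little at these sample sizes). The correlation
maximizes the multinomial cell-probability likelihood by bounded
one-dimensional search on (−1+10⁻⁶, 1−10⁻⁶) to tolerance 10⁻⁶; the
bivariate normal CDF is evaluated through Owen's T function, which is
vectorizable over the correlation and matches `scipy`'s Fortran CDF to
machine precision (unit-tested). Standard errors come from the observed
information via a numerical second derivative (step 10⁻⁴). Tables with a
zero cell get a +0.5 continuity correction to all cells, flagged in the
output, which keeps the likelihood finite without discarding replicates;
a margin with no affected (or no unaffected) pairs is degenerate and
raises.

**Component recovery.** Under the covariance-x convention the three
latent correlations are linear in `(G_A, E_P, E_S)` at known `x`, so the
inversion is exact:

    E_P = r_spouse
    G_A = 2·(r_po − x·E_P)
    E_S = r_sib − G_A/2 − x²·E_P.

`x` is always assumed, not estimated: with three moments and four
unknowns the system is underdetermined. Estimates outside [0, 1] are
reported and flagged, never truncated, so replicate bias summaries stay
unbiased. `recovery_experiment` replicates
simulate → tabulate → tetrachoric → invert with per-replicate seeds
spawned from the experiment seed, reporting mean, bias and RMSE per
component.

## Numerical and design choices

- Brute-force oracles in the test suite are independent of the
  implementation paths they check: the solver is checked against
  bisection of the defining ratio; the tetrachoric ML against an
  exhaustive 10⁻⁴-step likelihood grid whose CDF values come from the
  Plackett identity (cumulative trapezoid of the bivariate density over
  the correlation, anchored at ρ = 0), itself spot-checked against
  `scipy.stats.multivariate_normal.cdf`.
- Monte-Carlo tolerance for the simulator's moment match uses the number
  of independent families as the effective sample size, since pooled
  parent–offspring pairs within a family are correlated; this makes the
  4-standard-error band conservative.
- Problem sizes: moment checks use 2×10⁵ families per grid point over a
  24-point grid; tetrachoric consistency uses 10⁶ pairs; recovery
  experiments use 20 replicates of 5×10⁴ families. These sizes put
  Monte-Carlo error well below the effects being measured (biases of
  order 0.02 against a naive inflation of 0.3) while keeping a full run
  in seconds.
- Ties in the heritability ordering of the stacked transmission series
  are broken lexicographically by disorder name for determinism.
- TSV with a header row, UTF-8 and '.' decimals is the canonical tabular
  format (whitespace-safe disorder names); CSV is accepted by sniffing.
  Family tables carry a JSON sidecar with parameters, seed and threshold
  so simulation outputs are self-describing.

## Limitations

The closed-form model is a first-order variance account: it cannot by
itself distinguish transmitted environment from unmeasured genetics in a
single generation's data (that identification requires designs with
exposure contrasts), and the recovery experiments quantify estimator
behavior only under the package's own generative assumptions. The
transmission step is single-generation; persistence to later unexposed
generations is out of scope.
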