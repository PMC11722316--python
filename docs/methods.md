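# Methods

## Chemostat model

A well-mixed chemostat of fixed volume is diluted at rate `B` per
generation; influent media carries nutrient `phi0` and free lytic virus
`psi0`.  The cell population is a density matrix `n(p, q)` over integer
volume `p ∈ {p0, …, 2p0−1}` and viral load `q ∈ {0, …, Q}`, coupled to
scalar nutrient `phi` and free-virus `psi` pools.  Per generation:

* **Growth/division** — flux `A(1−r/E)·phi·p` from `(p, q)` to `(p+1, q)`.
  Outflow from the top class with `q = 0` is division: two newborns at
  `(p0, 0)`.  Division is arrested by a single virion (no top-class
  outflow for `q ≥ 1`), but growth up to the division volume is not.
* **Infection** — flux `C·psi·p` from `(p, 0)` to `(p, 1)`, each event
  consuming one free virion (superinfection exclusion: only virus-free
  cells are infected).  The matching influx term is included in the cell
  balance so that ingestion conserves the free + intracellular virion sum.
* **Replication** — flux `F·q` from `(p, q)` to `(p, q+1)`; no outflow at
  the cap `q = Q`.
* **Clearance (immunity)** — flux `r·p` from `(p, q)` to `(p, q−1)`,
  destroying one virion per event; the growth cost is the `(1−r/E)`
  factor, so `r = E` stalls growth entirely.
* **Death** — dilution at rate `B` (no virion release) plus lysis with
  hazard `(rho/T)^G` at concentration `rho = (q/Q)(p0/p)`; lysis releases
  all `q` virions.  At `rho ≥ T` lysis is certain within the current step.
  The hazard form is the only monotone reading consistent with certain
  lysis at `rho = T` and a gradual (small `G`) vs step-like (large `G`)
  profile.
* **PCD** — cells with `rho > 1−a` are removed with *no* virion release.
  `a = 0` disables PCD; otherwise `1−T ≤ a ≤ 1`.
* **Resources** — `phi` relaxes to `phi0` at rate `B` and is consumed at
  `C·phi·Σ p·n`; `psi` relaxes to `psi0` at rate `B`.

Timescale is normalized by the growth rate (`A = 1`): time is measured in
generations at maximum nutrient.  Dynamics are mean-field and
deterministic; the core takes no random seed.

### Numerical scheme

Explicit first-order operator splitting in the order growth → infection →
replication → clearance → PCD → death → resources.  PCD precedes the
lysis stage because PCD-competent cells must never survive to lyse: this
makes "removal releases no virions" exact rather than accurate to
O(dt²).  Newborns produced by division do not grow within their birth
step (snapshot semantics for the growth stage).

The step size is chosen per generation so that the total outflow
probability of every *occupied* class stays below 0.5, with a safety
margin for within-chunk growth of `psi` and of the occupied viral-load
range.  Viral-load columns holding less than 1e-14 of the total
population are truncated to zero and do not constrain the step size; the
truncation threshold adapts, so genuinely occupied high-load classes
(e.g. the upper burst-size mode) are retained.  Halving the step changes
converged fitness by well under 1% on the reference ecology (checked in
the test suite).

Convergence: the run is converged when the relative spread of the total
population over a 10-generation sliding window falls below `tol`
(default 1e-4).  Runs hitting the generation cap are classified cyclic if
the final 50 generations contain ≥ 3 population peaks with relative
amplitude above `tol`; cyclic fitness is the geometric mean of those
peaks.  Extinction is declared when the population falls below 1e-9 of
the inoculum, or earlier when it is below 1e-4 of the inoculum, has
declined monotonically for 10 generations, and the resources have relaxed
to their influent values (`phi > 0.95·phi0`, `psi < 1.05·psi0`): in that
low-density limit the linearized dynamics are autonomous, so a declining
population cannot recover.  `r ≥ E` with `B > 0` (zero growth against
constant dilution) short-circuits to extinction.  `B = 0` (closed
culture) is admitted as a limit for conservation checks; all study
ecologies use `0 < B < 1`.

### Landscapes and sweeps

The strategy grid is `{0} ∪ [1−T, 1]` for `a` (the `a = 0` point is the
no-PCD reference required by the sensitivity measure) × `[0, E]` for `r`,
21×21 by default.  Ties at the fitness maximum break toward the smaller
`a`, then the smaller `r` (the cheaper strategy).  PCD-sensitivity is
`1 − fitness(a=0, r_opt)/fitness(a_opt, r_opt)`; landscapes are labelled
PCD-sensitive when it strictly exceeds 0.1.  Sweep neighbor differences
are reported for consecutive parameter values whose landscapes both have
sensitivity ≥ 0.1.  Trend statements (optimal PCD investment decreases
with viral pressure `psi0` and increases with carrying capacity `1/C`;
immunity the reverse) are checked as monotone trends over 4-point sweeps
rather than pointwise, because plateaus in PCD-insensitive landscapes
make the arg-max imprecise.

### Reference ecology and problem sizes

The study conditions for the consistency and trend checks use a reduced
state matrix `p0 = 6`, `Q = 200` and the ecology `B = 0.15` (dilution in
the 5–20%/generation range typical of experimental chemostats),
`C = 0.01` (high carrying capacity), `E = 0.5`, `F = 0.5`, `G = 2`,
`T = 0.5`, `phi0 = 1`, `psi0 = 0.1`.  This sits in the PCD-sensitive
regime (high replication rate, large carrying capacity, low viral
pressure).  The viral-pressure sweep uses `psi0 ∈ {0.5, 2, 8, 32}`; the
carrying-capacity sweep uses `C ∈ {0.005, 0.02, 0.08, 0.32}` at
`psi0 = 8` (an interior optimum needs enough viral pressure for immunity
to matter).  These grids are deliberately small enough to run on one CPU
in minutes; they are this package's choice, not a claim about the full
ecological grids explored elsewhere.

### Burst-size distribution

The released-virion distribution weights each load class by its lysis
flux at the final state (`n·hazard`, with `n/dt` for classes at or above
the lethal concentration).  In surviving infected populations the
division-arrest of infected cells yields a large low-load subpopulation
(low-count lysis peak) while autocatalytic replication piles survivors
near the lethal threshold (high-count peak) — a two-peaked distribution
under low lysis slope and fast replication.

## Genomic investment

Investment of a genome in a category is the fraction of genome length
(nucleotides, 1-based inclusive coordinates) covered by the union of that
category's gene intervals — overlaps are counted once, since the cost
being proxied is transcription/translation of the covered sequence.
Defense systems map to PCD / Immunity / undefined via a user-supplied
classification; "PDC" (Phage Defense Candidate) labels and unmapped
systems are excluded.  Toxin/antitoxin genes count toward PCD only as
mutual-nearest pairs (start-coordinate distance, same contig) with no
annotated gene strictly between them; unpaired TA genes are discarded.
One representative genome per species is drawn with a seeded generator.

## Power-law regression

Both observed investments are lognormal perturbations (common log-scale
SD `epsilon`) of a latent species investment `I_best`:

    logL = Σ_i [ log LogN(I_Imm,i ; I_best,i, ε) +
                 log LogN(I_PCD,i ; β·I_best,i^α, ε) ]

`I_best` is profiled per point in closed form,
`μ* = (x + α(y − log β))/(1 + α²)` with `x = log I_Imm`, `y = log I_PCD`
— the orthogonal projection onto the regression line in log space —
and `ε² = RSS/(2n)` is profiled analytically, leaving a deterministic
two-parameter optimization over `(α, log β)` (multi-start bounded scalar
minimization, tolerance 1e-8).  Species with a zero in either investment
have no finite logarithm and are dropped (counted).  Two consequences of
the per-point profiling are worth knowing: the `α` estimate coincides
with total least squares (consistent under the generating model), while
the `ε` estimate is the incidental-parameter-biased profile value that
converges to the generating SD divided by √2.  BIC uses `k = 3` free
parameters (`α, β, ε`) or `k = 2` with `α` fixed; profiled latents are
not counted.  With real investment tables unavailable offline, the BIC
gaps are demonstrated as an *ordering* (flat ≫ linear ≫ 0) on synthetic
data generated at the fitted exponent, not as specific magnitudes.

## Abundance classes and deviation analysis

Within-sample abundance ranks use the convention larger rank = more
abundant, so the quartile rules select the intended groups; quartiles use
linear interpolation and the threshold comparisons are strict both ways
(a species sitting exactly at `Ta` is intermediate).  Species detected in
fewer than 100 samples are excluded.  `Ta` is chosen to maximize the
smaller of the two group sizes among species with genomes, ties to the
smallest `Ta`.  Group comparisons use Mann–Whitney U (exact null for
small untied samples, asymptotic with tie correction otherwise).

The genome-size expectation is a Gaussian linear regression of investment
on genome size with flat priors, sampled by random-walk Metropolis
(4 chains × 10,000 iterations, 2,000 burn-in, OLS-scaled proposals,
split-R̂ < 1.1 required).  Deviation p-values: each of 10,000 ensembles
draws one posterior sample and simulates investments at the group's
genome sizes; the one-sided empirical p is the fraction of simulated
group means at or beyond the observed mean, in the direction of the
observed deviation, floored at 1/n_ensembles.  Signed log p is
`−log10(p)` for positive (overinvested) deviations and `+log10(p)` for
negative ones.  Quadrant labels are ordered pairs
(status in low-abundant group, status in high-abundant group), so
"low-high" means underinvested among low-abundant and overinvested among
high-abundant species.

## Synthetic data

Generators emulate the structure the pipeline assumes: latent
log-investment uniform on `[log 1e-4, log 1e-1]` (spanning realistic
genome fractions), exponent 0.554 with scale `β = 0.04` and noise
`ε = 0.8` (chosen once to place the investment cloud at realistic
magnitudes with visible scatter; the empirical noise level is not
published), genome sizes lognormal with median 3.5 Mnt, and
rank-abundance tables from a lognormal species-abundance model with
class-shifted means.  What the generators do *not* emulate: phylogenetic
correlation among species, gene content beyond what the operations read,
compositional coupling between species within a sample, and any
zero-investment mechanism beyond simple zero-inflation.  Passing
recovery/calibration tests therefore demonstrates correctness of the
estimators under their assumed model, not robustness to the full
messiness of real annotation and metagenome data.

## Known limitations

* Mean-field dynamics cannot show demographic stochasticity; an
  environment where recovery from tiny densities is deterministic may be
  rescued where a real population would go extinct.
* The fitness landscape is evaluated on a monomorphic population per
  grid cell; competition between strategies (cheater invasion) and
  evolutionary dynamics are out of scope.
* PCD carries no explicit growth cost in the model, while the genomic
  investment measure treats PCD and immunity symmetrically.
* Exact reproduction of empirical headline numbers (fitted exponent on
  the real species table, BIC gaps, Mann–Whitney p-values, quadrant
  counts) requires the external genome/metagenome resources and is out
  of scope; the package demonstrates the estimators' correctness on
  synthetic data at matched sample sizes.
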