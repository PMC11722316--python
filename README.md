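# defensim

Ecological determinants of prokaryotic antivirus defense strategy:
chemostat modelling of immunity vs programmed cell death (PCD), and the
comparative-genomics statistics relating genomic defense investment to
viral pressure and census population size.

## The problem

Prokaryotic defense systems fall into two broad categories: **immunity**
(restriction–modification, CRISPR-Cas, BREX, DISARM, ...), which clears
virus from the infected cell, and **PCD / abortive infection**
(toxin–antitoxin modules, CBASS, ...), which altruistically kills the
infected cell before virions are released.  When is each strategy worth
its cost?  `defensim` provides, for modellers and comparative genomicists:

1. **A structured chemostat model.**  Cells structured by integer volume
   `p ∈ {p0..2p0−1}` and viral load `q ∈ {0..Q}` grow at rate
   `A(1−r/E)·φ·p`, divide (if virus-free) on leaving the top size class,
   are infected at rate `C·ψ·p` (superinfection exclusion), accumulate
   virus at rate `F·q`, clear it at rate `r·p`, and lyse with hazard
   `(ρ/T)^G` at intracellular concentration `ρ = (q/Q)(p0/p)` (certain
   lysis at `ρ ≥ T`).  PCD removes any cell with `ρ > 1−a` without virion
   release.  Fitness of a strategy `(a, r)` is the equilibrium population
   size.  Fitness landscapes over the strategy grid, their optima, the
   PCD-sensitivity measure `1 − n(a=0, r_opt)/n(a_opt, r_opt)` and
   one-parameter ecological sweeps are built on top
   (`defensim.chemostat`, `defensim.landscape`).

2. **Genomic-investment statistics.**  Per-species investments
   `I_Imm`, `I_PCD` (fraction of genome length in nucleotides occupied by
   each defense category, with mutual-nearest toxin/antitoxin pairing)
   are related by the errors-in-variables power law
   `I_PCD = β·I_Imm^α` with lognormal noise, fitted by profile maximum
   likelihood and compared to the fixed `α = 1` / `α = 0` models by BIC
   (`defensim.investment`, `defensim.powerlaw`).  Species are classified
   into consistently high/low gut abundance from rank-abundance
   quartiles, compared by Mann–Whitney U, and scored against the
   genome-size expectation via a Bayesian regression and
   posterior-predictive deviation p-values
   (`defensim.abundance`).  Synthetic generators for all inputs live in
   `defensim.synth`.

## Worked example: power-law fit

```python
from defensim.synth import SyntheticConfig, gen_investment_table
from defensim.powerlaw import PowerLawInvestmentModel, bic_compare

records = gen_investment_table(SyntheticConfig(seed=42, n_species=4657))
model = PowerLawInvestmentModel(records)
fit = model.fit()
print(fit.summary())
```

```
Power-law investment regression (profile maximum likelihood)
============================================================
model:      I_PCD = beta * I_Imm^alpha, lognormal noise
alpha:      0.559558
beta:       0.0405881
epsilon:    0.568583  (log-scale noise SD)
logL:       48897.3
BIC:        -97769.2  (k=3)
n used:     4657   dropped (zero investment): 0
```

The exponent `α ≈ 0.56 < 1` is sublinear: as total defense investment
(a proxy for viral pressure) grows, the PCD share declines relative to
immunity.  `bic_compare([fit, model.fit(fixed_alpha=1.0),
model.fit(fixed_alpha=0.0)])` ranks the free fit far ahead of the naive
linear and flat models (ΔBIC ≈ 4383 and 10050 on this synthetic table —
the same ordering, linear ≪ flat, seen in real data).

## Worked example: fitness landscape

```python
from defensim.chemostat import Environment
from defensim.landscape import evaluate_landscape

env = Environment(p0=6, Q=200, B=0.15, C=0.01, E=0.5, F=0.5,
                  G=2.0, T=0.5, phi0=1.0, psi0=0.1)
ls = evaluate_landscape(env)  # default 21x21 (a, r) grid
print(ls.a_opt, ls.r_opt_scaled, ls.sensitivity, ls.sensitive)
```

On this low-viral-pressure, high-carrying-capacity ecology the optimum is
pure PCD (`a_opt = 1.0`, `r_opt/E = 0.0`, equilibrium population 10.7 in
units of the inoculum) and the landscape is strongly PCD-sensitive
(sensitivity 1.0: without PCD the population collapses at the optimal
immunity level).  Raising `psi0` moves the optimum toward immunity;
lowering `C` (larger carrying capacity) moves it toward PCD.

A CLI mirrors the library: `defensim simulate|landscape|sweep|investment|
fit-powerlaw|classify-abundance|deviation|synth|run` (see `--help`).

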