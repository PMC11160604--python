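# dmtasim

A stochastic simulator of the **hit-to-lead design–make–test–analyze (DMTA)
cycle** in small-molecule drug discovery, with the econometric analyses used
to compare discovery strategies: success-probability CDFs, expected costs,
exponential cost-versus-model-error fits, and the breakeven monetary value of
a predictive model.

## Who this is for

Method developers and discovery scientists who want to ask *strategy*
questions quantitatively: how do ideation creativity, synthesis batch size,
the ratio of molecules scored to molecules tested, and predictive-model error
change the probability that a campaign reaches its target candidate profile
(TCP) before the budget runs out — and what is a predictive model worth, per
calculation?

## The model

A campaign starts from a handful of weak fragment **hits** and iterates DMTA
cycles until a tested molecule satisfies every TCP objective or the budget of
molecules made is exhausted ("a race of these two variables"):

- **Design / ideation** — analogs of the current best molecules are generated
  from their forward-synthesis routes: a reactant in the final step is
  replaced with a building block drawn by Boltzmann-weighted fingerprint
  similarity at temperature *T* (p ∝ exp(s/T); *T* = 0 is deterministic
  nearest-neighbor, *T* = ∞ random search; *n*-replacement controls how many
  reactants swap), or the molecule is grown by one step with a random
  compatible block. A campaign-wide cache forbids re-ideating old chemistry.
- **Design / scoring** — candidates are scored by *NoisyOracles*: the
  ground-truth oracle value plus i.i.d. Gaussian error of spread σ, modeling
  a predictive model of stated inaccuracy.
- **Design / selection** — per-objective values map through a piecewise
  utility *u*: 1 inside the ideal interval, linear 0→1 across the
  acceptable-to-ideal band, and an unbounded quadratic penalty outside the
  acceptable interval. Candidates are partitioned into successive
  non-dominated (Pareto) fronts on their utilities, scalarized within fronts
  by a weighted mean, and a batch is filled ε-greedily.
- **Make / Test** — selected molecules are annotated as made (depleting the
  budget, $3000 per compound made and tested by default) and measured with
  the noiseless oracles.
- **Analyze** — measurements supplant predictions; the systematic
  overestimation of top-ranked noisy scores (regression to the mean) is
  removed by refitting, each cycle, an ordinary least-squares model
  *measured = α + β·predicted* per objective and deflating future
  predictions with it.

The default TCP follows oral-drug norms: potency pIC50 ≥ 8 acceptable
(≥ 9 ideal) on a [3, 11] dynamic range, Log P in [0, 4] ([0, 3] ideal),
Log S in [−4, 0] ([−3, 0] ideal).

Everything external is replaced by a bundled, seeded synthetic testbed
(`dmtasim.fixtures`): a building-block catalog with the functional handles
the four-reaction repertoire consumes (amide coupling, sulfonamide formation,
reductive amination, Suzuki coupling), fragment hits with valid routes, a
solubility surrogate anti-correlated with Log P, and a synthetic affinity
landscape — a hidden-optimum Gaussian basin over z-scored physicochemical
descriptors, punctuated by activity-cliff motifs, one of which carries a
large "pharmacophore" bonus so top potency requires a specific structural
feature. Real catalogs (CSV/SDF), reaction SMARTS files, and external oracle
backends drop in through the same interfaces.

## Worked example

```python
from dmtasim.fixtures import default_fixture
from dmtasim.campaign import CampaignConfig, run_campaign
from dmtasim.ideation import IdeationConfig

fx = default_fixture(seed=0)          # catalog, reactions, hits, oracles, TCP
config = CampaignConfig(
    tcp=fx.tcp,
    ideation=IdeationConfig(temperature=0.08, n_replace=1),
    sigmas={k: 1.0 for k in fx.oracles},   # model error, pIC50 / log units
    batch_size=8, scoring_ratio=10, budget=250, seed=7,
)
result = run_campaign(config, fx.oracles, fx.templates, fx.catalog, fx.hits)
```

prints (via the fields of `result`):

```
success: True
molecules made: 37
molecules scored: 319
cycles: 4
monetary cost: $111,000
winning molecule: COc1ccoc1CN(C)C(=O)c1ccncc1C
measured: {'affinity': 7.24, 'lipophilicity': 2.26, 'solubility': -1.81}
```

The campaign reached the (landscape-rescaled) potency bar of 7.125 pIC50
with acceptable lipophilicity and solubility after 4 cycles and 37 molecules
made — $111,000 at $3000 per compound. Ensembles quantify strategy effects;
for example, 30 trials per condition at a tight budget:

```
sigma=0.5: success rate within 40 made = 0.97, median molecules to success = 29
sigma=2.0: success rate within 40 made = 0.73, median molecules to success = 37
```

i.e. a worse predictive model turns a near-certain cheap campaign into a
costlier gamble — the ordering the econometric analyses formalize. The same
sweeps run from the shell:

```bash
dmtasim make-fixtures --seed 0 --out fixtures/
dmtasim run-campaign --config campaign.yaml --out out/
dmtasim run-ensemble --config campaign.yaml --trials 50 --sweep sigma=0.5,1,2 --out out/
```

## Layout

| module | contents |
| --- | --- |
| `dmtasim.chem_space` | building blocks, reaction templates, routes, records, catalog I/O |
| `dmtasim.ideation` | similarity ranking, Boltzmann sampling, replacement/growth, cache |
| `dmtasim.oracles` | oracle contract, Gaussian-noise wrapper, Log P oracle, pluggable backends |
| `dmtasim.tcp` | objective specs, piecewise utility, TCP satisfaction |
| `dmtasim.selection` | Pareto fronts, scalarized ranking, ε-greedy, bias model |
| `dmtasim.campaign` | the DMTA loop, budget race, lineage, reset/step environment |
| `dmtasim.econometrics` | ensembles, success CDFs, expected costs, cost-model fits, breakeven value, trajectories |
| `dmtasim.fixtures` | synthetic catalog/reactions/hits/landscape/solubility |
| `dmtasim.cli` | `dmtasim` command-line entry points |

See `docs/methods.md` for the scientific account: model assumptions,
parameter defaults and why, what the synthetic testbed does and does not
emulate, and known limitations.
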