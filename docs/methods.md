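# Methods

This note documents the model behind `dmtasim`, the defaults and why they
were chosen, what the synthetic testbed emulates, and the package's known
limitations.

## The campaign as a stochastic process

A discovery program is modeled as a realization of a stochastic process: a
sequence of design–make–test–analyze (DMTA) cycles starting from weak hits
and ending when a tested molecule satisfies the target candidate profile
(TCP) or the budget of molecules made is exhausted. Ensembles of independent
realizations (differing only in seed) yield the quantities of interest: the
empirical CDF of success over molecules made or cycles, success rate at a
budget, cost quantiles, and derived comparisons between strategies. Failed
trials are right-censored at the budget and never imputed, so CDFs plateau
at the overall success fraction.

## Chemistry representation

Molecules are canonical SMILES; the dedup key for every compound in a
campaign is the canonical SMILES of the sanitized molecule (fast and
deterministic; InChI-level tautomer folding is unnecessary in a closed
enumeration). Similarity uses hashed circular (Morgan) fingerprints,
radius 2, 2048 bits — the de-facto standard — with parameters carried in
`FingerprintParams` so similarity values are reproducible.

Synthetic routes are forward-only: each step names a reaction template and
its reactants (building blocks or earlier step products) and pins the
product chosen among the enumerated outcomes, so replay is deterministic and
`replay_route` validates every record. Reaction application enumerates all
sanitizable products of an RDKit reaction; products failing valence or
sanitization are dropped and counted. With `protect=True`, atoms outside one
matched reactive site per reactant are marked with RDKit's `_protected`
property, restricting multi-site reactants to a single regiochemistry.

## Utility and selection

Each objective contributes a piecewise utility: 1 inside the ideal interval,
linear 0→1 across the band between an acceptable bound and its same-side
ideal bound, and a quadratic penalty beyond an acceptable bound with ramp
width equal to that band (falling back to 10% of the dynamic range when the
band has zero width). Where ideal and acceptable bounds coincide (Log P and
Log S lower/upper bounds in the standard profile), the quadratic descends
from the boundary utility of 1 rather than 0 — the only choice that keeps
the function continuous everywhere, which we treat as the defining property
of the shape; the price is a sliver of positive utility within one fallback
width outside the acceptable window on such sides. The composite utility is
a weighted arithmetic mean (uniform by default): it saturates at 1 exactly
when every objective is ideal, and any missing objective dominates with −∞
so unevaluable molecules never win a selection.

Selection operates on per-objective utilities of bias-corrected predictions
(measurements supersede predictions wherever available). Candidates are
partitioned by deterministic fast non-dominated sorting — the partition into
successive Pareto fronts is a well-defined object, and a deterministic
algorithm makes campaigns exactly reproducible — then ordered by front,
weighted-mean utility, and dedup key (a stable tie-break). Batches fill
ε-greedily (default ε = 0.1): each slot is uniform-random over the remaining
pool with probability ε, else the best-ranked remaining candidate.

Program success is judged on *measured* values only, against the acceptable
intervals by default (the ideal-interval criterion is available via
`TCP.success_criterion`).

## Noisy scoring and bias correction

A `NoisyOracle` adds i.i.d. Normal(0, σ²) error to the ground-truth oracle,
modeling an unbiased predictive model of inaccuracy σ in the oracle's units.
Noise is resampled at every scoring call by default (each use of a model is
a fresh prediction); a frozen-per-molecule mode exists for studies that want
a deterministic surrogate. "σ = ∞" is implemented as σ = 10⁶ — far beyond
any objective's dynamic range — to keep arithmetic finite.

Because selected candidates are the top of a noisy ranking, their raw
predictions overestimate truth on average. The Analyze step refits, from the
full ledger of prediction–measurement pairs, a per-objective OLS model
*measured = α + β·predicted* (active once 10 pairs accumulate; attenuation
β < 1 appears automatically under noise) and corrects subsequent
predictions with it. The regression direction (measured on predicted) is
the choice that makes the corrected score an estimate of the measurement;
it is configurable in principle but not swept here.

## Campaign defaults

| knob | default | rationale |
| --- | --- | --- |
| batch size | 8 molecules/cycle | small batches resolve the budget race finely at desk scale |
| scoring ratio | 10 scored : 1 tested | large enough that selection quality matters |
| budget | 250 made | several times the median cost of a guided campaign |
| cost per compound | $3000 | standard make-and-test figure used in the breakeven arithmetic |
| ε | 0.1 | exploration floor; swept in experiments |
| temperature | 0.08 | inside the empirically best band (see below) |
| n-replacement | 1 | most conservative move; ALL enables the full creativity range |
| parent pool | 5 | the number of starting hits |
| stall rule | 3 consecutive empty ideations → failure | exhausted neighborhoods terminate rather than spin |

Make and Test are coupled (every made molecule is tested): the $3000 unit
covers make-and-test, and a separate test batch is only relevant for assay
cascades, which are out of scope. RNG streams for ideation, oracle noise,
and selection are spawned independently from the campaign seed, so
component behavior is isolated and byte-reproducible; ensemble trial *i*
derives its seed from (base seed, *i*).

## The synthetic testbed

The fixtures module stands in for everything external, at "desk scale":

- **Catalog** — 250 blocks (≤ 12 heavy atoms) by seeded combinatorial
  decoration of ring/chain scaffolds with the functional handles the four
  reactions consume (acid, amine, aldehyde, sulfonyl chloride, aryl halide,
  boronic acid); a census guarantees ≥ 5 compatible blocks per reaction
  role.
- **Reactions** — amide coupling, sulfonamide formation, reductive
  amination, Suzuki coupling: two-component, robust, and ubiquitous in
  medicinal chemistry.
- **Hits** — one-step, fragment-sized (≤ 20 heavy atoms) products with
  replayable routes, selected to be weak but measurable (true pIC50 in
  [3.1, 4.5]): above the landscape floor so a gradient is felt from cycle
  one, far below the bar.
- **Affinity landscape** — pIC50(m) = 3 + A·exp(−d(m)²/s²) + Σ cliffs,
  clipped to [3, 11], where d is the Euclidean distance of m's z-scored
  8-descriptor vector (Log P, MW, TPSA, HBD, HBA, rings, fraction Csp3,
  heavy atoms; normalized against a seeded 1–3-step reference enumeration)
  from a hidden optimum. The optimum is the descriptor vector of an actual
  enumerable *three-step* product with Log P inside the ADME window, so top
  potency is reachable but only by multi-cycle elaboration and never in
  conflict with the other objectives. A = 3 and s = 0.8 × the median
  reference distance; one *pharmacophore* motif (chosen by prevalence
  2–25% in the reference sample) carries a +2.5 bonus, plus two minor
  cliff motifs (±1.5–1.6, including single-atom "magic halogen" motifs).
  The compressed amplitude and the bonus motif are what make model error
  bite: within-pool true differences are comparable to realistic σ, and
  clearing the bar requires both basin proximity and the motif.
- **TCP rescaling** — the affinity bar is 75% of the achievable span
  (basin maximum + best cliff bonus), the ideal bound 85%; Log P and Log S
  bounds are the standard oral-drug values verbatim.
- **Solubility** — Log S = 0.8 − Log P − 0.02·heavy atoms + seeded
  structure-hashed jitter (SD 0.3), clipped to [−8, 1]: deterministic per
  molecule, strongly anti-correlated with Log P (Pearson r < −0.6), so the
  two ADME objectives genuinely conflict.

These generator constants were calibrated once on pilot ensembles so that
the testbed is solvable (noiseless campaigns succeed reliably within a
400-molecule budget) while preserving graded sensitivity to model error,
scoring ratio, batch size, and ideation temperature, then frozen; the
acceptance suite was written against the frozen conditions.

### What the testbed does and does not emulate

It reproduces the *mechanisms*: SAR with activity cliffs, anti-correlated
ADME objectives, forward-synthesis-constrained ideation, noisy scoring, a
budget race. It does not reproduce the scale of real campaigns: the
enumerable space is ~10⁴–10⁵ products rather than 10²¹, so per-cycle
candidate pools cover structural neighborhoods much faster than in reality,
campaigns finish in tens rather than thousands of molecules, and absolute
success rates and costs are not comparable to published full-scale figures.
Two quantitative audit notes follow from desk scale: the SAR association
between fingerprint distance and potency difference is positive and highly
significant but moderate (Spearman ρ ≈ 0.2; much of remote space sits at
the potency floor, and hashed-fingerprint distance couples only loosely to
descriptor-space distance), and single-atom matched pairs on ≤ 30-atom
products cap near Tanimoto 0.8 with a binary 2048-bit circular fingerprint,
so activity-cliff pairs (|ΔpIC50| ≥ 1.5) are audited at similarity > 0.75.
Conclusions supported by the tests are *orderings* — success rate
non-increasing in σ, non-decreasing in scoring ratio, molecules-to-success
rising and cycles-to-success falling with batch size, an intermediate
ideation temperature weakly dominating both extremes under all-replacement —
not absolute magnitudes.

## Numerical choices

- Boltzmann sampling weights exp((s − s_max)/T) (max-subtracted for
  stability), without replacement by default; T = 0 short-circuits to the
  deterministic top-k and T = ∞ to uniform.
- Ties everywhere break lexicographically by dedup key, making every
  ordering stable and campaigns byte-reproducible.
- The exponential cost model budget(σ) = a·e^{kσ} is fit by OLS in log
  space (deterministic, stable); R² and MAE are reported on the natural
  molecule scale. Non-positive costs are excluded; fewer than three usable
  points is an error.
- Bootstrap intervals (1000 seeded resamples, percentile method) accompany
  success rates and cost quantiles; an unattainable target rate returns an
  explicit sentinel, never an extrapolation.
- Breakeven model value = (median molecules made without the model − with
  it) × cost per compound / number of scoring calculations; medians, not
  means, are used throughout for cost summaries.

## Known limitations

- Ideation cannot combine addition and replacement in one move, and growth
  ignores similarity; both limit how nimble chemical moves can be.
- Bias correction is per-objective affine; correlated or asymmetric model
  errors are not modeled.
- The no-model baseline (scoring disabled, random selection among ideated
  candidates) is one specific reading of "make every molecule we ideate";
  at desk scale ideation outruns the batch, so the batch is a random
  subset.
- The docking and trained-solubility backends are interfaces only; the
  synthetic landscape is a stand-in with the right qualitative character,
  not a docking emulator.
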