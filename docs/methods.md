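# Model and methods

## The infection cycle

The simulator advances a phage population in discrete, non-overlapping
generations. Each generation:

1. **Feed.** Each bacterial species provides a fresh pool of
   `supply_per_step` cells (default 500 per species). Bacteria do not
   persist, reproduce or coevolve; the environment is well mixed.
2. **Encounter.** Phage act in uniformly shuffled order. Each phage draws
   one encounter; the species is chosen with probability proportional to
   the remaining pool counts. If both pools are empty the phage finds no
   host.
3. **Binding.** The phage binds with its heritable affinity for that
   species' receptor (`p_A` or `p_B`, each in [0, 1]).
4. **Restriction.** Injected DNA carrying the host's methylation pattern
   always survives. Mismatched or unmarked DNA survives with the host's
   escape probability ε (default 10⁻³ when restriction is on; ε = 1 on
   both hosts turns restriction off). A cell whose R-M system destroys the
   injected DNA *survives and remains in the pool*; only a successful
   infection removes a cell (one infection per cell). The restricted phage
   dies either way.
5. **Burst.** A surviving phage lyses the cell into β progeny (default 10).
   Progeny inherit the parental affinity pair, each mutating independently
   with probability μ: one affinity (chosen uniformly) moves by ±δ (sign
   uniform, default δ = 0.1) and the other moves by −τ times that change
   (default τ = 0, no trade-off); both are clipped to [0, 1]. Methylation
   is assigned by the active scheme (below). The neutral lineage label and
   the identity of the producing host are recorded on every progeny.
6. **Turnover.** Every phage of the parental generation dies, whether or
   not it reproduced. The next generation is exactly β times the number of
   successful infections (optionally truncated by a carrying cap, off by
   default).

Because each pool is consumed by successful infections, the equilibrium
phage population is about β × (cells infected per generation), which
exceeds the bacterial supply — the intended resource-competition regime.

### Methylation schemes

* **random** — progeny get pattern A or B with 50:50 odds regardless of
  parent or host.
* **genetic** — progeny inherit the parental pattern, flipping A↔B with a
  per-progeny pattern mutation rate (defaults to the affinity mutation
  rate).
* **plastic, efficiency m** — a fraction m of progeny get the producing
  host's pattern; the rest are unmarked. Unmarked genomes face the
  endonuclease of *every* host. m ∈ {1.0, 0.5, 0.1} gives the 100%/50%/10%
  plastic variants; a per-host efficiency override is available for
  asymmetric methyltransferases.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `supply_per_step` | 500 + 500 | cells per species per generation; sets the scale of competition |
| `burst_size` β | 10 | progeny per infection; with the supply this bounds the population at ~10⁴ |
| `restriction_escape` ε | 10⁻³ (on) / 1 (off) | survival odds of improperly marked DNA; natural escape odds span roughly 10⁻¹–10⁻⁷ |
| `mutation_rate` μ | 0.01 | per-progeny affinity mutation probability (see below) |
| `mutation_step_size` δ | 0.1 | affinity change per mutation |
| `tradeoff` τ | 0 | coupling of the two affinities; 0 = no trade-off |
| `initial_population` | 1000 | founders, clonal, marked with pattern A |
| `initial_p_A`, `initial_p_B` | 0.5, 0.5 | founder affinities |
| `test_lineage_size` | 0 (10 in presets) | neutrally labelled founders with optional pattern/affinity overrides |
| `steps` | 200 | generations per replicate |

The baseline mutation rate deserves comment. Rare (10⁻⁴) and common (0.1)
per-progeny rates are the two endpoints used in the precedence experiments.
As the everyday default the package uses 0.01: it is high enough that
affinity evolution is clearly visible within the 200-generation horizon,
and low enough that the standing affinity variance stays small. The latter
matters because grouping the final generation by host-of-production is
implicitly a one-generation selection filter (phage produced from A had to
bind A); with a large standing variance that filter alone opens a small but
systematic within-group gap between `p_A` and `p_B` even when no
specialization has occurred, polluting the no-restriction and
random-methylation controls.

## Metrics

* **Specialization** groups the final generation by the host that produced
  each phage and reports group means of `p_A` and `p_B`. Host-of-production
  in the final generation identifies the last round of successful
  infections, so "phage produced from X" and "phage infecting X at the
  end" coincide.
* **Pedigree (predictive power)** is the fraction of final B-produced
  phage carrying the test-lineage label. It is undefined — flagged, never
  silently dropped — when no phage were produced from B.
* **Pattern contrast** reruns the same seeds with the test lineage founded
  with pattern B versus pattern A and reports the mean paired difference in
  test-lineage descendants on host B; positive values mean the methylation
  pattern itself had predictive power.
* **Precedence** runs many independent trials, finds the first successful
  reproduction on host B in each (runs stop at that event), and asks
  whether that parent's `p_B` *strictly* exceeded the mean `p_B` of its own
  generation — a clonal tie counts as "not genetically distinct". The
  population mean is evaluated at the generation of the breach, not at
  time 0, since the question is whether the breacher stood out among its
  contemporaries. Points with fewer than 10 successful trials out of 100
  are flagged as non-qualifying.
* **Bootstrap intervals** are percentile bootstraps (default 10⁴
  resamples) over *replicate* means; the replicate is the independent
  unit. Extinct replicates are excluded from means and counted separately.

## Analytics

The closed-form one-generation expectation is

    W(pattern, p_A, p_B) = β · [ f_A · p_A · s_A + f_B · p_B · s_B ],

with `s_X = 1` for the cognate pattern and ε_X otherwise (unmarked is never
cognate), `f_A + f_B = 1` the relative host concentrations. Selection
coefficients are `W_mut/W_wt − 1`. Because binding and restriction survival
multiply within each host term, methylation pattern and adsorption are
epistatic: `s(pattern + affinity) ≠ s(pattern) + s(affinity)`. Adsorption
rate constants map to binding probabilities via `p = min(k/k_ref, 1)` with
a configurable reference rate (default 1.0). `W` is by construction the
single-generation expectation of the simulator's own cycle without cell
competition; the test suite verifies the two agree to Monte-Carlo error,
which is the package's internal oracle for the stochastic engine.

Waiting-time comparisons treat both routes onto a new host as memoryless:
an affinity mutation with per-generation probability q_mut, and a
restriction bypass with q_byp = p_B · ε; for N independent phage the
per-generation no-event probability is (1 − q)^N and the cumulative curve
is its t-th power.

## Reproducibility and numerical choices

* Every stochastic operation takes an explicit `numpy.random.Generator`.
  A run is a pure function of (parameters, seed); replicate seeds are
  expanded from a master seed with `numpy.random.SeedSequence`, so the
  i-th replicate is reproducible regardless of how many replicates are
  requested.
* The engine applies the identical per-agent cycle in vectorised form:
  uniforms are pre-drawn per generation, a scalar loop runs only while
  both pools are non-empty (each infection shifts the encounter odds of
  the phage behind it in the shuffled order), and the remaining
  single-pool phase is fully vectorised. The per-agent operations in
  `model_core` are the reference semantics and are what the unit tests and
  the Monte-Carlo oracle exercise.
* Per-generation shuffling of the acting order is part of the model (it is
  how cell competition is resolved) and of the reproducibility contract.
* Affinities are clipped to [0, 1] after every mutation; a perturbation at
  a boundary can therefore be silent.
* Extinction (population 0 before the horizon) truncates the run; the
  replicate is flagged and excluded from metric means but reported in all
  counts. An empty host pool, `p_B = 0` with no mutation, and a zero-step
  horizon are all well-defined degenerate inputs.
* Scenario tables are written as TSV with a fixed float format, so
  re-running with the same seed reproduces byte-identical files.

## Problem sizes used by the tests and the acceptance script

Headline checks run the full study protocol: 30 replicates of 200
generations for the pedigree and specialization experiments and 100 trials
for precedence (with a 100-generation horizon, since breaches occur early
and runs stop at the first B-reproduction). The null pedigree control runs
at a 5-generation horizon: under winner-takes-burst reproduction
(offspring variance ≈ β − 1) a neutral 10-copy lineage is almost surely
lost by generation 200, so the founding-share expectation — a martingale
property — is only statistically recoverable from 30 replicates at short
horizons; the choice was made by a power analysis over candidate horizons.
Unit tests use desk-scale populations (tens of phage, a handful of
generations) plus 10⁵–10⁶-trial Monte-Carlo frequency checks of the
per-agent operations.

## What the generator emulates — and does not

The simulator captures the features the hypotheses depend on: two hosts
with distinct receptors and R-M systems, plastic/genetic/random methylation
inheritance, competition for a limited cell supply, heritable continuous
binding affinities, and complete pedigree tracking. It deliberately omits:
mutations at R-M recognition sites (so genetic assimilation of the plastic
phenotype cannot occur), phage–bacteria coevolution, more than two hosts,
spatial structure, overlapping generations or free-phage persistence
between steps, phage decay, and within-generation reinfection by progeny.
Passing tests therefore speak to the internal logic of the
plasticity-predicts-pedigree argument, not to quantitative rates in any
real phage–host system; absolute parameter values (burst size, supplies,
mutation rates) are order-of-magnitude choices, not measurements.

## Known limitations

* The test lineage can be lost to drift before establishing on host B
  (roughly 5% of test-lineage replicates); pedigree fractions are reported
  per replicate so such replicates are visible rather than averaged away.
* With 10% plastic methylation and restriction on, the default parameter
  set makes extinction nearly certain rather than merely common; the
  marked fraction of a burst (β·m = 1) sits exactly at the replacement
  boundary, so this regime is sensitive to β and m.
* The precedence fractions depend on the standing affinity variance and
  therefore on μ and δ jointly; only their ordering across conditions is a
  robust model output.
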