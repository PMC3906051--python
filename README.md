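# culturesim

A spatially explicit agent-based model of cumulative adaptive culture in
resource-limited populations, together with the experiment sweeps and
end-value statistics used to study how natural selection, demography and
group connectivity interact in cultural evolution.

## The model in brief

Individuals live in groups, one group per square of a bounded 10×10 grid.
Each square holds stocks of ten resource types that replenish every yearly
time step. An individual can only consume resources for which it carries the
corresponding cultural trait; traits form an ordered list (trait 1, trait 2,
…, up to 10) and each carries an integer skill value 1–10. The per-step
extraction rate of a trait is

```
rate = basic_rate + selection_differential × (skill − 1)
```

so the *selection differential* s — the experiments' central knob — is the
extra yield per unit of skill. Individuals pay a 5-unit metabolic
requirement per step, store at most 50 units of energy, and die of
starvation or old age. Reproduction is sexual and energy-gated: partners
must be at least 15 years old and hold ≥ 20 energy units, and each parent
transfers 10 units to the newborn, which ties the birth rate to resource
availability.

Culture changes through three channels:

* **vertical transmission** — newborns copy each parental trait value with a
  5% error of ±1 skill unit;
* **social learning** — individuals that failed to meet their 5-unit
  requirement ("resource pressure") either acquire the next trait from a
  group member (or a member of a Moore-neighbouring group, when the
  interaction radius is 2) or re-learn an owned trait from a random model
  when somebody demonstrably better exists; copies carry the same ±1 error;
* **independent invention** — an individual under pressure that has mastered
  its last trait (skill 10) and can pay the innovation cost adds the next
  trait at skill 1. Every invention is logged (step, group, trait,
  individual).

Groups in which more than half the members go hungry fission onto an empty
neighbouring square (if large enough) or migrate to a richer one, which lets
the population colonise the grid. Mean traits per individual is the measure
of cumulative culture; *competition* is the fraction of the population that
missed the 5-unit requirement.

Replicate end values are compared with two-sided **exact** Wilcoxon rank-sum
tests (complete enumeration of all C(n+m, n) rank assignments, midranks
under ties) and Bonferroni correction per test family — appropriate for the
ten replicates per parameter cell the experiments use.

## Worked example

```python
from culturesim import SimulationConfig, run

cfg = SimulationConfig(selection_differential=0.5, resource_level=50,
                       interaction_radius=2)
result = run(cfg, seed=1)
print(result.timeseries.iloc[[0, 250, 500, 750, 1000]].to_string(index=False))
```

```
 step  pop  mean_group_size  mean_traits  competition  n_groups
    0   20            20.00          1.0     0.000000         1
  250   43            10.75          1.0     0.325581         4
  500 5043            50.43          5.0     0.691850       100
  750 9980            99.80         10.0     0.728958       100
 1000 9961            99.61         10.0     0.727035       100
```

The founding group of 20 lingers near the single-trait carrying capacity of
its square (resource level ÷ requirement = 10 per trait) until skill
mastery unlocks the invention of new traits; each invention raises the
equilibrium population, producing the staircase growth visible between
steps 250 and 750. Here the connected population ends with all ten traits,
~100 individuals per square, and 73% of individuals under resource
pressure. `result.events` holds the innovation log — in this run only ten
invention events stand behind the whole cultural repertoire, because
acquired traits spread socially:

```
 step  group_id  trait_index  individual_id
  344         2            2            394
  344        24            2            243
  401       100            3           3830
```

## Command line

```bash
culturesim run   --config cell.yaml --seed 1 --outdir runs/     # 10 replicates
culturesim sweep table1 --base-seed 1 --outdir sweep/           # 24-cell grid
culturesim sweep table1 --resource-levels 50 --n-runs 2 --max-steps 200  # desk scale
culturesim analyze --end-values sweep/end_values.csv --outdir sweep/
```

`run` writes per-replicate `timeseries.csv`, `events.csv`,
`end_values.json` and the fully resolved `config.resolved.json`; `sweep`
additionally writes `summary.csv` (cell means ± SD), a
`summary_table1_layout.csv` pivot (rows are resource level within selection
differential, column blocks the two regimes), and `comparisons.csv` with
the Bonferroni-corrected exact rank-sum
tests (factor 6 across selection differentials, 3 across resource levels,
pairwise between regimes).

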