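# reefcast

Stochastic simulation and permutational scenario analysis of coral-reef
futures under multiple interacting stressors.

`reefcast` is aimed at reef ecologists and managers who want to ask
"what happens to this reef over the next 40 years if we regulate water
quality, reduce fishing, and bleaching keeps occurring?" — and to quantify
how those stressors interact (antagonistically, additively or
synergistically) rather than treating them one at a time.

## The model

A local-scale mean-field model of a shallow reef is advanced by daily
difference equations. The state is four benthic proportional covers that
sum to one —

* hard coral *C*,
* grazed epilithic algal community (EAC) *E*, which doubles as the
  colonisable substrate,
* macroturf *T*,
* macroalgae *M*,

— plus three consumer biomasses (g m⁻²): herbivorous fish *H*, piscivorous
fish *P* and grazing sea urchins *U*. Benthic transfers are zero-sum
mass-action exchanges (coral lateral growth and recruitment onto
substrate, coral mortality and crowding, macroalgal/macroturf overgrowth
of coral, turf emergence and senescence, macroalgal spread and die-back,
grazing returning algae to EAC). Fish recruitment is scaled by a
coral-cover feedback φ(C) = r_min + (1 − r_min)·min(C, c_ref)/c_ref, so
habitat loss suppresses replenishment. All process rates are annual and
are listed with units in `docs/methods.md`.

Four stressor forcings act on the model:

| Forcing | Action |
|---|---|
| Nutrification | turf growth ×1.3–2, macroalgal growth ×2–7 |
| Sedimentation | coral growth ×(1−U[0,0.3]), recruitment ×(1−U[0,0.6]), mortality +U[0,0.2] yr⁻¹, settlement on macroturf blocked |
| Fishing | constant extraction (t km⁻² yr⁻¹), 68.3% herbivores / 31.7% piscivores |
| Bleaching | instantaneous loss of 10–60% of coral cover, 0/1/2 events per decade (or a fixed schedule) |

Nutrification and sedimentation act jointly as "water quality". Ranged
magnitudes are drawn uniformly once per replicate run — the Monte-Carlo
element. A scenario is one cell of the 3 (fishing) × 3 (bleaching) × 2
(water quality) factorial; each scenario × site is simulated as a seeded
20-replicate ensemble over 40 years for four synthetic site archetypes
(two healthier sites with urchins, two degraded macroalgae-dominated sites
without).

Simulated reef states at years 5, 10, 20 and 40 are compared on
normalised variables with Euclidean distances: crossed three-factor
PERMANOVA with permutation of residuals under a reduced model (4,999
permutations), unadjusted pairwise tests (153 for 18 scenarios), PERMDISP
for homogeneity of dispersions, CAP and nMDS ordination, mean-distance
effect sizes, and an antagonism/additivity/synergy classification.
Trajectory metrics report post-bleaching coral recovery and the time for
coral cover to reach a printed 0%.

## Worked example

```python
from reefcast import Scenario, make_site, run_ensemble, time_to_collapse, coral_recovery
from reefcast.scenarios import fixed_bleaching_regime

site = make_site("lucero_like")

# current-yield fishing under poor water quality, decadal bleaching
degraded = run_ensemble(
    Scenario("high", "once-per-decade", "unregulated"),
    site, n_replicates=20, master_seed=1,
    bleaching_override=fixed_bleaching_regime(),
)
print("collapse year:", time_to_collapse(degraded.mean_trajectory(), threshold=0.5))

# same fishing with regulated water quality: recovery between the two events
managed = run_ensemble(
    Scenario("high", "once-per-decade", "regulated"),
    site, n_replicates=20, master_seed=1,
    bleaching_override=fixed_bleaching_regime(),
)
print("post-bleaching cover:", coral_recovery(managed.mean_trajectory(), 20, 38).table_row())
```

prints

```
collapse year: 9
post-bleaching cover: {'cover_post': 23, 'absolute': 8, 'relative': 33}
```

Under unregulated water quality the ensemble-mean coral cover of the
healthier site reaches a printed 0% within 9 years despite identical
fishing; with water quality regulated, the same reef holds 23% cover
after a 30% bleaching event at year 20 and regains 8 percentage points
(a 33% relative increase) before the next event — water quality, not
fishing, is the binding constraint.

## The analysis pipeline

Numbered drivers under `analysis/` reproduce the full study flow and
write delimited tables (with SHA-256 manifests) under `results/`:

1. `01_build_sites.py` — emit the four site fixtures (YAML + flat
   parameter files);
2. `02_run_scenarios.py` — run the 18-scenario Monte-Carlo grid per site
   and extract snapshot community matrices (a few minutes at full scale);
3. `03_multivariate.py` — PERMANOVA / PERMDISP / pairwise tests /
   effect-size interaction classification / CAP and nMDS per site and
   snapshot year;
4. `04_trajectories.py` — fixed-schedule bleaching runs, the recovery
   table, and time-to-collapse plus year-40 fish biomass under poor water
   quality.

The same functionality is exposed as a CLI (`reefcast fixtures|grid|run|
snapshot|analyze|metrics|all`); `reefcast all --config run.yaml` drives
an end-to-end run from one YAML file whose single master seed controls
every source of randomness.

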