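# Methods

## Model structure

The simulator is a local-scale mean-field model of a shallow (~5–20 m)
reef cell (nominally 500 m × 500 m), advanced by explicit-Euler difference
equations with a daily update (all rates are annual; one step advances
1/365 of a year). The state holds four benthic proportional covers
(coral C, grazed epilithic algal community E, macroturf T, macroalgae M;
C+E+T+M = 1) and three consumer biomasses in g m⁻² (herbivorous fish H,
piscivorous fish P, sea urchins U). EAC plays a double role: it is both a
functional group (cropped fine turf on hard substrate) and the colonisable
space on which coral and algae expand.

Benthic transfers (annual flux densities, all mass-action):

| flux | form | meaning |
|---|---|---|
| E→C | (g_C·C + r_ext + r_endo·C)·E | lateral growth plus recruitment |
| T→C | (r_ext + r_endo·C)·T | recruitment onto macroturf (blocked by sediment) |
| C→E | (m_C + c_C·C)·C | baseline + crowding mortality |
| C→M | o_M·M·C | macroalgal overgrowth of coral |
| C→T | o_T·T·C | turf overgrowth of coral |
| E→T | γ·E | fine-turf growth pressure into macroturf |
| E→M | g_M·M·E | macroalgal vegetative spread |
| T→E | (k_HT·H + k_UT·U + m_T)·T | grazing and turf senescence |
| T→M | σ·T | turf maturation into macroalgae |
| M→E | (k_HM·H + k_UM·U + m_M)·M | grazing and macroalgal die-back |

Consumers gain biomass by recruitment and assimilated intake and lose it
to natural mortality, piscivory (herbivores only) and fishing extraction:

* dH = rec_H·φ(C) + ε_H·Y·(k_HE·E + k_HT·T + k_HM·M)·H − m_H·H − p·P·H − f_H
* dP = rec_P·φ(C) + ε_P·(realised piscivory) − m_P·P − f_P
* dU = r_U·U·(1 − U/K_U)  (present only at urchin sites; see below)

φ(C) = r_min + (1−r_min)·min(C, c_ref)/c_ref is the coral-cover feedback
on fish recruitment: reef fish recruit to live coral habitat, so
recruitment falls to a floor r_min as cover is lost and saturates at the
reference cover c_ref. Defaults r_min = 0.1 and c_ref = 0.3 make
recruitment unconstrained at ≥30% cover and strongly constrained below
~3%, consistent with the degraded-site behaviour the analysis expects.

Assumptions worth stating: one coral functional group (no species
structure), no spatial structure within the cell, constant external
larval supply (r_ext) for coral, constant-rate (not
proportional-to-biomass) fishing extraction because catches are specified
as yields, and no ocean acidification or storm damage.

### Crowding and senescence terms

Three processes extend the minimal flux list: density-dependent coral
mortality (c_C·C², "crowding"), macroturf senescence (m_T·T) and
macroalgal senescence/dislodgement (m_M·M). They are standard reef-model
ingredients (self-thinning and partial mortality in dense coral stands;
turf and fleshy-algal standing crops turn over on sub-annual scales), and
they are structurally necessary here: without them the system is bistable
in a way that contradicts the study design — healthy sites either run
away to ~50% coral or collapse, and degraded sites cannot persist at a
few per-cent cover. With them, each site archetype sits near its own
interior attractor.

### Urchins

Observed urchin trajectories are stable across scenarios, so the urchin
stock is modelled as a weakly self-regulating (logistic) population
decoupled from food availability: its grazing feeds back on the benthos,
but its biomass stays near the site carrying capacity (K_U = 10 g m⁻² at
urchin sites, 0 elsewhere, where it is frozen at zero). A consequence is
that the urchin column of a snapshot community matrix has zero variance
and is dropped before normalisation (the statistics layer does this
explicitly and reports it).

### Numerical scheme

Explicit Euler at dt = 1 day is stable for all rates used (fastest rate
× dt ≈ 0.03). Two truncation rules guarantee the structural invariants
under any forcing: each benthic pool scales its total daily outflow so it
cannot exceed the standing cover (keeping the cover sum exactly
conserved and covers non-negative), and consumer removals (mortality +
predation + extraction) are scaled so biomass cannot go negative —
realised piscivory after scaling is what piscivores assimilate.
Removal-scaling is applied after gains are credited. A fully drained pool
can undershoot zero by one ulp and is clamped. Bleaching events are
instantaneous: at the start of the event day, the scheduled fraction of
coral cover is moved to EAC before the daily update.

All state components may be numpy arrays, so a replicate ensemble
advances as one vectorised sweep; because the update uses only
elementwise IEEE arithmetic, each replicate of a vectorised run is
bit-identical to the same replicate simulated alone (this is tested).

## Default parameterisation

Annual rates; grazing coefficients are yr⁻¹ per g m⁻² of grazer.

| parameter | value | parameter | value |
|---|---|---|---|
| coral growth g_C | 0.26 | turf emergence γ | 1.4 |
| coral mortality m_C | 0.04 | turf senescence m_T | 0.5 |
| coral crowding c_C | 0.20 | turf→macroalgae σ | 0.02 |
| external recruitment r_ext | 0.004 | macroalgal growth g_M | 3.2 |
| endogenous recruitment r_endo | 0.03 | macroalgal senescence m_M | 1.0 |
| macroalgal overgrowth o_M | 0.7 | turf overgrowth o_T | 0.05 |
| herb. grazing k_HE/k_HT/k_HM | 0.8 / 0.30 / 0.10 | urchin grazing k_UE/k_UT/k_UM | 0.10 / 0.02 / 0.02 |
| herb. recruitment rec_H | 5.0 g m⁻² yr⁻¹ | pisc. recruitment rec_P | 1.2 g m⁻² yr⁻¹ |
| herb. mortality m_H | 1.0 | pisc. mortality m_P | 0.4 |
| piscivory p | 0.05 | assimilation ε_H/ε_P | 0.21 / 0.3 |
| algal yield Y | 6 g m⁻² per cover | urchin r_U, K_U | 0.2, 10 g m⁻² |

The parameterisation was calibrated (by forward simulation, not fitting)
so that the four site archetypes reproduce the qualitative study
surfaces: healthier sites hold ~25–35% coral for decades under regulated
water quality with post-bleaching recovery that increases as fishing
decreases; degraded sites persist at a few per-cent cover sustained
mainly by external recruitment; under poor water quality ensemble-mean
coral reaches a printed 0% within ~8–10 years at every site and fishing
level, and fish biomass at year 40 stays below ~700 kg km⁻²; and
macroalgae bloom only when nutrification raises their growth rate, not
merely when bleaching frees substrate. The macroalgal pair (g_M, m_M)
encodes a fast-turnover canopy whose net growth is negative on a healthy,
grazed reef (3.2·E < m_M + grazing at E ≈ 0.5) but strongly positive
under even the weakest nutrification draw (×2), which is what makes the
water-quality forcing reliably dominant — the mechanism behind the
antagonistic interactions the analysis detects.

## Site archetypes (synthetic-data generator)

Four archetypes emulate the structure of the study system: two
less-degraded sites with urchins (initial coral 0.30 / 0.28, low
macroalgae, H = 7 / 6 g m⁻²) and two degraded macroalgae-dominated sites
without urchins (coral 0.12 / 0.03, M = 0.34 / 0.42, H = 2 / 1 g m⁻²).
Site-specific overrides: the degraded sites have reduced fish recruitment
(poorer habitat) and different external coral supply (0.008 vs 0.002
yr⁻¹), and the second healthy site has slightly lower coral growth
(0.25), which yields its weaker post-bleaching recovery. These are
plausible reconstructions of a 2008-like condition, not survey values.

Optional jitter is multiplicative log-uniform with renormalised covers.
The jitter factors for a given seed are drawn identically for every
archetype, so cross-archetype coral ordering is preserved for all seeds
(tested over 1,000 seeds at amplitude 0.2). A degradation series
(`make_degradation_series`) interpolates the archetype rules over an
evenly spaced range of initial coral covers for sensitivity sweeps.

What the generator does *not* emulate: empirical survey values, historical
(1987–2008) stressor timelines, within-site spatial heterogeneity, or
site-specific bleaching susceptibility. Passing tests therefore
demonstrate that the pipeline reproduces the documented qualitative
behaviour of such a system, not that it predicts any real reef.

## Forcings and the scenario engine

Ranged forcing magnitudes are drawn uniformly once per replicate run;
bleaching severity is drawn per event. Stochastic bleaching timing is
per-year Bernoulli with p = events-per-decade/10 (the minimal-structure
reading of a stated long-run frequency); fixed-schedule mode (events at
years 20 and 38 removing 30% and 15% of cover) is used for the
trajectory and recovery analyses. "Decrease by a factor of 0–0.3" is
implemented as multiplication by (1 − u), u ~ U[0, 0.3]; the identity
value 1.0 is additionally admitted for the nutrification scales so a
no-effect forcing can be represented. Water-quality application is
guarded by a flag so it cannot be applied twice to one parameter set.
Catches are split 68.3% herbivores / 31.7% piscivores; fishing levels
are 0, 1.3–1.4 (half of current yield) and 2.6–2.8 t km⁻² yr⁻¹ (current
yield), with 1 t km⁻² ≡ 1 g m⁻².

Replicate i of scenario s draws its seed from a pure function
(`SeedSequence(master_seed, spawn_key=(s, i))`, truncated below 2³¹), so
any single replicate is reproducible without re-running the grid and an
entire run is reproducible from one master seed.

## Statistics

All multivariate analyses use Euclidean distances on z-scored
(mean 0, sd 1, denominator n−1) snapshot variables: covers in %,
biomasses in g m⁻². Zero-variance columns must be dropped before
normalisation (`drop_constant_columns`).

**PERMANOVA.** The total sum of squares is Σd²/n (equivalently the
squared Frobenius norm of the grand-mean-centred principal-coordinate
configuration). Term sums of squares come from orthogonal effect
projectors built by Möbius (inclusion–exclusion) expansion over
cell-averaging projectors, exact for balanced designs (the design is
required to be balanced; the 2×3×3 grid with 20 replicates gives term
dfs 1, 2, 2, 2, 2, 4, 4 and residual df 342). Pseudo-F per term uses the
full-model residual mean square. p-values use Freedman–Lane permutation
of residuals under the reduced model: for term T, the fit of the model
containing every other term is kept and its residual rows are permuted;
p = (exceedances + 1)/(n_perm + 1), so p ∈ [1/(n_perm+1), 1]. On
univariate one-factor data the pseudo-F equals the classical ANOVA F to
1e−9, sampled p matches exact enumeration on two groups of three, and
pooled type-I error over 500 null datasets stays at the nominal level
(all tested). A zero total sum of squares is reported as degenerate with
no p. Principal-coordinate axes with negative eigenvalues are kept in a
separate block whose squared contributions are subtracted (corrected
distances); with Euclidean input that block is empty up to rounding.

**Pairwise tests** are one-way PERMANOVAs per unordered scenario pair
(153 for 18 groups), reporting both pseudo-F and pseudo-t = √F, with no
multiplicity adjustment (the convention of the analysis this mirrors).

**PERMDISP** computes distances to group centroids in principal-coordinate
space (with the negative-axis correction), an ANOVA F on those distances,
and a permutation p obtained by permuting the least-squares residuals of
the distances; centroids, not spatial medians, are used. The statistic
matches scikit-bio's centroid-based PERMDISP (tested) and is invariant
under rigid translation of a group.

**CAP** truncates the orthonormalised principal coordinates to m axes and
solves the canonical eigenproblem of the group projector restricted to
that subspace. With m = "auto", m minimises leave-one-out
misclassification of nearest-centroid allocation in canonical space,
ties resolved toward fewer axes; the leave-one-out loop refits the
canonical axes per left-out observation on the fixed principal
coordinates. Canonical correlations are clipped to [0, 1].

**nMDS** delegates to scikit-learn's SMACOF with isotonic regression
(metric_mds=False) over 20 random restarts by default, reporting
normalised Kruskal stress-1.

**Effect sizes and interactions.** The effect size of a stressor
combination is the mean Euclidean distance between the undisturbed
scenario's runs and the stressed scenario's runs. A two-stressor
interaction is antagonistic / additive / synergistic according to whether
the combined effect is below / within / above the sum of the single
effects, with a configurable tolerance (default 0).

## Trajectory metrics

Recovery between two scheduled bleaching events reads coral cover the day
after the first event and the day before the second; relative recovery is
100 × absolute / post-event cover, referenced to the post-event reading
(this is the only reference that reproduces the tabulated
whole-percent identities, e.g. 11/20 → 55%). Non-positive change is
flagged and rendered as a dash. Time-to-collapse is the first day coral
cover falls to a threshold, converted to years (rounded up). The default
threshold is 0.5% cover — the largest value that still prints as 0% at
whole-percent resolution; with a constant external larval supply exactly
zero cover is unreachable (cover settles at a tiny recruitment-sustained
equilibrium, ~10⁻³ % under poor water quality), so "reaches 0%" is read
at printed resolution. Collapse and year-40 fish biomass are measured on
the ensemble-mean trajectory; 1 g m⁻² = 1000 kg km⁻².

## Problem sizes

The standard study design (20 replicates, 40-year horizon, 4,999
permutations, snapshots at years 5/10/20/40) is the default throughout.
The test suite exercises the same code at reduced sizes chosen for a
laptop-scale run — short-horizon ensembles for engine contracts,
199–999 permutations for permutation-test calibration, 500 null datasets
of a 2×3×3 design with 2 replicates for the type-I check — while the
poor-water-quality bounds and the acceptance script run the full
20-replicate, 40-year ensembles (16 ensembles, well under a minute).

## Known limitations

* The parameterisation is a calibrated reconstruction; absolute covers
  and biomasses carry no empirical authority beyond their qualitative
  ordering and bounds.
* Linear (mass-action) grazing and piscivory; no saturating functional
  responses, so grazer impact scales without limit in biomass.
* One coral group: no diversity in bleaching susceptibility or growth
  form.
* Constant external larval supply: regional degradation feedbacks on
  recruitment are outside the model.
* The balanced-design PERMANOVA rejects unbalanced data rather than
  approximating Type-III partitioning; this matches the factorial design
  it serves.
* Decoupled urchins cannot respond to food collapse; they are a
  stability assumption, not a prediction.
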