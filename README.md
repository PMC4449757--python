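# ecotrap

Simulation models of **ecological traps for pest control**: can a pest be
eradicated without controlling it everywhere?

When a pest such as the feral pig (*Sus scrofa*) is culled in one part of a
landscape but not in another of equal habitat quality, per-capita resources
rise in the controlled area and density-dependent habitat selection pulls
immigrants out of the uncontrolled source into the controlled sink. If
control mortality outweighs the benefit of lowered competition, the
controlled area becomes an *ecological trap* — and with enough of the
landscape controlled, the whole population, controlled and uncontrolled
alike, can be driven to extinction. `ecotrap` is for quantitative
ecologists and pest managers who want to explore where that threshold lies.

## Models

Three tiers, all run at a monthly time step over a 50-year horizon, all
coupled by the same immigration mechanism. The per-capita resource
gradient between the controlled patch (capacity $A_c$, abundance $N_c$)
and the uncontrolled patch ($A_u$, $N_u$) is

$$G_t = \frac{A_c}{N_{c,t}} - \frac{A_u}{N_{u,t}},$$

and each month a fraction $f = \tanh(\gamma G_t)/12$ of the source
population immigrates into the patch with more resource per head; $\gamma$
sets the strength of density dependence (0.1 weak, 1.0 strong).

1. **Two-patch logistic trap** (`ecotrap.logistic`) — deterministic
   discrete logistic growth ($r_m = 0.792\,\mathrm{yr}^{-1}$ for feral
   pigs, monthly increment $r_m/12$) in each patch, with annual control
   mortality $d$ applied to the controlled patch as a survival-compounded
   monthly fraction $1-(1-d)^{1/12}$.
2. **Stochastic rangeland model** (`ecotrap.rangeland`) — a
   pasture–kangaroo–pig consumer–resource system for the Paroo River
   district (1000 km²): quarterly rainfall drawn from a truncated normal
   (mean 193 mm, SD 90 mm) drives pasture growth; red kangaroos and pigs
   eat pasture through saturating functional responses and their rates of
   increase are saturating (Ivlev) functions of pasture biomass. The
   immigration gradient is measured against a **shadow twin** — a
   no-control, no-dispersal copy of the system fed the identical rainfall
   sequence — via $G_P = M_c/P_c - M_u/P_u$.
3. **Density-dependent aerial control** (`ecotrap.aerial`) — replaces the
   fixed mortality with an empirical helicopter-shooting functional
   response, $q(P) = a\,(1-e^{-(P-b)/d_{\mathrm{eff}}})$ kills h⁻¹ above a
   refuge density $b$ (zero below it), parameterized for three Australian
   shooting programs (Mary River, Macquarie Marshes, Paroo River), with
   one 7.5-hour session per month.

Extinction means the combined population drops below two individuals.

## Worked example

```python
from ecotrap import (LogisticParams, run_logistic, RangelandParams,
                     DispersalParams, replicate_interactive)
from ecotrap.rangeland import FixedMortalityControl

# Deterministic tier: control 90% of the landscape at 90% annual
# mortality, weak density dependence.
res = run_logistic(LogisticParams(prop_controlled=0.9, d_annual=0.9, gamma=0.1))
print(res.extinction_years, round(res.mean_Nc, 1), round(res.mean_Nu, 1))
# 15.5 41.2 19.7

# Stochastic tier: 200 replicates at 50% coverage, 90% mortality.
summary = replicate_interactive(
    RangelandParams(prop_controlled=0.5),
    FixedMortalityControl(0.9),
    DispersalParams(gamma=0.1),
    n_reps=200, base_seed=42)
print(summary.n_extinct, round(summary.mean_ext_years, 1),
      round(summary.sd_ext_years, 1))
# 200 10.1 0.7
```

The first run says: with 90% of the habitat controlled at 90% annual
mortality, the deterministic population is extinct after 15.5 years, having
averaged ~41 pigs in the trap and ~20 in the source along the way. The
stochastic tier reaches extinction much sooner (all 200 replicates, mean
10.1 ± 0.7 years at only 50% coverage): environmental variability makes
the population easier to extinguish. Swapping in the aerial-shooting
response (`AerialShootingControl(SITES["Paroo River"])`) eliminates
extinction entirely — the refuge density puts a floor under the population.

The same experiments are scriptable from the shell:

```sh
ecotrap logistic-sweep --out results/
ecotrap interactive-sweep --reps 200 --seed 42 --out results/
ecotrap ddcontrol-sweep --reps 100 --out results/
ecotrap single-run --tier interactive --prop 0.5 --control 0.9 --gamma 0.1 --trajectories
ecotrap make-tables --which table3 --reps 200 --out results/
```

Each sweep crosses proportion of area controlled (10–90%) × control level
(10/50/90% mortality, or the three shooting sites) × γ (0.1, 1.0) and
writes a tidy CSV; identical seeds reproduce every CSV byte for byte.
`--config file.yaml` overrides any default (grids, initial densities,
rainfall moments, session hours, …).

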