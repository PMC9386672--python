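# sexcoevo

Why do females of many species clear infections faster than males, while the
same pathogens are more virulent in males? `sexcoevo` implements a
co-evolutionary analysis of this question for researchers in evolutionary
epidemiology: a two-sex SIS host–pathogen model in which host
immunocompetence (the sex-specific recovery rate γ_i) and pathogen virulence
(the sex-specific disease-induced mortality rate α_i) evolve jointly, and in
which mother-to-child (vertical) transmission and sex-differences in the
fertility cost of immunity drive the sexes apart.

## Model

The resident ecology tracks susceptible and infected hosts of each sex
(S_f, S_m, I_f, I_m; N their total):

```
dS_f/dt = b (S_f + (1−v) I_f)(S_m + I_m)/N + γ_f I_f − S_f (β_ff I_f + β_fm I_m) − μN S_f
dS_m/dt = b (S_f + (1−v) I_f)(S_m + I_m)/N + γ_m I_m − S_m (β_mf I_f + β_mm I_m) − μN S_m
dI_f/dt = b v I_f (S_m + I_m)/N + S_f (β_ff I_f + β_fm I_m) − (γ_f + α_f + μN) I_f
dI_m/dt = b v I_f (S_m + I_m)/N + S_m (β_mf I_f + β_mm I_m) − (γ_m + α_m + μN) I_m
```

with harmonic-mean mating, a one-to-one birth sex ratio, vertical
transmission probability v, and density-dependent natural mortality μN.
Two trade-offs close the model:

* **pathogen**: β(α_j) = β_max α_j / (α_j + d) — transmission can only rise
  by killing hosts faster;
* **host**: b(γ_f, γ_m) = b_max exp(−c_f γ_f²) exp(−c_m γ_m²) — recovery is
  paid for in fertility, by either mate.

Evolution is analysed with adaptive dynamics. A rare mutant pathogen (or
host allele) experiences the resident endemic equilibrium as a fixed
environment; its linear lineage dynamics are split into a birth part F and a
transition part T, and invasion fitness is the next-generation reduction
W = ρ(F(−T)⁻¹), with invasion iff W > 1. Traits follow the signs of the
selection gradients ∂W/∂(mutant trait) until all four gradients vanish; the
outcome is then checked to be a two-dimensional ESS for each party on a
lattice of mutant trait pairs.

## Worked example

Equal immunity costs (c_f = c_m = 0.01) and vertical transmission v = 0.5:

```python
from sexcoevo import (LifeHistoryParams, solve_coevolution, case_metrics,
                      classify_region, verify_ess)

p = LifeHistoryParams(b_max=2, beta_max=1.1, d=4, mu=0.1,
                      c_f=0.01, c_m=0.01, v=0.5)
out = solve_coevolution(p)
t = out.traits_star
print(f"gamma_f* = {t.gamma_f:.4f}   gamma_m* = {t.gamma_m:.4f}")
print(f"alpha_f* = {t.alpha_f:.4f}   alpha_m* = {t.alpha_m:.4f}")
m = case_metrics(out, p)
print(f"chi_f = {m.chi_f:.4f}  chi_m = {m.chi_m:.4f}")
print("region:", classify_region(m).value)
print("ESS:", verify_ess(out, p))
```

prints

```
gamma_f* = 0.9201   gamma_m* = 0.8147
alpha_f* = 1.9540   alpha_m* = 2.6333
chi_f = 0.5152  chi_m = 0.6030
region: FEMALE_DEFENDED_MALE_VIRULENT
ESS: (True, True)
```

Vertical transmission alone pushes the co-evolved state off the symmetric
diagonal: females recover faster than males (γ_f* > γ_m*) while the pathogen
evolves higher virulence in males (α_m* > α_f*), and in case-metric terms an
infection is more likely to kill a male (χ_m > χ_f). Both trait pairs are
evolutionarily stable. The same analysis at v = 0 with c_f = c_m collapses
onto the diagonal (no sex differences), and sweeping (v, Δc) with
`sweep_phase_plane` maps where each qualitative pattern holds.

The same things are available from the shell:

```
sexcoevo solve --v 0.5 --c-0 0.01
sexcoevo sweep --c-0 0.1 --out sweep.csv
sexcoevo classify sweep.csv --basis case_metrics
sexcoevo scenarios list
```

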