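"""Fit the pooled log-linear cytokine model for every microbe.

All (cytokine, stimulus, subject) records enter one regression per
microbe: ln(concentration) on cytokine-by-stimulus dummies, age, sex, and
the microbe's zero-anchored abundance rank.  Species whose rank
coefficient survives Bonferroni < 0.005 at >20% prevalence are called
immunomodulatory, positive or negative by its sign.
"""

from gradimmune import (
    SimulationConfig, build_observation_table, classify_species,
    fit_all_species, simulate_cohort,
)

beta = 1e-3  # planted effect per rank unit
config = SimulationConfig(
    n_rural=70, n_urban=230, n_external=1, n_species=40, n_metabolites=2,
    n_pathways=1, n_gradient_species=0,
    immunomod_spec=[("sp_005", beta), ("sp_006", -beta)],
)
cohort = simulate_cohort(config, seed=2)

obs = build_observation_table(cohort["cytokines"], cohort["metadata"],
                              cohort["tz_abundance"])
print(f"observations: {obs.n_rows} of a possible {obs.full_grid_size()} "
      "(missing records dropped)")

effects, counts = classify_species(fit_all_species(obs))
print("classification counts:", counts)
for e in effects:
    if e.classification != "neutral":
        print(f"  {e.species_id}: beta_m={e.beta_m:+.2e}/rank, "
              f"p_Bonferroni={e.p_bonferroni:.2e} -> {e.classification}")
# The planted species should appear with the planted signs; the estimated
# beta_m is the change in ln(pg/mL) per abundance-rank unit.
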