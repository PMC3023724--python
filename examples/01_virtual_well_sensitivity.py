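"""How many cells must a single-cell intensity assay measure?

Builds a 49,503-cell pool of baseline phospho-signal intensities (control
mean 1.0, SD 1.80 — the heterogeneity of an unstimulated primary sensory
neuron culture), resamples 10,000 "virtual wells" per well size and prints
the SD of the well means next to the finite-population closed form. Twice
that SD is the smallest whole-culture intensity change the assay can call
at that cell count; a change confined to one fifth of the cells must be
five times larger within the subgroup.
"""

from quam import baseline_intensity_population, detectable_effect, sensitivity_table

pool = baseline_intensity_population(49_503, mean=1.0, sd=1.80, seed=0)
table = sensitivity_table(pool, (250, 1000, 5000, 10_000, 20_000),
                          n_wells=10_000, seed=1)

print(f"{'cells/well':>10} {'SD of mean':>11} {'closed form':>12} "
      f"{'detectable':>11}")
for _, r in table.iterrows():
    print(f"{int(r.cells_per_well):>10d} {r.sd_of_means:>11.4f} "
          f"{r.sd_closed_form:>12.4f} {r.detectable_effect_pct:>10.1f}%")

whole, sub = detectable_effect(round(100 * table.sd_of_means[0]) / 100,
                               k=2, subgroup_fraction=1 / 5)
print(f"\nAt 250 cells/well: changes below ~{whole:.0f}% of the culture mean "
      f"are not statistically sound;\na response confined to 1/5 of the "
      f"cells must exceed ~{sub:.0f}% within that subgroup.")
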