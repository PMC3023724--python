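"""Classify IB4(+) vs IB4(-) neurons by histogram intersection.

Per-cell IB4 lectin intensities form a continuum, not two separated groups:
a low unspecific-binding mode plus a broad specific mode. A lectin-blocked
control culture samples the unspecific mode alone; the intensity where the
stained culture's density rises above the blocked control's density is the
positive/negative cutoff. Prints the cutoff, the recovered positive
fraction and its agreement with the generator's ground truth.
"""

from quam import ScenarioConfig, classify_positive, generate_population, sample_blocked_control

scenario = ScenarioConfig(n_cells=40_000, ib4_positive_fraction=0.71, seed=6)
pop = generate_population(scenario)
blocked = sample_blocked_control(scenario, 5000, seed=7)

res = classify_positive(blocked, pop["intensity_ib4"].to_numpy())
truth = (pop["ib4_status"] == "positive").to_numpy()

print(f"blocked-control cells: {len(blocked)},  stained cells: {len(pop)}")
print(f"histogram-intersection cutoff: {res.cutoff:.3f} (normalized intensity)")
print(f"recovered IB4(+) fraction: {100 * res.fraction_above_test:.1f}%  "
      f"(ground truth {100 * truth.mean():.1f}%)")
print(f"single-cell agreement with truth: "
      f"{100 * (res.labels == truth).mean():.1f}%")
print("\nThe estimate is conservative: positives hidden under the blocked-"
      "\ncontrol density classify negative.")
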