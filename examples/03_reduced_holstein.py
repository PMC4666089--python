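"""A desk-scale Holstein breeding program under two mating schemes.

Runs the 12-locus Holstein panel at reduced scale (2,000 cows, 50 bulls,
20 herds, 10 years, 2 replicates) under the inbreeding-penalized scheme and
its recessive-aware modification, then prints frequency and loss summaries.
Takes a couple of minutes.
"""

import numpy as np

from herdmate import holstein_scenario, run_replicates

for scheme in ("pryce", "modified_pryce"):
    scenario = holstein_scenario().reduced(years=10, replicates=2, seed=7, scheme=scheme)
    results = run_replicates(scenario)
    final = {
        locus: np.mean([r.summaries[-1].allele_frequency[locus] for r in results])
        for locus in scenario.locus_names
    }
    deaths = np.mean([sum(su.n_embryo_deaths for su in r.summaries) for r in results])
    gain = np.mean([
        r.summaries[-1].mean_tbv_cows - r.summaries[0].mean_tbv_cows for r in results
    ])
    print(f"\n{scheme} after {scenario.years} years (mean of {scenario.replicates} replicates):")
    print(f"  HH1 frequency      0.0192 -> {final['HH1']:.4f}")
    print(f"  Red coat frequency 0.0542 -> {final['Red coat color']:.4f}")
    print(f"  Horned frequency   0.9929 -> {final['Horned']:.4f}")
    print(f"  embryo deaths (total): {deaths:.0f};  cow genetic gain: ${gain:.0f}")

print(
    "\nBoth schemes gain merit at similar rates; the modified scheme also\n"
    "prices recessive-genotype risk into each mating. At this desk scale,\n"
    "drift from the small bull population dominates individual rare-allele\n"
    "trajectories, so replicate means are the quantity to read."
)
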