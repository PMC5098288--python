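"""Simulate a dairy-cattle population and split it by birth date.

Builds genotypes, additive breeding values and weekly dry-matter-intake
records for a desk-scale herd, then partitions animals into a training
pool (born before the split date) and a test set (born on/after).
"""

import selftraingp as sg

params = sg.SimulationParams(
    n_animals=400, n_markers=1000, n_qtl=200,
    heritability=0.15,            # typical for residual feed intake
    cohort_variance_fraction=0.10,
    missing_rate=0.02,
    test_fraction=0.3,
    seed=42,
)
pop = sg.simulate_population(params)

train, test = sg.make_split(pop)   # split at Jan 1 of the last birth year
print(f"animals: {params.n_animals}, markers: {params.n_markers}, "
      f"missing entries: {pop.genotypes.n_missing}")
print(f"training pool (born before {params.split_date}): {len(train)}")
print(f"test set (born on/after):                        {len(test)}")
print(f"realized genetic-variance fraction: "
      f"{sg.realized_heritability(pop):.3f} (configured {params.heritability})")
# The realized fraction estimates the configured heritability: the share of
# per-animal phenotypic deviation that is additive-genetic and hence the
# ceiling on what genomic prediction can explain.
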