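"""One self-training round: labelled + genotype-only animals.

Step 1 trains the SVR base predictor f on labelled animals; Step 2
predicts pseudo-phenotypes for the genotype-only animals; Step 3 retrains
on the union to get f*.  Both are evaluated on the same held-out test set.
"""

import selftraingp as sg

pop = sg.simulate_population(sg.SimulationParams(
    n_animals=700, n_markers=1000, n_qtl=200, heritability=0.4,
    test_fraction=0.2, seed=5,
))
train, test = sg.make_split(pop)
labeled, unlabeled = train[:150], train[150:500]
phen = pop.phenotype_series()

result = sg.self_train(
    pop.genotypes.subset_animals(labeled), phen,
    pop.genotypes.subset_animals(unlabeled),
    sg.PredictorSpec(),            # C=1, gamma=1/n_markers, epsilon=0.1
)
G_test = pop.genotypes.subset_animals(test)
r_sl = sg.evaluate(result.base, G_test, phen)
r_ssl = sg.evaluate(result.augmented, G_test, phen)

print(f"labelled {result.n_labeled}, pseudo-labelled {result.n_unlabeled}, "
      f"test {len(test)}")
print(f"R_SL  (supervised f)      = {100 * r_sl.correlation:.1f}%  "
      f"(MSE {r_sl.mse:.3f})")
print(f"R_SSL (self-trained f*)   = {100 * r_ssl.correlation:.1f}%  "
      f"(MSE {r_ssl.mse:.3f})")
print(f"gain from self-training   = "
      f"{100 * (r_ssl.correlation - r_sl.correlation):+.2f} points")
# R_SL/R_SSL are correlations between predicted and measured phenotypes in
# the test set; the gain is what the genotype-only animals contributed.
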