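"""The three validation designs on one simulated population.

Runs a supervised learning curve, a paired labelled × pseudo-labelled
ratio sweep and the plateau search for the optimal ratio; saves
error-bar figures under scratch/.
"""

from pathlib import Path

import selftraingp as sg
from selftraingp.plotting import plot_learning_curve, plot_ratio_sweep

pop = sg.simulate_population(sg.SimulationParams(
    n_animals=600, n_markers=800, n_qtl=150, heritability=0.4,
    test_fraction=0.2, seed=9,
))
train, test = sg.make_split(pop)
pool_labeled, pool_unlabeled = train[:200], train[200:480]
phen = pop.phenotype_series()

config = sg.ExperimentConfig(
    labeled_sizes=(25, 50, 100, 175),
    sweep_labeled_sizes=(50, 100),
    unlabeled_sizes=(100, 200),
    n_replicates=20, plateau_increment=70, seed=9,
)

curve = sg.learning_curve(pop.genotypes, phen, pool_labeled, test, config)
print("learning curve (mean correlation ± 95% CI):")
for s in curve:
    print(f"  {s.label:15s} {s.mean_correlation:.3f} ± {s.ci_correlation:.3f}")

sweep = sg.ratio_sweep(pop.genotypes, phen, pool_labeled, pool_unlabeled,
                       test, config)
print("\nratio sweep (paired gain R_SSL − R_SL):")
print(sweep.summary_frame()[["n_labeled", "n_unlabeled", "mean_diff",
                             "ci_diff"]].to_string(index=False))

plateau = sg.plateau_search(pop.genotypes, phen, pool_labeled,
                            pool_unlabeled, test, config,
                            labeled_sizes=(100,))
res = plateau[100]
print(f"\nplateau at n_labeled=100: stopping ratio "
      f"{res.mean_ratio:.2f} ± {res.ci_ratio:.2f}, "
      f"max gain {100 * res.mean_improvement:+.2f} points "
      f"({res.n_exhausted}/{len(res.replicates)} replicates exhausted the pool)")
# The stopping ratio is how many pseudo-labelled animals per labelled
# animal are worth adding before per-step gains fall below 0.01%.

out = Path("scratch")
out.mkdir(exist_ok=True)
plot_learning_curve(curve, config.labeled_sizes).figure.savefig(
    out / "learning_curve.png", dpi=120)
plot_ratio_sweep(sweep).figure.savefig(out / "ratio_sweep.png", dpi=120)
print(f"\nfigures saved under {out}/")
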