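"""Run a desk-scale GA campaign with the deterministic surrogate fitness.

Seeds come from the bundled synthetic fragment library; each generation is
assembled from 10 elitism + 50 mutation + 50 crossover compounds, filtered
through Lipinski, scored, and ranked.
"""
from evochem import RunConfig, run

config = RunConfig(generations=5, n_elitism=10, n_mutation=50, n_crossover=50,
                   filter_chain=["Lipinski"], selector="ranking", rng_seed=7)
state, ledger, summaries = run(config)

print("gen  size  best     mean     top10")
for s in summaries:
    print(f"{s.generation:>3}  {s.population_size:>4}  {s.best:7.2f}  "
          f"{s.mean:7.2f}  {s.top10_mean:7.2f}")

best = state.population[0]
print(f"\nbest compound: {best.smiles}  (id {best.id}, "
      f"score {best.scores['primary']:.2f})")
# Scores follow the docking convention: more negative = predicted fitter.
# The best score never worsens across generations because elites advance
# unchanged and are not rescored.
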