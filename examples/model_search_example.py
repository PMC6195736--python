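"""Exhaustive omit/include/partition model search on simulated data.

The truth has position-specific neighbor effects (a codon-position-by-
neighbor interaction), so the best model must *partition* by codon
position rather than merely include it additively.  A reduced factor set
keeps the search desk-scale; every spec is scored under both Poisson and
NB2 families and ranked by the smaller of the two summed AICs.
"""

from mitosub import (
    SimulationConfig,
    TrueModel,
    build_state_table,
    enumerate_models,
    rank_models,
    search_models,
    simulate,
)

print(f"full protein-coding model space: "
      f"{len(enumerate_models('protein_coding'))} specs "
      f"(rRNA/control: {len(enumerate_models('rRNA'))} each, "
      f"tRNA: {len(enumerate_models('tRNA'))})")

effects = {
    "codon_position*right_neighbor": {"3:G": 1.2, "1:G": -1.0},
    "codon_position*left_neighbor": {"2:T": 1.0, "3:T": -0.8},
}
dataset = simulate(
    SimulationConfig(
        seed=5, n_tips=80, true_model=TrueModel(intercept=-3.5, effects=effects)
    )
)
table = build_state_table(
    dataset.tree, dataset.true_times, dataset.genome, region_class="protein_coding"
)
factors = ["codon_position", "left_neighbor", "right_neighbor"]
scores = search_models(
    table, "protein_coding", r=0.05, factors=factors, response_schemes=["ALL"]
)
report = rank_models(scores)
cols = ["rank", "codon_position", "left_neighbor", "right_neighbor",
        "aic_poisson", "aic_negbin", "best_family"]
print(f"\nreduced search over {len(report)} specs; top 5 by min AIC:")
print(report[cols].head(5).to_string(index=False))
print("\n(the winner partitions by codon position, recovering the "
      "interaction structure the data was generated under)")
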