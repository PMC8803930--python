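"""Cross-model convergence: direction matrix, candidate selection, dendrogram.

Plants two metabolites up in 4 of 5 models and one in only 2; the >=4-model
rule restricted to the nucleotide / amino-acid / lipid classes keeps the
first two and drops the third.
"""

from regenconverge import (
    PlantedMetabolite,
    SynthConfig,
    build_direction_matrix,
    gen_metabolome_study,
    impute_minimum,
    model_similarity,
    rescale_median,
    select_candidates,
    test_dpmp,
)

cfg = SynthConfig(
    n_models=5,
    n_metabolites=100,
    seed=3,
    missing_rate=0.0,
    planted_up_metabolites=(
        PlantedMetabolite("M0001", frozenset({1, 2, 3, 4}), 2.0, "Nucleotide"),
        PlantedMetabolite("M0002", frozenset({2, 3, 4, 5}), 1.5, "Lipid"),
        PlantedMetabolite("M0003", frozenset({1, 2}), 2.0, "Amino Acid"),
    ),
)
study = gen_metabolome_study(cfg)

tables = {
    model: test_dpmp(rescale_median(impute_minimum(matrix)), study.designs[model])
    for model, matrix in study.matrices.items()
}
table = build_direction_matrix(tables)
print("signed significance codes (+1 up, -1 down, 0 tested null):")
print(table.codes.loc[["M0001", "M0002", "M0003"]])

candidates = select_candidates(table, study.annotation, min_models=4)
print("\ncandidates (up in >=4 models, Nucleotide/Amino Acid/Lipid):")
print(candidates)
# M0003 is planted in only 2 models, so it falls below the convergence bar.

tree = model_similarity(table.log2fc, metric="correlation")
print("\nmodel dendrogram (correlation distance, average linkage):")
print(tree.to_newick())
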