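# regenconverge

Cross-model metabolomic and transcriptomic convergence analysis for
regeneration-associated metabolite discovery.

## The problem

Tissues and organisms with high regenerative capacity — axolotl limb
blastema, deer antler stem cells, young primate tissues, wild-type human
mesenchymal stem cells (hMSCs) — can be contrasted against low-regenerative
counterparts (pre-amputation tissue, primary hMSCs, aged tissues,
Werner-syndrome hMSCs). If a metabolite is consistently elevated on the
high-regenerative side across many such evolutionarily distant models, it is
a candidate driver of regenerative capacity worth testing in a cell-based
screen. `regenconverge` implements that comparative pipeline as a tested
Python library for analysts working with untargeted-metabolomics area-count
matrices and companion bulk-RNA-seq contrasts.

## What it computes

Per model contrast (high-regenerative vs control), metabolite matrices are
normalized as in the standard untargeted workflow — missing cells imputed
with the compound minimum (missingness treated as below detection limit),
each metabolite rescaled to median 1, then auto-scaled (mean 0, unit sample
SD) for testing and ordination. Differentially present metabolic products
(**DPMPs**) are metabolites with two-group P < 0.05 (Welch t by default);
fold change is log2(mean_high / mean_control) on median-scaled values.

Pathway-level aggregation uses the **differential abundance score**

```
DA = (n increased − n decreased) / n identified   ∈ [−1, 1]
```

per super- or sub-pathway (−1: every identified metabolite decreased; +1:
all increased), and its transcriptomic analogue the **DE score** =
(# significant DEGs in a gene set) / (# genes in the set). DEGs use the
dual cutoff BH-adjusted P < 0.05 (raw P selectable per contrast) and
|log2FC| > 0.25. **Rescue DEGs** intersect opposite-direction calls from an
injury contrast and a treatment contrast (down upon injury ∩ up upon
treatment, and the mirror set).

Cross-model machinery: a metabolite × model signed-significance matrix;
candidate selection (up-DPMP in ≥ 4 models within the nucleotide / amino
acid / lipid super-pathways, the rule that surfaced uridine); model
dendrograms (1 − Pearson r or Euclidean distance, average linkage, Newick
export); PLS-DA ordination; a replicate-permutation Pearson-correlation
test with add-one empirical p-values; joint gene+metabolite hypergeometric
pathway over-representation; and proliferation-screen ranking
(mean treated / mean vehicle confluence, best concentration per
metabolite).

A synthetic-study generator (`SynthConfig`, `gen_metabolome_study`,
`gen_expression_study`, `gen_screen_plate`) produces every input with
planted ground truth, so the entire pipeline is testable end to end with no
external data.

## Worked example

`examples/03_convergence_candidates.py` plants two convergent metabolites
(up in 4 of 5 models) and one non-convergent (2 models), then runs the full
chain:

```
candidates (up in >=4 models, Nucleotide/Amino Acid/Lipid):
               n_models super_pathway  max_abs_log2fc
metabolite_id
M0001                 4    Nucleotide        2.199014
M0002                 4         Lipid        1.767781

model dendrogram (correlation distance, average linkage):
(model_05:0.71998,((model_03:0.287634,model_04:0.287634):0.215356,
 (model_01:0.301168,model_02:0.301168):0.201822):0.21699);
```

`n_models` is the number of models where the metabolite is a significant
up-DPMP; `max_abs_log2fc` the strongest supporting fold change (the
tie-breaker). The planted 2-model metabolite is correctly excluded by the
≥4-model convergence bar. The other scripts in `examples/` walk through
normalization and DPMP calling, DA scores, rescue DEGs and DE scores, the
metabolite screen, and the permutation correlation test.

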