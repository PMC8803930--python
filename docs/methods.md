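# Methods

## Model and procedure

The pipeline treats each "model" as an independent paired contrast of
samples with higher vs lower regenerative capacity and asks which
metabolites move the same way in many models at once. The chain is:

1. **Normalization.** Raw area counts are imputed per metabolite with the
   observed compound minimum (missing values assumed below the detection
   limit), divided by the per-metabolite median (median → 1), and — for
   testing and ordination only — auto-scaled to mean 0 and unit sample SD
   (denominator n − 1). Zero-variance metabolites cannot be auto-scaled and
   are dropped with a warning.
2. **DPMP calling.** Per metabolite, a two-sample location test between the
   high-regenerative and control groups. Welch's t is the default; a
   pooled-variance t and a Mann-Whitney rank-sum test (normal approximation
   with tie and continuity corrections) are selectable. Significance is raw
   P < 0.05 — no multiplicity correction for DPMPs, matching the standard
   MetaboAnalyst-style two-group workflow; BH q-values are reported for
   reference. Fold change is computed on median-scaled values (ratios are
   meaningless after centring). Because a per-feature affine rescaling
   applied to all samples leaves the t statistic unchanged, p-values agree
   before and after auto-scaling to ~1e-9, which the suite asserts.
3. **Pathway scores.** DA = (increased − decreased)/identified per super-
   or sub-pathway; the numerator counts only significant DPMPs by default
   (a switch counts all tested metabolites by fold-change sign), the
   denominator all tested metabolites annotated to the pathway. DE score =
   significant DEGs / genes in set, both restricted to the tested universe.
   The "relative DE score" is the set's DE score divided by the all-genes
   background DE score (reported as absent when the background is zero);
   this ratio-to-background definition is a declared choice — the source
   analyses plot the quantity without defining it.
4. **DEGs and rescue sets.** The built-in desk-scale engine is a two-group
   Welch/Wilcoxon test on log-scale expression with the dual cutoff
   (BH-adjusted or raw P < 0.05, |log2FC| > 0.25, both strict); externally
   produced per-gene (log2fc, p) tables — e.g. count-model output — are
   ingested by `contrast_from_table` and re-flagged under the same dialect.
   Rescue DEGs (up) = significantly down in injured-vs-sham ∩ up in
   treated-vs-vehicle; rescue (down) is the mirror intersection.
5. **Convergence.** Per-model contrast tables are stacked into a
   metabolite × model matrix coded +1/−1/0/absent; candidates are
   metabolites up in ≥ k models (default 4) whose super-pathway lies in
   {Nucleotide, Amino Acid, Lipid}, ranked by support count then maximum
   |log2FC| among supporting models. Model similarity uses 1 − Pearson r
   (or Euclidean distance) on fold-change profiles with pairwise-complete
   features — models carry different metabolite panels, so pairwise
   completion maximizes usable features; a strict all-model intersection
   mode exists. Agglomeration is average linkage; trees export to Newick
   with branch lengths from merge heights.
6. **Permutation correlation.** Replicate-to-sample assignment is shuffled
   independently per metabolite within each group; each permutation yields
   a full Pearson matrix. Reported are the permutation-mean matrix and the
   add-one empirical p-value (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1), so
   the smallest attainable p at 100 permutations is 1/101.
7. **PLS-DA.** Two-block PLS of the auto-scaled matrix against a centred
   one-hot class indicator (scikit-learn's NIPALS-style fit, deterministic
   initialization — reproducible without a seed); only the sample scores
   are exposed, as an ordination sanity check of group separation.
8. **Screen ranking.** Relative proliferation = mean treated confluence /
   mean shared-vehicle confluence per (metabolite, concentration); each
   metabolite is summarized by its maximum ratio across concentrations
   (mean selectable), ties broken toward the lower concentration, no
   significance testing — the screen ranks, it does not test.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` (DPMP) | 0.05 | raw-p significance cutoff per contrast |
| `alpha`, `lfc_threshold` (DEG) | 0.05, 0.25 | dual cutoff, both strict |
| `min_models` | 4 | convergence bar for candidate selection |
| `super_filter` | Nucleotide, Amino Acid, Lipid | candidate classes |
| consistency flag | 7 models | DA > 0 in ≥ 7 models highlights a pathway |
| `n_perm` | 100 | permutations for the correlation test |

## Synthetic-study generator

`SynthConfig` defaults emulate the discovery design: 11 models, 5 samples
per group, a 500-metabolite panel classified into the 9 standard
super-pathways with nested sub-pathways, 10% missing cells, log2-scale
noise SD 0.25. Abundances are log-normal (positive and right-skewed like
area counts — no distribution is prescribed by the workflow itself);
planted metabolites have an exact group-mean log2 ratio equal to their
planted effect in their planted models only. Missingness is MCAR by
default, with a left-censoring mode (low values more likely missing) that
mirrors the below-detection-limit reading of minimum imputation. A
`detection_rate` mask emulates per-model panel differences. Expression is
negative-binomial (dispersion 0.05, var = μ + 0.05 μ²) over a three-arm
sham / injured+vehicle / injured+treated design, n = 6 per arm, reported
as log2(count+1); planted rescue genes drop by 2 log2 units upon injury
and are fully restored by treatment. Screen plates draw Gaussian well
noise (SD 2 confluence points around a 40% baseline) with a saturating
dose profile reaching the planted multiplicative effect at the top
concentration. One master seed spawns per-model substreams, so outputs are
byte-identical under a fixed configuration.

What the generator does **not** emulate: batch and injection-order
effects, correlated metabolite blocks, retention-time or identification
errors, library-size variation and count overdispersion heterogeneity,
dropout structure of single-cell data. Passing recovery tests therefore
demonstrates the correctness and calibration of the decision rules under
clean planted signal, not robustness to those real-data pathologies.

## Calibration and recovery conditions

- Null calibration: 2,000 metabolites, 5 samples/group, 50 seeds at
  generator defaults; the raw-p DPMP rate sits slightly below nominal
  (≈ 0.044; Welch t is mildly conservative at n = 5), within 0.05 ± 0.01.
  Null expression studies leave rescue sets empty in ≥ 90% of runs.
- Convergent-candidate recovery: 8 metabolites per run planted up
  (log2FC = 2) in exactly 4 of 11 models, 250-metabolite panel, noise SD
  0.25, complete matrices, 100 seeds; recall and precision of the
  ≥4-model selection both ≥ 90%. Complete matrices are used because this
  experiment probes the selection rule under its stated effect-and-noise
  model; under 10% MCAR missingness, minimum imputation pulls missing
  high-group cells down to the compound minimum, inflating within-group
  variance and costing per-model power (measured ≈ 0.92 vs 1.0) — an
  artifact of minimum imputation worth knowing about, documented here
  rather than folded into the recovery experiment.
- Rescue-gene recall: planted |log2FC| = 2 at n = 6/group with ~60
  background responders per contrast (real injury and treatment remodel
  hundreds of genes; the adaptive BH threshold depends on that discovery
  load — with a background-free null the same effect recalls only ~0.83).
- The published 29-candidate list lives in a supplementary table that is
  not redistributable here; the count check runs against a synthetic
  stand-in study with 29 planted convergent metabolites, which the
  selection rule must return exactly.

## Numerical choices and degenerate inputs

- Sample SD (ddof = 1) everywhere; strict inequalities at both DEG
  thresholds; t = 0 with identical constant groups is reported as p = 1.
- Metabolites with no observed values cannot be imputed (error naming
  them); zero medians cannot be rescaled (error); zero group means leave
  log2FC undefined (NaN, flagged by a warning) while the p-value is still
  reported.
- Hypergeometric p-values are upper tails P(X ≥ k); BH adjustment is the
  step-up procedure via statsmodels, cross-checked in the suite against a
  brute-force sort/scale/cumulative-minimum oracle to 1e-12.
- Candidate ties at equal support break by maximum |log2FC| across
  supporting models; screen ties at equal ratio break toward the lower
  concentration.
- Joint pathway analysis keeps only over-representation on the pooled
  gene+metabolite universe; pathway-topology weighting is deliberately
  dropped (no pathway graphs are shipped).
- Outputs are tabular (TSV/JSON/YAML) plus Newick trees; plotting is left
  to the caller.

## Known limitations

- The two-group engines are not count models; for real RNA-seq counts an
  external DESeq2/edgeR run should be ingested via `contrast_from_table`.
- Pairwise-complete distances can make the model dendrogram non-metric in
  pathological panel configurations; the strict-intersection mode avoids
  this at the cost of features.
- The permutation-correlation scheme follows one reading of a tersely
  described procedure (within-group replicate shuffling, add-one p); other
  readings (e.g. bootstrap over replicates) would report different means.
- Day-6 endpoint confluence is the screen readout; a growth-slope mode is
  not implemented.
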