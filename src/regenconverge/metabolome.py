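"""Metabolite-matrix normalization and differential-abundance calling.

The normalization chain mirrors the standard untargeted-metabolomics
workflow for area-count matrices with below-detection missingness:

1. ``impute_minimum`` -- missing cells take the metabolite's observed minimum
   (missing values are assumed to sit below the detection limit);
2. ``rescale_median`` -- each metabolite is divided by its own median so the
   per-metabolite median equals 1;
3. ``auto_scale``     -- each metabolite is mean-centred and divided by its
   sample standard deviation (used for testing and ordination only).

Differentially present metabolic products (DPMPs) are then called per model
contrast (high-regenerative vs control) with a two-group location test at a
raw P < 0.05 cutoff; fold changes are taken on the median-scaled values,
where ratios are still meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import TEST_METHODS, bh_adjust, contrast_table, two_group_test

logger = logging.getLogger(__name__)

#: Metabolon-style two-level classification: nine super-pathways, each
#: sub-pathway nested in exactly one of them.
SUPER_PATHWAYS = (
    "Amino Acid",
    "Carbohydrate",
    "Energy",
    "Lipid",
    "Nucleotide",
    "Peptide",
    "Cofactors and Vitamins",
    "Xenobiotics",
    "Partially Characterized Molecules",
)

STAGES = ("raw", "imputed", "median_scaled", "auto_scaled")

GROUPS = ("high_regen", "control")


@dataclass
class AbundanceMatrix:
    """Samples x metabolites abundance values plus a processing-stage tag.

    ``values`` is indexed by sample id with one column per metabolite id.
    Raw and imputed matrices hold non-negative area counts (missing = NaN
    only at the ``raw`` stage); ``median_scaled`` matrices have a
    per-metabolite median of 1; ``auto_scaled`` matrices are mean-zero with
    unit sample variance per metabolite.
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("sample ids and metabolite ids must be unique")
        if self.stage != "raw" and self.values.isna().any().any():
            raise ValueError(f"stage {self.stage!r} matrices must be complete")
        if self.stage in ("raw", "imputed") and (self.values < 0).any().any():
            raise ValueError("abundances must be non-negative before auto-scaling")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check a metabolite annotation table (index metabolite_id).

    Requires columns super_pathway / sub_pathway / low_confidence, known
    super-pathway names, and each sub-pathway nested in exactly one
    super-pathway.
    """
    required = {"super_pathway", "sub_pathway", "low_confidence"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    unknown = set(ann["super_pathway"]) - set(SUPER_PATHWAYS)
    if unknown:
        raise ValueError(f"unknown super-pathway names: {sorted(unknown)}")
    parents = ann.groupby("sub_pathway")["super_pathway"].nunique()
    crossed = parents[parents > 1]
    if not crossed.empty:
        raise ValueError(
            f"sub-pathways nested in more than one super-pathway: {list(crossed.index)}"
        )
    return ann


def impute_minimum(m: AbundanceMatrix) -> AbundanceMatrix:
    """Fill each metabolite's missing cells with its observed minimum.

    Observed cells are unchanged; a metabolite with no observed value at
    all cannot be imputed and raises.
    """
    if m.stage != "raw":
        raise ValueError(f"impute_minimum expects a raw matrix, got stage {m.stage!r}")
    all_missing = m.values.columns[m.values.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            f"metabolites with no observed values cannot be imputed: {list(all_missing)}"
        )
    filled = m.values.fillna(m.values.min(axis=0))
    return AbundanceMatrix(filled, stage="imputed")


def rescale_median(m: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each metabolite by its own median so the median becomes 1."""
    if m.stage not in ("raw", "imputed"):
        raise ValueError(f"rescale_median expects raw/imputed values, got {m.stage!r}")
    if m.values.isna().any().any():
        raise ValueError("matrix must be complete (impute first)")
    med = m.values.median(axis=0)
    zero = med.index[med <= 0]
    if len(zero):
        raise ValueError(f"non-positive median, cannot rescale: {list(zero)}")
    return AbundanceMatrix(m.values / med, stage="median_scaled")


def auto_scale(m: AbundanceMatrix) -> AbundanceMatrix:
    """Mean-centre and divide by the sample SD (ddof=1), per metabolite.

    Zero-variance metabolites cannot be scaled; they are dropped with a
    warning.
    """
    if m.stage != "median_scaled":
        raise ValueError(f"auto_scale expects a median_scaled matrix, got {m.stage!r}")
    sd = m.values.std(axis=0, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        logger.warning(
            "dropping %d zero-variance metabolite(s) before auto-scaling: %s",
            len(constant),
            list(constant),
        )
    kept = m.values.drop(columns=constant)
    scaled = (kept - kept.mean(axis=0)) / sd.drop(constant)
    return AbundanceMatrix(scaled, stage="auto_scaled")


def _split_groups(values: pd.DataFrame, design: pd.DataFrame):
    if not {"sample_id", "group"} <= set(design.columns):
        raise ValueError("design table needs sample_id and group columns")
    design = design.set_index("sample_id") if design.index.name != "sample_id" else design
    groups = set(design["group"])
    if set(GROUPS) - groups:
        raise ValueError(f"design must contain both groups {GROUPS}, found {sorted(groups)}")
    out = {}
    for g in GROUPS:
        ids = design.index[design["group"] == g]
        missing = set(ids) - set(values.index)
        if missing:
            raise ValueError(f"design samples absent from matrix: {sorted(missing)}")
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has {len(ids)} sample(s); need at least 2")
        out[g] = values.loc[ids]
    return out["high_regen"], out["control"]


def test_dpmp(
    m: AbundanceMatrix,
    design: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "welch",
) -> pd.DataFrame:
    """Call DPMPs for one high-regenerative-vs-control contrast.

    ``log2fc`` is log2(mean high_regen / mean control) on the median-scaled
    values; ``p_value`` comes from a two-sample location test (Welch t by
    default — identical on auto-scaled values, since per-feature affine
    rescaling shared by all samples leaves the t statistic unchanged).
    Significance uses the raw P < ``alpha`` cutoff; BH q-values are reported
    in ``adjusted_p`` for reference but do not drive the flag.
    """
    if m.stage not in ("median_scaled", "auto_scaled"):
        raise ValueError(
            f"test_dpmp expects median_scaled or auto_scaled values, got {m.stage!r}"
        )
    if method not in TEST_METHODS:
        raise ValueError(f"unknown test method {method!r}")
    high, ctrl = _split_groups(m.values, design)
    p = two_group_test(high.to_numpy(), ctrl.to_numpy(), method=method)
    if m.stage == "median_scaled":
        mean_high = high.mean(axis=0).to_numpy()
        mean_ctrl = ctrl.mean(axis=0).to_numpy()
        ok = (mean_high > 0) & (mean_ctrl > 0)
        log2fc = np.full(mean_high.shape, np.nan)
        log2fc[ok] = np.log2(mean_high[ok] / mean_ctrl[ok])
        n_undef = int(np.isnan(log2fc).sum())
        if n_undef:
            logger.warning("fold change undefined (zero group mean) for %d metabolite(s)", n_undef)
    else:
        # centred values: ratios are meaningless; direction from mean difference
        log2fc = (high.mean(axis=0) - ctrl.mean(axis=0)).to_numpy()
    table = contrast_table(
        m.metabolite_ids, log2fc, p, adjust="none", alpha=alpha, lfc_threshold=0.0
    )
    table["adjusted_p"] = bh_adjust(p)
    return table
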