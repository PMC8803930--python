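"""Differential-expression calling, rescue-DEG construction and DE scores.

Works on log-scale expression matrices (samples x genes). The built-in
engine is a two-group Welch t or Wilcoxon rank-sum test; per-gene
(log2fc, p) tables produced by external count-based tools can be ingested
through :func:`contrast_from_table` and flow through the same downstream
operations.

Cutoff dialect: significance needs the configured p-value (BH-adjusted by
default, raw selectable per contrast) strictly below alpha AND |log2FC|
strictly above the fold-change threshold (default 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._stats import bh_adjust, contrast_table, two_group_test

__all__ = [
    "GeneSet",
    "RescueSets",
    "bh_adjust",
    "test_deg",
    "contrast_from_table",
    "rescue_degs",
    "de_score",
    "relative_de_score",
]

CONTRAST_COLUMNS = ("log2fc", "p_value", "adjusted_p", "direction", "significant")


@dataclass(frozen=True)
class GeneSet:
    """A named gene list (e.g. regeneration, mitochondrial, metabolic).

    Members need not all appear in an expression matrix; the intersection
    with the tested universe is taken at use.
    """

    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(genes))


@dataclass(frozen=True)
class RescueSets:
    """Genes whose injury-induced change is reversed by treatment.

    rescue_up:   significantly down in injury-vs-sham AND up in
                 treated-vs-vehicle.
    rescue_down: significantly up in injury AND down upon treatment.
    """

    rescue_up: frozenset
    rescue_down: frozenset


def _groups(values: pd.DataFrame, design: pd.DataFrame, treatment: str, reference: str):
    design = design.set_index("sample_id") if design.index.name != "sample_id" else design
    out = []
    for label in (treatment, reference):
        ids = design.index[design["group"] == label]
        if len(ids) < 2:
            raise ValueError(f"group {label!r} has {len(ids)} sample(s); need at least 2")
        missing = set(ids) - set(values.index)
        if missing:
            raise ValueError(f"design samples absent from matrix: {sorted(missing)}")
        out.append(values.loc[ids])
    return out


def test_deg(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    treatment: str,
    reference: str,
    method: str = "welch",
    adjust: str = "bh",
    alpha: float = 0.05,
    lfc_threshold: float = 0.25,
) -> pd.DataFrame:
    """Two-group DEG test on a log-scale expression matrix (samples x genes).

    log2fc is the difference of group means (treatment minus reference) on
    the log scale. ``adjust='bh'`` gates significance on the BH-adjusted
    p-value, ``'none'`` on the raw p-value; both thresholds are strict.
    """
    if not np.isfinite(expression.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix must be finite")
    treat, ref = _groups(expression, design, treatment, reference)
    log2fc = (treat.mean(axis=0) - ref.mean(axis=0)).to_numpy()
    p = two_group_test(treat.to_numpy(), ref.to_numpy(), method=method)
    return contrast_table(
        expression.columns, log2fc, p,
        adjust=adjust, alpha=alpha, lfc_threshold=lfc_threshold,
    )


def contrast_from_table(
    table: pd.DataFrame,
    adjust: str = "bh",
    alpha: float = 0.05,
    lfc_threshold: float = 0.25,
) -> pd.DataFrame:
    """Re-flag an externally produced per-gene (log2fc, p_value) table.

    Lets count-model output (e.g. a DESeq2 export) enter the pipeline with
    the same cutoff dialect as the built-in engine.
    """
    if not {"log2fc", "p_value"} <= set(table.columns):
        raise ValueError("table needs log2fc and p_value columns")
    return contrast_table(
        table.index, table["log2fc"].to_numpy(float), table["p_value"].to_numpy(float),
        adjust=adjust, alpha=alpha, lfc_threshold=lfc_threshold,
    )


def _significant(table: pd.DataFrame, direction: str) -> frozenset:
    mask = table["significant"] & (table["direction"] == direction)
    return frozenset(table.index[mask])


def rescue_degs(injury: pd.DataFrame, treatment: pd.DataFrame) -> RescueSets:
    """Intersect opposite-direction DEG sets from injury and treatment contrasts.

    ``injury`` is the injured-vs-sham contrast, ``treatment`` the
    treated-vs-vehicle contrast, both as contrast-result tables indexed by
    gene.
    """
    return RescueSets(
        rescue_up=_significant(injury, "down") & _significant(treatment, "up"),
        rescue_down=_significant(injury, "up") & _significant(treatment, "down"),
    )


def de_score(degs: pd.DataFrame, gene_set: GeneSet, universe: Iterable[str]) -> float:
    """Fraction of a gene set's (tested) genes that are significant DEGs.

    DE score = (# significant DEGs in set ∩ universe) / (# genes in
    set ∩ universe); always in [0, 1].
    """
    members = gene_set.members & set(universe)
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the universe")
    idx = degs.index.intersection(members)
    n_deg = int(degs.loc[idx, "significant"].sum())
    return n_deg / len(members)


def relative_de_score(
    degs: pd.DataFrame, gene_set: GeneSet, universe: Iterable[str]
) -> float | None:
    """DE score of the set divided by the all-genes background DE score.

    Returns None when the background rate is zero (no DEGs at all), a
    documented degenerate case rather than an error.
    """
    universe = set(universe)
    background = de_score(degs, GeneSet("universe", frozenset(universe)), universe)
    if background == 0:
        return None
    return de_score(degs, gene_set, universe) / background
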