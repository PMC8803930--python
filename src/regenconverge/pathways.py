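"""Pathway-level aggregation: DA scores and joint gene+metabolite enrichment.

The differential-abundance (DA) score of a pathway in one model contrast is

    DA = (n increased - n decreased) / n identified

where "identified" counts every tested metabolite annotated to the pathway
and increased/decreased count, by default, only significant DPMPs. The score
lies in [-1, 1]: -1 when every identified metabolite decreased, +1 when all
increased.

Joint pathway enrichment pools differentially expressed metabolic genes and
DPMPs into one hit list and scores each pathway by the one-sided
hypergeometric tail probability of at least the observed number of hits, on
a pooled gene+metabolite universe (over-representation only; no
pathway-topology weighting).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from ._stats import bh_adjust

logger = logging.getLogger(__name__)

LEVELS = ("super", "sub")


def da_score(
    dpmps: pd.DataFrame,
    annotation: pd.DataFrame,
    level: str = "super",
    model_id: str | None = None,
    significant_only: bool = True,
    include_low_confidence: bool = True,
) -> pd.DataFrame:
    """Per-pathway DA scores from one model's contrast-result table.

    ``dpmps`` is indexed by metabolite id; ``annotation`` is indexed by
    metabolite id with super_pathway / sub_pathway / low_confidence columns.
    With ``significant_only`` (default) the numerator counts significant
    DPMPs by direction; otherwise every tested metabolite counts by the
    sign of its fold change.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    unannotated = dpmps.index.difference(annotation.index)
    if len(unannotated):
        raise ValueError(f"tested metabolites missing annotation: {list(unannotated)}")
    ann = annotation.loc[dpmps.index]
    if not include_low_confidence:
        keep = ~ann["low_confidence"].astype(bool)
        ann, dpmps = ann[keep], dpmps[keep.to_numpy()]
    col = "super_pathway" if level == "super" else "sub_pathway"
    if significant_only:
        up = dpmps["significant"] & (dpmps["direction"] == "up")
        down = dpmps["significant"] & (dpmps["direction"] == "down")
    else:
        up = dpmps["log2fc"] > 0
        down = dpmps["log2fc"] < 0
    frame = pd.DataFrame(
        {"pathway": ann[col].to_numpy(), "up": up.to_numpy(), "down": down.to_numpy()}
    )
    grouped = frame.groupby("pathway", sort=True)
    table = pd.DataFrame(
        {
            "n_identified": grouped.size(),
            "n_up": grouped["up"].sum().astype(int),
            "n_down": grouped["down"].sum().astype(int),
        }
    )
    table["da_score"] = (table["n_up"] - table["n_down"]) / table["n_identified"]
    table.insert(0, "level", level)
    table.insert(0, "model_id", model_id)
    table.index.name = "pathway_id"
    empty = set(annotation[col].unique()) - set(table.index)
    if empty:
        logger.warning("pathways with no tested metabolite omitted: %s", sorted(empty))
    return table[["model_id", "level", "da_score", "n_identified", "n_up", "n_down"]]


def flag_consistent_pathways(
    score_tables: Mapping[str, pd.DataFrame], min_models: int = 7
) -> pd.Series:
    """Flag pathways whose DA score is positive in at least ``min_models`` models.

    ``score_tables`` maps model id to its :func:`da_score` table. Returns a
    boolean Series over the union of pathways (the heat-map highlighting
    rule for sub-pathways consistently increased across models).
    """
    positive = pd.DataFrame(
        {model: table["da_score"] > 0 for model, table in score_tables.items()}
    ).fillna(False)
    return positive.sum(axis=1) >= min_models


def joint_pathway_enrichment(
    demgs: Iterable[str],
    dpmps: Iterable[str],
    membership: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of pooled gene + metabolite hits.

    ``membership`` maps pathway id to its member features (genes and
    metabolites mixed); features outside ``universe`` are ignored. For each
    pathway the p-value is the upper tail P(X >= observed hits) of a
    hypergeometric draw of ``len(hits)`` features from the universe. A
    BH-adjusted column is included.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    hits = set(demgs) | set(dpmps)
    stray = hits - universe
    if stray:
        raise ValueError(f"hit features outside the universe: {sorted(stray)[:10]}")
    n_univ, n_hits = len(universe), len(hits)
    rows = []
    for pathway, members in membership.items():
        members = set(members) & universe
        if not members:
            logger.warning("pathway %r has no members in the universe; skipped", pathway)
            continue
        k = len(hits & members)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_hits))
        rows.append((pathway, len(members), k, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["pathway_id", "n_members", "n_hits", "p_value"]
    ).set_index("pathway_id")
    table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy()) if len(table) else []
    return table
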