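"""Cross-model aggregation and candidate selection.

Each "model" is one paired contrast of higher- vs lower-regenerative
samples (axolotl blastema day 11 vs 0, antler stem cells vs primary hMSCs,
young vs aged primate tissues, wild-type vs Werner-syndrome hMSCs, ...).
This module stacks their per-metabolite contrast results into a signed
significance matrix, counts in how many models each metabolite is
up-/down-regulated, selects convergent candidates (up-DPMP in >= k models
within chosen super-pathways), clusters models by the similarity of their
fold-change profiles, runs a PLS-DA ordination sanity check, and provides
the replicate-permutation Pearson-correlation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.cross_decomposition import PLSRegression

from .metabolome import SUPER_PATHWAYS, AbundanceMatrix

DEFAULT_SUPER_FILTER = frozenset({"Nucleotide", "Amino Acid", "Lipid"})


@dataclass
class ConvergenceTable:
    """Metabolite x model signed-significance matrix.

    ``codes`` holds +1 (significant up), -1 (significant down), 0 (tested,
    not significant) and NaN (not tested in that model). ``log2fc`` is the
    matching fold-change matrix, used for tie-breaking and similarity.
    """

    codes: pd.DataFrame
    log2fc: pd.DataFrame

    @property
    def up_count(self) -> pd.Series:
        return (self.codes == 1).sum(axis=1)

    @property
    def down_count(self) -> pd.Series:
        return (self.codes == -1).sum(axis=1)


def build_direction_matrix(tables: Mapping[str, pd.DataFrame]) -> ConvergenceTable:
    """Stack per-model contrast tables into a ConvergenceTable.

    ``tables`` maps model id to a contrast-result table indexed by
    metabolite. Metabolites untested in a model get NaN (never 0).
    """
    models = list(tables)
    if len(models) != len(set(models)):
        raise ValueError("duplicate model ids")
    all_features = pd.Index(sorted(set().union(*(t.index for t in tables.values()))))
    codes = pd.DataFrame(np.nan, index=all_features, columns=models)
    lfc = pd.DataFrame(np.nan, index=all_features, columns=models)
    for model, table in tables.items():
        if table.empty:
            continue
        sig = table["significant"].to_numpy().astype(bool)
        dirs = table["direction"].to_numpy()
        code = np.zeros(len(table))
        code[sig & (dirs == "up")] = 1
        code[sig & (dirs == "down")] = -1
        codes.loc[table.index, model] = code
        lfc.loc[table.index, model] = table["log2fc"].to_numpy()
    codes.index.name = lfc.index.name = "metabolite_id"
    return ConvergenceTable(codes=codes, log2fc=lfc)


def select_candidates(
    table: ConvergenceTable,
    annotation: pd.DataFrame,
    min_models: int = 4,
    direction: str = "up",
    super_filter: frozenset = DEFAULT_SUPER_FILTER,
) -> pd.DataFrame:
    """Convergent candidate metabolites.

    Keeps metabolites significant in the given direction in at least
    ``min_models`` models whose super-pathway lies in ``super_filter``
    (defaults mirror the discovery rule: >=4 models, nucleotide / amino
    acid / lipid classes). Sorted by support count (desc), then maximum
    |log2FC| across supporting models (desc).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    unknown = set(super_filter) - set(SUPER_PATHWAYS)
    if unknown:
        raise ValueError(f"unknown super-pathway names in filter: {sorted(unknown)}")
    missing = table.codes.index.difference(annotation.index)
    if len(missing):
        raise ValueError(f"metabolites missing annotation: {list(missing)[:10]}")
    target = 1 if direction == "up" else -1
    support = (table.codes == target).sum(axis=1)
    supported_lfc = table.log2fc.where(table.codes == target)
    max_abs_lfc = supported_lfc.abs().max(axis=1)
    supers = annotation.loc[table.codes.index, "super_pathway"]
    keep = (support >= min_models) & supers.isin(super_filter)
    out = pd.DataFrame(
        {
            "n_models": support[keep],
            "super_pathway": supers[keep],
            "max_abs_log2fc": max_abs_lfc[keep],
        }
    )
    out = out.sort_values(
        ["n_models", "max_abs_log2fc"], ascending=[False, False], kind="mergesort"
    )
    out.index.name = "metabolite_id"
    return out


@dataclass
class ModelTree:
    """Agglomerative dendrogram over model ids.

    ``linkage_matrix`` is a scipy linkage matrix; leaves are ``labels`` in
    order. Under average linkage on a valid distance the merge heights are
    ultrametric.
    """

    linkage_matrix: np.ndarray
    labels: Sequence[str]
    metric: str
    method: str

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Serialize as a Newick string with branch lengths from merge heights."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def render(node: int) -> str:
            if node < n:
                return str(self.labels[node])
            row = self.linkage_matrix[node - n]
            left, right = int(row[0]), int(row[1])
            h = row[2]
            parts = []
            for child in (left, right):
                parts.append(f"{render(child)}:{h - heights[child]:.6g}")
            heights[node] = h
            return "(" + ",".join(parts) + ")"

        return render(2 * n - 2) + ";"


def _pairwise_distance(
    profiles: pd.DataFrame, metric: str, min_shared: int = 2
) -> np.ndarray:
    """Condensed distance over profile columns, pairwise-complete features."""
    models = list(profiles.columns)
    m = len(models)
    d = np.zeros(m * (m - 1) // 2)
    k = 0
    for i in range(m):
        for j in range(i + 1, m):
            pair = profiles.iloc[:, [i, j]].dropna()
            if len(pair) < min_shared:
                raise ValueError(
                    f"models {models[i]!r} and {models[j]!r} share "
                    f"{len(pair)} feature(s); need at least {min_shared}"
                )
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if metric == "correlation":
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    raise ValueError(
                        f"constant profile for {models[i]!r} or {models[j]!r}; "
                        "correlation distance undefined"
                    )
                d[k] = 1.0 - float(np.corrcoef(x, y)[0, 1])
            else:
                d[k] = float(np.linalg.norm(x - y))
            k += 1
    return d


def model_similarity(
    profiles: pd.DataFrame,
    metric: str = "correlation",
    method: str = "average",
    strict_intersection: bool = False,
) -> ModelTree:
    """Hierarchical clustering of models by their fold-change profiles.

    ``profiles`` is a feature x model matrix (NaN = feature not measured in
    that model). Distances use pairwise-complete features by default
    (models carry different metabolite panels); ``strict_intersection``
    restricts to features present in every model. ``metric`` is
    ``correlation`` (1 - Pearson r) or ``euclidean``.
    """
    if metric not in ("correlation", "euclidean"):
        raise ValueError("metric must be 'correlation' or 'euclidean'")
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 models to cluster")
    if strict_intersection:
        profiles = profiles.dropna()
    d = _pairwise_distance(profiles, metric)
    z = linkage(d, method=method)
    return ModelTree(z, list(profiles.columns), metric=metric, method=method)


def plsda_ordination(
    m: AbundanceMatrix, labels: Sequence[str], n_components: int = 2
) -> pd.DataFrame:
    """Sample scores from a PLS-DA ordination of an auto-scaled matrix.

    Fits a two-block PLS of the feature matrix against a centred one-hot
    class indicator (NIPALS-style, deterministic — no seed needed) and
    returns the X-scores, n_samples x n_components.
    """
    if m.stage != "auto_scaled":
        raise ValueError("plsda_ordination expects an auto_scaled matrix")
    labels = pd.Series(list(labels), index=m.values.index)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    if (counts < 2).any():
        raise ValueError("each class needs at least 2 samples")
    max_rank = min(m.values.shape[0] - 1, m.values.shape[1])
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds rank bound {max_rank}")
    y = pd.get_dummies(labels).to_numpy(dtype=float)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(m.values.to_numpy(), y - y.mean(axis=0))
    return pd.DataFrame(
        pls.x_scores_,
        index=m.values.index,
        columns=[f"PLS{i + 1}" for i in range(n_components)],
    )


@dataclass
class PermutationCorrelation:
    """Output of the replicate-permutation Pearson-correlation test."""

    observed: pd.DataFrame
    mean_permuted: pd.DataFrame
    p_values: pd.DataFrame
    n_perm: int


def permutation_correlation(
    m: AbundanceMatrix,
    design: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationCorrelation:
    """Permutation test for pairwise Pearson correlations among metabolites.

    For each of ``n_perm`` permutations, replicate-to-sample assignments
    are shuffled independently per metabolite within each group, and the
    metabolite x metabolite Pearson correlation matrix is recomputed. The
    reported matrix is the mean coefficient over permutations; the
    empirical significance of each observed r uses the add-one convention
    p = (1 + #{permuted |r| >= observed |r|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    design = design.set_index("sample_id") if design.index.name != "sample_id" else design
    X = m.values.to_numpy(dtype=float)
    group_rows = [
        np.flatnonzero(m.values.index.isin(design.index[design["group"] == g]))
        for g in design["group"].unique()
    ]
    for rows in group_rows:
        if len(rows) < 3:
            raise ValueError("each group needs at least 3 replicates for permutation")
    ids = m.values.columns
    obs = np.corrcoef(X, rowvar=False)
    rng = np.random.default_rng(seed)
    mean = np.zeros_like(obs)
    exceed = np.zeros_like(obs)
    abs_obs = np.abs(obs)
    n_feat = X.shape[1]
    for _ in range(n_perm):
        Xp = X.copy()
        for rows in group_rows:
            sub = X[rows]
            order = rng.permuted(
                np.tile(np.arange(len(rows)), (n_feat, 1)).T, axis=0
            )
            Xp[rows] = np.take_along_axis(sub, order, axis=0)
        r = np.corrcoef(Xp, rowvar=False)
        mean += r
        exceed += np.abs(r) >= abs_obs
    mean /= n_perm
    p = (1.0 + exceed) / (n_perm + 1.0)
    wrap = lambda a: pd.DataFrame(a, index=ids, columns=ids)
    return PermutationCorrelation(wrap(obs), wrap(mean), wrap(p), n_perm)
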