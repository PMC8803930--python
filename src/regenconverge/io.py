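"""Plain-text readers and writers for every table the pipeline exchanges.

All files are UTF-8 TSV with '.' decimals; an empty cell means missing.
Abundance/expression matrices carry the sample id in the first column and
one feature per further column (a ``genes x samples`` orientation can be
declared on read). Ground-truth sidecars are YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .metabolome import AbundanceMatrix, validate_annotation

CONTRAST_HEADER = ["feature_id", "log2fc", "p_value", "adjusted_p", "direction", "significant"]


def write_abundance(m: AbundanceMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def read_abundance(path, stage: str = "raw") -> AbundanceMatrix:
    values = pd.read_csv(path, sep="\t", index_col="sample_id")
    return AbundanceMatrix(values, stage=stage)


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="metabolite_id")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="metabolite_id")
    ann["low_confidence"] = ann["low_confidence"].astype(bool)
    return validate_annotation(ann)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="sample_id")


def read_expression(path, orientation: str = "samples_by_genes") -> pd.DataFrame:
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError("orientation must be 'samples_by_genes' or 'genes_by_samples'")
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "genes_by_samples":
        expr = expr.T
    expr.index.name = "sample_id"
    return expr


def read_gene_set(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_gene_set(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n", encoding="utf-8")


def write_contrast(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="feature_id")


def read_contrast(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="feature_id")
    missing = set(CONTRAST_HEADER[1:]) - set(table.columns)
    if missing:
        raise ValueError(f"contrast table missing columns: {sorted(missing)}")
    table["significant"] = table["significant"].astype(bool)
    return table


def write_screen_plate(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, sep="\t", index=False)


def read_screen_plate(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ground_truth(truth: dict, path) -> None:
    """YAML sidecar for planted ground truth (plain dict/list content)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)


def read_ground_truth(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick + ("" if newick.endswith("\n") else "\n"), encoding="utf-8")
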