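"""Synthetic study generators with planted ground truth.

Every input the pipeline consumes can be generated here, so the whole
analysis is testable without any download:

* ``gen_metabolome_study`` -- per-model samples x metabolites area-count
  matrices (log-normal abundances, MCAR or left-censored missingness, a
  shared two-level pathway annotation) with planted convergent
  up-metabolites whose group-mean ratio is 2**log2fc in their planted
  models only;
* ``gen_expression_study`` -- negative-binomial counts for a three-arm
  design (sham / injured+vehicle / injured+treated), returned as
  log2(count+1) matrices for the injury and treatment contrasts, with
  planted DEGs and planted rescue genes (down upon injury, restored by
  treatment);
* ``gen_screen_plate`` -- 96-well-style confluence tables with planted
  multiplicative proliferation effects.

A single master seed deterministically spawns per-model substreams, so
identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metabolome import SUPER_PATHWAYS, AbundanceMatrix


class ConfigError(ValueError):
    """Invalid synthetic-study configuration; the message names the field."""


@dataclass(frozen=True)
class PlantedMetabolite:
    """A metabolite planted as upregulated in a subset of models."""

    metabolite_id: str
    models: frozenset
    log2fc: float
    super_pathway: str | None = None


@dataclass(frozen=True)
class PlantedGene:
    """A gene planted as differential in one contrast ('injury' or 'treatment')."""

    gene_id: str
    contrast: str
    log2fc: float


@dataclass
class SynthConfig:
    """Study conditions for all generators.

    Defaults emulate the discovery design: 11 paired models (blastema,
    antler stem cells, eight primate tissues, hMSCs), 5 samples per group,
    a 500-metabolite panel classified into 9 super-pathways, ~10% missing
    cells, and log2-scale noise SD 0.25.
    """

    n_models: int = 11
    n_samples_per_group: int = 5
    n_metabolites: int = 500
    n_pathways_super: int = 9
    n_pathways_sub: int = 36
    planted_up_metabolites: tuple = ()
    missing_rate: float = 0.1
    abundance_log_sd: float = 0.25
    seed: int = 0
    left_censored_missingness: bool = False
    detection_rate: float = 1.0
    low_confidence_rate: float = 0.05

    n_genes: int = 2000
    n_samples_per_expr_group: int = 6
    expression_dispersion: float = 0.05
    expression_mean_log2_range: tuple = (5.0, 10.0)
    planted_degs: tuple = ()
    planted_rescue_genes: tuple = ()
    rescue_log2fc: float = 2.0

    screen_effects: dict = field(default_factory=dict)
    screen_concentrations: tuple = (10.0, 50.0, 100.0, 200.0)
    screen_baseline: float = 40.0
    screen_noise_sd: float = 2.0
    screen_wells_per_condition: int = 6

    def __post_init__(self) -> None:
        self.validate()

    # -- id spaces ---------------------------------------------------------
    def model_ids(self) -> list[str]:
        return [f"model_{k:02d}" for k in range(1, self.n_models + 1)]

    def metabolite_ids(self) -> list[str]:
        return [f"M{i:04d}" for i in range(1, self.n_metabolites + 1)]

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def validate(self) -> None:
        for name in (
            "n_models", "n_samples_per_group", "n_metabolites",
            "n_pathways_super", "n_pathways_sub", "n_genes",
            "n_samples_per_expr_group", "screen_wells_per_condition",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.abundance_log_sd <= 0:
            raise ConfigError("abundance_log_sd must be positive")
        if not 0 < self.detection_rate <= 1:
            raise ConfigError("detection_rate must lie in (0, 1]")
        if self.n_pathways_super > len(SUPER_PATHWAYS):
            raise ConfigError(
                f"n_pathways_super exceeds the {len(SUPER_PATHWAYS)} known classes"
            )
        if self.n_pathways_sub < self.n_pathways_super:
            raise ConfigError("n_pathways_sub must be >= n_pathways_super")
        met_ids = set(self.metabolite_ids())
        valid_models = set(range(1, self.n_models + 1))
        supers = set(SUPER_PATHWAYS[: self.n_pathways_super])
        for p in self.planted_up_metabolites:
            if p.metabolite_id not in met_ids:
                raise ConfigError(
                    f"planted_up_metabolites: id {p.metabolite_id!r} not in the panel"
                )
            if not p.models or not set(p.models) <= valid_models:
                raise ConfigError(
                    f"planted_up_metabolites: model set {sorted(p.models)} "
                    f"not within 1..{self.n_models}"
                )
            if p.super_pathway is not None and p.super_pathway not in supers:
                raise ConfigError(
                    f"planted_up_metabolites: unknown super_pathway {p.super_pathway!r}"
                )
        gene_ids = set(self.gene_ids())
        for g in self.planted_degs:
            if g.gene_id not in gene_ids:
                raise ConfigError(f"planted_degs: id {g.gene_id!r} not in the panel")
            if g.contrast not in ("injury", "treatment"):
                raise ConfigError(
                    f"planted_degs: contrast must be 'injury' or 'treatment', got {g.contrast!r}"
                )
        stray = set(self.planted_rescue_genes) - gene_ids
        if stray:
            raise ConfigError(f"planted_rescue_genes: unknown ids {sorted(stray)}")
        for metab, effect in self.screen_effects.items():
            if effect <= 0:
                raise ConfigError(f"screen_effects: effect for {metab!r} must be positive")


# ---------------------------------------------------------------------------
# metabolome study


@dataclass
class MetabolomeTruth:
    """Planted effects: metabolite id -> {model id: log2fc}."""

    effects: dict

    def expected_candidates(
        self, annotation: pd.DataFrame, min_models: int = 4,
        super_filter=frozenset({"Nucleotide", "Amino Acid", "Lipid"}),
    ) -> set:
        """Metabolites planted up in >= min_models models within the filter."""
        return {
            metab
            for metab, per_model in self.effects.items()
            if len(per_model) >= min_models
            and annotation.loc[metab, "super_pathway"] in super_filter
        }


@dataclass
class MetabolomeStudy:
    matrices: dict
    designs: dict
    annotation: pd.DataFrame
    truth: MetabolomeTruth


def _make_annotation(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    supers = list(SUPER_PATHWAYS[: cfg.n_pathways_super])
    sub_names = [f"SUB{j:03d}" for j in range(1, cfg.n_pathways_sub + 1)]
    sub_super = {s: supers[j % len(supers)] for j, s in enumerate(sub_names)}
    subs_by_super = {}
    for s, sup in sub_super.items():
        subs_by_super.setdefault(sup, []).append(s)
    forced = {
        p.metabolite_id: p.super_pathway
        for p in cfg.planted_up_metabolites
        if p.super_pathway is not None
    }
    ids = cfg.metabolite_ids()
    chosen_subs = []
    for metab in ids:
        if metab in forced:
            sub = subs_by_super[forced[metab]][
                rng.integers(len(subs_by_super[forced[metab]]))
            ]
        else:
            sub = sub_names[rng.integers(len(sub_names))]
        chosen_subs.append(sub)
    ann = pd.DataFrame(
        {
            "super_pathway": [sub_super[s] for s in chosen_subs],
            "sub_pathway": chosen_subs,
            "low_confidence": rng.random(len(ids)) < cfg.low_confidence_rate,
        },
        index=pd.Index(ids, name="metabolite_id"),
    )
    return ann


def gen_metabolome_study(cfg: SynthConfig) -> MetabolomeStudy:
    """Generate raw abundance matrices + designs + annotation + ground truth.

    Abundances are log-normal: log2 value = metabolite baseline + planted
    effect (high-regen samples of planted models only) + N(0,
    abundance_log_sd). Missing cells are MCAR at ``missing_rate`` (or
    left-censored when configured: low values are more likely missing);
    every metabolite keeps at least one observed value per model.
    """
    master = np.random.default_rng(cfg.seed)
    ann = _make_annotation(cfg, master)
    met_ids = cfg.metabolite_ids()
    n_met = len(met_ids)
    n = cfg.n_samples_per_group
    effects = {}
    for p in cfg.planted_up_metabolites:
        effects.setdefault(p.metabolite_id, {})
        for k in p.models:
            effects[p.metabolite_id][f"model_{k:02d}"] = p.log2fc

    matrices, designs = {}, {}
    child_seeds = master.integers(0, 2**31 - 1, size=cfg.n_models)
    for k, model in enumerate(cfg.model_ids(), start=1):
        rng = np.random.default_rng(child_seeds[k - 1])
        baseline = rng.uniform(10.0, 20.0, size=n_met)
        effect = np.array([effects.get(m, {}).get(model, 0.0) for m in met_ids])
        sample_ids = [f"{model}_high_{i + 1}" for i in range(n)] + [
            f"{model}_ctrl_{i + 1}" for i in range(n)
        ]
        is_high = np.array([1.0] * n + [0.0] * n)
        log2 = (
            baseline[None, :]
            + np.outer(is_high, effect)
            + rng.normal(0.0, cfg.abundance_log_sd, size=(2 * n, n_met))
        )
        values = np.power(2.0, log2)
        if cfg.missing_rate > 0:
            if cfg.left_censored_missingness:
                # low values are more likely below the detection limit
                ranks = values.argsort(axis=0).argsort(axis=0)
                frac = (ranks + 0.5) / values.shape[0]
                prob = np.clip(2.0 * cfg.missing_rate * (1.0 - frac), 0.0, 0.999)
            else:
                prob = np.full(values.shape, cfg.missing_rate)
            mask = rng.random(values.shape) < prob
            # keep at least one observed value per metabolite
            all_gone = mask.all(axis=0)
            if all_gone.any():
                keep_rows = rng.integers(values.shape[0], size=int(all_gone.sum()))
                mask[keep_rows, np.flatnonzero(all_gone)] = False
            values = np.where(mask, np.nan, values)
        frame = pd.DataFrame(
            values, index=pd.Index(sample_ids, name="sample_id"), columns=met_ids
        )
        if cfg.detection_rate < 1.0:
            planted_here = [m for m, per in effects.items() if model in per]
            others = [m for m in met_ids if m not in planted_here]
            n_keep = max(1, int(round(cfg.detection_rate * n_met))) - len(planted_here)
            kept = list(rng.choice(others, size=max(n_keep, 0), replace=False))
            frame = frame[[m for m in met_ids if m in set(kept) | set(planted_here)]]
        matrices[model] = AbundanceMatrix(frame, stage="raw")
        designs[model] = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "model_id": model,
                "group": ["high_regen"] * n + ["control"] * n,
                "replicate": list(range(1, n + 1)) * 2,
            }
        )
    return MetabolomeStudy(matrices, designs, ann, MetabolomeTruth(effects))


# ---------------------------------------------------------------------------
# expression study


@dataclass
class ExpressionTruth:
    """Planted DEGs per contrast and the planted rescue-up gene set."""

    degs: dict
    rescue_up: frozenset


@dataclass
class ExpressionStudy:
    #: contrast id ('injury' or 'treatment') -> (log2 expression matrix, design)
    contrasts: dict
    gene_sets: dict
    truth: ExpressionTruth


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion  # var = mu + dispersion * mu^2
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_expression_study(cfg: SynthConfig) -> ExpressionStudy:
    """Three-arm negative-binomial expression study with planted rescue genes.

    Groups sham / injured+vehicle / injured+treated, each
    ``n_samples_per_expr_group`` samples. Planted rescue genes drop by
    ``rescue_log2fc`` upon injury and are fully restored by treatment, so
    they are down in injured-vs-sham and up in treated-vs-vehicle;
    ``planted_degs`` shift one contrast only; all other genes are null.
    Returns log2(count+1) matrices for the two contrasts.
    """
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(0, 2**31 - 1))
    genes = cfg.gene_ids()
    n_genes = len(genes)
    n = cfg.n_samples_per_expr_group
    base_log2 = rng.uniform(*cfg.expression_mean_log2_range, size=n_genes)
    group_log2 = {g: base_log2.copy() for g in ("sham", "vehicle", "treated")}
    rescue = set(cfg.planted_rescue_genes)
    idx = {g: i for i, g in enumerate(genes)}
    for g in rescue:
        group_log2["vehicle"][idx[g]] -= cfg.rescue_log2fc  # down upon injury
        # treated arm restored to the sham level
    degs = {"injury": {}, "treatment": {}}
    for p in cfg.planted_degs:
        degs[p.contrast][p.gene_id] = p.log2fc
        if p.contrast == "injury":
            # injury effect persists in both injured arms unless rescued
            group_log2["vehicle"][idx[p.gene_id]] += p.log2fc
            group_log2["treated"][idx[p.gene_id]] += p.log2fc
        else:
            group_log2["treated"][idx[p.gene_id]] += p.log2fc
    for g in rescue:
        degs["injury"][g] = -cfg.rescue_log2fc
        degs["treatment"][g] = cfg.rescue_log2fc

    counts = {}
    for arm in ("sham", "vehicle", "treated"):
        mu = np.power(2.0, group_log2[arm])
        counts[arm] = _nb_counts(
            rng, np.tile(mu, (n, 1)), cfg.expression_dispersion
        ).astype(float)

    def matrix(arms: list) -> tuple:
        sample_ids, rows, groups = [], [], []
        for arm, label in arms:
            sample_ids += [f"{arm}_{i + 1}" for i in range(n)]
            rows.append(np.log2(counts[arm] + 1.0))
            groups += [label] * n
        expr = pd.DataFrame(
            np.vstack(rows), index=pd.Index(sample_ids, name="sample_id"), columns=genes
        )
        design = pd.DataFrame(
            {"sample_id": sample_ids, "group": groups,
             "replicate": list(range(1, n + 1)) * len(arms)}
        )
        return expr, design

    contrasts = {
        "injury": matrix([("sham", "sham"), ("vehicle", "injured")]),
        "treatment": matrix([("vehicle", "vehicle"), ("treated", "treated")]),
    }
    # small curated-style gene lists; planted rescue genes seeded into the
    # metabolic set so set-level scores can react to the planted biology
    pool = [g for g in genes if g not in rescue]
    set_size = max(10, n_genes // 10)
    gene_sets = {}
    for name in ("regeneration", "mitochondrial", "metabolic"):
        members = set(rng.choice(pool, size=min(set_size, len(pool)), replace=False))
        if name == "metabolic":
            members |= rescue
        gene_sets[name] = members
    return ExpressionStudy(
        contrasts, gene_sets, ExpressionTruth(degs, frozenset(rescue))
    )


# ---------------------------------------------------------------------------
# screen plates


def gen_screen_plate(cfg: SynthConfig) -> pd.DataFrame:
    """Confluence table for a metabolite proliferation screen.

    One shared set of vehicle wells per plate plus, for every metabolite in
    ``screen_effects`` and every concentration, ``screen_wells_per_condition``
    treated wells. Treated means follow baseline * effect * dose profile
    (saturating in concentration, reaching the full planted effect at the
    top dose); Gaussian well noise on the confluence scale.
    """
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(0, 2**31 - 1) + 1)
    rows = []
    w = cfg.screen_wells_per_condition
    well_counter = 0

    def next_well() -> str:
        nonlocal well_counter
        plate, pos = divmod(well_counter, 96)
        r, c = divmod(pos, 12)
        well_counter += 1
        return f"P{plate + 1:02d}_{chr(ord('A') + r)}{c + 1:02d}"

    for i in range(w):
        conf = rng.normal(cfg.screen_baseline, cfg.screen_noise_sd)
        rows.append(("vehicle", 0.0, "uM", next_well(), "vehicle", max(conf, 0.0), 6))
    concs = cfg.screen_concentrations
    cmax = max(concs)
    for metab, effect in cfg.screen_effects.items():
        for conc in concs:
            profile = (conc / (conc + 50.0)) / (cmax / (cmax + 50.0))
            mean = cfg.screen_baseline * (1.0 + (effect - 1.0) * profile)
            for i in range(w):
                conf = rng.normal(mean, cfg.screen_noise_sd)
                rows.append((metab, conc, "uM", next_well(), "treated", max(conf, 0.0), 6))
    return pd.DataFrame(
        rows,
        columns=["metabolite", "concentration", "unit", "well", "group", "confluence", "day"],
    )
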