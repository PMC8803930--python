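import numpy as np
import pandas as pd
import pytest

from regenconverge import AbundanceMatrix, PlantedMetabolite, SynthConfig, gen_metabolome_study
from regenconverge.metabolome import impute_minimum, rescale_median, test_dpmp as dpmp_test


def make_contrast(entries):
    """Contrast-result table from (feature, log2fc, p, significant, direction) rows."""
    frame = pd.DataFrame(
        entries, columns=["feature_id", "log2fc", "p_value", "significant", "direction"]
    ).set_index("feature_id")
    frame["adjusted_p"] = frame["p_value"]
    return frame[["log2fc", "p_value", "adjusted_p", "direction", "significant"]]


def make_annotation(supers, subs=None, low_confidence=None):
    """Annotation table from {metabolite: super_pathway} (+ optional subs/flags)."""
    ids = list(supers)
    return pd.DataFrame(
        {
            "super_pathway": [supers[m] for m in ids],
            "sub_pathway": [subs[m] if subs else f"sub of {supers[m]}" for m in ids],
            "low_confidence": [low_confidence[m] if low_confidence else False for m in ids],
        },
        index=pd.Index(ids, name="metabolite_id"),
    )


@pytest.fixture
def two_group_design():
    def build(n_high, n_ctrl, prefix=""):
        ids = [f"{prefix}h{i}" for i in range(n_high)] + [f"{prefix}c{i}" for i in range(n_ctrl)]
        return pd.DataFrame(
            {
                "sample_id": ids,
                "model_id": "m1",
                "group": ["high_regen"] * n_high + ["control"] * n_ctrl,
                "replicate": list(range(n_high)) + list(range(n_ctrl)),
            }
        )

    return build


@pytest.fixture
def small_study():
    """A 3-model study with one metabolite planted up in every model."""
    cfg = SynthConfig(
        n_models=3,
        n_metabolites=40,
        n_samples_per_group=5,
        seed=7,
        missing_rate=0.05,
        planted_up_metabolites=(
            PlantedMetabolite("M0001", frozenset({1, 2, 3}), 2.5, "Nucleotide"),
        ),
    )
    return gen_metabolome_study(cfg)


def run_dpmp(study, model):
    med = rescale_median(impute_minimum(study.matrices[model]))
    return dpmp_test(med, study.designs[model])
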