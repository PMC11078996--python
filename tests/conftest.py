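import numpy as np
import pytest
from dataclasses import replace

from oomorph.attribution import masv_ranking
from oomorph.evaluation import ablation_eval, roc_auc
from oomorph.features import assemble_feature_table
from oomorph.modeling import ModelConfig, patient_split, train_classifier
from oomorph.phantom import (
    PhantomSpec,
    generate_cohort_dataset,
    recovery_outcome_model,
)

#: spec whose every boundary is an exact, centred, unrotated ellipse
ZERO_JITTER = replace(
    PhantomSpec(), noise_sd=0.0, boundary_noise_amplitude=0.0,
    elongation_jitter=0.0, size_jitter=0.0, ratio_jitter=0.0,
    axis_jitter=0.0, center_offset=0.0, rotation=0.0)


@pytest.fixture(scope="session")
def zero_jitter_spec():
    return ZERO_JITTER


def ellipse_spec(a: float, b: float, image_size: int = 256) -> PhantomSpec:
    """Zero-jitter spec whose ooplasm is an exact (a, b) semi-axis ellipse."""
    t, pvs_s, oop_s = 16.0, 0.95, 0.90
    return replace(ZERO_JITTER,
                   image_size=image_size,
                   zp_outer_axes=(a / (pvs_s * oop_s) + t, b / (pvs_s * oop_s) + t),
                   zp_thickness=t, pvs_outer_scale=pvs_s, ooplasm_scale=oop_s)


@pytest.fixture(scope="session")
def recovery_study():
    """The driver-recovery experiment: 500 patients, outcome driven by
    oocyte age, ooplasm roundness and ooplasm-vs-PVS area ratio.

    Shared session-wide because generation and training dominate test time.
    """
    seed = 7
    records = generate_cohort_dataset(500, seed=seed,
                                      outcome_model=recovery_outcome_model())
    table = assemble_feature_table(records)
    split = patient_split(table, seed=seed)
    model = train_classifier(table, split, ModelConfig(seed=seed))
    te = split.mask(table, "test")
    rows = table.data.loc[te]
    prob = model.probability(rows[model.feature_names])
    true_p = {r.oocyte_id: r.true_probability for r in records}
    bayes_auc = roc_auc(rows["oocyte_id"].map(true_p), rows["outcome"])
    test_auc = roc_auc(prob, rows["outcome"])
    ranking = masv_ranking(model, rows[model.feature_names],
                           max_reference=100, seed=seed)
    ablations = ablation_eval(table, split, ["ooplasm", "zp"],
                              ModelConfig(seed=seed), full_model=model)
    return {
        "records": records, "table": table, "split": split, "model": model,
        "test_rows": rows, "prob": np.asarray(prob),
        "test_auc": test_auc, "bayes_auc": bayes_auc,
        "masv": ranking, "ablations": {a["group"]: a for a in ablations},
    }


@pytest.fixture(scope="session")
def small_dataset():
    """Small default-model cohort dataset for structural tests."""
    records = generate_cohort_dataset(40, seed=11)
    return records, assemble_feature_table(records)
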