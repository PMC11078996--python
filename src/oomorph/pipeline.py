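"""End-to-end reproducible pipeline: phantom generation, (optional)
rendering + segmentation + measurement, feature assembly, patient-level
split, training, evaluation, attribution, and a summary report.

A run is fully determined by its :class:`RunConfig`; the config is
serialized into the run directory and the summary JSON is byte-identical
across repeated runs with the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as oio
from .attribution import masv_ranking
from .evaluation import ablation_eval, evaluate_scores, subgroup_eval
from .features import FeatureTable, assemble_feature_table
from .modeling import ModelConfig, patient_split, save_model, train_classifier
from .morphometry import measure_regions
from .phantom import (
    OocyteRecord,
    PhantomSpec,
    default_outcome_model,
    generate_cohort_dataset,
    render_record,
)
from .segmentation import evaluate_segmentation, segment_baseline

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 0
    n_patients: int = 300
    use_predicted_masks: bool = False   # render + segment + re-measure
    n_rendered: int = 50                # images rendered for the IoU report
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    ablation_groups: tuple[str, ...] = ("ooplasm", "pvs", "zp", "clinical", "cohort")
    subgroups: tuple[str, ...] = ("age", "clinic")
    masv_reference: int = 100
    masv_rows: int = 500

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(o)
        return json.dumps(dataclasses.asdict(self), default=enc, indent=1,
                          sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _round(x, nd=6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages; returns the run directory.

    Stage order: phantom dataset -> (optional) render/segment/measure ->
    features -> split -> train -> evaluate (incl. subgroups and ablations)
    -> attribution -> summary.json.  Any stage failure raises
    :class:`PipelineError` naming the stage; artifacts written so far are
    left in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json())
    summary: dict = {"config_hash": config.config_hash, "seed": config.seed}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("phantom")
        records = generate_cohort_dataset(
            config.n_patients, seed=config.seed, spec=config.phantom,
            outcome_model=default_outcome_model())
        oio.write_metadata(out / "metadata.csv", records)
    except Exception as exc:
        raise PipelineError(f"stage 'phantom' failed: {exc}") from exc

    try:
        stage("segmentation")
        n_seg = min(config.n_rendered, len(records))
        pairs = []
        segmented: dict[str, np.ndarray] = {}
        for rec in records[:n_seg]:
            image, labels = render_record(rec, config.phantom)
            pred = segment_baseline(image, config.phantom.intensity_levels)
            pairs.append((labels, pred))
            segmented[rec.oocyte_id] = pred
        seg_report = evaluate_segmentation(pairs)
        summary["segmentation_iou"] = seg_report.summary()
    except Exception as exc:
        raise PipelineError(f"stage 'segmentation' failed: {exc}") from exc

    try:
        stage("measure+features")
        if config.use_predicted_masks:
            measured = []
            for rec in records[:n_seg]:
                geoms = measure_regions(segmented[rec.oocyte_id])
                measured.append(dataclasses.replace(rec, geometry=geoms))
            table = assemble_feature_table(measured)
        else:
            # ground-truth geometry supplied: segmentation stage is skipped
            # as the feature source and features come from the truth
            table = assemble_feature_table(records)
        oio.write_feature_table(table, out / "features.csv")
    except Exception as exc:
        raise PipelineError(f"stage 'features' failed: {exc}") from exc

    try:
        stage("split+train")
        split = patient_split(table, config.fractions, seed=config.seed)
        model = train_classifier(table, split, config.model)
        save_model(model, out / "model.json")
    except Exception as exc:
        raise PipelineError(f"stage 'train' failed: {exc}") from exc

    try:
        stage("evaluate")
        te = split.mask(table, "test")
        rows = table.data.loc[te]
        prob = model.probability(rows[model.feature_names])
        rep = evaluate_scores(prob, rows["outcome"].to_numpy())
        summary["test"] = {"auc": rep.auc, "sensitivity": rep.sensitivity,
                           "specificity": rep.specificity, "n": rep.n}
        subgroup_summaries = {}
        for by in config.subgroups:
            subs = subgroup_eval(prob, rows, by=by)
            subgroup_summaries[by] = [
                {"subgroup": s["subgroup"], "auc": s["report"].auc,
                 "n": s["report"].n,
                 "p_vs_overall": None if s["delong_vs_overall"] is None
                 else s["delong_vs_overall"].p_value}
                for s in subs]
        summary["subgroups"] = subgroup_summaries
        if config.ablation_groups:
            abl = ablation_eval(table, split, config.ablation_groups,
                                config.model, full_model=model)
            summary["ablations"] = [
                {"group": a["group"], "auc": a["auc"],
                 "p_vs_full": a["delong"].p_value} for a in abl]
    except Exception as exc:
        raise PipelineError(f"stage 'evaluate' failed: {exc}") from exc

    try:
        stage("attribution")
        rng = np.random.default_rng(config.seed)
        n_rows = min(config.masv_rows, len(rows))
        idx = rng.choice(len(rows), n_rows, replace=False)
        masv = masv_ranking(model, rows.iloc[idx][model.feature_names],
                            max_reference=config.masv_reference,
                            seed=config.seed)
        summary["masv_top10"] = {k: float(v) for k, v in masv.masv.head(10).items()}
    except Exception as exc:
        raise PipelineError(f"stage 'attribution' failed: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(_round(summary), indent=1, sort_keys=True))
    return out
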