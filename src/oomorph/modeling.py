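"""Outcome classification: patient-level splitting, gradient-boosted trees,
probability/logit prediction and two-model ensembling.

Splitting is done at the patient level so no patient contributes oocytes to
more than one of train/validation/test — oocytes from one patient are
correlated and an oocyte-level split would leak information.  The
classifier is a LightGBM binary model; its raw score is the logit, the
probability is the sigmoid of the logit, and the predicted label is
positive exactly when the logit is positive (probability above 0.5).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.special import expit

from .features import FeatureTable

__all__ = [
    "SplitAssignment",
    "ModelConfig",
    "ClassifierModel",
    "patient_split",
    "train_classifier",
    "predict",
    "ensemble",
    "save_model",
    "load_model",
]

SPLITS = ("train", "validation", "test")


@dataclass(frozen=True)
class SplitAssignment:
    """Per-oocyte split membership with patient-level integrity."""

    by_oocyte: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, split: str) -> list[str]:
        if split not in SPLITS:
            raise KeyError(f"unknown split {split!r}")
        return [o for o, s in self.by_oocyte.items() if s == split]

    def mask(self, table: FeatureTable, split: str) -> np.ndarray:
        return table.data["oocyte_id"].map(self.by_oocyte).eq(split).to_numpy()


def patient_split(table: FeatureTable | pd.DataFrame,
                  fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> SplitAssignment:
    """Assign oocytes to train/validation/test by whole patients.

    Patients are shuffled deterministically by seed and assigned greedily to
    the split with the largest remaining oocyte deficit, which keeps the
    oocyte-level fractions close to the request even with heavy-tailed
    per-patient counts.

    Raises
    ------
    ValueError
        If fractions do not sum to 1, or one patient alone holds more
        oocytes than the largest requested fraction (no valid split exists).
    """
    df = table.data if isinstance(table, FeatureTable) else table
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    counts = df.groupby("patient_id")["oocyte_id"].count()
    total = int(counts.sum())
    if counts.max() > max(fractions) * total:
        raise ValueError(
            f"patient {counts.idxmax()!r} holds {counts.max()}/{total} oocytes, "
            "more than the largest split fraction; no leakage-free split exists")
    rng = np.random.default_rng(seed)
    patients = counts.index.to_numpy()
    patients = patients[rng.permutation(len(patients))]
    target = np.array(fractions) * total
    assigned = np.zeros(3)
    patient_to_split: dict[str, str] = {}
    for p in patients:
        deficit = target - assigned
        k = int(np.argmax(deficit))
        patient_to_split[p] = SPLITS[k]
        assigned[k] += counts[p]
    by_oocyte = {o: patient_to_split[p]
                 for o, p in zip(df["oocyte_id"], df["patient_id"])}
    return SplitAssignment(by_oocyte=by_oocyte, fractions=tuple(fractions),
                           seed=seed)


@dataclass(frozen=True)
class ModelConfig:
    """LightGBM training configuration.

    Hyperparameters are the package's own defaults, chosen to be modest for
    tabular features in the tens of columns: shallow-ish trees, moderate
    shrinkage, early stopping on the validation split.  ``oversample``
    duplicates minority-class training rows per clinic (seeded) to balance
    classes; off by default.
    """

    n_estimators: int = 400
    learning_rate: float = 0.05
    num_leaves: int = 31
    min_child_samples: int = 20
    early_stopping_rounds: int = 50
    oversample: bool = False
    seed: int = 0


@dataclass
class ClassifierModel:
    """Trained gradient-boosted decision-tree classifier.

    Guarantees probability == sigmoid(logit) to machine precision and
    label == (logit > 0).
    """

    booster: lgb.Booster
    feature_names: list[str]
    config: ModelConfig

    @property
    def schema_hash(self) -> str:
        return hashlib.sha256("\n".join(self.feature_names).encode()).hexdigest()[:16]

    def _check_schema(self, rows: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_names if c not in rows.columns]
        extra = [c for c in rows.columns if c not in self.feature_names]
        if missing:
            raise ValueError(f"schema mismatch: missing columns {missing}; "
                             f"extra columns {extra}")
        return rows[self.feature_names]

    def logit(self, rows: pd.DataFrame) -> np.ndarray:
        x = self._check_schema(rows)
        return np.asarray(self.booster.predict(x, raw_score=True), dtype=float)

    def probability(self, rows: pd.DataFrame) -> np.ndarray:
        return expit(self.logit(rows))


def _oversample_minority(df: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Duplicate minority-class rows per clinic up to the majority count."""
    rng = np.random.default_rng(seed)
    parts = []
    for _, grp in df.groupby("clinic"):
        counts = grp["outcome"].value_counts()
        parts.append(grp)
        if len(counts) < 2:
            continue
        minority = counts.idxmin()
        deficit = int(counts.max() - counts.min())
        pool = grp[grp["outcome"] == minority]
        take = rng.integers(0, len(pool), size=deficit)
        parts.append(pool.iloc[take])
    return pd.concat(parts, ignore_index=True)


def train_classifier(table: FeatureTable, split: SplitAssignment,
                     config: ModelConfig | None = None) -> ClassifierModel:
    """Train on the train split with early stopping on the validation split.

    Raises
    ------
    ValueError
        If the training outcome is single-class, or train/validation share
        a patient.
    """
    config = config or ModelConfig()
    df = table.data
    tr = split.mask(table, "train")
    va = split.mask(table, "validation")
    overlap = set(df.loc[tr, "patient_id"]) & set(df.loc[va, "patient_id"])
    if overlap:
        raise ValueError(f"patients in both train and validation: {sorted(overlap)[:5]}")
    cols = table.feature_columns
    train_df = df.loc[tr]
    if config.oversample:
        train_df = _oversample_minority(train_df, config.seed)
    y_tr = train_df["outcome"].to_numpy()
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training outcome is single-class; cannot fit")
    params = dict(
        objective="binary",
        learning_rate=config.learning_rate,
        num_leaves=config.num_leaves,
        min_child_samples=config.min_child_samples,
        seed=config.seed,
        deterministic=True,
        num_threads=1,
        verbosity=-1,
    )
    dtrain = lgb.Dataset(train_df[cols], label=y_tr, params={"verbosity": -1})
    callbacks = []
    valid_sets = []
    if va.any() and config.early_stopping_rounds:
        dval = lgb.Dataset(df.loc[va, cols], label=df.loc[va, "outcome"].to_numpy(),
                           reference=dtrain)
        valid_sets = [dval]
        callbacks = [lgb.early_stopping(config.early_stopping_rounds, verbose=False)]
    booster = lgb.train(params, dtrain, num_boost_round=config.n_estimators,
                        valid_sets=valid_sets, callbacks=callbacks)
    return ClassifierModel(booster=booster, feature_names=list(cols), config=config)


def predict(model: ClassifierModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Probability, logit and thresholded label for each row.

    The label is positive exactly when the logit is positive, i.e. the
    probability exceeds the 0.5 threshold.
    """
    z = model.logit(rows)
    p = expit(z)
    return pd.DataFrame({"probability": p, "logit": z, "label": (z > 0).astype(int)},
                        index=rows.index)


def ensemble(p_a, p_b, weights: tuple[float, float] = (0.5, 0.5)) -> np.ndarray:
    """Weighted mean of two probability vectors.

    The combination rule is the minimal-assumption default for merging a
    feature-based and an image-based probability; weights are configurable.
    """
    a = np.asarray(p_a, dtype=float)
    b = np.asarray(p_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if np.any((a < 0) | (a > 1) | (b < 0) | (b > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    wa, wb = weights
    if wa < 0 or wb < 0 or wa + wb == 0:
        raise ValueError("weights must be non-negative and not both zero")
    return (wa * a + wb * b) / (wa + wb)


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Persist booster, schema and config with a schema hash, as JSON."""
    payload = {
        "format_version": 1,
        "schema_hash": model.schema_hash,
        "feature_names": model.feature_names,
        "config": asdict(model.config),
        "booster": model.booster.model_to_string(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ClassifierModel:
    payload = json.loads(Path(path).read_text())
    booster = lgb.Booster(model_str=payload["booster"])
    model = ClassifierModel(booster=booster,
                            feature_names=payload["feature_names"],
                            config=ModelConfig(**payload["config"]))
    if model.schema_hash != payload["schema_hash"]:
        raise ValueError("stored schema hash does not match feature names")
    return model
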