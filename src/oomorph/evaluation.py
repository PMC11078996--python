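"""Evaluation statistics for outcome classifiers.

Implements ROC AUC as the Mann–Whitney probability (ties counted half), the
paired DeLong test for correlated ROC curves, Welch's unequal-variance
t-test for comparing features between outcome groups, PCA reduction at a
target explained variance, feature-group ablations, and subgroup analysis
by clinical age bins or by clinic.

The DeLong machinery follows the placement-value formulation: each
positive's placement is the fraction of negatives it outranks (ties half),
and the AUC covariance between two score vectors on the same samples is
estimated from the empirical covariance of their placement values.  No
multiple-testing correction is applied across subgroups or ablations; the
raw two-sided p-values are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .features import FeatureTable
from .modeling import (
    ClassifierModel,
    ModelConfig,
    SplitAssignment,
    predict,
    train_classifier,
)

__all__ = [
    "EvalReport",
    "DeLongResult",
    "roc_auc",
    "sens_spec",
    "evaluate_scores",
    "delong_paired",
    "delong_variance",
    "welch_t",
    "pca_reduce",
    "ablation_eval",
    "subgroup_eval",
    "AGE_BINS",
]

#: clinical age bins (inclusive integer-year edges): <30, 30-34, 35-37,
#: 38-39, >=40
AGE_BINS = (("<30", -np.inf, 29), ("30-34", 30, 34), ("35-37", 35, 37),
            ("38-39", 38, 39), (">=40", 40, np.inf))


@dataclass(frozen=True)
class EvalReport:
    """AUC, sensitivity and specificity of thresholded scores on one set."""

    auc: float | None
    sensitivity: float | None
    specificity: float | None
    n: int
    n_positive: int
    n_negative: int
    subgroup: str | None = None


@dataclass(frozen=True)
class DeLongResult:
    """Paired comparison of two AUCs on the same samples."""

    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return y


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via midranks.

    Equals the Mann–Whitney statistic P(score+ > score-) + 0.5 P(tie).
    Raises if only one class is present.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present for AUC")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def sens_spec(labels_pred, labels_true) -> tuple[float | None, float | None]:
    """(sensitivity, specificity) = (TP/(TP+FN), TN/(TN+FP)).

    A side with no samples yields None (undefined), never silently 0.
    """
    yp = _check_binary(labels_pred)
    yt = _check_binary(labels_true)
    if yp.shape != yt.shape:
        raise ValueError("prediction/truth length mismatch")
    pos, neg = yt == 1, yt == 0
    sens = float((yp[pos] == 1).mean()) if pos.any() else None
    spec = float((yp[neg] == 0).mean()) if neg.any() else None
    return sens, spec


def evaluate_scores(probabilities, labels_true, threshold: float = 0.5,
                    subgroup: str | None = None) -> EvalReport:
    """Full report from probabilities: AUC (None if single-class),
    sensitivity/specificity at the strictly-above threshold."""
    p = np.asarray(probabilities, dtype=float)
    y = _check_binary(labels_true)
    n_pos = int(y.sum())
    auc = roc_auc(p, y) if 0 < n_pos < len(y) else None
    sens, spec = sens_spec((p > threshold).astype(int), y)
    return EvalReport(auc=auc, sensitivity=sens, specificity=spec,
                      n=len(y), n_positive=n_pos, n_negative=len(y) - n_pos,
                      subgroup=subgroup)


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and placement values (V10 per positive, V01 per negative)."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return float(v10.mean()), v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC) for a single score vector."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both outcome classes must be present")
    auc, v10, v01 = _placements(s, y)
    if len(v10) < 2 or len(v01) < 2:  # variance undefined with one placement
        return auc, float("nan")
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    return auc, float(var)


def delong_paired(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong test for the AUC difference of two models scored on
    the same samples.

    Identical score vectors short-circuit to z = 0, p = 1.  A zero
    estimated variance with unequal AUCs is a numerical degeneracy and
    raises.
    """
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both outcome classes must be present")
    auc_a, v10a, v01a = _placements(a, y)
    auc_b, v10b, v01b = _placements(b, y)
    if np.array_equal(a, b):
        return DeLongResult(auc_a, auc_b, 0.0, 0.0, 1.0)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) > 1e-12:
            raise FloatingPointError(
                "zero estimated DeLong variance with unequal AUCs")
        return DeLongResult(auc_a, auc_b, 0.0, 0.0, 1.0)
    z = diff / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a, auc_b, float(var), float(z), float(p))


def welch_t(values_pos, values_neg) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch–Satterthwaite df, p).

    Convention: t is computed as mean(pos) - mean(neg) over the pooled
    standard error, so a negative t means the positive group is lower.
    """
    x = np.asarray(values_pos, dtype=float)
    z = np.asarray(values_neg, dtype=float)
    if len(x) < 2 or len(z) < 2:
        raise ValueError("each group needs at least two values")
    vx, vz = x.var(ddof=1), z.var(ddof=1)
    if vx == 0 and vz == 0:
        if x.mean() == z.mean():
            return 0.0, float(len(x) + len(z) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    se2 = vx / len(x) + vz / len(z)
    t = (x.mean() - z.mean()) / math.sqrt(se2)
    df = se2**2 / (vx**2 / (len(x)**2 * (len(x) - 1))
                   + vz**2 / (len(z)**2 * (len(z) - 1)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def pca_reduce(table: FeatureTable | pd.DataFrame,
               explained_variance: float = 0.95
               ) -> tuple[pd.DataFrame, int]:
    """Standardize features and keep the fewest principal components whose
    cumulative explained variance reaches the threshold.

    Constant columns are dropped with a warning before standardization.
    Returns (component scores, n_components).
    """
    x = table.matrix() if isinstance(table, FeatureTable) else table
    if x.shape[1] < 2:
        raise ValueError("need at least two feature columns")
    keep = x.columns[x.std(ddof=0) > 0]
    if len(keep) < x.shape[1]:
        import warnings
        warnings.warn(f"dropping constant columns: "
                      f"{sorted(set(x.columns) - set(keep))}", stacklevel=2)
    z = StandardScaler().fit_transform(x[keep])
    pca = PCA(random_state=0)
    scores = pca.fit_transform(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, explained_variance - 1e-12) + 1)
    k = min(k, scores.shape[1])
    cols = [f"PC{i+1}" for i in range(k)]
    return pd.DataFrame(scores[:, :k], columns=cols, index=x.index), k


def ablation_eval(table: FeatureTable, split: SplitAssignment,
                  groups_to_drop, config: ModelConfig | None = None,
                  full_model: ClassifierModel | None = None) -> list[dict]:
    """Retrain without each feature group and compare to the full model.

    Every ablated model is evaluated on the identical test rows and
    compared to the full model's probabilities with the paired DeLong test.
    Returns one record per dropped group:
    {group, auc, sensitivity, specificity, delong: DeLongResult}.
    """
    groups_to_drop = list(groups_to_drop)
    if not groups_to_drop:
        raise ValueError("no groups to drop")
    config = config or ModelConfig()
    if full_model is None:
        full_model = train_classifier(table, split, config)
    te = split.mask(table, "test")
    test_rows = table.data.loc[te]
    y = test_rows["outcome"].to_numpy()
    p_full = full_model.probability(test_rows[full_model.feature_names])
    results = []
    for group in groups_to_drop:
        sub = table.drop_groups([group])
        model_g = train_classifier(sub, split, config)
        p_g = model_g.probability(sub.data.loc[te, model_g.feature_names])
        rep = evaluate_scores(p_g, y)
        results.append({
            "group": group,
            "auc": rep.auc,
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "delong": delong_paired(p_g, p_full, y),
        })
    return results


def _age_bin(age: float) -> str:
    for name, lo, hi in AGE_BINS:
        if lo <= age <= hi:
            return name
    raise ValueError(f"age {age} falls in no bin")


def subgroup_eval(probabilities, table_rows: pd.DataFrame, by: str = "age",
                  exclude_age_over: float | None = None,
                  method: str = "nested") -> list[dict]:
    """Per-subgroup performance with a DeLong comparison to the overall set.

    ``by`` is "age" (clinical bins <30, 30-34, 35-37, 38-39, >=40) or
    "clinic".  ``exclude_age_over`` optionally removes oocytes older than a
    cutoff (e.g. 43) before analysis, as done for external validation
    cohorts where post-43 outcomes are nearly uniformly negative.

    The subgroup is part of the overall set, so subgroup and overall AUCs
    are not independent; with ``method="nested"`` the variance of the
    difference is estimated as var(subgroup) - var(overall) (floored at a
    small positive multiple of var(subgroup)), the natural estimate for a
    nested sample; ``method="independent"`` uses the sum instead.  Either
    way the comparison carries the nesting caveat.

    Single-class subgroups get AUC None, with sensitivity/specificity still
    reported.
    """
    p = np.asarray(probabilities, dtype=float)
    rows = table_rows.reset_index(drop=True)
    if len(p) != len(rows):
        raise ValueError("probabilities/rows length mismatch")
    if exclude_age_over is not None:
        keep = rows["oocyte_age"].to_numpy() <= exclude_age_over
        rows, p = rows.loc[keep].reset_index(drop=True), p[keep]
    y = rows["outcome"].to_numpy()
    auc_all, var_all = delong_variance(p, y)
    if by == "age":
        keys = rows["oocyte_age"].map(_age_bin)
        order = [b[0] for b in AGE_BINS]
    elif by == "clinic":
        keys = rows["clinic"]
        order = sorted(keys.unique())
    else:
        raise ValueError("subgroup key must be 'age' or 'clinic'")
    out = []
    for name in order:
        sel = (keys == name).to_numpy()
        if not sel.any():
            continue
        rep = evaluate_scores(p[sel], y[sel], subgroup=name)
        delong = None
        if rep.auc is not None and rep.n_positive >= 2 and rep.n_negative >= 2:
            auc_s, var_s = delong_variance(p[sel], y[sel])
            if method == "nested":
                var_diff = max(var_s - var_all, 0.05 * var_s)
            elif method == "independent":
                var_diff = var_s + var_all
            else:
                raise ValueError("method must be 'nested' or 'independent'")
            z = (auc_s - auc_all) / math.sqrt(var_diff)
            delong = DeLongResult(auc_s, auc_all, float(var_diff), float(z),
                                  float(2 * stats.norm.sf(abs(z))))
        out.append({"subgroup": name, "report": rep, "delong_vs_overall": delong,
                    "overall_auc": auc_all})
    return out
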