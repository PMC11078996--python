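"""Additive Shapley explanations for gradient-boosted tree classifiers.

Attributions are computed in logit space: the base value is the mean model
logit over a reference set, each feature receives a signed logit
contribution, and base + sum(contributions) equals the model logit f(x)
exactly (local accuracy); the predicted probability is sigmoid(f(x)).

The value function is the interventional marginal expectation: for a
coalition S, v(S) is the model's mean output over hybrid inputs taking
coalition features from the explained sample and the rest from reference
samples.  For decision trees this expectation is computed exactly: walking
a tree with an (x, z) pair, every split either sends both points the same
way (no attribution) or splits them, in which case reaching a given leaf
requires a fixed set U of features taken from x and a disjoint set V taken
from z.  The Shapley value of such a leaf indicator has the closed form

    phi_i = +w (|U|-1)! |V|! / (|U|+|V|)!   for i in U,
    phi_i = -w |U|! (|V|-1)! / (|U|+|V|)!   for i in V,

so exact attributions cost one tree walk per (sample, reference, tree)
triple.  The walk is JIT-compiled; coalition membership is tracked in a
64-bit mask, which caps explainable models at 64 features.

A brute-force oracle (explicit enumeration of all coalitions with the same
value function) is exported for verification on small models.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit

from .modeling import ClassifierModel

__all__ = [
    "Explanation",
    "ImportanceRanking",
    "explain_sample",
    "explain_matrix",
    "masv_ranking",
    "export_waterfall",
    "waterfall_fx",
    "shapley_brute_force",
]

_MAX_FEATURES = 64


@dataclass(frozen=True)
class Explanation:
    """Additive attribution of one prediction, in logit units."""

    base_value: float
    attributions: dict[str, float]
    fx: float
    probability: float

    def check_additivity(self, tol: float = 1e-6) -> None:
        gap = abs(self.base_value + sum(self.attributions.values()) - self.fx)
        if gap > tol:
            raise AssertionError(f"local accuracy violated: gap {gap:.2e}")


@dataclass(frozen=True)
class ImportanceRanking:
    """Mean absolute attribution per feature, sorted descending
    (ties broken by feature name)."""

    masv: pd.Series

    def top(self, k: int) -> list[str]:
        return self.masv.index[:k].tolist()


def _flatten_booster(booster) -> tuple[np.ndarray, ...]:
    """Flatten a LightGBM booster dump into parallel node arrays."""
    dump = booster.dump_model()
    feat, thresh, left, right, leaf, value, roots = [], [], [], [], [], [], []

    def _add(node) -> int:
        idx = len(feat)
        feat.append(-1); thresh.append(0.0); left.append(-1); right.append(-1)
        leaf.append(True); value.append(0.0)
        if "leaf_value" in node and "split_feature" not in node:
            value[idx] = float(node["leaf_value"])
            return idx
        leaf[idx] = False
        feat[idx] = int(node["split_feature"])
        thresh[idx] = float(node["threshold"])
        if node.get("decision_type", "<=") != "<=":
            raise NotImplementedError("only numeric '<=' splits are supported")
        left[idx] = _add(node["left_child"])
        right[idx] = _add(node["right_child"])
        return idx

    for tree in dump["tree_info"]:
        roots.append(_add(tree["tree_structure"]))
    return (np.array(feat, dtype=np.int64), np.array(thresh, dtype=np.float64),
            np.array(left, dtype=np.int64), np.array(right, dtype=np.int64),
            np.array(leaf, dtype=np.bool_), np.array(value, dtype=np.float64),
            np.array(roots, dtype=np.int64))


def _shapley_weights(max_k: int = _MAX_FEATURES) -> tuple[np.ndarray, np.ndarray]:
    """W1[u, v] = (u-1)! v! / (u+v)!  and  W2[u, v] = u! (v-1)! / (u+v)!."""
    w1 = np.zeros((max_k + 1, max_k + 1))
    w2 = np.zeros((max_k + 1, max_k + 1))
    for u in range(max_k + 1):
        for v in range(max_k + 1):
            if u >= 1:
                w1[u, v] = math.exp(math.lgamma(u) + math.lgamma(v + 1)
                                    - math.lgamma(u + v + 1))
            if v >= 1:
                w2[u, v] = math.exp(math.lgamma(u + 1) + math.lgamma(v)
                                    - math.lgamma(u + v + 1))
    return w1, w2


_W1, _W2 = _shapley_weights()


@njit(cache=False)
def _pair_tree_phi(root, feat, thresh, left, right, leaf, value,
                   x, z, w1, w2, phi):  # pragma: no cover - jitted
    """Accumulate exact interventional Shapley terms for one (x, z, tree)."""
    stack_node = np.empty(512, dtype=np.int64)
    stack_u = np.empty(512, dtype=np.uint64)
    stack_v = np.empty(512, dtype=np.uint64)
    stack_cu = np.empty(512, dtype=np.int64)
    stack_cv = np.empty(512, dtype=np.int64)
    top = 0
    stack_node[0] = root
    stack_u[0] = np.uint64(0)
    stack_v[0] = np.uint64(0)
    stack_cu[0] = 0
    stack_cv[0] = 0
    while top >= 0:
        node = stack_node[top]
        u_mask = stack_u[top]
        v_mask = stack_v[top]
        u = stack_cu[top]
        v = stack_cv[top]
        top -= 1
        if leaf[node]:
            if u + v == 0:
                continue
            w = value[node]
            mask = u_mask
            while mask != np.uint64(0):
                pos = 0
                mm = mask
                while (mm & np.uint64(1)) == np.uint64(0):
                    mm >>= np.uint64(1)
                    pos += 1
                phi[pos] += w * w1[u, v]
                mask &= mask - np.uint64(1)
            mask = v_mask
            while mask != np.uint64(0):
                pos = 0
                mm = mask
                while (mm & np.uint64(1)) == np.uint64(0):
                    mm >>= np.uint64(1)
                    pos += 1
                phi[pos] -= w * w2[u, v]
                mask &= mask - np.uint64(1)
            continue
        f = feat[node]
        t = thresh[node]
        cx = left[node] if x[f] <= t else right[node]
        cz = left[node] if z[f] <= t else right[node]
        bit = np.uint64(1) << np.uint64(f)
        if cx == cz:
            top += 1
            stack_node[top] = cx
            stack_u[top] = u_mask
            stack_v[top] = v_mask
            stack_cu[top] = u
            stack_cv[top] = v
        elif (u_mask & bit) != np.uint64(0):
            top += 1
            stack_node[top] = cx
            stack_u[top] = u_mask
            stack_v[top] = v_mask
            stack_cu[top] = u
            stack_cv[top] = v
        elif (v_mask & bit) != np.uint64(0):
            top += 1
            stack_node[top] = cz
            stack_u[top] = u_mask
            stack_v[top] = v_mask
            stack_cu[top] = u
            stack_cv[top] = v
        else:
            top += 1
            stack_node[top] = cx
            stack_u[top] = u_mask | bit
            stack_v[top] = v_mask
            stack_cu[top] = u + 1
            stack_cv[top] = v
            top += 1
            stack_node[top] = cz
            stack_u[top] = u_mask
            stack_v[top] = v_mask | bit
            stack_cu[top] = u
            stack_cv[top] = v + 1


@njit(cache=False)
def _explain_all(feat, thresh, left, right, leaf, value, roots,
                 X, Z, w1, w2):  # pragma: no cover - jitted
    n, f = X.shape
    m = Z.shape[0]
    phi = np.zeros((n, f))
    row_phi = np.zeros(f)
    for i in range(n):
        for j in range(m):
            for r in range(roots.shape[0]):
                _pair_tree_phi(roots[r], feat, thresh, left, right, leaf,
                               value, X[i], Z[j], w1, w2, row_phi)
        for k in range(f):
            phi[i, k] = row_phi[k] / m
            row_phi[k] = 0.0
    return phi


def explain_matrix(model: ClassifierModel, rows: pd.DataFrame,
                   reference: pd.DataFrame) -> np.ndarray:
    """Exact interventional Shapley attributions (logit units) for every
    row, averaged over the reference set.  Shape (n_rows, n_features)."""
    if len(model.feature_names) > _MAX_FEATURES:
        raise ValueError(f"explainer supports at most {_MAX_FEATURES} features")
    if len(reference) == 0:
        raise ValueError("reference set must be non-empty")
    X = rows[model.feature_names].to_numpy(dtype=np.float64)
    Z = reference[model.feature_names].to_numpy(dtype=np.float64)
    arrays = _flatten_booster(model.booster)
    return _explain_all(*arrays, X, Z, _W1, _W2)


def explain_sample(model: ClassifierModel, row: pd.DataFrame | pd.Series,
                   reference: pd.DataFrame) -> Explanation:
    """Explain one prediction.

    The base value is the mean model logit over the reference set; the
    attributions move the prediction from that prior expectation to the
    sample's own logit f(x), whose sigmoid is the predicted probability.
    """
    if isinstance(row, pd.Series):
        row = row.to_frame().T
    if len(row) != 1:
        raise ValueError("explain_sample expects exactly one row")
    phi = explain_matrix(model, row, reference)[0]
    base = float(model.logit(reference).mean())
    fx = float(model.logit(row)[0])
    return Explanation(
        base_value=base,
        attributions=dict(zip(model.feature_names, map(float, phi))),
        fx=fx,
        probability=float(expit(fx)),
    )


def masv_ranking(model: ClassifierModel, rows: pd.DataFrame,
                 reference: pd.DataFrame | None = None,
                 max_reference: int = 1000, seed: int = 0) -> ImportanceRanking:
    """Mean absolute Shapley value per feature over a dataset, descending.

    ``reference`` defaults to the explained rows themselves; references
    larger than ``max_reference`` are subsampled with the given seed.
    """
    if len(rows) == 0:
        raise ValueError("empty dataset")
    ref = rows if reference is None else reference
    if len(ref) > max_reference:
        rng = np.random.default_rng(seed)
        ref = ref.iloc[rng.choice(len(ref), max_reference, replace=False)]
    phi = explain_matrix(model, rows, ref)
    masv = pd.Series(np.abs(phi).mean(axis=0), index=model.feature_names)
    masv = masv.iloc[np.lexsort([masv.index, -masv.to_numpy()])]
    return ImportanceRanking(masv=masv)


def export_waterfall(explanation: Explanation, top_k: int) -> dict:
    """Ordered waterfall record: top-k features by |attribution| plus an
    "other" remainder that preserves base + sum = f(x)."""
    if top_k < 1:
        raise ValueError("top_k must be at least 1")
    items = sorted(explanation.attributions.items(),
                   key=lambda kv: (-abs(kv[1]), kv[0]))
    shown = items[:top_k]
    rest = items[top_k:]
    record = {
        "base_value": explanation.base_value,
        "fx": explanation.fx,
        "probability": explanation.probability,
        "features": [{"feature": k, "attribution": v} for k, v in shown],
    }
    if rest:
        record["features"].append(
            {"feature": "other", "attribution": float(sum(v for _, v in rest))})
    return record


def waterfall_fx(record: dict | str) -> float:
    """Recompute f(x) from an exported waterfall (JSON string or dict)."""
    if isinstance(record, str):
        record = json.loads(record)
    return float(record["base_value"]
                 + sum(f["attribution"] for f in record["features"]))


def shapley_brute_force(raw_predict, x: np.ndarray, reference: np.ndarray
                        ) -> np.ndarray:
    """Exact Shapley values by coalition enumeration (testing oracle).

    ``raw_predict`` maps an (n, f) array to raw model outputs.  The value
    of coalition S is the mean prediction over hybrids taking S's features
    from x and the rest from each reference row.  Cost 2^f; intended for
    small f only.
    """
    x = np.asarray(x, dtype=float).ravel()
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    f = x.size
    if f > 16:
        raise ValueError("brute force is for small feature counts")
    values = {}
    for r in range(f + 1):
        for S in itertools.combinations(range(f), r):
            hybrid = ref.copy()
            hybrid[:, list(S)] = x[list(S)]
            values[S] = float(np.mean(raw_predict(hybrid)))
    phi = np.zeros(f)
    for i in range(f):
        others = [j for j in range(f) if j != i]
        for r in range(f):
            w = math.factorial(r) * math.factorial(f - r - 1) / math.factorial(f)
            for S in itertools.combinations(others, r):
                phi[i] += w * (values[tuple(sorted(S + (i,)))] - values[S])
    return phi
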