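"""Exact interventional Shapley attributions for the tree downstream model.

For a tree ensemble f and a background (reference) sample r, the
interventional set function is ``v(S) = f(x_S, r_{!S})`` — features in the
coalition S take the explained sample's values, the rest take the
reference's.  The Shapley values of this game are computed *exactly* per
(sample, reference) pair and averaged over the background set, in the
model's native output space (log-odds for the binary GBT), so the
efficiency axiom holds there: sum(phi) + base_value == f(x).

The algorithm works leaf by leaf.  For one leaf, collect the distinct
features on its root path and classify each as

* A — the explained sample satisfies every split on that feature in the
  leaf's direction but the reference does not (the feature must be in S);
* B — the reference satisfies them but the sample does not (the feature
  must be out of S);
* free — both satisfy them (irrelevant); if neither does, the leaf is
  unreachable for this pair and contributes nothing.

The leaf's indicator game is then a conjunction "all of A in S, none of
B in S", whose Shapley values have the closed form (a = |A|, b = |B|):

    phi_i = +v * (a-1)! b! / (a+b)!   for i in A
    phi_i = -v * a! (b-1)! / (a+b)!   for i in B

(the probability that, in a random ordering of the a+b constrained
features, i arrives exactly after the rest of A and before all of B).
Summing over leaves and trees and averaging over references yields the
exact interventional Shapley values of the ensemble.

Per-variable summation: the hundreds of embedding features of one signal
are *summed* (not averaged) into a single attribution per signal, which
preserves efficiency and keeps signal attributions on the same scale as
the untouched static-feature attributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd

from .evaluate import DownstreamModel

_MAX_PATH_FEATURES = 64


def _coef_tables(kmax: int = _MAX_PATH_FEATURES):
    fact = [factorial(i) for i in range(kmax + 2)]
    wa = np.zeros((kmax + 1, kmax + 1))
    wb = np.zeros((kmax + 1, kmax + 1))
    for a in range(kmax + 1):
        for b in range(kmax + 1 - a):
            if a >= 1:
                wa[a, b] = fact[a - 1] * fact[b] / fact[a + b]
            if b >= 1:
                wb[a, b] = fact[a] * fact[b - 1] / fact[a + b]
    return wa, wb


_WA, _WB = _coef_tables()


@dataclass
class _Leaf:
    value: float
    features: np.ndarray      # distinct feature ids on the path
    thresholds: list          # per distinct feature: list of (thr, go_left)


def _collect_leaves(node: dict, path: list, leaves: list[_Leaf]) -> None:
    if "leaf_value" in node and "split_feature" not in node:
        per_feat: dict[int, list] = {}
        for feat, thr, left in path:
            per_feat.setdefault(feat, []).append((thr, left))
        leaves.append(
            _Leaf(
                value=float(node["leaf_value"]),
                features=np.array(sorted(per_feat), dtype=int),
                thresholds=[per_feat[f] for f in sorted(per_feat)],
            )
        )
        return
    feat = int(node["split_feature"])
    thr = float(node["threshold"])
    _collect_leaves(node["left_child"], path + [(feat, thr, True)], leaves)
    _collect_leaves(node["right_child"], path + [(feat, thr, False)], leaves)


def _dump_leaves(booster, num_iteration: int | None) -> list[_Leaf]:
    dump = booster.dump_model(num_iteration=num_iteration or -1)
    leaves: list[_Leaf] = []
    for tree in dump["tree_info"]:
        root = tree["tree_structure"]
        if "split_feature" not in root:  # stump tree: constant
            leaves.append(
                _Leaf(
                    value=float(root.get("leaf_value", root.get("internal_value", 0.0))),
                    features=np.array([], dtype=int),
                    thresholds=[],
                )
            )
            continue
        _collect_leaves(root, [], leaves)
    return leaves


def _satisfies(X: np.ndarray, leaf: _Leaf) -> np.ndarray:
    """(n, F_leaf) bool: does each row satisfy *all* splits of each feature."""
    n = X.shape[0]
    out = np.ones((n, leaf.features.size), dtype=bool)
    for k, feat in enumerate(leaf.features):
        col = X[:, feat]
        for thr, go_left in leaf.thresholds[k]:
            out[:, k] &= (col <= thr) if go_left else (col > thr)
    return out


@dataclass
class AttributionResult:
    """Per-feature Shapley attributions with the per-variable aggregation.

    ``phi`` is (n_samples, n_features) in the model's native output space
    (log-odds for the GBT); ``base_value`` is the mean model output over
    the background set.  After :func:`aggregate_by_variable`,
    ``aggregated`` holds one column per signal/static variable and
    ``aggregated_names`` their order; efficiency survives the summation.
    """

    phi: np.ndarray
    base_value: float
    predictions: np.ndarray
    aggregated: np.ndarray | None = None
    aggregated_names: tuple[str, ...] | None = None
    background_size: int = 0


def tree_attributions(
    model: DownstreamModel,
    samples: np.ndarray,
    background: np.ndarray,
) -> AttributionResult:
    """Exact interventional Shapley values for a GBT, averaged over the
    background set; output space is the model's raw log-odds.
    """
    if model.kind != "gbt":
        raise ValueError(
            "interventional tree attributions require the gbt downstream "
            "model; no model-agnostic fallback is provided"
        )
    X = np.asarray(samples, dtype=float)
    R = np.asarray(background, dtype=float)
    if R.shape[0] == 0:
        raise ValueError("background set must be nonempty")
    n, F = X.shape
    m = R.shape[0]
    leaves = _dump_leaves(model.booster, model.best_iteration)
    phi = np.zeros((n, F))
    for leaf in leaves:
        if leaf.features.size == 0:
            continue  # constant contribution, enters base and f(x) equally
        if leaf.features.size > _MAX_PATH_FEATURES:
            raise ValueError("tree path exceeds supported feature count")
        ax = _satisfies(X, leaf)          # (n, Fl)
        ar = _satisfies(R, leaf)          # (m, Fl)
        # pair classification, broadcast (n, m, Fl)
        in_a = ax[:, None, :] & ~ar[None, :, :]
        in_b = ~ax[:, None, :] & ar[None, :, :]
        dead = (~ax[:, None, :] & ~ar[None, :, :]).any(axis=2)
        a = in_a.sum(axis=2)
        b = in_b.sum(axis=2)
        alive = ~dead
        coef_a = np.where(alive, _WA[a, b], 0.0) * leaf.value
        coef_b = np.where(alive, _WB[a, b], 0.0) * leaf.value
        # sum over references; average at the end
        contrib = in_a * coef_a[:, :, None] - in_b * coef_b[:, :, None]
        phi[:, leaf.features] += contrib.sum(axis=1)
    phi /= m
    pred = model.predict_raw(X)
    base = float(model.predict_raw(R).mean())
    return AttributionResult(
        phi=phi, base_value=base, predictions=pred, background_size=m
    )


def aggregate_by_variable(
    result: AttributionResult, provenance: "list[str]"
) -> AttributionResult:
    """Sum feature attributions into one value per variable.

    ``provenance`` maps each feature index to its variable label
    (``"SAO2:dim_17"`` or ``"static:age"``); all features sharing the
    part before the colon's embedded-dimension suffix — i.e. the signal
    name, or the full ``static:<field>`` label — are summed.  Summation
    (not averaging) preserves the efficiency identity.
    """
    if len(provenance) != result.phi.shape[1]:
        raise ValueError("provenance must cover every feature index")

    def var_of(label: str) -> str:
        if label.startswith("static:"):
            return label
        return label.split(":", 1)[0]

    names: list[str] = []
    for lab in provenance:
        v = var_of(lab)
        if v not in names:
            names.append(v)
    agg = np.zeros((result.phi.shape[0], len(names)))
    index = {v: i for i, v in enumerate(names)}
    for j, lab in enumerate(provenance):
        agg[:, index[var_of(lab)]] += result.phi[:, j]
    result.aggregated = agg
    result.aggregated_names = tuple(names)
    return result


def summary_table(
    result: AttributionResult,
    variable_values: np.ndarray | None = None,
    top_k: int = 5,
) -> pd.DataFrame:
    """Ranked per-sample attribution export for summary plots.

    Variables are ranked by mean absolute aggregated attribution; the
    rows are (sample, variable, rank, attribution, color_value), where
    the color value is the supplied per-sample variable value (a static
    field's value, or e.g. the sum of a signal's embedding features).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if result.aggregated is None:
        raise ValueError("aggregate_by_variable must run first")
    agg = result.aggregated
    names = list(result.aggregated_names)
    importance = np.abs(agg).mean(axis=0)
    order = np.argsort(-importance, kind="mergesort")[:top_k]
    rows = []
    for rank, j in enumerate(order, start=1):
        for i in range(agg.shape[0]):
            rows.append(
                {
                    "sample": i,
                    "variable": names[j],
                    "rank": rank,
                    "mean_abs_attribution": importance[j],
                    "attribution": agg[i, j],
                    "color_value": (
                        float(variable_values[i, j])
                        if variable_values is not None
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
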