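"""Decision trees over principal-component scores.

One CART-style tree (Gini impurity, axis-aligned splits, shallow depth) is
fitted for each of the 100 case-vs-control-set training pairings; the final
model is the candidate with the highest average F value (harmonic mean of
sensitivity and positive predictive value) across all 100 pairings, ties
broken by lowest candidate index.  Leaves carry stable ids ("M1", "F3", ...)
so subgroups can be narrated, plus their training case fraction, which serves
as the continuous risk score for ROC analysis (a hard-label tree has no other
native score).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .selection import PCModel, project
from . import evaluate as _evaluate

AS, NON_AS = "AS", "NON_AS"


@dataclass(frozen=True)
class TreeConfig:
    max_depth: int = 3
    min_leaf: int = 10
    criterion: str = "gini"
    leaf_prefix: str = "M"      # "M" male stratum, "F" female

    def validate(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class PCTreeModel:
    """Serializable binary tree over component scores.

    Parallel node arrays (index = node id, root 0): internal nodes hold the
    component index and threshold (score <= threshold goes left); leaves have
    feature -1 and carry a label, a stable leaf id, the training case
    fraction, and the training sample count.
    """

    n_components: int
    feature: np.ndarray          # component index, -1 at leaves
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_label: np.ndarray       # "" at internal nodes
    leaf_id: np.ndarray          # "" at internal nodes
    case_fraction: np.ndarray
    n_train: np.ndarray
    leaf_prefix: str = "M"
    pc_model: PCModel | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def leaves(self) -> np.ndarray:
        return np.flatnonzero(self.feature < 0)

    def apply(self, scores: np.ndarray) -> np.ndarray:
        """Node index of the leaf reached by each score row."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        node = np.zeros(len(scores), dtype=int)
        while True:
            internal = self.feature[node] >= 0
            if not internal.any():
                return node
            idx = np.flatnonzero(internal)
            f = self.feature[node[idx]]
            go_left = scores[idx, f] <= self.threshold[node[idx]]
            node[idx] = np.where(go_left, self.left[node[idx]],
                                 self.right[node[idx]])

    def predict_scores(self, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(labels, leaf ids, leaf case fractions) for score rows."""
        if len(np.atleast_2d(scores)) == 0:
            e = np.array([])
            return e.astype(str), e.astype(str), e
        nodes = self.apply(scores)
        return (self.leaf_label[nodes], self.leaf_id[nodes],
                self.case_fraction[nodes])


def fit_tree(scores: np.ndarray, labels: np.ndarray, cfg: TreeConfig,
             pc_model: PCModel | None = None) -> PCTreeModel:
    """Fit one axis-aligned tree on component scores.

    Single-class input yields a depth-0 tree predicting that class.  Leaf ids
    are assigned in node-id (preorder) sequence: prefix + 1-based counter.
    """
    from sklearn.tree import DecisionTreeClassifier

    cfg.validate()
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - {AS, NON_AS}
    if bad:
        raise ValueError(f"labels outside {{AS, NON_AS}}: {sorted(bad)}")

    clf = DecisionTreeClassifier(criterion=cfg.criterion,
                                 max_depth=cfg.max_depth,
                                 min_samples_leaf=cfg.min_leaf,
                                 random_state=0)
    clf.fit(scores, labels)
    t = clf.tree_
    classes = list(clf.classes_)
    as_idx = classes.index(AS) if AS in classes else None

    n = t.node_count
    feature = t.feature.copy()
    leaf_label = np.full(n, "", dtype=object)
    leaf_id = np.full(n, "", dtype=object)
    case_fraction = np.zeros(n)
    counter = 0
    for node in range(n):
        v = t.value[node, 0]
        frac = float(v[as_idx] / v.sum()) if as_idx is not None else 0.0
        case_fraction[node] = frac
        if feature[node] < 0:
            counter += 1
            leaf_id[node] = f"{cfg.leaf_prefix}{counter}"
            leaf_label[node] = classes[int(np.argmax(v))]
    return PCTreeModel(
        n_components=scores.shape[1],
        feature=feature, threshold=t.threshold.copy(),
        left=t.children_left.copy(), right=t.children_right.copy(),
        leaf_label=leaf_label.astype(str), leaf_id=leaf_id.astype(str),
        case_fraction=case_fraction,
        n_train=t.n_node_samples.copy(),
        leaf_prefix=cfg.leaf_prefix, pc_model=pc_model)


def fit_candidates(case_scores: np.ndarray,
                   control_score_sets: list[np.ndarray],
                   cfg: TreeConfig, pc_model: PCModel | None = None,
                   n_cohorts: int | None = None) -> list[PCTreeModel]:
    """One candidate tree per (cases vs control set k) training pairing."""
    if n_cohorts is not None and len(control_score_sets) < n_cohorts:
        raise ValueError(f"need {n_cohorts} control score sets, "
                         f"got {len(control_score_sets)}")
    out = []
    for ctl in control_score_sets:
        X = np.vstack([case_scores, ctl])
        y = np.array([AS] * len(case_scores) + [NON_AS] * len(ctl))
        out.append(fit_tree(X, y, cfg, pc_model=pc_model))
    return out


def _pairing_f(model: PCTreeModel, case_scores: np.ndarray,
               control_score_sets: list[np.ndarray]) -> np.ndarray:
    """F value of a model on every paired (cases, control set k) evaluation."""
    case_pred = model.predict_scores(case_scores)[0]
    tp = float((case_pred == AS).sum())
    fn = len(case_pred) - tp
    fs = np.empty(len(control_score_sets))
    for k, ctl in enumerate(control_score_sets):
        ctl_pred = model.predict_scores(ctl)[0]
        fp = float((ctl_pred == AS).sum())
        tn = len(ctl_pred) - fp
        fs[k] = _evaluate.f_value(tp, fn, fp, tn)
    return fs


def select_best(candidates: list[PCTreeModel], case_scores: np.ndarray,
                control_score_sets: list[np.ndarray]
                ) -> tuple[PCTreeModel, pd.DataFrame]:
    """Evaluate every candidate against all paired sets; winner = highest
    mean F, ties broken by lowest candidate index.  Returns (winner, report
    with per-pairing F values, mean F and rank per candidate)."""
    if not candidates:
        raise ValueError("no candidates")
    per_pair = np.vstack([_pairing_f(m, case_scores, control_score_sets)
                          for m in candidates])
    mean_f = per_pair.mean(axis=1)
    best = int(np.argmax(mean_f))          # argmax takes the lowest tied index
    order = np.argsort(-mean_f, kind="stable")
    rank = np.empty(len(candidates), dtype=int)
    rank[order] = np.arange(1, len(candidates) + 1)
    report = pd.DataFrame({"candidate": np.arange(len(candidates)),
                           "mean_f": mean_f, "rank": rank,
                           "chosen": np.arange(len(candidates)) == best})
    report = pd.concat([report,
                        pd.DataFrame(per_pair,
                                     columns=[f"f_set_{k + 1}"
                                              for k in range(per_pair.shape[1])])],
                       axis=1)
    return candidates[best], report


def predict(model: PCTreeModel, raw_features: pd.DataFrame) -> pd.DataFrame:
    """Project raw binary features through the model's PCA and traverse the
    tree.  Feature columns are aligned to the training dictionary: unseen
    columns are ignored, missing ones treated as absent (0)."""
    if model.pc_model is None:
        raise ValueError("model has no attached PCModel; use predict_scores "
                         "with precomputed component scores")
    if len(raw_features) == 0:
        return pd.DataFrame(columns=["unit_id", "label", "leaf_id", "risk_score"])
    scores = project(model.pc_model, raw_features,
                     n_components=model.n_components)
    labels, leaf_ids, fracs = model.predict_scores(scores)
    return pd.DataFrame({"unit_id": raw_features.index,
                         "label": labels, "leaf_id": leaf_ids,
                         "risk_score": fracs})


def leaf_report(model: PCTreeModel) -> pd.DataFrame:
    """One row per leaf: id, label, root-to-leaf path conditions, training
    composition.  Component i is labelled A, B, C ... as in the PCA output."""
    paths: dict[int, str] = {}

    def walk(node: int, path: str) -> None:
        if model.feature[node] < 0:
            paths[node] = path or "(root)"
            return
        name = chr(ord("A") + int(model.feature[node])) \
            if model.feature[node] < 26 else f"PC{model.feature[node] + 1}"
        thr = model.threshold[node]
        sep = " and " if path else ""
        walk(model.left[node], f"{path}{sep}{name} <= {thr:.3f}")
        walk(model.right[node], f"{path}{sep}{name} > {thr:.3f}")

    walk(0, "")
    rows = [{"leaf_id": model.leaf_id[n], "label": model.leaf_label[n],
             "path": paths[n], "n_train": int(model.n_train[n]),
             "case_fraction": float(model.case_fraction[n])}
            for n in model.leaves]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization: human-readable structured text
# ---------------------------------------------------------------------------

def write_tree_model(model: PCTreeModel, path: str | Path,
                     pc_model_ref: str = "pca_loadings.csv") -> None:
    lines = ["aspredict-tree v1",
             f"pc_model_ref: {pc_model_ref}",
             f"n_components: {model.n_components}",
             f"leaf_prefix: {model.leaf_prefix}",
             f"n_nodes: {model.n_nodes}"]
    for i in range(model.n_nodes):
        if model.feature[i] >= 0:
            lines.append(f"node {i} split component={int(model.feature[i])} "
                         f"threshold={float(model.threshold[i])!r} "
                         f"left={int(model.left[i])} right={int(model.right[i])}")
        else:
            lines.append(f"node {i} leaf id={model.leaf_id[i]} "
                         f"label={model.leaf_label[i]} "
                         f"case_fraction={float(model.case_fraction[i])!r} "
                         f"n_train={int(model.n_train[i])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tree_model(path: str | Path,
                    pc_model: PCModel | None = None) -> PCTreeModel:
    lines = Path(path).read_text().strip().splitlines()
    if lines[0] != "aspredict-tree v1":
        raise ValueError(f"not an aspredict tree model file: {path}")
    header = dict(line.split(": ", 1) for line in lines[1:5])
    n = int(header["n_nodes"])
    feature = np.full(n, -2, dtype=int)
    threshold = np.full(n, np.nan)
    left = np.full(n, -1, dtype=int)
    right = np.full(n, -1, dtype=int)
    leaf_label = np.full(n, "", dtype=object)
    leaf_id = np.full(n, "", dtype=object)
    case_fraction = np.zeros(n)
    n_train = np.zeros(n, dtype=int)
    for line in lines[5:]:
        parts = line.split()
        i = int(parts[1])
        kv = dict(p.split("=", 1) for p in parts[3:])
        if parts[2] == "split":
            feature[i] = int(kv["component"])
            threshold[i] = float(kv["threshold"])
            left[i] = int(kv["left"])
            right[i] = int(kv["right"])
        else:
            feature[i] = -1
            leaf_id[i] = kv["id"]
            leaf_label[i] = kv["label"]
            case_fraction[i] = float(kv["case_fraction"])
            n_train[i] = int(kv["n_train"])
    return PCTreeModel(n_components=int(header["n_components"]),
                       feature=feature, threshold=threshold, left=left,
                       right=right, leaf_label=leaf_label.astype(str),
                       leaf_id=leaf_id.astype(str),
                       case_fraction=case_fraction, n_train=n_train,
                       leaf_prefix=header["leaf_prefix"], pc_model=pc_model)
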