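"""Two-stage hybrid training.

Stage 1 trains the attention/SPP backbone end-to-end with a single affine
(linear) classification head on the flattened 21*C descriptor — Adam,
cross-entropy, default learning rate 1e-4 and (effective) batch size 16,
gradients accumulated image-by-image because board sizes are heterogeneous.

Stage 2 freezes the feature extractor, exports one descriptor row per sample
(a FeatureTable), and fits classical heads on those rows: a linear-kernel
margin classifier (one-vs-rest SVC), depth-3 gradient-boosted trees with
shrinkage 0.2, or multinomial logistic regression.  The held-out test set is
never touched by cross-validation; only an explicit test evaluation uses it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .dataio import SplitPlan, load_image, proportional_rescale
from .metrics import ClassMetrics, ConfusionMatrix, FoldReport, aggregate_folds, class_metrics, confusion
from .network.autodiff import Tensor
from .network.backbone import (
    BackboneConfig,
    forward_extract,
    forward_features_t,
    init_params,
    _prepare_image,
    spp_pool_t,
)
from .network.pooling import n_blocks

__all__ = [
    "TrainConfig",
    "HeadSpec",
    "FeatureTable",
    "stage1_train",
    "freeze_and_extract",
    "fit_head",
    "predict",
    "run_crossval",
    "evaluate_test",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 16
    optimizer: str = "adam"
    epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


HEAD_KINDS = ("linear_softmax", "linear_margin", "boosted_trees")


@dataclass(frozen=True)
class HeadSpec:
    """Stage-2 classifier: ``linear_margin`` = SVC(kernel="linear") one-vs-rest,
    ``boosted_trees`` = XGBoost(max_depth=3, learning_rate=0.2),
    ``linear_softmax`` = multinomial logistic regression."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in HEAD_KINDS:
            raise ValueError(f"unknown head kind {self.kind!r}; choose from {HEAD_KINDS}")


@dataclass
class FeatureTable:
    """One flattened pyramid descriptor per sample, aligned with labels,
    fold ids (0 = hold-out test) and manifest row indices."""

    rows: np.ndarray  # (n, n_blocks * C)
    labels: list[str]
    fold_ids: list[int]
    indices: list[int]

    def __post_init__(self):
        n = self.rows.shape[0]
        if not (len(self.labels) == len(self.fold_ids) == len(self.indices) == n):
            raise ValueError("labels/fold_ids/indices must align with rows")

    @property
    def width(self) -> int:
        return self.rows.shape[1]

    def select(self, manifest_indices) -> np.ndarray:
        pos = {idx: r for r, idx in enumerate(self.indices)}
        return np.array([pos[i] for i in manifest_indices])

    def save(self, path_prefix) -> None:
        path_prefix = Path(path_prefix)
        np.save(path_prefix.with_suffix(".npy"), self.rows)
        sidecar = {
            "n": int(self.rows.shape[0]),
            "width": int(self.rows.shape[1]),
            "labels": self.labels,
            "fold_ids": self.fold_ids,
            "indices": self.indices,
            "flatten_order": "blocks outer (level-major, row-major), channels inner",
        }
        path_prefix.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path_prefix) -> "FeatureTable":
        path_prefix = Path(path_prefix)
        rows = np.load(path_prefix.with_suffix(".npy"))
        meta = json.loads(path_prefix.with_suffix(".json").read_text())
        return cls(rows, meta["labels"], meta["fold_ids"], meta["indices"])


# --------------------------------------------------------------------------
# stage 1: backbone + linear head
# --------------------------------------------------------------------------

class _Adam:
    def __init__(self, tensors: dict[str, Tensor], lr: float):
        self.tensors = tensors
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in tensors.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in tensors.items()}

    def step(self, scale: float = 1.0) -> None:
        self.t += 1
        for k, tensor in self.tensors.items():
            g = (tensor.grad if tensor.grad is not None else np.zeros_like(tensor.data)) * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            tensor.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for tensor in self.tensors.values():
            tensor.grad = None


def _class_order(manifest) -> list[str]:
    return sorted(set(manifest["label"]))


def _load_prepared(manifest, indices, rescale: float | None):
    out = {}
    for i in indices:
        img = load_image(manifest["path"].iloc[i])
        if rescale is not None:
            img = proportional_rescale(img, rescale)
        out[i] = _prepare_image(img).transpose(2, 0, 1)
    return out


def _descriptor_t(img_chw: np.ndarray, config: BackboneConfig, pt: dict[str, Tensor]) -> Tensor:
    fmap = forward_features_t(Tensor(img_chw), config, pt)
    return spp_pool_t(fmap, config.pyramid_levels)


def stage1_train(
    manifest,
    plan: SplitPlan,
    fold: int | None,
    config: TrainConfig,
    backbone: BackboneConfig,
    rescale: float | None = None,
    init: dict[str, np.ndarray] | None = None,
):
    """Train backbone + linear head on the training partition, excluding the
    held-out ``fold`` (``fold=None`` uses every training fold; the hold-out
    test set is never included).  Returns (params, per-epoch mean loss log).

    ``epochs=0`` returns the initialisation untouched.  With a fixed seed the
    whole procedure — init, shuffling, updates — is deterministic.
    """
    if fold is not None and not 1 <= fold <= plan.k:
        raise ValueError(f"fold must lie in 1..{plan.k}, got {fold}")
    train_idx = plan.train_indices(exclude_fold=fold)
    if not train_idx:
        raise ValueError("empty training partition")
    classes = _class_order(manifest)
    width = n_blocks(backbone.pyramid_levels) * backbone.out_channels

    params = dict(init) if init is not None else init_params(backbone, config.seed)
    if "head.w" not in params:
        params = dict(params)
        params["head.w"] = np.zeros((len(classes), width))
        params["head.b"] = np.zeros(len(classes))
    if config.epochs == 0:
        return params, []

    pt = {k: Tensor(v.copy(), requires_grad=True) for k, v in params.items()}
    opt = _Adam(pt, config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x51A6E1]))
    images = _load_prepared(manifest, train_idx, rescale)
    y = {i: classes.index(manifest["label"].iloc[i]) for i in train_idx}

    loss_log: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            for i in batch:
                flat = _descriptor_t(images[i], backbone, pt).reshape(1, -1)
                logits = flat @ _transpose(pt["head.w"]) + pt["head.b"].reshape(1, -1)
                z = logits.data[0]
                z = z - z.max()
                p = np.exp(z) / np.exp(z).sum()
                losses.append(float(-np.log(max(p[y[i]], 1e-300))))
                grad = p.copy()
                grad[y[i]] -= 1.0
                logits.backward(grad[None, :])
            opt.step(scale=1.0 / len(batch))
        loss_log.append(float(np.mean(losses)))
    return {k: t.data.copy() for k, t in pt.items()}, loss_log


def _transpose(t: Tensor) -> Tensor:
    def back(g):
        if t.requires_grad:
            t._accum(g.T)

    return Tensor(t.data.T, parents=(t,), backward=back)


# --------------------------------------------------------------------------
# stage 2: frozen extraction + classical heads
# --------------------------------------------------------------------------

def freeze_and_extract(
    params: dict[str, np.ndarray],
    backbone: BackboneConfig,
    manifest,
    plan: SplitPlan | None = None,
    rescale: float | None = None,
    indices=None,
) -> FeatureTable:
    """Extract one flattened descriptor row per manifest sample with frozen
    weights (no parameter is read-modified anywhere on this path).

    Fold ids come from ``plan`` (0 marks hold-out test samples); with no plan
    every fold id is 0.
    """
    if indices is None:
        indices = list(range(len(manifest)))
    rows, labels, fold_ids = [], [], []
    for i in indices:
        img = load_image(manifest["path"].iloc[i])
        if rescale is not None:
            img = proportional_rescale(img, rescale)
        try:
            desc = forward_extract(img, backbone, params)
        except ValueError as e:
            raise ValueError(f"sample {i} ({manifest['path'].iloc[i]}): {e}") from e
        rows.append(desc.flat)
        labels.append(manifest["label"].iloc[i])
        fold_ids.append(plan.fold_assignments.get(i, 0) if plan is not None else 0)
    return FeatureTable(np.stack(rows), labels, fold_ids, list(indices))


def fit_head(table: FeatureTable, spec: HeadSpec, train_rows) -> dict:
    """Fit one classical head on the selected rows of a feature table."""
    train_rows = list(train_rows)
    x = table.rows[train_rows]
    y = [table.labels[r] for r in train_rows]
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes to fit a head, got {classes}")
    if spec.kind == "linear_margin":
        model = OneVsRestClassifier(
            SVC(kernel="linear", C=float(spec.params.get("C", 1.0)), random_state=spec.seed)
        )
        model.fit(x, y)
    elif spec.kind == "linear_softmax":
        model = LogisticRegression(max_iter=int(spec.params.get("max_iter", 1000)))
        model.fit(x, y)
    else:  # boosted_trees
        model = XGBClassifier(
            max_depth=int(spec.params.get("max_depth", 3)),
            learning_rate=float(spec.params.get("learning_rate", 0.2)),
            n_estimators=int(spec.params.get("n_estimators", 100)),
            random_state=spec.seed,
            verbosity=0,
        )
        model.fit(x, [classes.index(lab) for lab in y])
    return {"spec": spec, "model": model, "classes": classes, "width": table.width}


def predict(head: dict, table: FeatureTable, rows) -> list[str]:
    """Predict labels for the selected rows; order follows ``rows``."""
    rows = list(rows)
    if not rows:
        return []
    if table.width != head["width"]:
        raise ValueError(
            f"feature width {table.width} does not match training width {head['width']}"
        )
    x = table.rows[rows]
    raw = head["model"].predict(x)
    if head["spec"].kind == "boosted_trees":
        return [head["classes"][int(v)] for v in raw]
    return [str(v) for v in raw]


# --------------------------------------------------------------------------
# cross-validated evaluation
# --------------------------------------------------------------------------

def _assert_no_leak(plan: SplitPlan, indices) -> None:
    leaked = set(indices) & plan.all_test_indices
    if leaked:
        raise RuntimeError(
            f"hold-out test samples {sorted(leaked)} leaked into a training input"
        )


def run_crossval(
    manifest,
    plan: SplitPlan,
    backbone: BackboneConfig,
    train_cfg: TrainConfig,
    heads: list[HeadSpec],
    rescale: float | None = None,
) -> dict[str, FoldReport]:
    """The full protocol: per fold, stage-1 train on k-1 folds, freeze and
    extract descriptors, fit every head on the same k-1 folds, evaluate on the
    held-out fold.  Returns one fold-aggregated report per head kind.

    The 8:2 hold-out test set is excluded throughout; use
    :func:`evaluate_test` for the final test-set report.
    """
    if not heads:
        raise ValueError("head list is empty")
    if plan.k < 2:
        raise ValueError("cross-validation needs k >= 2")
    classes = _class_order(manifest)
    per_head_metrics: dict[str, list[ClassMetrics]] = {h.kind: [] for h in heads}
    per_head_matrices: dict[str, list[ConfusionMatrix]] = {h.kind: [] for h in heads}
    for fold in range(1, plan.k + 1):
        fit_idx = plan.train_indices(exclude_fold=fold)
        eval_idx = plan.fold_indices(fold)
        _assert_no_leak(plan, fit_idx)
        params, _ = stage1_train(manifest, plan, fold, train_cfg, backbone, rescale)
        table = freeze_and_extract(
            params, backbone, manifest, plan, rescale, indices=plan.train_indices()
        )
        fit_rows = table.select(fit_idx)
        eval_rows = table.select(eval_idx)
        y_true = [table.labels[r] for r in eval_rows]
        for head_spec in heads:
            head = fit_head(table, head_spec, fit_rows)
            y_pred = predict(head, table, eval_rows)
            cm = confusion(y_true, y_pred, classes)
            per_head_matrices[head_spec.kind].append(cm)
            per_head_metrics[head_spec.kind].append(class_metrics(cm))
    return {
        kind: aggregate_folds(ms, per_head_matrices[kind])
        for kind, ms in per_head_metrics.items()
    }


def evaluate_test(
    manifest,
    plan: SplitPlan,
    backbone: BackboneConfig,
    train_cfg: TrainConfig,
    head_spec: HeadSpec,
    rescale: float | None = None,
    params: dict[str, np.ndarray] | None = None,
):
    """Final, explicitly separate hold-out evaluation: stage-1 train on the
    whole training partition (unless trained ``params`` are supplied), fit the
    head on all training rows, predict the untouched test set."""
    classes = _class_order(manifest)
    if params is None:
        params, _ = stage1_train(manifest, plan, None, train_cfg, backbone, rescale)
    train_idx = plan.train_indices()
    test_idx = sorted(plan.all_test_indices)
    _assert_no_leak(plan, train_idx)
    table = freeze_and_extract(
        params, backbone, manifest, plan, rescale, indices=train_idx + test_idx
    )
    head = fit_head(table, head_spec, table.select(train_idx))
    eval_rows = table.select(test_idx)
    y_true = [table.labels[r] for r in eval_rows]
    y_pred = predict(head, table, eval_rows)
    cm = confusion(y_true, y_pred, classes)
    return class_metrics(cm), cm
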