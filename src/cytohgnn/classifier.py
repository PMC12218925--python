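"""Transductive hypergraph neural-network classifier and the graph-
convolution baseline.

Architecture (three learnable layers):

    HGConv(in -> hidden) -> BN -> ReLU -> dropout
    HGConv(hidden -> hidden) -> BN -> ReLU -> dropout
    FC(hidden -> C) -> softmax

where each hypergraph convolution is ``X' = P X Theta`` with the
normalised propagation operator ``P = Dv^-1/2 H W De^-1 H^T Dv^-1/2``.
Training is transductive and full-batch: every sample is a vertex of one
fixed hypergraph, the cross-entropy loss is evaluated on the training
vertices only, and parameters are updated with Adam (learning rate 0.01,
weight decay 5e-4 as L2 on the weight matrices, 200 epochs by default).
The parameters achieving the best validation accuracy are retained (ties
keep the earliest epoch).

Setting ``propagation=False`` replaces ``P`` with the identity in both
convolutions — the ablation arm, which is blind to the hypergraph
structure.  The ``GCNClassifier`` swaps ``P`` for the symmetrically
normalised kNN-graph adjacency ``D^-1/2 (A + I) D^-1/2`` and keeps
everything else identical, giving a like-for-like pairwise-graph baseline.

Gradients are derived analytically (see ``loss_and_grads``); a finite-
difference check against them is part of the test suite.  All classifier
arithmetic is double precision.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import DegenerateInputError, InvalidConfigError, ShapeError
from .feature_table import FeatureTable
from .hypergraph import Hypergraph, PropagationOperator, build_hypergraph, propagation_operator
from .nn_ops import bn_backward, bn_forward, relu, softmax

__all__ = [
    "HGNNConfig",
    "init_parameters",
    "model_forward",
    "loss_and_grads",
    "TransductiveClassifier",
    "HypergraphClassifier",
    "GCNClassifier",
    "ClassifierResults",
    "gcn_operator",
    "ablate_propagation",
]


@dataclass(frozen=True)
class HGNNConfig:
    """Hyperparameters of the hypergraph classifier.

    Defaults follow the reference training recipe: hidden width 32,
    dropout 0.5, Adam with learning rate 0.01 and weight decay 5e-4,
    200 epochs.
    """

    in_dim: int = 2304
    hidden_dim: int = 32
    n_classes: int = 5
    dropout: float = 0.5
    learning_rate: float = 0.01
    weight_decay: float = 5e-4
    epochs: int = 200
    propagation: bool = True
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise InvalidConfigError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.learning_rate <= 0:
            raise InvalidConfigError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.epochs < 1:
            raise InvalidConfigError(f"epochs must be >= 1, got {self.epochs}")
        if min(self.in_dim, self.hidden_dim, self.n_classes) < 1:
            raise InvalidConfigError("in_dim, hidden_dim and n_classes must be positive")
        if self.weight_decay < 0:
            raise InvalidConfigError("weight_decay must be non-negative")


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_parameters(config: HGNNConfig, rng: Optional[np.random.Generator] = None) -> Dict:
    """Seeded random initialisation of all learnable parameters.

    Weight matrices use Glorot-uniform; batch-norm scales start at 1,
    shifts at 0, running statistics at (0, 1).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h = config.hidden_dim
    params = {
        "Theta1": _glorot(rng, (config.in_dim, h)),
        "Theta2": _glorot(rng, (h, h)),
        "W_fc": _glorot(rng, (h, config.n_classes)),
        "b_fc": np.zeros(config.n_classes),
    }
    for name in ("bn1", "bn2"):
        params[f"{name}_gamma"] = np.ones(h)
        params[f"{name}_beta"] = np.zeros(h)
        params[f"{name}_mean"] = np.zeros(h)
        params[f"{name}_var"] = np.ones(h)
    return params


def _as_operator(P, n: int):
    if P is None:
        return sp.identity(n, format="csr")
    if isinstance(P, PropagationOperator):
        return P.matrix
    return P


def model_forward(
    params: Dict,
    P,
    X: np.ndarray,
    config: HGNNConfig,
    *,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
    return_cache: bool = False,
):
    """Forward pass producing an (N, C) row-stochastic probability matrix.

    ``P`` may be a PropagationOperator, a sparse/dense matrix, or None for
    the identity (the propagation-off ablation).  Dropout is active only
    when ``training`` is true and needs ``rng``; batch norm uses batch
    statistics during training and running statistics otherwise.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != config.in_dim:
        raise ShapeError(f"X must be (N, {config.in_dim}), got {X.shape}")
    A = _as_operator(P, X.shape[0])
    if A.shape[0] != X.shape[0]:
        raise ShapeError(
            f"operator is {A.shape} but X has {X.shape[0]} vertices"
        )
    keep = 1.0 - config.dropout
    cache = {"masks": [None, None]}

    def _dropout(h, slot):
        if not training or config.dropout == 0:
            return h
        mask = (rng.random(h.shape) < keep).astype(np.float64) / keep
        cache["masks"][slot] = mask
        return h * mask

    PX = A @ X
    Z1 = PX @ params["Theta1"]
    B1, bn1_cache = bn_forward(
        Z1, params["bn1_gamma"], params["bn1_beta"],
        params["bn1_mean"], params["bn1_var"],
        training=training, eps=config.bn_eps, momentum=config.bn_momentum,
    )
    R1 = relu(B1)
    D1 = _dropout(R1, 0)
    PD1 = A @ D1
    Z2 = PD1 @ params["Theta2"]
    B2, bn2_cache = bn_forward(
        Z2, params["bn2_gamma"], params["bn2_beta"],
        params["bn2_mean"], params["bn2_var"],
        training=training, eps=config.bn_eps, momentum=config.bn_momentum,
    )
    R2 = relu(B2)
    D2 = _dropout(R2, 1)
    logits = D2 @ params["W_fc"] + params["b_fc"]
    probs = softmax(logits)
    if not return_cache:
        return probs
    cache.update(
        A=A, PX=PX, B1=B1, bn1_cache=bn1_cache, D1=D1, PD1=PD1,
        B2=B2, bn2_cache=bn2_cache, D2=D2, probs=probs,
    )
    return probs, cache


def loss_and_grads(
    params: Dict,
    P,
    X: np.ndarray,
    labels: np.ndarray,
    train_mask: np.ndarray,
    config: HGNNConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, Dict]:
    """Training-mode cross-entropy on the masked vertices and its analytic
    gradients with respect to every learnable parameter.

    The returned loss excludes the L2 penalty; weight decay is applied by
    the optimiser as an additive gradient term on the weight matrices.
    """
    labels = np.asarray(labels)
    mask = np.asarray(train_mask, dtype=bool)
    n_train = int(mask.sum())
    if n_train == 0:
        raise DegenerateInputError("empty training mask")
    probs, cache = model_forward(
        params, P, X, config, training=True, rng=rng, return_cache=True
    )
    idx = np.flatnonzero(mask)
    loss = -float(np.mean(np.log(probs[idx, labels[idx]] + 1e-300)))

    # d loss / d logits, zero outside the training mask
    G = np.zeros_like(probs)
    G[idx] = probs[idx]
    G[idx, labels[idx]] -= 1.0
    G /= n_train

    grads: Dict[str, np.ndarray] = {}
    grads["W_fc"] = cache["D2"].T @ G
    grads["b_fc"] = G.sum(axis=0)
    dD2 = G @ params["W_fc"].T
    if cache["masks"][1] is not None:
        dD2 = dD2 * cache["masks"][1]
    dB2 = dD2 * (cache["B2"] > 0)
    dZ2, grads["bn2_gamma"], grads["bn2_beta"] = bn_backward(dB2, cache["bn2_cache"])
    grads["Theta2"] = cache["PD1"].T @ dZ2
    A = cache["A"]
    dD1 = (A.T @ dZ2) @ params["Theta2"].T
    if cache["masks"][0] is not None:
        dD1 = dD1 * cache["masks"][0]
    dB1 = dD1 * (cache["B1"] > 0)
    dZ1, grads["bn1_gamma"], grads["bn1_beta"] = bn_backward(dB1, cache["bn1_cache"])
    grads["Theta1"] = cache["PX"].T @ dZ1
    return loss, grads


# ------------------------------------------------------------------ #


@dataclass
class ClassifierResults:
    """Fit results: best parameters, training history and predictions.

    ``history`` is a DataFrame with columns epoch, train_loss,
    val_accuracy.  Prediction uses inference-mode batch norm and the
    parameters from the best validation epoch.
    """

    model: "TransductiveClassifier"
    params: Dict
    history: pd.DataFrame
    best_epoch: int
    best_val_accuracy: float

    def predict_proba(self, idx: Optional[np.ndarray] = None) -> np.ndarray:
        probs = model_forward(
            self.params, self.model.operator, self.model.features,
            self.model.config, training=False,
        )
        return probs if idx is None else probs[np.asarray(idx)]

    def predict(self, idx: Optional[np.ndarray] = None) -> np.ndarray:
        """Argmax class per vertex; ties resolve to the lowest class index."""
        return np.argmax(self.predict_proba(idx), axis=1)

    def evaluate(self, idx: np.ndarray):
        """EvaluationReport on the given vertex subset."""
        from .evaluation import compute_metrics

        idx = np.asarray(idx)
        probs = self.predict_proba(idx)
        return compute_metrics(
            self.model.labels[idx],
            np.argmax(probs, axis=1),
            probabilities=probs,
            n_classes=self.model.config.n_classes,
            class_names=self.model.class_names,
        )

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            f"{type(self.model).__name__} fit",
            "=" * 46,
            f"vertices:           {self.model.features.shape[0]}",
            f"input dim:          {cfg.in_dim}",
            f"hidden dim:         {cfg.hidden_dim}",
            f"classes:            {cfg.n_classes}",
            f"propagation:        {cfg.propagation}",
            f"epochs:             {cfg.epochs}",
            f"learning rate:      {cfg.learning_rate}",
            f"weight decay:       {cfg.weight_decay}",
            f"dropout:            {cfg.dropout}",
            f"best epoch:         {self.best_epoch}",
            f"best val accuracy:  {self.best_val_accuracy:.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)


class TransductiveClassifier:
    """Base model: features + labels + a fixed propagation operator.

    Subclasses choose the operator (hypergraph diffusion, normalised graph
    adjacency, or identity).  ``fit`` performs full-batch transductive
    training and returns a :class:`ClassifierResults`.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        operator,
        config: Optional[HGNNConfig] = None,
        class_names: Optional[Sequence[str]] = None,
    ):
        self.features = np.asarray(features, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=np.int64)
        if self.features.ndim != 2:
            raise ShapeError("features must be an (N, D) matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise ShapeError("labels must align with feature rows")
        n_classes = int(self.labels.max()) + 1
        if config is None:
            config = HGNNConfig(in_dim=self.features.shape[1], n_classes=n_classes)
        else:
            if config.in_dim != self.features.shape[1]:
                config = replace(config, in_dim=self.features.shape[1])
            if config.n_classes < n_classes:
                config = replace(config, n_classes=n_classes)
        self.config = config
        self.operator = operator
        if class_names is None:
            class_names = [f"class_{c}" for c in range(self.config.n_classes)]
        self.class_names = list(class_names)

    def fit(
        self,
        train_idx: np.ndarray,
        val_idx: np.ndarray,
        seed: Optional[int] = None,
    ) -> ClassifierResults:
        """Train with Adam; keep the best-validation-accuracy parameters.

        ``train_idx`` and ``val_idx`` must be disjoint vertex index sets
        and every class must appear in the training set.
        """
        cfg = self.config
        train_idx = np.asarray(train_idx)
        val_idx = np.asarray(val_idx)
        if train_idx.size == 0 or val_idx.size == 0:
            raise DegenerateInputError("training and validation masks must be non-empty")
        if np.intersect1d(train_idx, val_idx).size:
            raise DegenerateInputError("training and validation masks overlap")
        present = np.unique(self.labels[train_idx])
        if present.size < cfg.n_classes:
            missing = sorted(set(range(cfg.n_classes)) - set(present.tolist()))
            raise DegenerateInputError(f"classes {missing} absent from the training mask")

        n = self.features.shape[0]
        train_mask = np.zeros(n, dtype=bool)
        train_mask[train_idx] = True
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        params = init_parameters(cfg, rng)

        decayed = ("Theta1", "Theta2", "W_fc")
        learnable = [
            "Theta1", "Theta2", "W_fc", "b_fc",
            "bn1_gamma", "bn1_beta", "bn2_gamma", "bn2_beta",
        ]
        m = {k: np.zeros_like(params[k]) for k in learnable}
        v = {k: np.zeros_like(params[k]) for k in learnable}
        b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps

        best = {"epoch": 0, "acc": -1.0, "params": None}
        records = []
        for epoch in range(1, cfg.epochs + 1):
            loss, grads = loss_and_grads(
                params, self.operator, self.features, self.labels,
                train_mask, cfg, rng=rng,
            )
            if not np.isfinite(loss):
                raise DegenerateInputError(f"training diverged at epoch {epoch} (loss={loss})")
            for key in learnable:
                g = grads[key]
                if key in decayed and cfg.weight_decay:
                    g = g + cfg.weight_decay * params[key]
                m[key] = b1 * m[key] + (1 - b1) * g
                v[key] = b2 * v[key] + (1 - b2) * g * g
                mhat = m[key] / (1 - b1 ** epoch)
                vhat = v[key] / (1 - b2 ** epoch)
                params[key] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            val_probs = model_forward(params, self.operator, self.features, cfg)
            val_pred = np.argmax(val_probs[val_idx], axis=1)
            val_acc = float(np.mean(val_pred == self.labels[val_idx]))
            records.append({"epoch": epoch, "train_loss": loss, "val_accuracy": val_acc})
            if val_acc > best["acc"]:  # strict: ties keep the earliest epoch
                best = {"epoch": epoch, "acc": val_acc,
                        "params": copy.deepcopy(params)}

        return ClassifierResults(
            model=self,
            params=best["params"],
            history=pd.DataFrame.from_records(records),
            best_epoch=best["epoch"],
            best_val_accuracy=best["acc"],
        )


class HypergraphClassifier(TransductiveClassifier):
    """Hypergraph neural network over a kNN hypergraph of the features.

    Build it from a feature matrix (a hypergraph with ``k`` neighbours per
    hyperedge is constructed automatically) or pass a prebuilt
    :class:`Hypergraph`.  With ``config.propagation=False`` the diffusion
    operator is the identity and the model ignores the hypergraph — the
    ablation arm.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        k: int = 10,
        hypergraph: Optional[Hypergraph] = None,
        config: Optional[HGNNConfig] = None,
        class_names: Optional[Sequence[str]] = None,
    ):
        features = np.asarray(features, dtype=np.float64)
        if hypergraph is None:
            hypergraph = build_hypergraph(features, k)
        self.hypergraph = hypergraph
        use_propagation = config.propagation if config is not None else True
        operator = propagation_operator(hypergraph) if use_propagation else None
        super().__init__(features, labels, operator, config=config, class_names=class_names)

    @classmethod
    def from_feature_table(
        cls,
        table: FeatureTable,
        k: int = 10,
        config: Optional[HGNNConfig] = None,
    ) -> "HypergraphClassifier":
        return cls(
            table.features, table.labels, k=k, config=config,
            class_names=table.class_names,
        )


def gcn_operator(X: np.ndarray, k: int) -> sp.csr_matrix:
    """Symmetrically normalised kNN-graph adjacency with self-loops.

    The directed kNN relation is symmetrised (an edge if either endpoint
    selects the other), the identity is added, and the result is scaled as
    ``D^-1/2 (A + I) D^-1/2`` — the conventional graph-convolution
    operator.  ``k = 0`` reduces to the identity (per-node behaviour).
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    hg = build_hypergraph(X, k)
    # membership minus self-loops gives the directed kNN relation
    M = (hg.H - sp.identity(n, format="csr")).tocsr()
    A = ((M + M.T) > 0).astype(np.float64) + sp.identity(n, format="csr")
    deg = np.asarray(A.sum(axis=1)).ravel()
    d_isqrt = sp.diags(1.0 / np.sqrt(deg))
    return sp.csr_matrix(d_isqrt @ A @ d_isqrt)


class GCNClassifier(TransductiveClassifier):
    """Conventional graph-convolution baseline on the pairwise kNN graph.

    Same widths, optimiser and training protocol as the hypergraph model;
    only the propagation operator differs.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        k: int = 10,
        config: Optional[HGNNConfig] = None,
        class_names: Optional[Sequence[str]] = None,
    ):
        features = np.asarray(features, dtype=np.float64)
        operator = gcn_operator(features, k)
        super().__init__(features, labels, operator, config=config, class_names=class_names)


def ablate_propagation(
    features: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    test_idx: np.ndarray,
    k: int = 10,
    config: Optional[HGNNConfig] = None,
    class_names: Optional[Sequence[str]] = None,
):
    """Paired evaluation with and without feature propagation.

    Both arms share the data, split, seed and every hyperparameter; only
    the diffusion operator differs (P vs identity).  Returns
    ``(report_with, report_without)``.
    """
    if config is None:
        config = HGNNConfig(in_dim=np.asarray(features).shape[1],
                            n_classes=int(np.asarray(labels).max()) + 1)
    reports = []
    for propagate in (True, False):
        cfg = replace(config, propagation=propagate)
        model = HypergraphClassifier(
            features, labels, k=k, config=cfg, class_names=class_names
        )
        result = model.fit(train_idx, val_idx)
        reports.append(result.evaluate(test_idx))
    return reports[0], reports[1]
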