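"""Graph-convolutional regression of spot expression from image features.

Message passing on the (refined) spot graph with symmetric degree
normalization,

    x_n^l = ReLU( sum_{m : (m,n) in E'} x_m^{l-1} W_l / sqrt(deg(n) deg(m)) ),

for layers l < L, followed by a per-spot linear read-out x^L = x^{L-1} W_L.
No bias terms appear anywhere.  The training loss per section is

    MSE(X^L, Y) - lambda * sum_j PCC(x_j^L, y_j),

with the Pearson correlation taken per gene across spots.  Gradients are
analytic (plain backpropagation through the dense normalized adjacency) and
optimization is full-batch Adam with early stopping on held-out sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .data import Section
from .graph import RefinedGraph, SpatialGraph

__all__ = [
    "LossConfig",
    "normalized_adjacency",
    "forward",
    "composite_loss",
    "loss_and_grad",
    "GTNRegressor",
]


@dataclass(frozen=True)
class LossConfig:
    """Trade-off weight of the per-gene correlation reward in the loss."""

    lam: float = 0.0
    mse_reduction: str = "mean"  # "mean" or "sum" over matrix elements

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.mse_reduction not in ("mean", "sum"):
            raise ValueError("mse_reduction must be 'mean' or 'sum'")


def normalized_adjacency(
    graph: SpatialGraph | RefinedGraph | np.ndarray, self_loops: bool
) -> np.ndarray:
    """Dense D^{-1/2} (A [+ I]) D^{-1/2} with zero rows for isolated nodes."""
    if isinstance(graph, np.ndarray):
        a = np.asarray(graph, dtype=float).copy()
    else:
        a = graph.adjacency().toarray()
    if self_loops:
        np.fill_diagonal(a, a.diagonal() + 1.0)
    deg = a.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    return a * inv_sqrt[:, None] * inv_sqrt[None, :]


def _forward_cached(
    s_hat: np.ndarray, x: np.ndarray, weights: Sequence[np.ndarray]
):
    """Forward pass keeping the per-layer caches needed for backprop."""
    h = x
    pre = []  # pre-activations of message-passing layers
    props = []  # S_hat @ h^{l-1}
    for w in weights[:-1]:
        p = s_hat @ h
        a = p @ w
        pre.append(a)
        props.append(p)
        h = np.maximum(a, 0.0)
    out = h @ weights[-1]
    return out, h, pre, props


def forward(
    graph: SpatialGraph | RefinedGraph,
    features,
    weights: Sequence[np.ndarray],
    self_loops: bool = True,
) -> np.ndarray:
    """Predicted spots x D_Y matrix for one section."""
    x = getattr(features, "values", features)
    x = np.asarray(x, dtype=float)
    if len(weights) < 2:
        raise ValueError("need at least one message-passing layer plus the "
                         "final linear map (L >= 2)")
    if x.shape[1] != weights[0].shape[0]:
        raise ValueError("feature dim does not match first weight matrix")
    for wa, wb in zip(weights[:-1], weights[1:]):
        if wa.shape[1] != wb.shape[0]:
            raise ValueError("consecutive weight shapes do not chain")
    s_hat = normalized_adjacency(graph, self_loops)
    out, _, _, _ = _forward_cached(s_hat, x, weights)
    return out


def _pcc_columns(pred: np.ndarray, target: np.ndarray):
    """Per-gene Pearson correlation; degenerate columns get 0."""
    pc = pred - pred.mean(axis=0)
    tc = target - target.mean(axis=0)
    pn = np.sqrt((pc**2).sum(axis=0))
    tn = np.sqrt((tc**2).sum(axis=0))
    ok = (pn > 1e-12) & (tn > 1e-12)
    r = np.zeros(pred.shape[1])
    r[ok] = (pc[:, ok] * tc[:, ok]).sum(axis=0) / (pn[ok] * tn[ok])
    return r, pc, tc, pn, tn, ok


def composite_loss(
    pred: np.ndarray, target: np.ndarray, config: LossConfig
) -> float:
    """MSE minus lambda times the summed per-gene Pearson correlations."""
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.shape != target.shape:
        raise ValueError("prediction and target shapes differ")
    if pred.shape[0] < 2:
        raise ValueError("need >= 2 spots for per-gene correlations")
    diff = pred - target
    mse = (diff**2).sum()
    if config.mse_reduction == "mean":
        mse /= diff.size
    r, *_ = _pcc_columns(pred, target)
    return float(mse - config.lam * r.sum())


def _loss_grad_wrt_pred(pred, target, config: LossConfig):
    diff = pred - target
    mse = (diff**2).sum()
    g = 2.0 * diff
    if config.mse_reduction == "mean":
        mse /= diff.size
        g = g / diff.size
    r, pc, tc, pn, tn, ok = _pcc_columns(pred, target)
    loss = mse - config.lam * r.sum()
    if config.lam != 0.0:
        # d r_j / d pred_j = tc / (pn tn) - r * pc / pn^2, zero if degenerate
        gp = np.zeros_like(pred)
        gp[:, ok] = tc[:, ok] / (pn[ok] * tn[ok]) - r[ok] * pc[:, ok] / (
            pn[ok] ** 2
        )
        g = g - config.lam * gp
    return float(loss), g


def loss_and_grad(
    graph: SpatialGraph | RefinedGraph,
    features,
    target,
    weights: Sequence[np.ndarray],
    config: LossConfig,
    self_loops: bool = True,
    s_hat: np.ndarray | None = None,
):
    """Composite loss for one section and its gradients w.r.t. the weights."""
    x = np.asarray(getattr(features, "values", features), float)
    y = np.asarray(getattr(target, "values", target), float)
    if s_hat is None:
        s_hat = normalized_adjacency(graph, self_loops)
    out, h_last, pre, props = _forward_cached(s_hat, x, weights)
    loss, d_out = _loss_grad_wrt_pred(out, y, config)
    grads = [None] * len(weights)
    grads[-1] = h_last.T @ d_out
    dh = d_out @ weights[-1].T
    for l in range(len(weights) - 2, -1, -1):
        da = dh * (pre[l] > 0)
        grads[l] = props[l].T @ da
        if l > 0:
            dh = s_hat.T @ (da @ weights[l].T)
    return loss, grads


class GTNRegressor(BaseEstimator):
    """Multi-section graph regressor trained with full-batch Adam.

    Parameters
    ----------
    hidden_dims
        Widths D_1..D_{L-1} of the message-passing layers; the final linear
        layer maps to the gene panel.
    lam
        Pearson-correlation trade-off weight in the loss (0 = MSE only).
    self_loops
        Add each spot to its own neighbourhood before degree normalization.
        Protects spots isolated by refinement from all-zero hidden states.
    mse_reduction
        "mean" (default, comparable across section sizes) or "sum".
    learning_rate, max_epochs, patience
        Adam step size, epoch budget, and early-stopping patience counted in
        validation checks (one check per epoch).
    init_scale
        Scale multiplier on the Glorot-style weight initialization.
    random_state
        Seed of the weight initialization.
    """

    def __init__(
        self,
        hidden_dims: tuple = (16,),
        lam: float = 0.0,
        self_loops: bool = True,
        mse_reduction: str = "mean",
        learning_rate: float = 0.01,
        max_epochs: int = 200,
        patience: int = 10,
        init_scale: float = 1.0,
        random_state: int = 0,
    ):
        self.hidden_dims = hidden_dims
        self.lam = lam
        self.self_loops = self_loops
        self.mse_reduction = mse_reduction
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.init_scale = init_scale
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _loss_config(self) -> LossConfig:
        return LossConfig(self.lam, self.mse_reduction)

    def _init_weights(self, d_x: int, d_y: int) -> list[np.ndarray]:
        rng = np.random.default_rng(self.random_state)
        dims = [d_x, *self.hidden_dims, d_y]
        if len(dims) < 3:
            raise ValueError("need at least one hidden layer (L >= 2)")
        return [
            rng.normal(
                0.0,
                self.init_scale * np.sqrt(2.0 / (a + b)),
                size=(a, b),
            )
            for a, b in zip(dims[:-1], dims[1:])
        ]

    @staticmethod
    def _bundle(sections, graphs, self_loops):
        """Pair each section with its (refined) graph's dense propagator."""
        out = []
        for sec, g in zip(sections, graphs):
            out.append(
                (
                    normalized_adjacency(g, self_loops),
                    sec.features.values,
                    sec.expression.values,
                )
            )
        return out

    def _dataset_loss(self, bundles, weights, config):
        total = 0.0
        for s_hat, x, y in bundles:
            out, *_ = _forward_cached(s_hat, x, weights)
            loss, _ = _loss_grad_wrt_pred(out, y, config)
            total += loss
        return total

    # -- estimator API -----------------------------------------------------

    def fit(
        self,
        train_sections: Sequence[Section],
        train_graphs: Sequence[SpatialGraph | RefinedGraph],
        val_sections: Sequence[Section] | None = None,
        val_graphs: Sequence | None = None,
    ):
        """Train on whole sections; early-stop on validation sections.

        Without validation sections the full epoch budget is used and the
        final weights are kept.
        """
        config = self._loss_config()
        train = self._bundle(train_sections, train_graphs, self.self_loops)
        val = (
            self._bundle(val_sections, val_graphs, self.self_loops)
            if val_sections
            else None
        )
        d_x = train[0][1].shape[1]
        d_y = train[0][2].shape[1]
        weights = self._init_weights(d_x, d_y)

        m = [np.zeros_like(w) for w in weights]
        v = [np.zeros_like(w) for w in weights]
        b1, b2, eps = 0.9, 0.999, 1e-8

        best_val = np.inf
        best_weights = [w.copy() for w in weights]
        best_train = np.inf
        bad = 0
        history = []
        for epoch in range(1, self.max_epochs + 1):
            total = 0.0
            grads = [np.zeros_like(w) for w in weights]
            for s_hat, x, y in train:
                loss, g = loss_and_grad(
                    None, x, y, weights, config, s_hat=s_hat
                )
                total += loss
                for acc, gi in zip(grads, g):
                    acc += gi
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or check the inputs"
                )
            for i, w in enumerate(weights):
                m[i] = b1 * m[i] + (1 - b1) * grads[i]
                v[i] = b2 * v[i] + (1 - b2) * grads[i] ** 2
                mh = m[i] / (1 - b1**epoch)
                vh = v[i] / (1 - b2**epoch)
                w -= self.learning_rate * mh / (np.sqrt(vh) + eps)

            rec = {"epoch": epoch, "train_loss": total}
            if val is not None:
                vloss = self._dataset_loss(val, weights, config)
                rec["val_loss"] = vloss
                if vloss < best_val - 1e-12:
                    best_val = vloss
                    best_weights = [w.copy() for w in weights]
                    best_train = self._dataset_loss(train, weights, config)
                    bad = 0
                else:
                    bad += 1
                history.append(rec)
                if bad >= self.patience:
                    break
            else:
                history.append(rec)

        if val is None:
            best_weights = weights
            best_val = np.nan
            best_train = self._dataset_loss(train, weights, config)

        self.weights_ = best_weights
        self.best_val_loss_ = float(best_val)
        self.train_loss_ = float(best_train)
        self.history_ = history
        self.n_features_in_ = d_x
        self.n_genes_out_ = d_y
        return self

    def predict(
        self, section: Section, graph: SpatialGraph | RefinedGraph
    ) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("regressor is not fitted")
        return forward(
            graph, section.features, self.weights_, self.self_loops
        )
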