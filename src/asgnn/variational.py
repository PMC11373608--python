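"""Smoothing-based variational optimization over the meta-projection W0.

The refinement projection W0 changes the refined graph discontinuously, so
it cannot be trained by gradient descent.  Instead a Gaussian variational
distribution Q_t = N(mu_t, sigma_t I) over vec(W0) is maintained; at each
meta-epoch S samples are drawn, each sample's remaining parameters W_1..L
are trained by the inner gradient-descent routine, and the sample training
losses L_s are converted to scores F_s = max(-L_s + c, 0).  The score-
weighted updates

    mu_{t+1}    = sum_s F_s vec(W0^s) / sum_s F_s
    sigma_{t+1} = sum_s F_s ||vec(W0^s) - mu_t||^2 / (2 D_X D_Z sum_s F_s)

improve the expected score in expectation.  ``sigma`` is the variance of
each coordinate (samples are mu + sqrt(sigma) * eps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .data import Section
from .refinement import (
    MetaProjection,
    RefinementConfig,
    refine_from_features,
)
from .regressor import GTNRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "VariationalState",
    "SampleRecord",
    "sample_w0",
    "score_sample",
    "smo_update",
    "smo_minimize",
    "run_meta_training",
    "AdaptiveSpatialGNN",
]


@dataclass(frozen=True)
class VariationalState:
    """Gaussian over vec(W0) at meta-epoch ``t`` plus loop settings."""

    mu: np.ndarray
    sigma: float
    t: int = 0
    n_samples: int = 1
    c: float | None = None

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float).ravel()
        object.__setattr__(self, "mu", mu)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_samples < 1:
            raise ValueError("need at least one sample per meta-epoch")
        if self.c is not None and self.c <= 0:
            raise ValueError("score offset c must be positive")

    @property
    def dim(self) -> int:
        return self.mu.size


@dataclass
class SampleRecord:
    """One W0 draw with its trained inner model and score."""

    w0: np.ndarray  # vec(W0)
    train_loss: float
    score: float
    val_loss: float = np.nan
    inner: object = None  # fitted GTNRegressor (or None for toy runs)
    meta_epoch: int = 0
    sample_index: int = 0


def sample_w0(
    state: VariationalState, seed: int, shape: tuple[int, int] | None = None
) -> list[np.ndarray]:
    """Draw S independent vec(W0) samples from N(mu_t, sigma_t I).

    With ``shape`` = (D_X, D_Z) the draws are reshaped to matrices.
    """
    rng = np.random.default_rng(seed)
    draws = state.mu[None, :] + np.sqrt(state.sigma) * rng.standard_normal(
        (state.n_samples, state.dim)
    )
    if shape is not None:
        if shape[0] * shape[1] != state.dim:
            raise ValueError("shape does not match state dimension")
        return [d.reshape(shape) for d in draws]
    return list(draws)


def score_sample(train_loss: float, c: float) -> float:
    """Clamped inverse loss F = max(-L + c, 0)."""
    if c <= 0:
        raise ValueError("score offset c must be positive")
    return max(-train_loss + c, 0.0)


def smo_update(
    samples: Sequence[SampleRecord],
    state: VariationalState,
    sigma_denominator: str = "printed",
) -> VariationalState:
    """Score-weighted mean/variance update of the variational Gaussian.

    ``sigma_denominator`` selects the variance normalization: "printed"
    divides by 2 D_X D_Z (the default), "norm" by D_X D_Z only (reading the
    factor 2 as part of a squared-norm typeset).
    """
    if sigma_denominator not in ("printed", "norm"):
        raise ValueError("sigma_denominator must be 'printed' or 'norm'")
    scores = np.array([s.score for s in samples], dtype=float)
    total = scores.sum()
    if total <= 0:
        raise RuntimeError(
            "all sample scores are zero: the offset c is too small for the "
            "observed losses; increase c so that -L_s + c > 0 for at least "
            "one sample"
        )
    w0s = np.stack([np.asarray(s.w0, float).ravel() for s in samples])
    mu_new = scores @ w0s / total
    dev = ((w0s - state.mu[None, :]) ** 2).sum(axis=1)
    denom = state.dim * total
    if sigma_denominator == "printed":
        denom *= 2.0
    sigma_new = float(scores @ dev / denom)
    if sigma_new <= 0:
        sigma_new = 1e-12  # all mass on one point: keep the Gaussian proper
    return replace(state, mu=mu_new, sigma=sigma_new, t=state.t + 1)


def _resolve_offset(c, losses):
    """Adaptive score offset: ensure -L_s + c > 0 for the observed losses."""
    if c is not None:
        return float(c)
    max_l = float(np.max(losses))
    if max_l > 0:
        return 2.0 * max_l
    return max_l + 1.0


def smo_minimize(
    loss_fn: Callable[[np.ndarray, int], float],
    dim: int,
    mu0: np.ndarray,
    sigma0: float = 1.0,
    c: float | None = None,
    n_samples: int = 30,
    meta_epochs: int = 60,
    seed: int = 0,
    sigma_denominator: str = "printed",
) -> tuple[SampleRecord, list[VariationalState], list[list[SampleRecord]]]:
    """Generic SMO loop minimizing ``loss_fn(w, sample_seed)``.

    Returns the best sample (lowest loss), the state trajectory (including
    the initial state) and the per-meta-epoch sample records.  Fully
    reproducible from ``seed``.
    """
    state = VariationalState(
        np.asarray(mu0, float).ravel(), sigma0, 0, n_samples, None
    )
    if state.dim != dim:
        raise ValueError("mu0 does not match dim")
    trajectory = [state]
    all_records: list[list[SampleRecord]] = []
    best: SampleRecord | None = None
    offset = c
    ss = np.random.SeedSequence(seed)
    for t in range(meta_epochs):
        draw_seed, *samp_seeds = ss.spawn(n_samples + 1)
        rng = np.random.default_rng(draw_seed)
        draws = state.mu[None, :] + np.sqrt(
            state.sigma
        ) * rng.standard_normal((n_samples, dim))
        losses = np.array(
            [
                loss_fn(draws[s], int(samp_seeds[s].generate_state(1)[0] % (2**31)))
                for s in range(n_samples)
            ]
        )
        if offset is None:
            offset = _resolve_offset(c, losses)
            logger.info("score offset c set adaptively to %.6g", offset)
        records = [
            SampleRecord(
                draws[s],
                float(losses[s]),
                score_sample(float(losses[s]), offset),
                meta_epoch=t,
                sample_index=s,
            )
            for s in range(n_samples)
        ]
        all_records.append(records)
        for r in records:
            if best is None or r.train_loss < best.train_loss:
                best = r
        state = smo_update(
            records,
            replace(state, c=offset),
            sigma_denominator=sigma_denominator,
        )
        trajectory.append(state)
    return best, trajectory, all_records


def _evaluate_w0_sample(
    w0_mat: np.ndarray,
    train_sections: Sequence[Section],
    val_sections: Sequence[Section],
    refinement: RefinementConfig,
    regressor_params: dict,
    seed: int,
):
    """Refine every section's graph for one W0 draw and train the inner GTN."""
    projection = MetaProjection(w0_mat)
    refined = {}
    for sec in [*train_sections, *val_sections]:
        graph, clusters = refine_from_features(
            sec.features, sec.graph, refinement,
            projection=projection, hops=sec.hops,
        )
        refined[sec.section_id] = (graph, clusters)
    model = GTNRegressor(random_state=seed, **regressor_params)
    model.fit(
        train_sections,
        [refined[s.section_id][0] for s in train_sections],
        val_sections or None,
        [refined[s.section_id][0] for s in val_sections] or None,
    )
    return model, refined


def run_meta_training(
    train_sections: Sequence[Section],
    val_sections: Sequence[Section],
    refinement: RefinementConfig,
    regressor_params: dict | None = None,
    n_samples: int = 30,
    meta_epochs: int = 60,
    sigma0: float = 1.0,
    mu0_scale: float = 0.1,
    c: float | None = None,
    seed: int = 0,
    sigma_denominator: str = "printed",
):
    """Outer variational loop over W0 with inner GTN training per sample.

    Returns ``(best, trajectory, records)`` where ``best`` is the sample
    with the lowest validation loss across all meta-epochs (its
    ``SampleRecord.inner`` is the fitted inner regressor), ``trajectory``
    the list of variational states and ``records`` the per-epoch sample
    records.
    """
    regressor_params = dict(regressor_params or {})
    d_x = train_sections[0].features.dim
    d_z = refinement.d_z
    dim = d_x * d_z
    ss = np.random.SeedSequence(seed)
    init_seed, loop_seed = ss.spawn(2)
    rng = np.random.default_rng(init_seed)
    mu0 = mu0_scale * rng.standard_normal(dim)

    state = VariationalState(mu0, sigma0, 0, n_samples, None)
    trajectory = [state]
    records_all: list[list[SampleRecord]] = []
    best: SampleRecord | None = None
    offset = c
    loop_ss = loop_seed
    for t in range(meta_epochs):
        draw_seed, *samp_seeds = loop_ss.spawn(n_samples + 1)
        draws = np.random.default_rng(draw_seed).standard_normal(
            (n_samples, dim)
        ) * np.sqrt(state.sigma) + state.mu[None, :]
        records = []
        for s in range(n_samples):
            inner_seed = int(samp_seeds[s].generate_state(1)[0] % (2**31))
            model, refined = _evaluate_w0_sample(
                draws[s].reshape(d_x, d_z),
                train_sections,
                val_sections,
                refinement,
                regressor_params,
                inner_seed,
            )
            rec = SampleRecord(
                draws[s],
                model.train_loss_,
                0.0,
                val_loss=model.best_val_loss_,
                inner=model,
                meta_epoch=t,
                sample_index=s,
            )
            records.append(rec)
            logger.info(
                "meta-epoch %d sample %d: train %.5f val %.5f",
                t, s, rec.train_loss, rec.val_loss,
            )
        if offset is None:
            offset = _resolve_offset(c, [r.train_loss for r in records])
            logger.info("score offset c set adaptively to %.6g", offset)
        for r in records:
            r.score = score_sample(r.train_loss, offset)
            key = r.val_loss if np.isfinite(r.val_loss) else r.train_loss
            bk = (
                best.val_loss
                if best is not None and np.isfinite(best.val_loss)
                else (best.train_loss if best is not None else np.inf)
            )
            if best is None or key < bk:
                best = r
        records_all.append(records)
        state = smo_update(
            records, replace(state, c=offset),
            sigma_denominator=sigma_denominator,
        )
        trajectory.append(state)
    return best, trajectory, records_all


class AdaptiveSpatialGNN(BaseEstimator):
    """Adaptive spatial GNN: variational graph refinement + GTN regression.

    ``fit`` runs the full meta-training loop on train/validation sections;
    ``predict`` refines a section's graph with the best W0 and applies the
    best inner regressor.
    """

    def __init__(
        self,
        alpha: float = 1.0,
        beta: float = 0.1,
        d_z: int = 3,
        ap_preference: float | None = None,
        ap_damping: float = 0.9,
        ap_max_iter: int = 1000,
        ap_convergence_iter: int = 50,
        hidden_dims: tuple = (16,),
        lam: float = 0.1,
        self_loops: bool = True,
        mse_reduction: str = "mean",
        learning_rate: float = 0.01,
        max_epochs: int = 200,
        patience: int = 10,
        n_samples: int = 30,
        meta_epochs: int = 60,
        sigma0: float = 1.0,
        mu0_scale: float = 0.1,
        c: float | None = None,
        sigma_denominator: str = "printed",
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.beta = beta
        self.d_z = d_z
        self.ap_preference = ap_preference
        self.ap_damping = ap_damping
        self.ap_max_iter = ap_max_iter
        self.ap_convergence_iter = ap_convergence_iter
        self.hidden_dims = hidden_dims
        self.lam = lam
        self.self_loops = self_loops
        self.mse_reduction = mse_reduction
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.n_samples = n_samples
        self.meta_epochs = meta_epochs
        self.sigma0 = sigma0
        self.mu0_scale = mu0_scale
        self.c = c
        self.sigma_denominator = sigma_denominator
        self.random_state = random_state

    def _refinement_config(self) -> RefinementConfig:
        return RefinementConfig(
            alpha=self.alpha,
            beta=self.beta,
            d_z=self.d_z,
            preference=self.ap_preference,
            damping=self.ap_damping,
            max_iter=self.ap_max_iter,
            convergence_iter=self.ap_convergence_iter,
        )

    def _regressor_params(self) -> dict:
        return dict(
            hidden_dims=self.hidden_dims,
            lam=self.lam,
            self_loops=self.self_loops,
            mse_reduction=self.mse_reduction,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            patience=self.patience,
        )

    def fit(
        self,
        train_sections: Sequence[Section],
        val_sections: Sequence[Section],
    ):
        best, trajectory, records = run_meta_training(
            train_sections,
            val_sections,
            self._refinement_config(),
            self._regressor_params(),
            n_samples=self.n_samples,
            meta_epochs=self.meta_epochs,
            sigma0=self.sigma0,
            mu0_scale=self.mu0_scale,
            c=self.c,
            seed=self.random_state,
            sigma_denominator=self.sigma_denominator,
        )
        d_x = train_sections[0].features.dim
        self.best_record_ = best
        self.projection_ = MetaProjection(best.w0.reshape(d_x, self.d_z))
        self.regressor_ = best.inner
        self.trajectory_ = trajectory
        self.records_ = records
        return self

    def refine(self, section: Section):
        """Refined graph + cluster assignment of a section under best W0."""
        if not hasattr(self, "projection_"):
            raise RuntimeError("model is not fitted")
        return refine_from_features(
            section.features,
            section.graph,
            self._refinement_config(),
            projection=self.projection_,
            hops=section.hops,
        )

    def predict(self, section: Section) -> np.ndarray:
        graph, _ = self.refine(section)
        return self.regressor_.predict(section, graph)
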