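"""Semi-supervised diffusion map from neural-network features.

An ensemble of small feedforward networks is trained to regress the
propagated quality score from the standardized performance profile.  The
concatenated last-hidden-layer activations of the ensemble define a learned,
non-Euclidean representation in which distance reflects *quality-relevant*
differences between profiles; a heat kernel on these features followed by
the usual diffusion-map construction projects the entities into a
low-dimensional space (3-D by default) oriented by quality.

Each ensemble member is a tanh network with a linear output, trained by
full-batch Adam with a fixed epoch budget and plateau early stopping.
Members differ by seeded initialization and bootstrap resampling of the
training rows, so the ensemble averages over fitting noise; training is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .config import PipelineConfig
from .coupled_geometry import (
    AffinityKernel,
    DiffusionGeometry,
    bandwidth_from_rule,
    diffusion_embed,
    ensure_connected,
)
from .preprocessing import QualityMatrix

__all__ = [
    "MLPRegressorGD",
    "FeatureSet",
    "EmbeddingResult",
    "train_ensemble",
    "ensemble_predict",
    "feature_heat_kernel",
    "diffusion_map",
]

_PLATEAU_PATIENCE = 30
_PLATEAU_RTOL = 1e-8
_WEIGHT_DECAY = 1e-3  # small L2 penalty: smooths the fit between bootstrap rows


class MLPRegressorGD:
    """Small fully-connected regressor trained by full-batch Adam.

    tanh hidden layers, single linear output, mean-squared-error loss.
    Exposes the loss at initialization and convergence and the last hidden
    layer's activations (the learned features).
    """

    def __init__(self, n_inputs: int, hidden_widths: list[int], rng: np.random.Generator):
        self.widths = list(hidden_widths)
        sizes = [n_inputs, *self.widths, 1]
        self.W = [
            rng.normal(0.0, np.sqrt(1.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.loss_init: float | None = None
        self.loss_final: float | None = None
        self.n_epochs_run: int = 0

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        h = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.tanh(h @ W + b)
            acts.append(h)
        acts.append(h @ self.W[-1] + self.b[-1])
        return acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._forward(X)[-1].ravel()

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """Last-hidden-layer activations."""
        return self._forward(X)[-2]

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int, lr: float) -> "MLPRegressorGD":
        y = y.reshape(-1, 1)
        n = len(X)
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best = np.inf
        stall = 0
        for epoch in range(1, epochs + 1):
            acts = self._forward(X)
            resid = acts[-1] - y
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            if self.loss_init is None:
                self.loss_init = loss
            self.loss_final = loss
            if loss < best * (1 - _PLATEAU_RTOL):
                best, stall = loss, 0
            else:
                stall += 1
                if stall >= _PLATEAU_PATIENCE:
                    break
            delta = 2.0 * resid / n
            for li in range(len(self.W) - 1, -1, -1):
                gW = acts[li].T @ delta + _WEIGHT_DECAY * self.W[li]
                gb = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ self.W[li].T) * (1.0 - acts[li] ** 2)
                for g, m, v, param in ((gW, mW[li], vW[li], self.W[li]),
                                       (gb, mb[li], vb[li], self.b[li])):
                    m *= beta1
                    m += (1 - beta1) * g
                    v *= beta2
                    v += (1 - beta2) * g**2
                    mhat = m / (1 - beta1**epoch)
                    vhat = v / (1 - beta2**epoch)
                    param -= lr * mhat / (np.sqrt(vhat) + eps)
            self.n_epochs_run = epoch
        return self


@dataclass
class FeatureSet:
    """Concatenated hidden-layer features of the trained ensemble."""

    entity_ids: list[str]
    features: np.ndarray
    seeds: list[int]
    init_losses: list[float]
    final_losses: list[float]
    models: list[MLPRegressorGD] = field(repr=False, default_factory=list)
    score_offset: float = 0.0
    score_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.features.shape[0] != len(self.entity_ids):
            raise ValueError("feature row count does not match entities")
        if not np.isfinite(self.features).all():
            raise ValueError("non-finite features")


@dataclass(frozen=True)
class EmbeddingResult:
    """Low-dimensional diffusion-map coordinates of the entities."""

    entity_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        if self.coordinates.shape[0] != len(self.entity_ids):
            raise ValueError("coordinate row count does not match entities")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("non-finite coordinates")

    def distance_matrix(self) -> np.ndarray:
        d = cdist(self.coordinates, self.coordinates)
        np.fill_diagonal(d, 0.0)
        return d


def train_ensemble(
    m: QualityMatrix, scores: dict[str, float], cfg: PipelineConfig
) -> FeatureSet:
    """Train ``cfg.ensemble_size`` networks on (profile -> propagated score)
    with bootstrap resamples and distinct seeded initializations; the feature
    of an entity is the concatenation of every member's last-hidden-layer
    activation on its profile."""
    missing = [e for e in m.entity_ids if e not in scores]
    if missing:
        raise ValueError(f"no propagated score for entities: {missing[:5]}")
    X = m.values
    y_raw = np.array([scores[e] for e in m.entity_ids], dtype=float)
    # standardize the target for optimizer conditioning; record the affine map
    offset = float(y_raw.mean())
    scale = float(y_raw.std()) or 1.0
    y = (y_raw - offset) / scale
    n = len(X)
    blocks, seeds, init_losses, final_losses, models = [], [], [], [], []
    for e in range(cfg.ensemble_size):
        seed = (cfg.rng_seed + 7919 * (e + 1)) % (2**31)
        rng = np.random.default_rng(seed)
        boot = rng.integers(0, n, size=n)
        net = MLPRegressorGD(X.shape[1], cfg.hidden_widths, rng)
        try:
            net.fit(X[boot], y[boot], cfg.train_epochs, cfg.learning_rate)
        except FloatingPointError as err:
            raise FloatingPointError(
                f"ensemble member {e} (seed {seed}): {err}"
            ) from err
        if net.loss_final > net.loss_init:
            raise RuntimeError(
                f"ensemble member {e} (seed {seed}) diverged: "
                f"final loss {net.loss_final:g} > initial {net.loss_init:g}"
            )
        blocks.append(net.hidden(X))
        seeds.append(seed)
        init_losses.append(net.loss_init)
        final_losses.append(net.loss_final)
        models.append(net)
    return FeatureSet(
        list(m.entity_ids),
        np.hstack(blocks),
        seeds,
        init_losses,
        final_losses,
        models,
        offset,
        scale,
    )


def ensemble_predict(fs: FeatureSet, X: np.ndarray) -> np.ndarray:
    """Ensemble-mean score prediction for profile rows ``X`` (original scale)."""
    if not fs.models:
        raise ValueError("feature set carries no trained models")
    pred = np.mean([net.predict(X) for net in fs.models], axis=0)
    return pred * fs.score_scale + fs.score_offset


def feature_heat_kernel(f: FeatureSet, cfg: PipelineConfig) -> AffinityKernel:
    """Heat kernel exp(-||feat_i - feat_j||^2 / eps) on the learned features."""
    sq = cdist(f.features, f.features, metric="sqeuclidean")
    iu = np.triu_indices_from(sq, k=1)
    eps = bandwidth_from_rule(sq[iu], cfg)
    if eps == 0:
        raise ValueError("zero bandwidth: all feature rows identical")
    w = np.exp(-sq / eps)
    np.fill_diagonal(w, 1.0)
    w = (w + w.T) / 2.0
    return ensure_connected(AffinityKernel(list(f.entity_ids), w))


def diffusion_map(k: AffinityKernel, cfg: PipelineConfig) -> EmbeddingResult:
    """Project onto the top ``cfg.embed_dims`` nontrivial diffusion
    coordinates lambda^t * psi.  Coordinates are mean-centered (a translation,
    so pairwise distances are untouched) and eigenvector signs are fixed, so
    the map is deterministic and plots share a common vantage point."""
    geom = diffusion_embed(k, cfg)
    if geom.eigenvectors.shape[1] - 1 < cfg.embed_dims:
        raise ValueError(
            f"kernel supports only {geom.eigenvectors.shape[1] - 1} nontrivial "
            f"coordinates; embed_dims={cfg.embed_dims}"
        )
    coords = geom.coordinates(cfg.embed_dims)
    coords = coords - coords.mean(axis=0)
    return EmbeddingResult(
        list(k.ids), coords, geom.eigenvalues[1 : cfg.embed_dims + 1]
    )
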