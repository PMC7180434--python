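"""Radial basis function network for vessel-vs-other tissue recognition.

Architecture: input layer (default 2 features — relative [HbO2] and [Hb]
per trial), one hidden layer of K Gaussian kernel units, and a single
linear output read as a continuous tissue index in [0, 1]. Training is the
classic two-stage procedure:

1. unsupervised: hidden-unit centers by k-means clustering of the training
   features (k-means++ seeding, Lloyd iterations); kernel widths from the
   mean distance to each center's nearest neighbours;
2. supervised: output weights (and bias) by the normalized least mean
   squares (NLMS) rule, one pass per sample per epoch,

       w <- w + mu * e * phi / (eps + ||phi||^2)

   with e = target - output and phi the hidden activation vector.

Targets are 1 for the vessel group and 0 for other tissue. The decision
threshold is picked from a grid (default 0.1..0.9, step 0.1) by maximising
training F-measure, ties broken toward 0.5 and then toward the lower value.
Inputs are z-scored with training-set statistics stored in the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evaluation import OTHER, VESSEL, metrics, confusion
from .exceptions import (
    CompatibilityError,
    ConfigurationError,
    NotTrainedError,
    SelectionError,
)

__all__ = [
    "TrainingConfig",
    "RBFNetwork",
    "kmeans_centers",
    "set_widths",
    "nlms_train",
    "select_threshold",
    "train_network",
    "labels_to_targets",
]

DEFAULT_GRID: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the two-stage RBFNN training procedure.

    n_centers is the hidden-layer size (operating point: 64). nlms_step is
    the NLMS step size mu, stable for 0 < mu < 2; nlms_reg the small
    positive regulariser eps in the normalisation. width_neighbors is the
    number of nearest centers averaged into each kernel width.
    """

    n_centers: int = 64
    threshold_grid: tuple[float, ...] = DEFAULT_GRID
    nlms_step: float = 0.5
    nlms_reg: float = 1e-6
    epochs: int = 100
    seed: int = 0
    width_neighbors: int = 2
    max_kmeans_iter: int = 300

    def __post_init__(self) -> None:
        if self.n_centers < 1:
            raise ConfigurationError("n_centers must be >= 1")
        if not (0.0 < self.nlms_step < 2.0):
            raise ConfigurationError(
                f"NLMS step mu = {self.nlms_step} outside the stable range (0, 2)"
            )
        if self.nlms_reg <= 0:
            raise ConfigurationError("nlms_reg must be > 0")
        if len(self.threshold_grid) == 0:
            raise ConfigurationError("threshold grid is empty")
        if min(self.threshold_grid) < 0.1 - 1e-12 or max(self.threshold_grid) > 0.9 + 1e-12:
            raise ConfigurationError("threshold grid must lie within [0.1, 0.9]")

    def as_dict(self) -> dict:
        return {
            "n_centers": self.n_centers,
            "threshold_grid": list(self.threshold_grid),
            "nlms_step": self.nlms_step,
            "nlms_reg": self.nlms_reg,
            "epochs": self.epochs,
            "seed": self.seed,
            "width_neighbors": self.width_neighbors,
            "max_kmeans_iter": self.max_kmeans_iter,
        }


def labels_to_targets(labels: Sequence[str]) -> np.ndarray:
    """Map 'vessel'/'other' labels to the 1/0 network targets."""
    return np.array([1.0 if lab == VESSEL else 0.0 for lab in labels])


def _sse(X: np.ndarray, centers: np.ndarray, assign: np.ndarray) -> float:
    return float(((X - centers[assign]) ** 2).sum())


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding; degenerates to uniform choice when all remaining
    squared distances are zero (duplicate points)."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total > 0:
            idx = rng.choice(n, p=d2 / total)
        else:
            idx = rng.integers(n)
        centers[j] = X[idx]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def kmeans_centers(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    return_history: bool = False,
):
    """Lloyd's k-means with k-means++ seeding.

    Returns the K x d center matrix (and, when ``return_history`` is set,
    the per-iteration within-cluster sum of squares, recorded after each
    assignment step). The SSE history is checked to be non-increasing at
    every iteration; an empty cluster is re-seeded at the point farthest
    from its assigned center. Terminates on assignment stability or after
    ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise CompatibilityError(f"feature matrix must be 2-D, got shape {X.shape}")
    n = X.shape[0]
    if k > n:
        raise ConfigurationError(f"k = {k} exceeds the number of samples n = {n}")
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(X, k, rng)
    prev_assign = None
    history: list[float] = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        sse = _sse(X, centers, assign)
        if history and sse > history[-1] * (1 + 1e-12) + 1e-15:
            raise AssertionError("k-means SSE increased between iterations")
        history.append(sse)
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        prev_assign = assign
        # update step; empty clusters re-seeded from the farthest point
        resid = d2[np.arange(n), assign]
        for j in range(k):
            members = assign == j
            if members.any():
                centers[j] = X[members].mean(axis=0)
            else:
                centers[j] = X[resid.argmax()]
    if return_history:
        return centers, history
    return centers


def set_widths(centers: np.ndarray, p: int = 2) -> np.ndarray:
    """Gaussian kernel widths from the local center spacing.

    sigma_j = mean Euclidean distance from center j to its p nearest other
    centers (p capped at K-1). A single center gets sigma = 1.0, and any
    zero width (duplicate centers) falls back to the mean positive width,
    or 1.0 if every width is zero.
    """
    centers = np.asarray(centers, dtype=float)
    k = centers.shape[0]
    if k == 1:
        return np.array([1.0])
    d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    p_eff = min(p, k - 1)
    nearest = np.sort(d, axis=1)[:, :p_eff]
    widths = nearest.mean(axis=1)
    if np.any(widths <= 0):
        positive = widths[widths > 0]
        widths[widths <= 0] = positive.mean() if positive.size else 1.0
    return widths


@dataclass
class RBFNetwork:
    """A trained (or in-training) RBF network.

    ``weights``/``bias`` are None until NLMS training has run; prediction on
    an untrained network raises :class:`NotTrainedError`. ``norm_mean`` and
    ``norm_scale`` standardise inputs with training-set statistics.
    """

    centers: np.ndarray
    widths: np.ndarray
    weights: Optional[np.ndarray] = None
    bias: Optional[float] = None
    threshold: float = 0.5
    norm_mean: Optional[np.ndarray] = None
    norm_scale: Optional[np.ndarray] = None
    feature_names: tuple[str, ...] = ("hbo2", "hb")
    seed: int = 0
    config: dict = field(default_factory=dict)

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]

    @property
    def trained(self) -> bool:
        return self.weights is not None and self.bias is not None

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.norm_mean is None:
            return X
        return (X - self.norm_mean) / self.norm_scale

    def activations(self, X: np.ndarray) -> np.ndarray:
        """Hidden-layer Gaussian activations, shape (n, K)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise CompatibilityError(
                f"input has {X.shape[1]} features, network expects {self.n_features}"
            )
        Xs = self._standardize(X)
        d2 = ((Xs[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.widths**2))

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Continuous output scores y = bias + sum_j w_j phi_j(x)."""
        if not self.trained:
            raise NotTrainedError("network weights have not been trained")
        return self.activations(X) @ self.weights + self.bias

    def classify(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels and scores; vessel iff score strictly above threshold."""
        scores = self.forward(X)
        labels = np.where(scores > self.threshold, VESSEL, OTHER)
        return labels, scores

    def classify_one(self, x: np.ndarray) -> tuple[str, float]:
        labels, scores = self.classify(np.atleast_2d(x))
        return str(labels[0]), float(scores[0])

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "widths": self.widths.tolist(),
            "weights": None if self.weights is None else self.weights.tolist(),
            "bias": self.bias,
            "threshold": self.threshold,
            "norm_params": {
                "mean": None if self.norm_mean is None else self.norm_mean.tolist(),
                "scale": None if self.norm_scale is None else self.norm_scale.tolist(),
            },
            "feature_names": list(self.feature_names),
            "seed": self.seed,
            "config": self.config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RBFNetwork":
        norm = d.get("norm_params") or {}
        mean = norm.get("mean")
        scale = norm.get("scale")
        return cls(
            centers=np.array(d["centers"], dtype=float),
            widths=np.array(d["widths"], dtype=float),
            weights=None if d.get("weights") is None else np.array(d["weights"], dtype=float),
            bias=d.get("bias"),
            threshold=float(d.get("threshold", 0.5)),
            norm_mean=None if mean is None else np.array(mean, dtype=float),
            norm_scale=None if scale is None else np.array(scale, dtype=float),
            feature_names=tuple(d.get("feature_names", ("hbo2", "hb"))),
            seed=int(d.get("seed", 0)),
            config=d.get("config", {}),
        )

    @classmethod
    def from_json(cls, text: str) -> "RBFNetwork":
        return cls.from_dict(json.loads(text))


def nlms_train(
    net: RBFNetwork,
    X: np.ndarray,
    targets: np.ndarray,
    config: TrainingConfig,
) -> RBFNetwork:
    """Train output weights and bias by normalized LMS.

    The bias is treated as an ordinary weight on a constant activation of 1
    and shares the normalisation. Samples are visited in a fresh shuffled
    order every epoch (deterministic under ``config.seed``); for
    mu in (0, 1] each update's a-posteriori error magnitude cannot exceed
    the a-priori error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    targets = np.asarray(targets, dtype=float)
    if X.shape[0] != targets.shape[0]:
        raise CompatibilityError(
            f"{X.shape[0]} samples but {targets.shape[0]} targets"
        )
    if X.shape[0] < 1:
        raise ConfigurationError("need at least one training sample")
    phi = net.activations(X)
    phi_b = np.hstack([phi, np.ones((phi.shape[0], 1))])  # bias column
    w = np.zeros(phi_b.shape[1]) if not net.trained else np.append(net.weights, net.bias)
    mu, eps = config.nlms_step, config.nlms_reg
    rng = np.random.default_rng(config.seed)
    n = phi_b.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for i in order:
            p = phi_b[i]
            e = targets[i] - p @ w
            w = w + mu * e * p / (eps + p @ p)
    net.weights = w[:-1]
    net.bias = float(w[-1])
    return net


def select_threshold(
    net: RBFNetwork,
    X: np.ndarray,
    labels: Sequence[str],
    grid: Sequence[float] = DEFAULT_GRID,
) -> float:
    """Grid value maximising training F-measure.

    Grid points where the F-measure is undefined (no predicted and no true
    positives) are skipped; exact ties are broken toward 0.5 and then
    toward the smaller threshold. Raises :class:`SelectionError` when the
    F-measure is undefined at every grid point.
    """
    if len(grid) == 0:
        raise SelectionError("threshold grid is empty")
    scores = net.forward(X)
    best = None
    for t in grid:
        pred = np.where(scores > t, VESSEL, OTHER)
        m = metrics(confusion(list(labels), list(pred)))
        if m.f_measure is None:
            continue
        key = (-m.f_measure, abs(t - 0.5), t)
        if best is None or key < best[0]:
            best = (key, t)
    if best is None:
        raise SelectionError("F-measure undefined at every threshold in the grid")
    return float(best[1])


def train_network(
    X: np.ndarray,
    labels: Sequence[str],
    config: TrainingConfig = TrainingConfig(),
    feature_names: tuple[str, ...] = ("hbo2", "hb"),
) -> RBFNetwork:
    """Full two-stage training: standardise, k-means centers, widths, NLMS
    weights, then threshold selection on the training set."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if config.n_centers > n:
        raise ConfigurationError(
            f"n_centers = {config.n_centers} exceeds training-set size {n}"
        )
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    centers = kmeans_centers(Xs, config.n_centers, seed=config.seed,
                             max_iter=config.max_kmeans_iter)
    widths = set_widths(centers, p=config.width_neighbors)
    net = RBFNetwork(
        centers=centers,
        widths=widths,
        norm_mean=mean,
        norm_scale=scale,
        feature_names=tuple(feature_names),
        seed=config.seed,
        config=config.as_dict(),
    )
    nlms_train(net, X, labels_to_targets(labels), config)
    net.threshold = select_threshold(net, X, labels, config.threshold_grid)
    return net
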