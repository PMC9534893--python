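"""From-scratch MLP and RBF regressors.

Both networks map the encoded, z-scored inputs to the five z-scored
traits.  The MLP uses hyperbolic-tangent (tansig) hidden layers and a
linear (purelin) output layer, the default topology being 4-14-12-5.
Its training objective is the mean squared error plus an L2 penalty on
all parameters, minimized with L-BFGS on analytic backpropagation
gradients; an optional evidence-style re-estimation of the penalty
strength (a Bayesian-regularization approximation) is available.

The RBF network has a single hidden layer of Gaussian units
``phi_k(x) = exp(-||x - c_k||^2 / (2 sigma_k^2))``; centers come from
seeded k-means on the training inputs, each width is the distance to
the nearest other center, and the linear output weights solve a ridge
least-squares problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.optimize import minimize

from .exceptions import ParameterError, TrainingError


# ---------------------------------------------------------------------------
# multilayer perceptron
# ---------------------------------------------------------------------------

@dataclass
class MLPConfig:
    """Training settings for the MLP.

    ``l2`` is the penalty strength on the standardized scale;
    ``reestimate_l2`` switches on the evidence-style update
    ``l2 <- gamma / (2 * sum(p^2))`` between refits.
    """

    hidden_layers: tuple[int, ...] = (14, 12)
    l2: float = 1e-4
    max_iter: int = 2000
    tol: float = 1e-12
    seed: int = 0
    reestimate_l2: bool = False
    n_reestimate: int = 3

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.tol <= 0:
            raise ParameterError("max_iter must be >= 1 and tol > 0")
        if self.l2 < 0:
            raise ParameterError("l2 must be non-negative")


class MLPNetwork:
    """Feed-forward network with tansig hidden layers and a linear output."""

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray]):
        if len(weights) != len(biases) or not weights:
            raise ParameterError("need matching, non-empty weight and bias lists")
        for k in range(len(weights) - 1):
            if weights[k].shape[1] != weights[k + 1].shape[0]:
                raise ParameterError("inconsistent layer shapes")
        for w, b in zip(weights, biases):
            if b.shape != (w.shape[1],):
                raise ParameterError("bias shape does not match weight shape")
        self.weights = [np.asarray(w, float) for w in weights]
        self.biases = [np.asarray(b, float) for b in biases]
        self.history: list[float] = []

    # -- construction -----------------------------------------------------
    @classmethod
    def initialize(cls, layer_sizes: tuple[int, ...], seed: int = 0) -> "MLPNetwork":
        """Small uniform random weights scaled by fan-in."""
        rng = np.random.default_rng(seed)
        weights, biases = [], []
        for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            scale = 1.0 / np.sqrt(n_in)
            weights.append(rng.uniform(-scale, scale, size=(n_in, n_out)))
            biases.append(np.zeros(n_out))
        return cls(weights, biases)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0],) + tuple(w.shape[1] for w in self.weights)

    # -- forward ----------------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        """Predictions for a 2-D input array (hidden tansig, output purelin)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.weights[0].shape[0]:
            raise ParameterError(
                f"expected input width {self.weights[0].shape[0]}, got {X.shape}"
            )
        a = X
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ w + b)
        return a @ self.weights[-1] + self.biases[-1]

    def _forward_cached(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        a = X
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ w + b)
            acts.append(a)
        acts.append(a @ self.weights[-1] + self.biases[-1])
        return acts

    # -- parameter vector -------------------------------------------------
    def get_params(self) -> np.ndarray:
        return np.concatenate(
            [w.ravel() for w in self.weights] + [b.ravel() for b in self.biases]
        )

    def set_params(self, vec: np.ndarray) -> None:
        offset = 0
        for k, w in enumerate(self.weights):
            self.weights[k] = vec[offset:offset + w.size].reshape(w.shape)
            offset += w.size
        for k, b in enumerate(self.biases):
            self.biases[k] = vec[offset:offset + b.size].reshape(b.shape)
            offset += b.size

    # -- loss and gradient ------------------------------------------------
    def loss_grad(self, X: np.ndarray, Y: np.ndarray, l2: float) -> tuple[float, np.ndarray]:
        """Objective (MSE + l2 * sum of squared parameters) and its
        gradient via backpropagation."""
        acts = self._forward_cached(X)
        pred = acts[-1]
        resid = pred - Y
        n_terms = resid.size
        loss = float(np.mean(resid**2))
        delta = 2.0 * resid / n_terms
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        for k in range(len(self.weights) - 1, -1, -1):
            grads_w[k] = acts[k].T @ delta
            grads_b[k] = delta.sum(axis=0)
            if k > 0:
                delta = (delta @ self.weights[k].T) * (1.0 - acts[k] ** 2)
        grad = np.concatenate(
            [g.ravel() for g in grads_w] + [g.ravel() for g in grads_b]
        )
        if l2 > 0:
            params = self.get_params()
            loss += l2 * float(params @ params)
            grad = grad + 2.0 * l2 * params
        return loss, grad

    def jacobian(self, X: np.ndarray) -> np.ndarray:
        """Per-sample, per-output gradients of the predictions,
        shape (n_samples * n_outputs, n_params); used by the
        evidence-style penalty update."""
        acts = self._forward_cached(X)
        n, q = acts[-1].shape
        blocks = []
        for o in range(q):
            delta = np.zeros((n, q))
            delta[:, o] = 1.0
            gw, gb = [], []
            for k in range(len(self.weights) - 1, -1, -1):
                gw.append(acts[k][:, :, None] * delta[:, None, :])
                gb.append(delta.copy())
                if k > 0:
                    delta = (delta @ self.weights[k].T) * (1.0 - acts[k] ** 2)
            gw.reverse()
            gb.reverse()
            blocks.append(
                np.concatenate(
                    [g.reshape(n, -1) for g in gw] + [g.reshape(n, -1) for g in gb],
                    axis=1,
                )
            )
        return np.concatenate(blocks, axis=0)


def _fit_once(net: MLPNetwork, X, Y, l2, max_iter, tol) -> None:
    history = []

    def objective(vec):
        net.set_params(vec)
        loss, grad = net.loss_grad(X, Y, l2)
        if not np.isfinite(loss):
            raise TrainingError(
                f"training diverged: non-finite loss at iteration {len(history)}"
            )
        return loss, grad

    def callback(vec):
        net.set_params(vec)
        history.append(net.loss_grad(X, Y, l2)[0])

    x0 = net.get_params()
    history.append(net.loss_grad(X, Y, l2)[0])
    result = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12},
    )
    net.set_params(result.x)
    net.history.extend(history)


def train_mlp(X: np.ndarray, Y: np.ndarray, config: MLPConfig | None = None) -> MLPNetwork:
    """Train an MLP on standardized inputs/targets.

    Deterministic given ``config.seed``.  The recorded objective history
    is non-increasing over accepted line-search iterations and the final
    training MSE never exceeds the initial one.
    """
    config = config or MLPConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ParameterError("X and Y row counts differ")
    if X.shape[0] < 10:
        raise ParameterError("need at least 10 training rows")
    if not np.isfinite(Y).all() or not np.isfinite(X).all():
        raise TrainingError("non-finite training data")

    sizes = (X.shape[1],) + tuple(config.hidden_layers) + (Y.shape[1],)
    net = MLPNetwork.initialize(sizes, seed=config.seed)
    l2 = config.l2
    rounds = config.n_reestimate if config.reestimate_l2 else 1
    for r in range(rounds):
        _fit_once(net, X, Y, l2, config.max_iter, config.tol)
        if config.reestimate_l2 and r < rounds - 1:
            # MacKay-style update: effective number of parameters gamma
            # from the Gauss-Newton Hessian, then l2 <- alpha/beta on the
            # MSE scale with alpha = gamma/(2 Ew), beta = (N - gamma)/(2 Ed)
            jac = net.jacobian(X)
            n_terms = X.shape[0] * Y.shape[1]
            eigs = np.linalg.eigvalsh((2.0 / n_terms) * (jac.T @ jac))
            gamma = float(np.sum(eigs / (eigs + 2.0 * l2)))
            ew = float(net.get_params() @ net.get_params())
            mse = float(np.mean((net.forward(X) - Y) ** 2))
            denom = max(ew * (n_terms - gamma), 1e-12)
            l2 = float(np.clip(gamma * mse / denom, 1e-8, 1e2))
    net.final_l2 = l2
    return net


# ---------------------------------------------------------------------------
# radial basis function network
# ---------------------------------------------------------------------------

def rbf_design_matrix(X: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Gaussian feature matrix: entry (i, k) = exp(-||x_i - c_k||^2 /
    (2 sigma_k^2)); entries lie in (0, 1] and equal 1 iff x_i = c_k."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    widths = np.asarray(widths, dtype=float)
    if np.any(widths <= 0):
        raise ParameterError("widths must be positive")
    sq = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-sq / (2.0 * widths**2))


class RBFNetwork:
    """Gaussian RBF layer plus a linear output layer."""

    def __init__(self, centers: np.ndarray, widths: np.ndarray, weights: np.ndarray):
        self.centers = np.atleast_2d(np.asarray(centers, float))
        self.widths = np.asarray(widths, float)
        self.weights = np.asarray(weights, float)
        if self.widths.shape != (self.centers.shape[0],):
            raise ParameterError("one width per center required")
        if np.any(self.widths <= 0):
            raise ParameterError("widths must be positive")
        if self.weights.shape[0] != self.centers.shape[0]:
            raise ParameterError("weight rows must match the number of centers")

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def forward(self, X: np.ndarray) -> np.ndarray:
        return rbf_design_matrix(X, self.centers, self.widths) @ self.weights


def _nearest_neighbor_widths(centers: np.ndarray) -> np.ndarray:
    if centers.shape[0] == 1:
        return np.ones(1)
    dists = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(dists, np.inf)
    widths = dists.min(axis=1)
    positive = widths[np.isfinite(widths) & (widths > 0)]
    fallback = positive.min() if positive.size else 1.0
    widths[~np.isfinite(widths) | (widths == 0)] = fallback
    return widths


def train_rbf(
    X: np.ndarray,
    Y: np.ndarray,
    k: int = 25,
    centers: np.ndarray | None = None,
    widths: float | np.ndarray | None = None,
    width_scale: float = 1.0,
    ridge: float = 1e-8,
    seed: int = 0,
) -> RBFNetwork:
    """Fit an RBF network on standardized data.

    Centers default to seeded k-means++ on the training inputs (pass
    ``centers`` explicitly for, e.g., the interpolation limit where the
    centers are the training points themselves).  Output weights solve
    ``(Phi' Phi + ridge I) W = Phi' Y``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if centers is None:
        if k > X.shape[0]:
            raise ParameterError("k cannot exceed the number of training rows")
        if k == X.shape[0]:
            centers = X.copy()
        else:
            centers, _ = kmeans2(X, k, minit="++", seed=seed)
    centers = np.atleast_2d(np.asarray(centers, float))
    if widths is None:
        widths = _nearest_neighbor_widths(centers) * width_scale
    widths = np.broadcast_to(np.asarray(widths, float), (centers.shape[0],)).copy()

    phi = rbf_design_matrix(X, centers, widths)
    gram = phi.T @ phi
    if ridge > 0:
        gram = gram + ridge * np.eye(gram.shape[0])
    try:
        weights = np.linalg.solve(gram, phi.T @ Y)
    except np.linalg.LinAlgError as exc:
        raise TrainingError(
            "singular RBF design matrix; increase the ridge parameter or "
            "reduce the number of (duplicate) centers"
        ) from exc
    return RBFNetwork(centers, widths, weights)
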