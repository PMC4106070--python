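"""Sparse autoencoders with maximum-correntropy or mean-square reconstruction
loss, layer-wise stacking, softmax head, and joint fine-tuning.

The robust variant (R-SAE) scores reconstruction by estimated correntropy —
the sample mean of a Gaussian kernel of the elementwise reconstruction error
— and maximizes it.  A kernel of size sigma saturates for errors of a few
sigma, so a single wildly corrupted feature entry can change the cost by at
most kappa_sigma(0)/n, whereas the mean-square loss of the standard variant
(S-SAE) grows without bound.  Both costs share a KL-divergence sparsity
penalty on mean hidden activations and an L2 weight-decay term:

    J_R-SAE = -J_MCC + J_weight + J_sparse        (minimized)
    J_S-SAE =  J_MSE + J_weight + J_sparse        (minimized)

Training is deterministic full-batch quasi-Newton (L-BFGS) with analytic
gradients; seeds control only the symmetric-uniform weight initialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

_RHO_CLAMP = 1e-8  # keeps KL(rho || rho_hat) finite at saturated units


@dataclass
class AEParams:
    """One autoencoder's parameter set: encoder (W1, b1), decoder (W2, b2)."""

    W1: np.ndarray  # hidden x input
    b1: np.ndarray  # hidden
    W2: np.ndarray  # input x hidden
    b2: np.ndarray  # input

    def __post_init__(self) -> None:
        d_hidden, d_in = self.W1.shape
        if self.W2.shape != (d_in, d_hidden) or self.b1.shape != (d_hidden,) or self.b2.shape != (d_in,):
            raise ValueError("inconsistent parameter shapes")

    def flatten(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in (self.W1, self.b1, self.W2, self.b2)])

    @classmethod
    def unflatten(cls, theta: np.ndarray, d_in: int, d_hidden: int) -> "AEParams":
        sizes = [d_hidden * d_in, d_hidden, d_in * d_hidden, d_in]
        W1, b1, W2, b2 = np.split(theta, np.cumsum(sizes)[:-1])
        return cls(W1=W1.reshape(d_hidden, d_in), b1=b1,
                   W2=W2.reshape(d_in, d_hidden), b2=b2)


@dataclass
class AEConfig:
    """Training settings for one autoencoder (and for fine-tuning).

    ``sigma`` is the correntropy kernel size on the [0, 1] feature scale
    (MCC loss only; small sigma = aggressive outlier suppression).
    ``weight_decay`` is the L2 coefficient lambda, ``sparsity_weight`` the KL
    penalty weight beta, ``sparsity_target`` the desired mean hidden
    activation rho.  Defaults are the operating point reported for the
    method: lambda = 0.003, beta = 3, rho = 0.1, sigma = 0.05.
    """

    loss_type: Literal["mcc", "mse"] = "mcc"
    sigma: float = 0.05
    weight_decay: float = 0.003
    sparsity_weight: float = 3.0
    sparsity_target: float = 0.1
    max_iter: int = 400
    seed: int = 0
    kernel_normalized: bool = False  # include the 1/(sqrt(2 pi) sigma) factor
    # The bare kernel definition carries a 1/(sqrt(2 pi) sigma) normalization;
    # inside the regularized cost that constant multiplies only the
    # reconstruction term (x8 at sigma = 0.05), silently weakening the shared
    # sparsity/decay weights relative to the MSE cost and changing balance
    # across a sigma sweep.  The training cost therefore drops it by default;
    # optima of the *unregularized* loss are unaffected either way.
    anneal_start: float = 0.8        # kernel-size continuation start (MCC only)

    def __post_init__(self) -> None:
        if self.loss_type not in ("mcc", "mse"):
            raise ValueError(f"unknown loss_type {self.loss_type!r}")
        if self.loss_type == "mcc" and self.sigma <= 0:
            raise ValueError("sigma must be positive for the MCC loss")
        if self.weight_decay < 0 or self.sparsity_weight < 0:
            raise ValueError("penalty weights must be nonnegative")
        if not (0.0 < self.sparsity_target < 1.0):
            raise ValueError("sparsity_target must be in (0, 1)")


def sigmoid(z: np.ndarray) -> np.ndarray:
    return expit(z)


def encode(x: np.ndarray, p: AEParams) -> np.ndarray:
    """Hidden representation s(W1 x + b1); accepts a vector or an n x d batch."""
    x = np.asarray(x, dtype=float)
    return sigmoid(x @ p.W1.T + p.b1)


def decode(h: np.ndarray, p: AEParams) -> np.ndarray:
    """Reconstruction s(W2 h + b2)."""
    h = np.asarray(h, dtype=float)
    return sigmoid(h @ p.W2.T + p.b2)


# ----------------------------------------------------------------- losses

def mse_loss(X: np.ndarray, Y: np.ndarray) -> float:
    """Mean over samples of half the squared reconstruction error."""
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    return float(0.5 * np.sum((Y - X) ** 2) / X.shape[0])


def gaussian_kernel(u: np.ndarray | float, sigma: float, normalized: bool = True) -> np.ndarray | float:
    """kappa_sigma(u) = exp(-u^2 / (2 sigma^2)) / (sqrt(2 pi) sigma)."""
    u = np.asarray(u, dtype=float)
    scale = 1.0 / (np.sqrt(2.0 * np.pi) * sigma) if normalized else 1.0
    out = scale * np.exp(-(u ** 2) / (2.0 * sigma ** 2))
    return float(out) if out.ndim == 0 else out


def correntropy_estimate(x: np.ndarray, y: np.ndarray, sigma: float,
                         normalized: bool = True) -> float:
    """Sample correntropy: mean Gaussian kernel of the paired differences."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return float(np.mean(gaussian_kernel(x - y, sigma, normalized)))


def mcc_loss(X: np.ndarray, Y: np.ndarray, sigma: float, normalized: bool = True) -> float:
    """Correntropy objective: per-sample sum of kernel values over the m
    components, averaged over the n samples.  Maximized iff Y == X, and any
    single entry contributes at most kappa_sigma(0)/n."""
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    if X.shape != Y.shape:
        raise ValueError("X and Y must have equal shapes")
    return float(np.sum(gaussian_kernel(X - Y, sigma, normalized)) / X.shape[0])


def sparsity_penalty(hidden: np.ndarray, rho: float, beta: float) -> float:
    """beta * sum_i KL(rho || rho_hat_i) over hidden units, where rho_hat_i
    is unit i's mean activation over the batch (clamped away from 0 and 1)."""
    H = np.atleast_2d(hidden)
    rho_hat = np.clip(H.mean(axis=0), _RHO_CLAMP, 1.0 - _RHO_CLAMP)
    kl = rho * np.log(rho / rho_hat) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat))
    return float(beta * np.sum(kl))


def weight_decay(W1: np.ndarray, W2: np.ndarray, lam: float) -> float:
    """(lambda/2) * sum of squared weights, biases excluded."""
    return float(0.5 * lam * (np.sum(np.asarray(W1) ** 2) + np.sum(np.asarray(W2) ** 2)))


# ------------------------------------------------------------- full costs

def _forward(p: AEParams, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    H = encode(X, p)
    return H, decode(H, p)


def rsae_cost(p: AEParams, X: np.ndarray, c: AEConfig) -> float:
    """Robust cost -J_MCC + J_weight + J_sparse (lower is better)."""
    if c.loss_type != "mcc":
        raise ValueError("rsae_cost requires loss_type='mcc'")
    H, Y = _forward(p, np.atleast_2d(X))
    return (-mcc_loss(X, Y, c.sigma, c.kernel_normalized)
            + weight_decay(p.W1, p.W2, c.weight_decay)
            + sparsity_penalty(H, c.sparsity_target, c.sparsity_weight))


def ssae_cost(p: AEParams, X: np.ndarray, c: AEConfig) -> float:
    """Standard cost J_MSE + J_weight + J_sparse."""
    H, Y = _forward(p, np.atleast_2d(X))
    return (mse_loss(X, Y)
            + weight_decay(p.W1, p.W2, c.weight_decay)
            + sparsity_penalty(H, c.sparsity_target, c.sparsity_weight))


def autoencoder_cost(p: AEParams, X: np.ndarray, c: AEConfig) -> float:
    return rsae_cost(p, X, c) if c.loss_type == "mcc" else ssae_cost(p, X, c)


def cost_gradient(p: AEParams, X: np.ndarray, c: AEConfig) -> AEParams:
    """Analytic gradient of the selected cost, in AEParams shape.

    For the MCC loss the reconstruction error signal is reweighted by
    exp(-e^2 / (2 sigma^2)), which vanishes for outlying entries — the
    bounded-influence mechanism.  The sparsity gradient flows through the
    batch-mean activations rho_hat (zero where the clamp is active).
    """
    X = np.atleast_2d(X)
    n, d = X.shape
    H, Y = _forward(p, X)
    E = Y - X
    if c.loss_type == "mcc":
        kappa = gaussian_kernel(E, c.sigma, c.kernel_normalized)
        G_Y = (kappa * E) / (c.sigma ** 2 * n)      # d(-J_MCC)/dY
    else:
        G_Y = E / n                                  # d(J_MSE)/dY
    delta2 = G_Y * Y * (1.0 - Y)
    gW2 = delta2.T @ H + c.weight_decay * p.W2
    gb2 = delta2.sum(axis=0)

    G_H = delta2 @ p.W2
    rho_raw = H.mean(axis=0)
    rho_hat = np.clip(rho_raw, _RHO_CLAMP, 1.0 - _RHO_CLAMP)
    active = (rho_raw > _RHO_CLAMP) & (rho_raw < 1.0 - _RHO_CLAMP)
    rho = c.sparsity_target
    dkl = c.sparsity_weight * (-rho / rho_hat + (1.0 - rho) / (1.0 - rho_hat)) * active
    G_H = G_H + dkl / n
    delta1 = G_H * H * (1.0 - H)
    gW1 = delta1.T @ X + c.weight_decay * p.W1
    gb1 = delta1.sum(axis=0)
    return AEParams(W1=gW1, b1=gb1, W2=gW2, b2=gb2)


# ---------------------------------------------------------------- training

def _init_params(d_in: int, d_hidden: int, rng: np.random.Generator) -> AEParams:
    # symmetric uniform fan-in/fan-out rule, biases zero
    r1 = np.sqrt(6.0 / (d_in + d_hidden))
    return AEParams(
        W1=rng.uniform(-r1, r1, size=(d_hidden, d_in)),
        b1=np.zeros(d_hidden),
        W2=rng.uniform(-r1, r1, size=(d_in, d_hidden)),
        b2=np.zeros(d_in),
    )


def _anneal_schedule(c: AEConfig) -> list[tuple[float, int]]:
    """(sigma, max_iter) continuation stages for the MCC loss.

    A narrow kernel gives near-zero gradient to any entry whose error exceeds
    a few sigma, so cold-started optimization stalls on errors it was meant to
    shrink.  The usual cure is kernel-size continuation: start wide (where
    correntropy is Taylor-equivalent to a quadratic loss), warm-start each
    halving of sigma from the previous solution, and finish at the target.
    The objective finally minimized is exactly the target-sigma cost.
    """
    if c.loss_type != "mcc" or c.anneal_start <= c.sigma:
        return [(c.sigma, c.max_iter)]
    sigmas = []
    s = c.anneal_start
    while s > c.sigma * 1.0001:
        sigmas.append(s)
        s /= 2.0
    warm_iters = max(25, c.max_iter // 8)
    return [(s, warm_iters) for s in sigmas] + [(c.sigma, c.max_iter)]


def train_autoencoder(X: np.ndarray, c: AEConfig, hidden_size: int) -> AEParams:
    """Fit one autoencoder on rows of X (values in [0, 1]) by deterministic
    full-batch L-BFGS on the selected cost; seeds control only the
    initialization.  The MCC loss is optimized by kernel-size continuation
    (see :func:`_anneal_schedule`); the final stage minimizes the cost at
    the configured sigma."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    rng = np.random.default_rng(c.seed)
    theta = _init_params(d, hidden_size, rng).flatten()

    for sigma_k, iters in _anneal_schedule(c):
        c_k = replace(c, sigma=sigma_k)

        def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
            p = AEParams.unflatten(theta, d, hidden_size)
            cost = autoencoder_cost(p, X, c_k)
            if not np.isfinite(cost):
                raise FloatingPointError("non-finite autoencoder cost during optimization")
            return cost, cost_gradient(p, X, c_k).flatten()

        res = minimize(objective, theta, jac=True, method="L-BFGS-B",
                       options={"maxiter": iters, "gtol": 1e-6, "ftol": 1e-12,
                                "maxcor": 20})
        if not np.all(np.isfinite(res.x)):
            raise FloatingPointError(f"optimizer returned non-finite parameters (nit={res.nit})")
        theta = res.x
    return AEParams.unflatten(theta, d, hidden_size)


@dataclass
class StackedNet:
    """Stacked encoder halves with a 2-class softmax head."""

    encoder_layers: list[tuple[np.ndarray, np.ndarray]]  # [(W, b), ...]
    softmax_W: np.ndarray                                # K x s_top
    softmax_b: np.ndarray                                # K

    @property
    def layer_sizes(self) -> list[int]:
        sizes = [self.encoder_layers[0][0].shape[1]]
        sizes += [W.shape[0] for W, _ in self.encoder_layers]
        return sizes

    @property
    def n_classes(self) -> int:
        return self.softmax_W.shape[0]


def extract_features(net: StackedNet, X: np.ndarray, depth: int | None = None) -> np.ndarray:
    """Forward pass to encoder layer ``depth`` (0 = input itself; default =
    top of the stack, the compact q-dimensional feature)."""
    A = np.atleast_2d(np.asarray(X, dtype=float))
    if depth is None:
        depth = len(net.encoder_layers)
    if not (0 <= depth <= len(net.encoder_layers)):
        raise ValueError(f"depth must be in [0, {len(net.encoder_layers)}]")
    for W, b in net.encoder_layers[:depth]:
        A = sigmoid(A @ W.T + b)
    return A


def pretrain_stack(X: np.ndarray, layer_sizes: Sequence[int], c: AEConfig) -> StackedNet:
    """Layer-wise unsupervised pretraining: train an autoencoder per stage,
    keep its encoder half, feed its hidden activations to the next stage.
    The softmax head starts at zero (uniform posteriors) for later training.
    """
    layer_sizes = list(layer_sizes)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != layer_sizes[0]:
        raise ValueError(f"X has {X.shape[1]} features but layer_sizes[0]={layer_sizes[0]}")
    encoders: list[tuple[np.ndarray, np.ndarray]] = []
    A = X
    for stage, (d_in, d_hidden) in enumerate(zip(layer_sizes, layer_sizes[1:])):
        stage_cfg = replace(c, seed=int(np.random.SeedSequence([c.seed, stage]).generate_state(1)[0] % 2**31))
        p = train_autoencoder(A, stage_cfg, d_hidden)
        encoders.append((p.W1, p.b1))
        A = encode(A, p)
    s_top = layer_sizes[-1]
    return StackedNet(encoder_layers=encoders,
                      softmax_W=np.zeros((2, s_top)), softmax_b=np.zeros(2))


# ------------------------------------------------------- softmax + fine-tune

def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    e = np.exp(Z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_predict_proba(net: StackedNet, X: np.ndarray) -> np.ndarray:
    """Class posteriors, one row per sample, rows summing to 1.
    Column 0 = nonseizure, column 1 = seizure."""
    F = extract_features(net, X)
    return _softmax(F @ net.softmax_W.T + net.softmax_b)


def predict(net: StackedNet, X: np.ndarray) -> np.ndarray:
    """Argmax labels (0 = nonseizure, 1 = seizure); exact posterior ties go
    to nonseizure — the conservative alarm policy."""
    return np.argmax(softmax_predict_proba(net, X), axis=1)


def _net_flatten(net: StackedNet) -> np.ndarray:
    parts = []
    for W, b in net.encoder_layers:
        parts += [W.ravel(), b]
    parts += [net.softmax_W.ravel(), net.softmax_b]
    return np.concatenate(parts)


def _net_unflatten(theta: np.ndarray, template: StackedNet) -> StackedNet:
    layers = []
    i = 0
    for W, b in template.encoder_layers:
        layers.append((theta[i:i + W.size].reshape(W.shape), theta[i + W.size:i + W.size + b.size]))
        i += W.size + b.size
    sw = template.softmax_W
    W = theta[i:i + sw.size].reshape(sw.shape)
    i += sw.size
    b = theta[i:i + template.softmax_b.size]
    return StackedNet(encoder_layers=layers, softmax_W=W, softmax_b=b)


def finetune_objective(net: StackedNet, X: np.ndarray, labels: np.ndarray,
                       lam: float) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy plus L2 decay over all weight matrices
    (encoder and softmax; biases excluded), with its analytic gradient in
    the flattened parameter order."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels, dtype=int)
    n = X.shape[0]
    acts = [X]
    A = X
    for W, b in net.encoder_layers:
        A = sigmoid(A @ W.T + b)
        acts.append(A)
    P = _softmax(A @ net.softmax_W.T + net.softmax_b)
    eps = 1e-300
    ce = -float(np.mean(np.log(P[np.arange(n), y] + eps)))
    decay = 0.5 * lam * (sum(np.sum(W ** 2) for W, _ in net.encoder_layers)
                         + np.sum(net.softmax_W ** 2))
    cost = ce + decay

    T = np.zeros_like(P)
    T[np.arange(n), y] = 1.0
    delta = (P - T) / n
    g_sw = delta.T @ acts[-1] + lam * net.softmax_W
    g_sb = delta.sum(axis=0)
    grads: list[tuple[np.ndarray, np.ndarray]] = []
    G = delta @ net.softmax_W
    for k in range(len(net.encoder_layers) - 1, -1, -1):
        W, _ = net.encoder_layers[k]
        A = acts[k + 1]
        d_k = G * A * (1.0 - A)
        grads.append((d_k.T @ acts[k] + lam * W, d_k.sum(axis=0)))
        G = d_k @ W
    grads.reverse()
    flat = []
    for gW, gb in grads:
        flat += [gW.ravel(), gb]
    flat += [g_sw.ravel(), g_sb]
    return cost, np.concatenate(flat)


def _minimize_net(net: StackedNet, X: np.ndarray, labels: np.ndarray, lam: float,
                  max_iter: int, train_mask: np.ndarray | None = None) -> StackedNet:
    theta0 = _net_flatten(net)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        cand = _net_unflatten(theta, net)
        cost, grad = finetune_objective(cand, X, labels, lam)
        if not np.isfinite(cost):
            raise FloatingPointError("non-finite fine-tuning cost")
        if train_mask is not None:
            grad = grad * train_mask
        return cost, grad

    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": 1e-6, "ftol": 1e-12,
                            "maxcor": 20})
    return _net_unflatten(res.x, net)


def train_softmax(net: StackedNet, X: np.ndarray, labels: np.ndarray,
                  c: AEConfig, max_iter: int | None = None) -> StackedNet:
    """Train only the softmax head on the (frozen) top-layer features —
    the classifier used to measure performance *before* fine-tuning."""
    mask = np.concatenate([np.zeros(W.size + b.size) for W, b in net.encoder_layers]
                          + [np.ones(net.softmax_W.size + net.softmax_b.size)])
    return _minimize_net(net, X, labels, c.weight_decay,
                         max_iter if max_iter is not None else c.max_iter, mask)


def fine_tune(net: StackedNet, X: np.ndarray, labels: np.ndarray,
              c: AEConfig, max_iter: int | None = None) -> StackedNet:
    """Supervised joint optimization of every parameter (encoders + softmax)
    by full-batch L-BFGS on cross-entropy + weight decay.  Sparsity is a
    pretraining device and is not applied here.  Returns an updated copy."""
    return _minimize_net(net, X, labels, c.weight_decay,
                         max_iter if max_iter is not None else c.max_iter)


# ------------------------------------------------------------ serialization

_FORMAT_VERSION = 1


def save_model(path: str | Path, net: StackedNet, config: AEConfig,
               extra: dict | None = None) -> None:
    """Serialize a trained network (plus its config and any extra metadata,
    e.g. scaler parameters and selected band) as structured JSON text."""
    doc = {
        "format_version": _FORMAT_VERSION,
        "layer_sizes": net.layer_sizes,
        "encoder_layers": [{"W": W.tolist(), "b": b.tolist()} for W, b in net.encoder_layers],
        "softmax": {"W": net.softmax_W.tolist(), "b": net.softmax_b.tolist()},
        "config": {k: v for k, v in vars(config).items()},
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> tuple[StackedNet, AEConfig, dict]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')}")
    layers = [(np.array(l["W"]), np.array(l["b"])) for l in doc["encoder_layers"]]
    net = StackedNet(encoder_layers=layers,
                     softmax_W=np.array(doc["softmax"]["W"]),
                     softmax_b=np.array(doc["softmax"]["b"]))
    cfg = AEConfig(**doc["config"])
    return net, cfg, doc["extra"]
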