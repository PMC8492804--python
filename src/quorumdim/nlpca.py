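"""Hierarchical nonlinear PCA via an autoassociative bottleneck network.

A d:h:n:h:d autoencoder (d = 20 histogram bins, h = 10 hidden units by
default, n bottleneck components) is fit to the embedded histogram vectors.
Hidden layers use tanh; the bottleneck and output are linear.  Hierarchy is
enforced by component masking: the training loss sums, over k = 0..n, the
reconstruction error obtained when only the first k bottleneck units are
active (the rest zeroed), so the first k components always form the best
k-dimensional representation and do not change as n grows (the k = 0 term
anchors the decoder's constant at the data center).  A weight-decay
penalty (coefficient 0.001 by default) regularizes the weights.

The data are centered and globally rms-scaled before training so that the
decay coefficient has a data-independent relative strength; explained
variance is reported in the original embedded space and is invariant to this
scaling.

Training is full-batch L-BFGS from multiple random initializations (the
restart with the lowest loss wins); everything is deterministic given the
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .embed import HistogramPoint, points_to_matrix
from .errors import InsufficientDataError, ZeroVarianceError

DEFAULT_HIDDEN = 10
DEFAULT_WEIGHT_DECAY = 1e-3
DEFAULT_RESTARTS = 20
DEFAULT_MAX_ITER = 1500


@dataclass
class NlpcaModel:
    layer_sizes: tuple                  # (d, h, n, h, d)
    n_components: int
    weights: dict                       # W1,b1,W2,b2,W3,b3,W4,b4
    weight_decay: float
    restarts: int
    best_loss: float
    seed: int
    mean_q: np.ndarray
    scale: float
    activation: str
    converged: bool
    restart_losses: list = field(default_factory=list)
    condition_ids: tuple = ()


def _act(x, kind):
    return np.tanh(x) if kind == "tanh" else x


def _act_deriv_from_out(a, kind):
    return 1.0 - a**2 if kind == "tanh" else np.ones_like(a)


def _shapes(d, h, n):
    return {
        "W1": (h, d), "b1": (h,),
        "W2": (n, h), "b2": (n,),
        "W3": (h, n), "b3": (h,),
        "W4": (d, h), "b4": (d,),
    }


def _pack(params, shapes):
    return np.concatenate([params[k].ravel() for k in shapes])


def _unpack(theta, shapes):
    params, i = {}, 0
    for k, shp in shapes.items():
        size = int(np.prod(shp))
        params[k] = theta[i : i + size].reshape(shp)
        i += size
    return params


def _loss_grad(theta, X, shapes, n, wd, kind):
    """Hierarchical loss and analytic gradient, full batch.

    Loss = sum_{k=0..n} mean((Y_k - X)^2) + wd * sum(W^2), biases undecayed.
    Y_k is the reconstruction with bottleneck units k+1..n zeroed.  The k=0
    term anchors the decoder's constant (the zero-component reconstruction)
    at the data center, the best zero-dimensional representation; it reaches
    the encoder through no gradient path.
    """
    P = _unpack(theta, shapes)
    W1, b1, W2, b2 = P["W1"], P["b1"], P["W2"], P["b2"]
    W3, b3, W4, b4 = P["W3"], P["b3"], P["W4"], P["b4"]
    N, d = X.shape

    A1 = _act(X @ W1.T + b1, kind)
    Z = A1 @ W2.T + b2

    loss = 0.0
    g = {k: np.zeros(shp) for k, shp in shapes.items()}
    dZ = np.zeros_like(Z)
    norm = 1.0 / (N * d)
    for k in range(0, n + 1):
        Zk = Z.copy()
        Zk[:, k:] = 0.0
        A3 = _act(Zk @ W3.T + b3, kind)
        Y = A3 @ W4.T + b4
        R = Y - X
        loss += norm * float((R**2).sum())
        dY = 2.0 * norm * R
        g["W4"] += dY.T @ A3
        g["b4"] += dY.sum(axis=0)
        dS3 = (dY @ W4) * _act_deriv_from_out(A3, kind)
        g["W3"] += dS3.T @ Zk
        g["b3"] += dS3.sum(axis=0)
        dZk = dS3 @ W3
        dZk[:, k:] = 0.0
        dZ += dZk

    g["W2"] += dZ.T @ A1
    g["b2"] += dZ.sum(axis=0)
    dS1 = (dZ @ W2) * _act_deriv_from_out(A1, kind)
    g["W1"] += dS1.T @ X
    g["b1"] += dS1.sum(axis=0)

    for w in ("W1", "W2", "W3", "W4"):
        loss += wd * float((P[w] ** 2).sum())
        g[w] += 2.0 * wd * P[w]
    return loss, _pack(g, shapes)


def _init(rng, shapes):
    params = {}
    for k, shp in shapes.items():
        if k.startswith("W"):
            fan_in = shp[1]
            params[k] = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shp)
        else:
            params[k] = np.zeros(shp)
    return params


def fit_nlpca(
    points: Sequence[HistogramPoint],
    n_components: int,
    hidden: int = DEFAULT_HIDDEN,
    weight_decay: float = DEFAULT_WEIGHT_DECAY,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    activation: str = "tanh",
) -> NlpcaModel:
    """Fit the bottleneck network; best of ``restarts`` initializations wins."""
    if not 1 <= n_components <= 5:
        raise ValueError("n_components must be in 1..5")
    if activation not in ("tanh", "linear"):
        raise ValueError("activation must be 'tanh' or 'linear'")
    points = list(points)
    if len(points) < 10:
        raise InsufficientDataError(f"need >= 10 points, got {len(points)}")
    Q = points_to_matrix(points)
    d = Q.shape[1]
    mean_q = Q.mean(axis=0)
    Xc = Q - mean_q
    scale = float(np.sqrt((Xc**2).mean()))
    if scale < 1e-12:
        raise ZeroVarianceError("all histogram points are identical")
    X = Xc / scale

    shapes = _shapes(d, hidden, n_components)
    best = None
    losses = []
    for r in range(restarts):
        rng = np.random.default_rng((seed * 100003 + r) % (2**31))
        theta0 = _pack(_init(rng, shapes), shapes)
        res = minimize(
            _loss_grad,
            theta0,
            args=(X, shapes, n_components, weight_decay, activation),
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10},
        )
        losses.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if not best.success and "ABNORMAL" in str(best.message):
        warnings.warn(f"NLPCA optimizer did not converge cleanly: {best.message}")

    return NlpcaModel(
        layer_sizes=(d, hidden, n_components, hidden, d),
        n_components=n_components,
        weights=_unpack(best.x, shapes),
        weight_decay=weight_decay,
        restarts=restarts,
        best_loss=float(best.fun),
        seed=seed,
        mean_q=mean_q,
        scale=scale,
        activation=activation,
        converged=bool(best.success),
        restart_losses=losses,
        condition_ids=tuple(p.condition_id for p in points),
    )


def save_model(model: NlpcaModel, path) -> None:
    """Serialize a fitted model as JSON (weights, seed, loss trace)."""
    import json

    payload = {
        "layer_sizes": list(model.layer_sizes),
        "n_components": model.n_components,
        "weights": {k: v.tolist() for k, v in model.weights.items()},
        "weight_decay": model.weight_decay,
        "restarts": model.restarts,
        "best_loss": model.best_loss,
        "seed": model.seed,
        "mean_q": model.mean_q.tolist(),
        "scale": model.scale,
        "activation": model.activation,
        "converged": model.converged,
        "restart_losses": model.restart_losses,
        "condition_ids": list(model.condition_ids),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> NlpcaModel:
    """Load a model serialized by :func:`save_model`."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    return NlpcaModel(
        layer_sizes=tuple(payload["layer_sizes"]),
        n_components=payload["n_components"],
        weights={k: np.asarray(v) for k, v in payload["weights"].items()},
        weight_decay=payload["weight_decay"],
        restarts=payload["restarts"],
        best_loss=payload["best_loss"],
        seed=payload["seed"],
        mean_q=np.asarray(payload["mean_q"]),
        scale=payload["scale"],
        activation=payload["activation"],
        converged=payload["converged"],
        restart_losses=payload["restart_losses"],
        condition_ids=tuple(payload["condition_ids"]),
    )


def _as_q_matrix(points_or_q) -> np.ndarray:
    if isinstance(points_or_q, HistogramPoint):
        return points_or_q.q[None, :]
    if isinstance(points_or_q, np.ndarray):
        return np.atleast_2d(points_or_q)
    return points_to_matrix(list(points_or_q))


def encode(model: NlpcaModel, points_or_q) -> np.ndarray:
    """Latent coordinates (n_components,) per point."""
    Q = _as_q_matrix(points_or_q)
    X = (Q - model.mean_q) / model.scale
    W = model.weights
    A1 = _act(X @ W["W1"].T + W["b1"], model.activation)
    Z = A1 @ W["W2"].T + W["b2"]
    return Z[0] if Z.shape[0] == 1 and not _is_collection(points_or_q) else Z


def _is_collection(x) -> bool:
    if isinstance(x, HistogramPoint):
        return False
    if isinstance(x, np.ndarray):
        return x.ndim == 2
    return True


def decode(model: NlpcaModel, latent) -> np.ndarray:
    """Map latent coordinates back to embedded (q-space) vectors.

    Output is in the original embedded space but is not constrained to the
    unit sphere; renormalize before computing spherical distances.
    """
    Z = np.atleast_2d(np.asarray(latent, dtype=float))
    if Z.shape[1] != model.n_components:
        raise ValueError(f"latent must have {model.n_components} entries")
    W = model.weights
    A3 = _act(Z @ W["W3"].T + W["b3"], model.activation)
    Y = A3 @ W["W4"].T + W["b4"]
    out = Y * model.scale + model.mean_q
    return out[0] if np.asarray(latent).ndim == 1 else out


def reconstruct(model: NlpcaModel, points_or_q, k: int | None = None) -> np.ndarray:
    """Rank-k reconstruction (first k bottleneck units; k=0 gives the baseline)."""
    if k is None:
        k = model.n_components
    if not 0 <= k <= model.n_components:
        raise ValueError(f"k={k} out of range 0..{model.n_components}")
    Q = _as_q_matrix(points_or_q)
    Z = np.atleast_2d(encode(model, Q))
    Z[:, k:] = 0.0
    return decode(model, Z)


def explained_variance(model: NlpcaModel, points, k: int | None = None) -> float:
    """1 - SSE(rank-k reconstruction) / total centered variance of q."""
    Q = _as_q_matrix(points)
    recon = np.atleast_2d(reconstruct(model, Q, k))
    ss_tot = float(((Q - Q.mean(axis=0)) ** 2).sum())
    sse = float(((Q - recon) ** 2).sum())
    return 1.0 - sse / ss_tot
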