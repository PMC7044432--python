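"""Feed-forward neural-network inverse model for Z-spectrum quantification.

A fully connected multilayer perceptron maps the intensities of one
Z-spectrum to the quantifiable parameters (concentration, exchange
rate, B0 and optionally B1).  Hidden layers use the hyperbolic-tangent
sigmoid (the standard sigmoid transfer of feed-forward regression
toolboxes; its zero-centered output keeps gradients alive through deep
stacks, which the logistic variant does not at seven layers), the
output layer is linear, and inputs/outputs are normalized to [-1, 1].  Training follows the scaled-conjugate-gradient (SCG)
backpropagation algorithm of Moller (1993) in full batch, minimizing a
regularized performance function

    performance = gamma * msw + (1 - gamma) * mse

where ``mse`` is the mean squared normalized error on the training
split and ``msw`` the mean of squares of all weights and biases.
Early stopping monitors the validation split: training halts after a
configurable number of consecutive epochs without a new best
validation error, and the best-validation weights are returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .datagen import TrainingSet

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "NormalizationBounds",
    "TrainedNetwork",
    "TrainingReport",
    "normalize",
    "denormalize",
    "performance",
    "train_network",
    "depth_sweep",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the regressor."""

    n_hidden_layers: int = 7
    hidden_width: int = 10
    #: "tanh" (tangent sigmoid, default) or "logistic"
    hidden_activation: str = "tanh"
    output_activation: str = "linear"

    def __post_init__(self):
        if self.n_hidden_layers < 1 or self.hidden_width < 1:
            raise ValueError("n_hidden_layers and hidden_width must be >= 1")
        if self.hidden_activation not in ("tanh", "logistic"):
            raise ValueError("hidden_activation must be 'tanh' or 'logistic'")
        if self.output_activation != "linear":
            raise ValueError("only a linear output layer is supported")

    def layer_sizes(self, n_in: int, n_out: int) -> list[int]:
        return [n_in] + [self.hidden_width] * self.n_hidden_layers + [n_out]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol for :func:`train_network`."""

    train_frac: float = 0.80
    val_frac: float = 0.15
    test_frac: float = 0.05
    patience: int = 40
    gamma: float = 0.01
    gradient_tol: float = 1e-7
    val_mse_tol: float = 1e-4
    max_epochs: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


@dataclass
class NormalizationBounds:
    """Per-dimension [lo, hi] pairs mapped linearly onto [-1, 1]."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if self.lo.shape != self.hi.shape:
            raise ValueError("lo and hi must have the same shape")
        if np.any(self.lo >= self.hi):
            raise ValueError("each bound must satisfy lo < hi")


def normalize(values, bounds: NormalizationBounds):
    """Affine map of each dimension from [lo, hi] onto [-1, 1]."""
    v = np.asarray(values, dtype=float)
    return 2.0 * (v - bounds.lo) / (bounds.hi - bounds.lo) - 1.0


def denormalize(values, bounds: NormalizationBounds):
    """Inverse of :func:`normalize`."""
    v = np.asarray(values, dtype=float)
    return bounds.lo + (v + 1.0) * (bounds.hi - bounds.lo) / 2.0


def performance(mse: float, msw: float, gamma: float) -> float:
    """Regularized training objective gamma*msw + (1-gamma)*mse."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if mse < 0 or msw < 0:
        raise ValueError("mse and msw must be >= 0")
    return gamma * msw + (1.0 - gamma) * mse


# ---------------------------------------------------------------------------
# Parameter vector <-> layer matrices
# ---------------------------------------------------------------------------


def _shapes(sizes: Sequence[int]):
    return [((sizes[i + 1], sizes[i]), (sizes[i + 1],)) for i in range(len(sizes) - 1)]


def _unpack(theta: np.ndarray, sizes: Sequence[int]):
    out, pos = [], 0
    for (ws, bs) in _shapes(sizes):
        nw, nb = ws[0] * ws[1], bs[0]
        W = theta[pos : pos + nw].reshape(ws)
        b = theta[pos + nw : pos + nw + nb]
        out.append((W, b))
        pos += nw + nb
    return out


def _pack(layers) -> np.ndarray:
    return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in layers])


def _init_theta(sizes: Sequence[int], rng: np.random.Generator) -> np.ndarray:
    """Nguyen-Widrow initialization for the sigmoid layers.

    Assumes inputs normalized to [-1, 1]; spreads the active regions of
    the units across the input range.  The linear output layer gets
    small uniform weights.
    """
    layers = []
    n_layers = len(sizes) - 1
    for li in range(n_layers):
        n_in, n_out = sizes[li], sizes[li + 1]
        if li < n_layers - 1:
            beta = 0.7 * n_out ** (1.0 / n_in)
            W = rng.uniform(-1.0, 1.0, size=(n_out, n_in))
            W *= beta / np.linalg.norm(W, axis=1, keepdims=True)
            b = beta * np.linspace(-1.0, 1.0, n_out) * np.sign(W[:, 0])
        else:
            lim = 1.0 / np.sqrt(n_in)
            W = rng.uniform(-lim, lim, size=(n_out, n_in))
            b = np.zeros(n_out)
        layers.append((W, b))
    return _pack(layers)


def _activate(x, act):
    if act == "tanh":
        return np.tanh(x)
    return 1.0 / (1.0 + np.exp(-x))


def _act_deriv(a, act):
    # derivative expressed through the activation value itself
    if act == "tanh":
        return 1.0 - a**2
    return a * (1.0 - a)


def _forward(theta, sizes, X, act="tanh"):
    a = X
    layers = _unpack(theta, sizes)
    for W, b in layers[:-1]:
        a = _activate(a @ W.T + b, act)
    W, b = layers[-1]
    return a @ W.T + b


def _loss_and_grad(theta, sizes, X, T, gamma, act="tanh", need_grad=True):
    """Performance value and its gradient by backpropagation."""
    layers = _unpack(theta, sizes)
    acts = [X]
    a = X
    for W, b in layers[:-1]:
        a = _activate(a @ W.T + b, act)
        acts.append(a)
    W, b = layers[-1]
    out = a @ W.T + b
    err = out - T
    n, k = T.shape
    mse = float(np.mean(err**2))
    msw = float(np.mean(theta**2))
    perf = gamma * msw + (1.0 - gamma) * mse
    if not need_grad:
        return perf, None, mse, msw
    grads = [None] * len(layers)
    delta = (2.0 * (1.0 - gamma) / (n * k)) * err
    for li in range(len(layers) - 1, -1, -1):
        W, b = layers[li]
        gW = delta.T @ acts[li]
        gb = delta.sum(axis=0)
        grads[li] = (gW, gb)
        if li > 0:
            delta = (delta @ W) * _act_deriv(acts[li], act)
    g = _pack(grads) + (2.0 * gamma / theta.size) * theta
    return perf, g, mse, msw


# ---------------------------------------------------------------------------
# Scaled conjugate gradient (Moller 1993)
# ---------------------------------------------------------------------------


def _scg_minimize(theta, fg, on_epoch, max_epochs, gradient_tol):
    """Full-batch SCG; calls ``on_epoch(epoch, theta, perf)`` after each
    accepted step and stops when it returns a reason string."""
    sigma0 = 5e-5
    lam, lam_bar = 5e-7, 0.0
    n_par = theta.size
    f_w, grad, *_ = fg(theta)
    r = -grad
    p = r.copy()
    success = True
    delta = 1.0
    for epoch in range(1, max_epochs + 1):
        if np.max(np.abs(grad)) < gradient_tol:
            return theta, epoch - 1, "gradient"
        p2 = float(p @ p)
        if p2 == 0.0:
            return theta, epoch - 1, "gradient"
        if success:
            sigma = sigma0 / np.sqrt(p2)
            _, g_sig, *_ = fg(theta + sigma * p)
            s = (g_sig - grad) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * p2
        if delta <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta / p2)
            delta = -delta + lam * p2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, g_new, *_ = fg(theta + alpha * p)
        comp = 2.0 * delta * (f_w - f_new) / mu**2
        if comp >= 0:  # successful step
            theta = theta + alpha * p
            f_w, grad = f_new, g_new
            r_new = -grad
            lam_bar = 0.0
            success = True
            if epoch % n_par == 0:
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            if comp >= 0.75:
                lam *= 0.25
            r = r_new
            reason = on_epoch(epoch, theta, f_w)
            if reason:
                return theta, epoch, reason
        else:
            lam_bar = lam
            success = False
        if comp < 0.25:
            lam += delta * (1.0 - comp) / p2
        if lam > 1e25:  # trust region collapsed; no further progress possible
            return theta, epoch, "gradient"
    return theta, max_epochs, "max_epochs"


# ---------------------------------------------------------------------------
# Public training API
# ---------------------------------------------------------------------------


@dataclass
class TrainingReport:
    epochs: int
    stop_reason: str  # patience | gradient | val_mse | max_epochs
    final_mse: float
    final_msw: float
    final_performance: float
    best_val_mse: float
    val_r: dict[str, float]


@dataclass
class TrainedNetwork:
    """A trained regressor with its normalization and provenance."""

    spec: NetworkSpec
    sizes: list[int]
    theta: np.ndarray
    input_bounds: NormalizationBounds
    output_bounds: NormalizationBounds
    label_names: list[str]
    provenance: dict = field(default_factory=dict)

    def predict(self, spectra) -> np.ndarray:
        """Forward pass over one or many spectra (rows), denormalized.

        ``spectra`` may be a 1-D intensity vector or an (n, n_offsets)
        array; the output has matching leading shape.
        """
        X = np.asarray(spectra, dtype=float)
        one = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.sizes[0]:
            raise ValueError(
                f"spectrum length {X.shape[1]} does not match network input "
                f"size {self.sizes[0]}; resample onto the training grid first"
            )
        Yn = _forward(self.theta, self.sizes, normalize(X, self.input_bounds), self.spec.hidden_activation)
        Y = denormalize(Yn, self.output_bounds)
        return Y[0] if one else Y

    def to_json(self) -> str:
        d = {
            "schema_version": 1,
            "spec": asdict(self.spec),
            "sizes": self.sizes,
            "theta": self.theta.tolist(),
            "input_bounds": {"lo": self.input_bounds.lo.tolist(), "hi": self.input_bounds.hi.tolist()},
            "output_bounds": {"lo": self.output_bounds.lo.tolist(), "hi": self.output_bounds.hi.tolist()},
            "label_names": self.label_names,
            "provenance": self.provenance,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "TrainedNetwork":
        d = json.loads(text)
        return cls(
            spec=NetworkSpec(**d["spec"]),
            sizes=list(d["sizes"]),
            theta=np.asarray(d["theta"], dtype=float),
            input_bounds=NormalizationBounds(**{k: np.asarray(v) for k, v in d["input_bounds"].items()}),
            output_bounds=NormalizationBounds(**{k: np.asarray(v) for k, v in d["output_bounds"].items()}),
            label_names=list(d["label_names"]),
            provenance=d.get("provenance", {}),
        )

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TrainedNetwork":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _output_bounds_from(data: TrainingSet) -> NormalizationBounds:
    """Output bounds from the generating label ranges when available.

    Using configured ranges rather than the empirical min/max keeps the
    output map stable across datasets and lets predictions exceed the
    training range gracefully.
    """
    ranges = data.provenance.get("ranges", {})
    lo, hi = [], []
    for i, name in enumerate(data.label_names):
        if name in ranges and ranges[name][0] < ranges[name][1]:
            lo.append(ranges[name][0])
            hi.append(ranges[name][1])
        else:
            col = data.Y[:, i]
            a, b = float(col.min()), float(col.max())
            if a == b:
                a, b = a - 0.5, b + 0.5
            lo.append(a)
            hi.append(b)
    return NormalizationBounds(np.array(lo), np.array(hi))


def train_network(
    data: TrainingSet,
    spec: NetworkSpec = NetworkSpec(),
    cfg: TrainingConfig = TrainingConfig(),
) -> tuple[TrainedNetwork, TrainingReport]:
    """Train the inverse model on an annotated dataset.

    The dataset is split at random (seeded) into training, validation
    and test subsets; full-batch SCG minimizes the regularized
    performance function on the training split; early stopping watches
    the validation split and the weights with the lowest validation
    error ever seen are the ones returned.
    """
    n = len(data)
    if n < 10:
        raise ValueError("dataset too small to split")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_tr = int(round(cfg.train_frac * n))
    n_val = int(round(cfg.val_frac * n))
    idx_tr, idx_val = perm[:n_tr], perm[n_tr : n_tr + n_val]
    idx_test = perm[n_tr + n_val :]

    in_b = NormalizationBounds(data.X.min(axis=0), data.X.max(axis=0))
    out_b = _output_bounds_from(data)
    Xn = normalize(data.X, in_b)
    Tn = normalize(data.Y, out_b)
    Xtr, Ttr = Xn[idx_tr], Tn[idx_tr]
    Xval, Tval = Xn[idx_val], Tn[idx_val]

    sizes = spec.layer_sizes(data.X.shape[1], data.Y.shape[1])
    theta0 = _init_theta(sizes, rng)

    act = spec.hidden_activation

    def fg(th):
        return _loss_and_grad(th, sizes, Xtr, Ttr, cfg.gamma, act)

    state = {"best_val": np.inf, "best_theta": theta0.copy(), "since_best": 0}

    def on_epoch(epoch, th, perf):
        val_pred = _forward(th, sizes, Xval, act)
        val_mse = float(np.mean((val_pred - Tval) ** 2))
        if val_mse < state["best_val"]:
            state["best_val"] = val_mse
            state["best_theta"] = th.copy()
            state["since_best"] = 0
        else:
            state["since_best"] += 1
        if val_mse < cfg.val_mse_tol:
            return "val_mse"
        if state["since_best"] >= cfg.patience:
            return "patience"
        return None

    theta, epochs, reason = _scg_minimize(
        theta0, fg, on_epoch, cfg.max_epochs, cfg.gradient_tol
    )
    theta = state["best_theta"]  # best validation weights, never the last iterate

    perf, _, mse, msw = _loss_and_grad(theta, sizes, Xtr, Ttr, cfg.gamma, act, need_grad=False)
    val_pred = _forward(theta, sizes, Xval, act)
    val_r = {}
    for i, name in enumerate(data.label_names):
        # R undefined for degenerate splits or constant columns
        if len(idx_val) > 2 and np.std(val_pred[:, i]) > 0 and np.std(Tval[:, i]) > 0:
            v = np.corrcoef(val_pred[:, i], Tval[:, i])[0, 1]
        else:
            v = np.nan
        val_r[name] = float(v)
    report = TrainingReport(
        epochs=epochs,
        stop_reason=reason,
        final_mse=mse,
        final_msw=msw,
        final_performance=perf,
        best_val_mse=state["best_val"],
        val_r=val_r,
    )
    net = TrainedNetwork(
        spec=spec,
        sizes=sizes,
        theta=theta,
        input_bounds=in_b,
        output_bounds=out_b,
        label_names=list(data.label_names),
        provenance={
            "dataset": data.provenance,
            "seed": cfg.seed,
            "stop_reason": reason,
            "epochs": epochs,
        },
    )
    return net, report


def depth_sweep(
    data: TrainingSet,
    depths: Sequence[int],
    repeats: int = 5,
    spec: NetworkSpec = NetworkSpec(),
    cfg: TrainingConfig = TrainingConfig(),
) -> pd.DataFrame:
    """Performance of independently trained networks per hidden-layer count.

    Each (depth, repeat) pair is trained from a distinct seed; the
    summary reports mean and standard deviation of the final
    performance-function value per depth.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    rows = []
    for depth in depths:
        perfs = []
        for rep in range(repeats):
            s = NetworkSpec(depth, spec.hidden_width, spec.hidden_activation)
            c = TrainingConfig(
                train_frac=cfg.train_frac,
                val_frac=cfg.val_frac,
                test_frac=cfg.test_frac,
                patience=cfg.patience,
                gamma=cfg.gamma,
                gradient_tol=cfg.gradient_tol,
                val_mse_tol=cfg.val_mse_tol,
                max_epochs=cfg.max_epochs,
                seed=cfg.seed + 1000 * depth + rep,
            )
            try:
                _, rep_report = train_network(data, s, c)
            except Exception as exc:
                raise RuntimeError(f"training failed at depth={depth}, repeat={rep}") from exc
            perfs.append(rep_report.final_performance)
        rows.append(
            {
                "depth": depth,
                "mean_performance": float(np.mean(perfs)),
                "sd_performance": float(np.std(perfs, ddof=1)),
                "performances": perfs,
            }
        )
    return pd.DataFrame(rows)
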