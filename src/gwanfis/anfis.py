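"""First-order Sugeno adaptive neuro-fuzzy inference system (ANFIS).

The model is the classic five-layer network:

1. fuzzification -- each input x_j is graded by a generalized bell membership
   function mu(x) = 1 / (1 + |(x - c)/a|^(2b)) per rule;
2. rule firing -- w_i = product over inputs of the rule's memberships;
3. normalization -- w_bar_i = w_i / sum_j w_j (always sums to 1);
4. linear consequents -- f_i = p_i . x + r_i, weighted by w_bar_i;
5. summation -- f = sum_i w_bar_i f_i.

Rule antecedents are generated by scatter partitioning: seeded k-means on the
training rows gives one cluster per rule; membership centers are the cluster
centroids and widths the per-dimension cluster spread.  Grid partitioning is
deliberately avoided -- with tens of selected genes the grid explodes
combinatorially.

Binary classification is posed as 0/1 regression on the single Sugeno output
with a 0.5 decision threshold; consequent parameters have a closed-form
least-squares fit given fixed antecedents.

Firing strengths are computed in the log domain: a rule's strength is a
product of up to hundreds of membership degrees, which underflows in linear
space long before the normalized strengths become ill-defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .exceptions import (
    DegenerateActivationError,
    DimensionMismatchError,
    InvalidConfigError,
)

__all__ = [
    "BellMF",
    "FuzzyRule",
    "ANFISModel",
    "bell_membership",
    "firing_strengths",
    "normalize_strengths",
    "forward",
    "predict_f",
    "predict_label",
    "init_model",
    "fit_consequents_ls",
    "save_model",
    "load_model",
]

_MIN_WIDTH = 1e-3


@dataclass(frozen=True)
class BellMF:
    """Generalized bell membership function with width a, shape b, center c."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InvalidConfigError("bell width a must be positive")
        if self.b <= 0:
            raise InvalidConfigError("bell shape b must be positive")


@dataclass
class FuzzyRule:
    """One Sugeno rule: per-input bell antecedents and a linear consequent."""

    antecedents: list[BellMF]
    consequent_weights: np.ndarray
    consequent_bias: float


@dataclass
class ANFISModel:
    """Rule bank stored as (n_rules, input_dim) parameter arrays.

    ``a``/``b``/``c`` are the premise (antecedent) parameters, ``p``/``r0``
    the consequent weights and biases.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    p: np.ndarray
    r0: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        for name in ("b", "c", "p"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.a.shape:
                raise DimensionMismatchError(f"parameter {name} has mismatched shape")
        self.r0 = np.asarray(self.r0, dtype=float)
        if self.a.ndim != 2 or self.a.shape[0] < 1:
            raise InvalidConfigError("model needs >= 1 rule and 2-D parameter arrays")
        if self.r0.shape != (self.n_rules,):
            raise DimensionMismatchError("bias vector length must equal rule count")
        if (self.a <= 0).any() or (self.b <= 0).any():
            raise InvalidConfigError("all bell widths and shapes must be positive")

    @property
    def n_rules(self) -> int:
        return self.a.shape[0]

    @property
    def input_dim(self) -> int:
        return self.a.shape[1]

    @property
    def rules(self) -> list[FuzzyRule]:
        return [
            FuzzyRule(
                antecedents=[
                    BellMF(self.a[i, j], self.b[i, j], self.c[i, j])
                    for j in range(self.input_dim)
                ],
                consequent_weights=self.p[i].copy(),
                consequent_bias=float(self.r0[i]),
            )
            for i in range(self.n_rules)
        ]

    @classmethod
    def from_rules(cls, rules: list[FuzzyRule]) -> "ANFISModel":
        dims = {len(r.antecedents) for r in rules}
        if len(dims) != 1:
            raise DimensionMismatchError("all rules must share the input dimension")
        a = np.array([[mf.a for mf in r.antecedents] for r in rules])
        b = np.array([[mf.b for mf in r.antecedents] for r in rules])
        c = np.array([[mf.c for mf in r.antecedents] for r in rules])
        p = np.array([np.asarray(r.consequent_weights, dtype=float) for r in rules])
        r0 = np.array([r.consequent_bias for r in rules])
        return cls(a=a, b=b, c=c, p=p, r0=r0)

    def copy(self) -> "ANFISModel":
        return ANFISModel(
            a=self.a.copy(), b=self.b.copy(), c=self.c.copy(),
            p=self.p.copy(), r0=self.r0.copy(),
        )


def bell_membership(x: float, mf: BellMF) -> float:
    """mu(x) = 1 / (1 + |(x - c)/a|^(2b)); equals 1 at the center, 0.5 at c +/- a."""
    return 1.0 / (1.0 + abs((x - mf.c) / mf.a) ** (2.0 * mf.b))


def _log_strengths(X: np.ndarray, model: ANFISModel) -> np.ndarray:
    """log w for each (sample, rule); shape (n, n_rules)."""
    z = np.abs((X[:, None, :] - model.c[None]) / model.a[None])
    # log mu = -log1p(z^(2b)); computed stably via 2b*log z for large z
    logz = np.where(z > 0, np.log(np.where(z > 0, z, 1.0)), -np.inf)
    expo = 2.0 * model.b[None] * logz
    log_mu = -np.logaddexp(0.0, expo)
    return log_mu.sum(axis=2)


def firing_strengths(input_vector: np.ndarray, model: ANFISModel) -> np.ndarray:
    """Layer-2 outputs: w_i = product of the rule's antecedent memberships."""
    x = np.asarray(input_vector, dtype=float)
    if x.shape != (model.input_dim,):
        raise DimensionMismatchError(
            f"input has {x.shape} but model expects ({model.input_dim},)"
        )
    return np.exp(_log_strengths(x[None, :], model)[0])


def normalize_strengths(w: np.ndarray) -> np.ndarray:
    """Layer-3 outputs: w_bar_i = w_i / sum(w); requires at least one positive w."""
    w = np.asarray(w, dtype=float)
    total = w.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise DegenerateActivationError("all firing strengths are zero")
    return w / total


def _normalized_strengths_matrix(X: np.ndarray, model: ANFISModel) -> np.ndarray:
    logw = _log_strengths(X, model)
    logw = logw - logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def forward(input_vector: np.ndarray, model: ANFISModel) -> tuple[float, dict]:
    """Full five-layer evaluation of one input; returns (f, layer diagnostics)."""
    x = np.asarray(input_vector, dtype=float)
    if x.shape != (model.input_dim,):
        raise DimensionMismatchError(
            f"input has {x.shape} but model expects ({model.input_dim},)"
        )
    o1 = np.array(
        [
            [bell_membership(x[j], BellMF(model.a[i, j], model.b[i, j], model.c[i, j]))
             for j in range(model.input_dim)]
            for i in range(model.n_rules)
        ]
    )
    w = firing_strengths(x, model)
    w_bar = _normalized_strengths_matrix(x[None, :], model)[0]
    f_rules = model.p @ x + model.r0
    o4 = w_bar * f_rules
    f = float(o4.sum())
    diagnostics = {"O1": o1, "O2": w, "O3": w_bar, "O4": o4, "O5": f,
                   "rule_outputs": f_rules}
    return f, diagnostics


def predict_f(model: ANFISModel, X: np.ndarray) -> np.ndarray:
    """Vectorized layer-5 output for a matrix of inputs."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise DimensionMismatchError(
            f"X has shape {X.shape} but model expects (*, {model.input_dim})"
        )
    w_bar = _normalized_strengths_matrix(X, model)
    f_rules = X @ model.p.T + model.r0[None, :]
    return (w_bar * f_rules).sum(axis=1)


def predict_label(f) -> np.ndarray | int:
    """Decision rule for 0/1 regression output: class 1 iff f >= 0.5."""
    f_arr = np.asarray(f, dtype=float)
    if not np.isfinite(f_arr).all():
        raise ArithmeticError("non-finite model output")
    labels = (f_arr >= 0.5).astype(int)
    return int(labels) if np.isscalar(f) or f_arr.ndim == 0 else labels


def init_model(X: np.ndarray, y: np.ndarray, n_rules: int = 4, seed: int = 0) -> ANFISModel:
    """Scatter-partition initialization via seeded k-means.

    Each of the ``n_rules`` clusters becomes one rule: membership centers at
    the cluster centroid, widths at the per-dimension cluster SD (floored at
    1e-3 so the bell stays defined), shape fixed at 2.  Consequents start as
    zero weights with bias equal to the cluster's mean label, so the untrained
    model already outputs a crude local class estimate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if n_rules < 1:
        raise InvalidConfigError("n_rules must be >= 1")
    if n_rules > n:
        raise InvalidConfigError(f"n_rules={n_rules} exceeds n_samples={n}")
    km = KMeans(n_clusters=n_rules, n_init=1, random_state=seed)
    assign = km.fit_predict(X)
    a = np.empty((n_rules, d))
    c = km.cluster_centers_.astype(float)
    r0 = np.empty(n_rules)
    global_sd = np.maximum(X.std(axis=0), _MIN_WIDTH)
    for i in range(n_rules):
        members = X[assign == i]
        if len(members) == 0:  # empty cluster: fall back to global spread
            a[i] = global_sd
            r0[i] = float(y.mean())
            continue
        a[i] = np.maximum(members.std(axis=0), _MIN_WIDTH)
        r0[i] = float(y[assign == i].mean())
    b = np.full((n_rules, d), 2.0)
    p = np.zeros((n_rules, d))
    return ANFISModel(a=a, b=b, c=c, p=p, r0=r0)


def fit_consequents_ls(model: ANFISModel, X: np.ndarray, y: np.ndarray) -> ANFISModel:
    """Closed-form least-squares fit of all consequents, antecedents fixed.

    The Sugeno output is linear in {p_i, r_i}: each design-matrix row is the
    concatenation of w_bar_i * [x, 1] blocks.  Rank-deficient systems take the
    minimum-norm solution, so training MSE never exceeds that of the
    zero-consequent model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    w_bar = _normalized_strengths_matrix(X, model)  # (n, r)
    aug = np.hstack([X, np.ones((n, 1))])  # (n, d+1)
    phi = (w_bar[:, :, None] * aug[:, None, :]).reshape(n, -1)
    theta, *_ = np.linalg.lstsq(phi, y, rcond=None)
    theta = theta.reshape(model.n_rules, model.input_dim + 1)
    out = model.copy()
    out.p = theta[:, :-1]
    out.r0 = theta[:, -1]
    return out


def save_model(model: ANFISModel, path) -> None:
    """Serialize the rule bank to structured JSON text (round-trip exact)."""
    payload = {
        "n_rules": model.n_rules,
        "input_dim": model.input_dim,
        "a": model.a.tolist(),
        "b": model.b.tolist(),
        "c": model.c.tolist(),
        "p": model.p.tolist(),
        "r0": model.r0.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path) -> ANFISModel:
    with open(path) as fh:
        payload = json.load(fh)
    return ANFISModel(
        a=np.array(payload["a"]), b=np.array(payload["b"]), c=np.array(payload["c"]),
        p=np.array(payload["p"]), r0=np.array(payload["r0"]),
    )
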