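"""Inverse regressors: PLSR, extreme learning machine, and GA-optimized ELM.

The ELM is a single-hidden-layer network with logistic-sigmoid hidden units
and a linear output: input weights and hidden biases are drawn uniformly on
[-1, 1] and never trained; only the output weights are solved, in closed
form, by least squares on the hidden activations.  The GA-ELM replaces the
random draw with a real-coded genetic algorithm over the input weights and
hidden biases: each individual of length l = s1*s2 + s2*s3 + s2 + s3 decodes
into a candidate network, its fitness is f = 1/(1 + E) with E the training
RMSE, selection is fitness-proportional within the above-average
subpopulation, and crossover/mutation fire with the adaptive probabilities
p = k*(f_max - f)/(f_max - f_mean) for above-average individuals and p = k
below average (k_c = k_m = 0.5 by default).  An elite copy of the best
individual survives every generation, so the best fitness is non-decreasing.

Features are standardized internally (training mean/scale) before entering
the sigmoid layer; PLSR relies on its own centering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.cross_decomposition import PLSRegression

from ._pls import kfold_indices

__all__ = [
    "PlsrModel",
    "ElmNetwork",
    "GaParams",
    "GaElmResult",
    "plsr_fit",
    "elm_fit",
    "individual_length",
    "fitness",
    "selection_probability",
    "adaptive_rate",
    "decode_individual",
    "encode_individual",
    "ga_elm_fit",
    "predict",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# PLSR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlsrModel:
    """Fitted PLS regression: predictions are (X - x_mean) @ coef + y_mean."""

    coef: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    n_latent: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.coef.shape[0]:
            raise ValueError(f"expected {self.coef.shape[0]} features, "
                             f"got {X.shape[1]}")
        return (X - self.x_mean) @ self.coef + self.y_mean


def plsr_fit(X: np.ndarray, y: np.ndarray,
             n_latent: int | None = None,
             folds: int = 10, seed: int = 0) -> PlsrModel:
    """Fit PLSR; if ``n_latent`` is None it is chosen by K-fold CV RMSE
    over 1..min(15, rank limit)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    max_latent = min(15, p, n - 1)
    if max_latent < 1:
        raise ValueError("not enough samples/features for one latent variable")
    if n_latent is None:
        fold_idx = kfold_indices(n, min(folds, n), seed)
        best = (np.inf, 1)
        for k in range(1, max_latent + 1):
            sq = 0.0
            for test in fold_idx:
                train = np.setdiff1d(np.arange(n), test)
                m = PLSRegression(n_components=min(k, len(train) - 1),
                                  scale=False)
                m.fit(X[train], y[train])
                sq += float(np.sum((y[test] - m.predict(X[test]).ravel()) ** 2))
            rmse = np.sqrt(sq / n)
            if rmse < best[0]:
                best = (rmse, k)
        n_latent = best[1]
    if not 1 <= n_latent <= max_latent:
        raise ValueError(f"n_latent={n_latent} outside 1..{max_latent}")
    m = PLSRegression(n_components=n_latent, scale=False)
    m.fit(X, y)
    return PlsrModel(coef=m.coef_.ravel().copy(),
                     x_mean=m._x_mean.copy(),
                     y_mean=float(np.mean(y)),
                     n_latent=n_latent)


# ---------------------------------------------------------------------------
# ELM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElmNetwork:
    """Single-hidden-layer network with sigmoid hidden units, linear output."""

    input_weights: np.ndarray   # (s1, s2)
    hidden_bias: np.ndarray     # (s2,)
    output_weights: np.ndarray  # (s2 + 1,): last entry is the output bias
    x_mean: np.ndarray          # (s1,) feature standardization
    x_scale: np.ndarray         # (s1,)
    seed: int | None = None

    @property
    def s1(self) -> int:
        return self.input_weights.shape[0]

    @property
    def s2(self) -> int:
        return self.input_weights.shape[1]

    def hidden(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.s1:
            raise ValueError(f"expected {self.s1} features, got {X.shape[1]}")
        Z = (X - self.x_mean) / self.x_scale
        return expit(Z @ self.input_weights + self.hidden_bias)

    def predict(self, X: np.ndarray) -> np.ndarray:
        H = self.hidden(X)
        return H @ self.output_weights[:-1] + self.output_weights[-1]


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


_RIDGE_EPS = 1e-8  # fallback regularization for a degenerate hidden matrix


def _solve_output_weights(H: np.ndarray, y: np.ndarray) -> np.ndarray:
    A = np.column_stack([H, np.ones(len(H))])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    if not np.all(np.isfinite(beta)):
        G = A.T @ A + _RIDGE_EPS * np.eye(A.shape[1])
        beta = np.linalg.solve(G, A.T @ y)
    return beta


def _elm_from_weights(X: np.ndarray, y: np.ndarray, W: np.ndarray,
                      b: np.ndarray, x_mean: np.ndarray, x_scale: np.ndarray,
                      seed: int | None = None) -> ElmNetwork:
    Z = (X - x_mean) / x_scale
    H = expit(Z @ W + b)
    beta = _solve_output_weights(H, y)
    return ElmNetwork(input_weights=W, hidden_bias=b, output_weights=beta,
                      x_mean=x_mean, x_scale=x_scale, seed=seed)


def elm_fit(X: np.ndarray, y: np.ndarray, s2: int = 20,
            seed: int = 0) -> ElmNetwork:
    """Fit an ELM: random input weights/biases, least-squares output weights."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if s2 < 1:
        raise ValueError("s2 must be >= 1")
    rng = np.random.default_rng(seed)
    s1 = X.shape[1]
    W = rng.uniform(-1.0, 1.0, size=(s1, s2))
    b = rng.uniform(-1.0, 1.0, size=s2)
    x_mean, x_scale = _standardizer(X)
    return _elm_from_weights(X, y, W, b, x_mean, x_scale, seed=seed)


# ---------------------------------------------------------------------------
# GA algebra
# ---------------------------------------------------------------------------

def individual_length(s1: int, s2: int, s3: int = 1) -> int:
    """Genome length l = s1*s2 + s2*s3 + s2 + s3."""
    if min(s1, s2, s3) < 1:
        raise ValueError("node counts must be positive")
    return s1 * s2 + s2 * s3 + s2 + s3


def fitness(E: float | np.ndarray) -> float | np.ndarray:
    """f = 1 / (1 + E) for a non-negative error E; in (0, 1]."""
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("error must be non-negative")
    out = 1.0 / (1.0 + E)
    return float(out) if out.ndim == 0 else out


def selection_probability(fitness_vector: Sequence[float]) -> np.ndarray:
    """p_i = f_i / sum(f); proportional selection probabilities."""
    f = np.asarray(fitness_vector, dtype=float)
    if f.size == 0:
        raise ValueError("empty population")
    if np.any(f <= 0):
        raise ValueError("fitness values must be positive")
    return f / f.sum()


def adaptive_rate(f_op: float, f_max: float, f_bar: float, k: float) -> float:
    """Adaptive crossover/mutation probability.

    p = k*(f_max - f_op)/(f_max - f_bar) for an above-average individual,
    p = k below average.  A degenerate uniform population (f_max == f_bar)
    returns 0 for the above-average branch: no operator pressure is left.
    """
    # tolerate round-off when a converged population makes mean(f) exceed
    # max(f) by an ulp
    tol = 1e-9 * max(1.0, abs(f_max))
    if f_max < f_bar - tol:
        raise ValueError("f_max must be >= f_bar")
    if f_op < f_bar:
        return float(k)
    if f_max - f_bar <= tol:
        return 0.0
    return float(k * (f_max - f_op) / (f_max - f_bar))


# ---------------------------------------------------------------------------
# GA-ELM
# ---------------------------------------------------------------------------

def decode_individual(v: np.ndarray, s1: int, s2: int,
                      s3: int = 1) -> dict[str, np.ndarray]:
    """Split a genome into network blocks, in the order input weights,
    output weights, hidden biases, output bias."""
    v = np.asarray(v, dtype=float)
    if v.shape != (individual_length(s1, s2, s3),):
        raise ValueError("genome length does not match the architecture")
    i = 0
    W_in = v[i:i + s1 * s2].reshape(s1, s2); i += s1 * s2
    W_out = v[i:i + s2 * s3].reshape(s2, s3); i += s2 * s3
    b_hid = v[i:i + s2]; i += s2
    b_out = v[i:i + s3]
    return {"input_weights": W_in, "output_weights": W_out,
            "hidden_bias": b_hid, "output_bias": b_out}


def encode_individual(blocks: dict[str, np.ndarray]) -> np.ndarray:
    """Inverse of :func:`decode_individual`."""
    return np.concatenate([
        np.asarray(blocks["input_weights"], dtype=float).ravel(),
        np.asarray(blocks["output_weights"], dtype=float).ravel(),
        np.asarray(blocks["hidden_bias"], dtype=float).ravel(),
        np.asarray(blocks["output_bias"], dtype=float).ravel(),
    ])


@dataclass(frozen=True)
class GaParams:
    """Genetic-algorithm settings (crossover/mutation gains of 0.5 by default)."""

    population: int = 30
    generations: int = 100
    k_c: float = 0.5
    k_m: float = 0.5
    mutation_sd: float = 0.1
    mutation_gene_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass(frozen=True)
class GaElmResult:
    network: ElmNetwork
    best_fitness_history: np.ndarray  # (generations + 1,)
    best_individual: np.ndarray


def ga_elm_fit(X: np.ndarray, y: np.ndarray, s2: int = 20,
               ga_params: GaParams | None = None,
               seed: int = 0) -> GaElmResult:
    """ELM with input weights and hidden biases chosen by the genetic search.

    E_i is the training RMSE of the ELM induced by individual i (output
    weights re-solved by least squares for every evaluation); the final
    network is built from the best individual ever seen.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    params = ga_params or GaParams()
    rng = np.random.default_rng(seed)
    s1, s3 = X.shape[1], 1
    l = individual_length(s1, s2, s3)
    x_mean, x_scale = _standardizer(X)

    def evaluate(v: np.ndarray) -> float:
        blocks = decode_individual(v, s1, s2, s3)
        net = _elm_from_weights(X, y, blocks["input_weights"],
                                blocks["hidden_bias"], x_mean, x_scale)
        resid = y - net.predict(X)
        return float(np.sqrt(np.mean(resid ** 2)))

    m = params.population
    pop = rng.uniform(-1.0, 1.0, size=(m, l))
    errors = np.array([evaluate(v) for v in pop])
    fit = fitness(errors)
    best_idx = int(np.argmax(fit))
    best_v, best_f = pop[best_idx].copy(), float(fit[best_idx])
    history = [best_f]

    for _ in range(params.generations):
        f_max, f_bar = float(fit.max()), float(fit.mean())
        # above-average subpopulation carries on breeding
        sub = np.flatnonzero(fit >= f_bar)
        if len(sub) < 2:
            sub = np.argsort(fit)[-2:]
        p_sel = selection_probability(fit[sub])

        children = np.empty((m - 1, l))
        for c in range(m - 1):
            i, j = rng.choice(sub, size=2, p=p_sel)
            child = pop[i].copy()
            p_c = adaptive_rate(max(fit[i], fit[j]), f_max, f_bar, params.k_c)
            if rng.random() < p_c:
                alpha = rng.random()
                child = alpha * pop[i] + (1.0 - alpha) * pop[j]
            p_m = adaptive_rate(fit[i], f_max, f_bar, params.k_m)
            if rng.random() < p_m:
                mask = rng.random(l) < params.mutation_gene_prob
                child[mask] += rng.normal(0.0, params.mutation_sd,
                                          size=int(mask.sum()))
            children[c] = child

        pop = np.vstack([best_v, children])  # elitism
        errors = np.array([evaluate(v) for v in pop])
        fit = fitness(errors)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_f:
            best_f = float(fit[gen_best])
            best_v = pop[gen_best].copy()
        history.append(best_f)

    blocks = decode_individual(best_v, s1, s2, s3)
    net = _elm_from_weights(X, y, blocks["input_weights"],
                            blocks["hidden_bias"], x_mean, x_scale, seed=seed)
    return GaElmResult(network=net,
                       best_fitness_history=np.array(history),
                       best_individual=best_v)


# ---------------------------------------------------------------------------
# Prediction and serialization
# ---------------------------------------------------------------------------

def predict(model, X: np.ndarray) -> np.ndarray:
    """Predict ΔN (mg/g) with any fitted model or GA-ELM result."""
    if isinstance(model, GaElmResult):
        model = model.network
    if isinstance(model, (PlsrModel, ElmNetwork)):
        out = model.predict(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite predictions")
        return out
    raise TypeError(f"cannot predict with {type(model).__name__}")


def save_model(model, path) -> None:
    """Serialize a fitted model to a JSON container."""
    if isinstance(model, GaElmResult):
        model = model.network
    if isinstance(model, PlsrModel):
        payload = {"kind": "plsr", "coef": model.coef.tolist(),
                   "x_mean": model.x_mean.tolist(), "y_mean": model.y_mean,
                   "n_latent": model.n_latent}
    elif isinstance(model, ElmNetwork):
        payload = {"kind": "elm",
                   "input_weights": model.input_weights.tolist(),
                   "hidden_bias": model.hidden_bias.tolist(),
                   "output_weights": model.output_weights.tolist(),
                   "x_mean": model.x_mean.tolist(),
                   "x_scale": model.x_scale.tolist(),
                   "seed": model.seed}
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    """Inverse of :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload["kind"] == "plsr":
        return PlsrModel(coef=np.array(payload["coef"]),
                         x_mean=np.array(payload["x_mean"]),
                         y_mean=float(payload["y_mean"]),
                         n_latent=int(payload["n_latent"]))
    if payload["kind"] == "elm":
        return ElmNetwork(input_weights=np.array(payload["input_weights"]),
                          hidden_bias=np.array(payload["hidden_bias"]),
                          output_weights=np.array(payload["output_weights"]),
                          x_mean=np.array(payload["x_mean"]),
                          x_scale=np.array(payload["x_scale"]),
                          seed=payload.get("seed"))
    raise ValueError(f"unknown model kind {payload['kind']!r}")
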