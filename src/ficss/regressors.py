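"""Multi-output calibration models: PLS2 and the extreme learning machine.

The PLS model here is the workhorse linear calibration model and also the
default screener inside the interval-selection search.  Because that search
fits thousands of small PLS models, the core is a direct SVD formulation of
PLS2: each component's weight vector is the dominant left singular vector of
X_deflated' Y, which is exactly the fixed point the classical NIPALS
iteration converges to.  Tests cross-check predictions against
scikit-learn's ``PLSRegression``.

The extreme learning machine (ELM) is a single-hidden-layer network whose
input weights and biases are drawn uniformly from [-1, 1] and never trained;
only the output weights are solved, by the Moore-Penrose pseudoinverse of
the hidden-layer output matrix.  With a sigmoid activation the hidden layer
is a random nonlinear feature map, which is what lets the ELM pick up the
nonlinearity that band overlap induces in NIR calibration problems.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "PLSModel",
    "pls_fit",
    "pls_predict",
    "choose_pls_components",
    "ELMModel",
    "elm_fit",
    "elm_predict",
    "elm_select_hidden_nodes",
    "DEFAULT_NODE_GRID",
]

#: hidden-node candidates: 4 to 40 in steps of 2
DEFAULT_NODE_GRID: tuple[int, ...] = tuple(range(4, 41, 2))


# ---------------------------------------------------------------------------
# PLS2
# ---------------------------------------------------------------------------

def _pls_core(X: np.ndarray, Y: np.ndarray, k: int):
    """Centered PLS2 regression coefficients via per-component SVD.

    Returns (B, x_mean, y_mean) with predictions (X - x_mean) @ B + y_mean.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xd = X - x_mean
    Yc = Y - y_mean
    n, p = Xd.shape
    m = Yc.shape[1]
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    Q = np.zeros((m, k))
    s_ref = tt_ref = None
    for a in range(k):
        S = Xd.T @ Yc
        s_norm = np.linalg.norm(S)
        if s_ref is None:
            s_ref = s_norm
        # covariance (or deflated X) numerically exhausted: stop early
        if s_norm <= max(n, p) * np.finfo(float).eps * max(s_ref, 1e-300):
            k = a
            W, P, Q = W[:, :k], P[:, :k], Q[:, :k]
            break
        if m == 1:
            w = S[:, 0]
        else:
            u, _, _ = np.linalg.svd(S, full_matrices=False)
            w = u[:, 0]
        w = w / np.linalg.norm(w)
        t = Xd @ w
        tt = t @ t
        if tt_ref is None:
            tt_ref = tt
        if tt <= (max(n, p) * np.finfo(float).eps) ** 2 * max(tt_ref, 1e-300):
            k = a
            W, P, Q = W[:, :k], P[:, :k], Q[:, :k]
            break
        pvec = Xd.T @ t / tt
        q = Yc.T @ t / tt
        Xd = Xd - np.outer(t, pvec)
        W[:, a], P[:, a], Q[:, a] = w, pvec, q
    if k == 0:
        return np.zeros((p, m)), x_mean, y_mean
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return B, x_mean, y_mean


@dataclass
class PLSModel:
    """Fitted PLS2 regression: centered X and Y, no variance scaling."""

    n_components: int
    coef_: np.ndarray          # (n_features, n_targets)
    x_mean_: np.ndarray
    y_mean_: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.coef_.shape[0]}"
            )
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


def pls_fit(X: np.ndarray, C: np.ndarray, n_components: int) -> PLSModel:
    """Fit a PLS2 model with the given number of latent variables."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    B, xm, ym = _pls_core(X, C, n_components)
    return PLSModel(n_components=n_components, coef_=B, x_mean_=xm, y_mean_=ym)


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def choose_pls_components(
    X: np.ndarray,
    C: np.ndarray,
    max_components: int = 15,
    cv: int = 5,
    seed: int = 0,
) -> int:
    """Pick the latent-variable count minimizing k-fold RMSECV.

    The cap (default 15) keeps the linear model parsimonious; folds are
    shuffled deterministically from the seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n, p = X.shape
    kmax = min(max_components, n - 1 - int(np.ceil(n / cv)), p)
    kmax = max(kmax, 1)
    folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
    err = np.zeros(kmax)
    for tr, te in folds.split(X):
        for k in range(1, kmax + 1):
            if k > min(len(tr) - 1, p):
                err[k - 1] += np.inf
                continue
            m = pls_fit(X[tr], C[tr], k)
            r = m.predict(X[te]) - C[te]
            err[k - 1] += np.mean(r**2)
    return int(np.argmin(err)) + 1


# ---------------------------------------------------------------------------
# ELM
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ELMModel:
    """Fitted extreme learning machine.

    ``input_weights`` (l x p) and ``biases`` (l,) are the frozen random
    draws; ``output_weights`` (l x m) is the pseudoinverse solution.  The
    input preprocessing (centering plus a scale) is stored so prediction is
    self-contained; given (seed, n_hidden, training data) the whole model is
    bit-reproducible.
    """

    input_weights: np.ndarray
    biases: np.ndarray
    output_weights: np.ndarray
    n_hidden: int
    seed: int
    x_mean_: np.ndarray
    x_scale_: np.ndarray  # per-feature divisor (already includes sqrt(p))

    def hidden(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_weights.shape[1]:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects "
                f"{self.input_weights.shape[1]}"
            )
        Z = (X - self.x_mean_) / self.x_scale_
        return _sigmoid(Z @ self.input_weights.T + self.biases)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.hidden(X) @ self.output_weights

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_hidden": self.n_hidden,
                "seed": self.seed,
                "input_weights": self.input_weights.tolist(),
                "biases": self.biases.tolist(),
                "output_weights": self.output_weights.tolist(),
                "x_mean": self.x_mean_.tolist(),
                "x_scale": self.x_scale_.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ELMModel":
        d = json.loads(text)
        return cls(
            input_weights=np.array(d["input_weights"]),
            biases=np.array(d["biases"]),
            output_weights=np.array(d["output_weights"]),
            n_hidden=int(d["n_hidden"]),
            seed=int(d["seed"]),
            x_mean_=np.array(d["x_mean"]),
            x_scale_=np.array(d["x_scale"]),
        )


def _elm_scale(X: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Preprocessing statistics for the ELM input layer.

    Centering is always per channel.  The default scale is a single global
    standard deviation times sqrt(n_features): the sqrt factor keeps the
    random projection w.x of order 1 (so the sigmoid stays in its active
    range with weights uniform on [-1, 1]), and the global rather than
    per-channel deviation avoids inflating near-dead channels that carry
    only instrument noise.
    """
    p = X.shape[1]
    mean = X.mean(axis=0)
    if mode == "global":
        sd = float(np.std(X - mean))
        scale = np.full(p, (sd if sd > 0 else 1.0) * np.sqrt(p))
    elif mode == "per-channel":
        sd = np.std(X - mean, axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        scale = sd * np.sqrt(p)
    elif mode == "none":
        scale = np.ones(p)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return mean, scale


def elm_fit(
    X: np.ndarray,
    C: np.ndarray,
    n_hidden: int,
    seed: int = 0,
    scaling: str = "global",
) -> ELMModel:
    """Fit an ELM: random uniform [-1, 1] input layer, pseudoinverse output.

    The output weights beta solve min ||H beta - C|| in the least-squares
    sense via the Moore-Penrose pseudoinverse of the hidden output matrix H
    (SVD with an rcond cutoff of machine epsilon times the larger dimension;
    the exact-math generalized inverse needs a cutoff in floating point).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n, p = X.shape
    if n == 0 or p == 0:
        raise ValueError("empty training matrix")
    if C.shape[0] != n:
        raise ValueError("X and C are not row-aligned")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if n_hidden >= 10 * n:
        warnings.warn(
            f"n_hidden={n_hidden} is >= 10x the sample count {n}: deep in the "
            "interpolation regime",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1.0, 1.0, size=(n_hidden, p))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    mean, scale = _elm_scale(X, scaling)
    Z = (X - mean) / scale
    H = _sigmoid(Z @ w.T + b)
    rcond = np.finfo(float).eps * max(H.shape)
    beta = np.linalg.pinv(H, rcond=rcond) @ C
    return ELMModel(
        input_weights=w,
        biases=b,
        output_weights=beta,
        n_hidden=n_hidden,
        seed=seed,
        x_mean_=mean,
        x_scale_=scale,
    )


def elm_predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def elm_select_hidden_nodes(
    X: np.ndarray,
    C: np.ndarray,
    grid: tuple[int, ...] = DEFAULT_NODE_GRID,
    repeats: int = 50,
    seed: int = 0,
    cv: int = 5,
    scaling: str = "global",
) -> tuple[int, dict[int, float]]:
    """Hidden-node count by repeated random restarts under k-fold CV.

    For each candidate l the ELM is refit ``repeats`` times with distinct
    seeds (the random input layer makes single fits unstable) and the
    validation RMSE is averaged; the l with the smallest mean wins.  Returns
    ``(best_l, {l: mean_rmse})``.
    """
    grid = tuple(int(g) for g in grid)
    if not grid:
        raise ValueError("empty node grid")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = X.shape[0]
    if n < cv:
        raise ValueError("not enough samples for the requested folds")
    folds = list(KFold(n_splits=cv, shuffle=True, random_state=seed).split(X))
    ss = np.random.SeedSequence(seed)
    fit_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(repeats)]
    mean_rmse: dict[int, float] = {}
    for l in grid:
        errs = []
        for r in range(repeats):
            for tr, te in folds:
                if len(te) == 0:
                    raise ValueError("empty validation fold")
                m = elm_fit(X[tr], C[tr], l, seed=fit_seeds[r], scaling=scaling)
                resid = m.predict(X[te]) - C[te]
                errs.append(float(np.sqrt(np.mean(resid**2))))
        mean_rmse[l] = float(np.mean(errs))
    best = min(mean_rmse, key=lambda l: (mean_rmse[l], l))
    return best, mean_rmse
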