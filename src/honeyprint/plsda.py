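"""PLS2 regression on dummy-coded class membership (PLS-DA).

The discriminant model regresses the autoscaled spectral matrix against a
one-hot "dummy" matrix of class membership.  Components are extracted with
NIPALS: for each latent variable the inner loop alternates

    w ∝ X'u (unit norm),  t = Xw,  q = Y't/(t't),  u = Yq/(q'q)

until the score vector stabilises, then X is deflated by t p' (p = X't/t't)
and Y by t q'.  The regression matrix is B = W (P'W)^{-1} Q'.  Predictions
are returned in dummy space; a decision rule (argmax by default, a Gaussian
equal-odds threshold as an alternative) maps them to class labels.

NIPALS is used in production because its per-component weights/scores are
exactly what VIP needs; an independently coded SIMPLS serves as a test
oracle elsewhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import ScalingModel, autoscale_apply, autoscale_fit

__all__ = [
    "DummyMatrix",
    "PLSModel",
    "GaussianThresholds",
    "encode_labels",
    "fit_pls2",
    "fit_plsda",
    "predict_responses",
    "fit_gaussian_thresholds",
    "classify",
    "save_model",
    "load_model",
]

_CONV_TOL = 1e-10
_MAX_ITER = 500


class NonConvergenceError(RuntimeError):
    """The NIPALS inner loop failed to stabilise for some component."""


@dataclass(frozen=True)
class DummyMatrix:
    """One-hot class membership; columns follow lexicographic class order."""

    Y: np.ndarray
    class_order: tuple[str, ...]


def encode_labels(labels) -> DummyMatrix:
    """One-hot encode class labels, columns ordered lexicographically."""
    labels = [None if (l is None or (isinstance(l, float) and np.isnan(l))) else str(l)
              for l in labels]
    if any(l is None for l in labels):
        raise ValueError("missing class label at position "
                         f"{labels.index(None)}")
    order = tuple(sorted(set(labels)))
    if len(order) < 2:
        raise ValueError("need at least two distinct classes")
    index = {c: j for j, c in enumerate(order)}
    Y = np.zeros((len(labels), len(order)))
    for i, l in enumerate(labels):
        Y[i, index[l]] = 1.0
    return DummyMatrix(Y=Y, class_order=order)


@dataclass
class PLSModel:
    """A fitted PLS2 decomposition plus the preprocessing it was trained with."""

    A: int
    W: np.ndarray            # p x A X-weights, unit columns
    P: np.ndarray            # p x A X-loadings
    Q: np.ndarray            # c x A Y-loadings
    T: np.ndarray            # n x A X-scores
    B: np.ndarray            # p x c regression coefficients (scaled X -> centred Y)
    y_means: np.ndarray      # per-class dummy means added back at prediction
    class_order: tuple[str, ...]
    scaling: ScalingModel | None = None


def _nipals(X: np.ndarray, Y: np.ndarray, A: int):
    """Core NIPALS PLS2 on already centred/scaled X and centred Y."""
    n, p = X.shape
    c = Y.shape[1]
    Xd = X.copy()
    Yd = Y.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((c, A))
    T = np.zeros((n, A))
    y_scale = float(np.linalg.norm(Y))
    for a in range(A):
        u = Yd[:, np.argmax((Yd ** 2).sum(axis=0))].copy()
        t_old = None
        for _ in range(_MAX_ITER):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise NonConvergenceError(
                    f"component {a + 1}: X carries no covariance with Y "
                    "(rank exhausted)"
                )
            w /= nw
            t = Xd @ w
            tt = float(t @ t)
            if tt == 0:
                raise NonConvergenceError(f"component {a + 1}: zero score vector")
            q = Yd.T @ t / tt
            qq = float(q @ q)
            if qq == 0:
                raise NonConvergenceError(f"component {a + 1}: zero Y-loading")
            u = Yd @ q / qq
            if t_old is not None and np.linalg.norm(t - t_old) <= _CONV_TOL * np.linalg.norm(t):
                break
            t_old = t
        else:
            # late components can oscillate slowly when the residual Y is
            # numerically degenerate; accept a loose fixed point (the
            # component barely moves predictions) but refuse real failures
            rel = float(np.linalg.norm(t - t_old) / max(np.linalg.norm(t), 1e-300))
            negligible = np.linalg.norm(q) * np.linalg.norm(t) <= 1e-8 * max(y_scale, 1e-300)
            if rel < 1e-6 and not negligible:
                warnings.warn(
                    f"NIPALS component {a + 1} accepted at relative change {rel:.1e}",
                    stacklevel=2,
                )
            elif not negligible:
                raise NonConvergenceError(
                    f"component {a + 1} did not converge in {_MAX_ITER} iterations"
                )
        p_load = Xd.T @ t / tt
        Xd -= np.outer(t, p_load)
        Yd -= np.outer(t, q)
        W[:, a] = w
        P[:, a] = p_load
        Q[:, a] = q
        T[:, a] = t
    return W, P, Q, T


def _regression_matrix(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    A = W.shape[1]
    R = W @ np.linalg.solve(P.T @ W, np.eye(A))
    return R @ Q.T


def fit_pls2(Xs: np.ndarray, Y, A: int) -> PLSModel:
    """Fit PLS2 on a pre-scaled X against a dummy (or generic) response.

    ``Y`` may be a :class:`DummyMatrix` or a raw response matrix; response
    columns are centred internally and the centring is stored as ``y_means``.
    """
    Xs = np.asarray(Xs, dtype=float)
    if isinstance(Y, DummyMatrix):
        Ymat, order = Y.Y, Y.class_order
    else:
        Ymat = np.atleast_2d(np.asarray(Y, dtype=float))
        if Ymat.shape[0] == 1 and Xs.shape[0] != 1:
            Ymat = Ymat.T
        order = tuple(f"y{j}" for j in range(Ymat.shape[1]))
    n, p = Xs.shape
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A={A} out of range 1..min(n-1={n-1}, p={p})")
    y_means = Ymat.mean(axis=0)
    W, P, Q, T = _nipals(Xs, Ymat - y_means, A)
    B = _regression_matrix(W, P, Q)
    return PLSModel(A=A, W=W, P=P, Q=Q, T=T, B=B, y_means=y_means,
                    class_order=order, scaling=None)


def fit_plsda(X: np.ndarray, labels, A: int) -> PLSModel:
    """Autoscale raw spectra, dummy-code labels and fit the PLS2 model."""
    scaling = autoscale_fit(X)
    Xs = autoscale_apply(scaling, X)
    dummy = encode_labels(labels)
    model = fit_pls2(Xs, dummy, A)
    model.scaling = scaling
    return model


def predict_responses(m: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted dummy values for new raw spectra (not clipped to [0, 1])."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if m.scaling is not None:
        Xs = autoscale_apply(m.scaling, X_new)
    else:
        Xs = X_new
    if Xs.shape[1] != m.B.shape[0]:
        raise ValueError(
            f"matrix has {Xs.shape[1]} variables but the model expects {m.B.shape[0]}"
        )
    return Xs @ m.B + m.y_means


# ---------------------------------------------------------------------------
# Decision rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianThresholds:
    """Per-class decision thresholds on predicted dummy values."""

    thresholds: np.ndarray
    class_order: tuple[str, ...]


def _gaussian_crossing(m0: float, s0: float, m1: float, s1: float) -> float:
    """Equal-odds crossing of two Gaussians (equal priors).

    Degenerate spreads fall back to the midpoint, which is also the exact
    answer for equal variances.
    """
    eps = 1e-12
    s0 = max(float(s0), eps)
    s1 = max(float(s1), eps)
    if abs(s0 - s1) < 1e-9 * max(s0, s1):
        return 0.5 * (m0 + m1)
    a = 1.0 / (2 * s0 ** 2) - 1.0 / (2 * s1 ** 2)
    b = m1 / (s1 ** 2) - m0 / (s0 ** 2)
    c = m0 ** 2 / (2 * s0 ** 2) - m1 ** 2 / (2 * s1 ** 2) + np.log(s1 / s0)
    disc = b ** 2 - 4 * a * c
    if disc < 0:
        return 0.5 * (m0 + m1)
    roots = np.array([(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)])
    lo, hi = sorted((m0, m1))
    inside = roots[(roots >= lo) & (roots <= hi)]
    if inside.size:
        return float(inside[0])
    return float(roots[np.argmin(np.abs(roots - 0.5 * (m0 + m1)))])


def fit_gaussian_thresholds(yhat_train: np.ndarray, dummy: DummyMatrix) -> GaussianThresholds:
    """Fit per-class in/out Gaussians to training predictions; threshold at equal odds."""
    yhat_train = np.asarray(yhat_train, dtype=float)
    c = len(dummy.class_order)
    thresholds = np.zeros(c)
    for k in range(c):
        inside = dummy.Y[:, k] == 1
        s_in = yhat_train[inside, k]
        s_out = yhat_train[~inside, k]
        if s_in.size == 0 or s_out.size == 0:
            raise ValueError(f"class {dummy.class_order[k]!r} absent from training data")
        thresholds[k] = _gaussian_crossing(
            s_out.mean(), s_out.std(ddof=1) if s_out.size > 1 else 0.0,
            s_in.mean(), s_in.std(ddof=1) if s_in.size > 1 else 0.0,
        )
    return GaussianThresholds(thresholds=thresholds, class_order=dummy.class_order)


def classify(
    yhat: np.ndarray,
    class_order: tuple[str, ...],
    rule: str = "argmax",
    thresholds: GaussianThresholds | None = None,
) -> np.ndarray:
    """Map predicted dummy values to class labels.

    ``argmax`` takes the largest predicted response (ties go to the
    lexicographically first class, which is the column order).  The
    ``gaussian_threshold`` rule assigns the class whose predicted response
    exceeds its own threshold by the largest margin.
    """
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float))
    if yhat.shape[1] < 2:
        raise ValueError("need at least two response columns")
    if rule == "argmax":
        idx = np.argmax(yhat, axis=1)
    elif rule == "gaussian_threshold":
        if thresholds is None:
            raise ValueError("gaussian_threshold rule needs fitted thresholds")
        idx = np.argmax(yhat - thresholds.thresholds, axis=1)
    else:
        raise ValueError(f"unknown decision rule {rule!r}")
    order = np.asarray(class_order, dtype=object)
    return order[idx]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_MODEL_SCHEMA = 1


def save_model(m: PLSModel, path: str | Path) -> None:
    payload = {
        "schema": _MODEL_SCHEMA,
        "A": m.A,
        "class_order": list(m.class_order),
        "W": m.W.tolist(),
        "P": m.P.tolist(),
        "Q": m.Q.tolist(),
        "T": m.T.tolist(),
        "B": m.B.tolist(),
        "y_means": m.y_means.tolist(),
        "scaling": None
        if m.scaling is None
        else {
            "means": m.scaling.means.tolist(),
            "sds": m.scaling.sds.tolist(),
            "constant": m.scaling.constant.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> PLSModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != _MODEL_SCHEMA:
        raise ValueError(f"unsupported model schema {payload.get('schema')!r}")
    scaling = payload["scaling"]
    return PLSModel(
        A=payload["A"],
        W=np.asarray(payload["W"], dtype=float),
        P=np.asarray(payload["P"], dtype=float),
        Q=np.asarray(payload["Q"], dtype=float),
        T=np.asarray(payload["T"], dtype=float),
        B=np.asarray(payload["B"], dtype=float),
        y_means=np.asarray(payload["y_means"], dtype=float),
        class_order=tuple(payload["class_order"]),
        scaling=None
        if scaling is None
        else ScalingModel(
            means=np.asarray(scaling["means"], dtype=float),
            sds=np.asarray(scaling["sds"], dtype=float),
            constant=np.asarray(scaling["constant"], dtype=bool),
        ),
    )
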