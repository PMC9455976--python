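"""VIP, selectivity ratio and RMSECV-guided backward variable elimination.

Variable Importance in Projection for variable j over A components:

    VIP_j = sqrt( p * sum_a [ SSY_a * (w_ja / ||w_a||)^2 ] / sum_a SSY_a )

with SSY_a = (q_a'q_a)(t_a't_a), the Y-variance explained by component a.
The mean of squared VIPs is exactly 1, which the tests exploit.

The selectivity ratio projects the scaled training matrix onto each class's
regression vector (target projection) and reports, per variable, the ratio
of explained to residual sum of squares; the per-class ratios are aggregated
by their maximum.

The elimination loop alternates cross-validation (choosing the number of
latent variables by minimum CV classification-error average) with removal of
the variables ranking lowest on the geometric mean of their VIP and SR
percentile ranks.  Variable groups are compared by the best class-mean
RMSECV they attain over model complexity, and the returned marker set is
the smallest group whose RMSECV lies within one standard error of the
overall minimum — the usual one-SE parsimony rule, which keeps the choice
well-defined when cross-validation noise flattens the minimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model_selection import CVScheme, cross_validate
from .plsda import PLSModel, DummyMatrix, encode_labels, fit_plsda

__all__ = [
    "EliminationConfig",
    "MarkerSet",
    "SelectionTrace",
    "IterationRecord",
    "vip",
    "selectivity_ratio",
    "eliminate_iteratively",
]

#: stands in for an infinite selectivity ratio (zero residual variance)
SR_SENTINEL = 1e12


def vip(m: PLSModel) -> np.ndarray:
    """Per-variable VIP scores of a fitted PLS2 model."""
    tt = (m.T ** 2).sum(axis=0)              # t_a't_a
    qq = (m.Q ** 2).sum(axis=0)              # q_a'q_a
    ssy = qq * tt
    total = ssy.sum()
    if total <= 0:
        raise ValueError("degenerate fit: no Y-variance explained by any component")
    w_norm2 = (m.W ** 2) / np.maximum((m.W ** 2).sum(axis=0), 1e-300)
    p = m.W.shape[0]
    return np.sqrt(p * (w_norm2 @ ssy) / total)


def selectivity_ratio(m: PLSModel, Xs: np.ndarray):
    """Per-variable, per-class selectivity ratios plus their max aggregate.

    ``Xs`` must be the scaled training matrix the model was fit on.  Returns
    ``(sr_matrix, aggregate)`` with shapes (p, c) and (p,).
    """
    Xs = np.asarray(Xs, dtype=float)
    p, c = m.B.shape
    if Xs.shape[1] != p:
        raise ValueError(f"Xs has {Xs.shape[1]} columns, model expects {p}")
    sstot = (Xs ** 2).sum(axis=0)
    sr = np.zeros((p, c))
    for k in range(c):
        b = m.B[:, k]
        nb = np.linalg.norm(b)
        if nb == 0:
            raise ValueError(f"zero regression vector for class {m.class_order[k]!r}")
        t = Xs @ (b / nb)
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"degenerate target projection for class {m.class_order[k]!r}")
        p_tp = Xs.T @ t / tt
        ssexpl = p_tp ** 2 * tt
        ssres = sstot - ssexpl
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ssres > 1e-12 * np.maximum(sstot, 1e-300),
                             ssexpl / np.maximum(ssres, 1e-300),
                             SR_SENTINEL)
        sr[:, k] = np.minimum(ratio, SR_SENTINEL)
    return sr, sr.max(axis=1)


@dataclass(frozen=True)
class EliminationConfig:
    """Free parameters of the backward-elimination loop."""

    remove_fraction: float = 0.10   # fraction of current variables dropped per round
    patience: int = 25              # non-improving rounds tolerated before stopping
    min_vars: int = 5               # never reduce below this many variables
    improvement_tol: float = 0.0    # strict: any decrease in mean RMSECV counts
    parsimony_se: float = 0.5       # accept the smallest set within this many
                                    # standard errors of the minimum RMSECV
    A_max: int = 20
    rule: str = "argmax"
    scale_once: bool = False


@dataclass
class MarkerSet:
    """Surviving variable indices (ascending) with their wavenumbers."""

    variable_indices: np.ndarray
    wavenumbers: np.ndarray

    def __len__(self) -> int:
        return self.variable_indices.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"index": self.variable_indices, "wavenumber": self.wavenumbers}
        )

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class IterationRecord:
    kept_indices: np.ndarray
    chosen_A: int
    rmsecv_avg: float
    classification_error_avg: float
    vip: np.ndarray
    sr: np.ndarray


@dataclass
class SelectionTrace:
    iterations: list[IterationRecord] = field(default_factory=list)
    best_iteration: int = 0

    def to_dict(self) -> dict:
        return {
            "best_iteration": self.best_iteration,
            "iterations": [
                {
                    "kept_indices": r.kept_indices.tolist(),
                    "chosen_A": r.chosen_A,
                    "rmsecv_avg": r.rmsecv_avg,
                    "classification_error_avg": r.classification_error_avg,
                    "vip": r.vip.tolist(),
                    "sr": r.sr.tolist(),
                }
                for r in self.iterations
            ],
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))


def eliminate_iteratively(
    X: np.ndarray,
    labels,
    wavenumbers: np.ndarray | None = None,
    scheme: CVScheme = CVScheme(),
    cfg: EliminationConfig = EliminationConfig(),
):
    """Backward-eliminate variables until RMSECV stops improving.

    Each round: (1) cross-validate on the surviving variables, choosing the
    number of latent variables by minimum CV classification-error average and
    recording the best class-mean RMSECV over complexity; (2) refit on all
    samples at the chosen complexity and compute VIP and aggregate SR;
    (3) drop the ``remove_fraction`` of variables with the lowest geometric
    mean of VIP and SR percentile ranks (at least one).  The loop stops after
    ``patience`` consecutive rounds without a new RMSECV minimum or when
    ``min_vars`` is reached.  The returned marker set is the smallest visited
    group within ``parsimony_se`` standard errors of the minimum RMSECV (the
    one-SE rule); the full trace is returned alongside.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if wavenumbers is None:
        wavenumbers = np.arange(p, dtype=float) + 1.0
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if p < cfg.min_vars:
        raise ValueError(f"need at least min_vars={cfg.min_vars} variables, got {p}")

    folds_sizes = np.bincount(np.arange(n) % scheme.n_splits) if n >= scheme.n_splits else np.ones(n, int)
    min_train = int(n - folds_sizes.max())

    kept = np.arange(p)
    trace = SelectionTrace()
    best = np.inf
    streak = 0
    while True:
        Xc = X[:, kept]
        A_eff = min(cfg.A_max, Xc.shape[1], min_train - 1)
        curve, _report = cross_validate(
            Xc, labels, scheme=scheme, A_max=A_eff,
            rule=cfg.rule, scale_once=cfg.scale_once,
        )
        # groups of variables are compared by the best cross-validated RMSE
        # they can attain over model complexity: recording at the error-chosen
        # A would make consecutive iterations incomparable whenever the
        # discrete LV choice flips
        rmsecv_avg = float(curve.rmsecv.mean(axis=1).min())
        model = fit_plsda(Xc, labels, curve.chosen_A)
        from .preprocess import autoscale_apply  # local to avoid cycle at import
        Xs = autoscale_apply(model.scaling, Xc)
        v = vip(model)
        _, sr_agg = selectivity_ratio(model, Xs)
        trace.iterations.append(
            IterationRecord(
                kept_indices=kept.copy(),
                chosen_A=curve.chosen_A,
                rmsecv_avg=rmsecv_avg,
                classification_error_avg=float(curve.cv_error_avg[curve.chosen_A - 1]),
                vip=v,
                sr=sr_agg,
            )
        )
        if rmsecv_avg < best - cfg.improvement_tol:
            best = rmsecv_avg
            streak = 0
        else:
            streak += 1
        if streak >= cfg.patience:
            break
        if kept.size <= cfg.min_vars:
            break
        p_cur = kept.size
        rank_v = rankdata(v) / p_cur
        rank_s = rankdata(sr_agg) / p_cur
        score = np.sqrt(rank_v * rank_s)
        n_remove = max(1, int(cfg.remove_fraction * p_cur))
        n_remove = min(n_remove, p_cur - cfg.min_vars)
        if n_remove <= 0:
            break
        order = np.argsort(score, kind="stable")
        kept = np.sort(kept[order[n_remove:]])

    vals = np.array([r.rmsecv_avg for r in trace.iterations])
    # one-SE parsimony: SE of an RMSE estimate over n residuals is roughly
    # rmse / sqrt(2 n); prefer the smallest variable group within that band
    se = vals.min() / np.sqrt(2.0 * n)
    within = np.flatnonzero(vals <= vals.min() + cfg.parsimony_se * se)
    trace.best_iteration = int(within.max())
    best_rec = trace.iterations[trace.best_iteration]
    markers = MarkerSet(
        variable_indices=best_rec.kept_indices.copy(),
        wavenumbers=wavenumbers[best_rec.kept_indices],
    )
    return markers, trace
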