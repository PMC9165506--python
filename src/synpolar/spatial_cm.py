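"""Spatial connectome model (SCM): learn wiring rules from known polarities.

Without curated rules, the linear model A = X O Y^T is inverted for a
minimal real-valued rule matrix using only pairs of known polarity.
Vectorizing row-by-row (a = vec(A), o = vec(O)) turns the model into
a = (X (x) Y) o with (x) the Kronecker product; truncating to the rows of
pairs with observed connections of known polarity gives the training system
a' = K' o.  The minimal-norm solution is ridge regression

    o~ = (K'^T K' + alpha I)^-1 K'^T a'

with limits o~ ∝ K'^T a' as alpha -> inf and o~ = K'^+ a' (Moore-Penrose)
as alpha -> 0.  The learned O~ is substituted back into B~ = X O~ Y^T to
score every connection; predictions are ranked by |score| descending.

The full N^2 x (#NT * #R) Kronecker matrix is never materialized: design
rows are built pair by pair, one Kronecker product of an X row with a Y row
at a time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ExpressionMatrix,
    RankedPredictions,
    ScoreMatrix,
    SignedConnectome,
    ValidationError,
    WiringRuleNetwork,
    logger,
)

#: Default logarithmic grid for the regularization strength alpha.
DEFAULT_ALPHA_GRID = tuple(np.logspace(-3, 3, 121))


@dataclass(frozen=True)
class RidgeConfig:
    """Ridge-regression hyperparameters.

    alpha: regularization strength (>= 0; 0 selects the pseudoinverse branch).
    alpha_grid: candidate strengths for data-driven selection, ascending.
    seed: RNG seed recorded alongside any selection done with this config.
    """

    alpha: float = 1.0
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError("alpha must be nonnegative")
        grid = tuple(float(a) for a in self.alpha_grid)
        if any(a <= 0 for a in grid) or list(grid) != sorted(grid):
            raise ValidationError("alpha_grid must be positive and ascending")
        object.__setattr__(self, "alpha_grid", grid)


def build_design(X: ExpressionMatrix, Y: ExpressionMatrix,
                 training_pairs: Sequence[tuple[str, str]],
                 signs: SignedConnectome) -> tuple[np.ndarray, np.ndarray]:
    """Truncated design matrix K' and sign vector a' for the training pairs.

    Row for pair (i, j) is kron(Xb[i], Yb[j]); column (k, l) sits at index
    k * #R + l (row-major vec convention).  Every training pair must carry a
    nonzero sign.
    """
    if X.entity_ids != Y.entity_ids:
        raise ValidationError("X and Y list different neurons")
    idx = {lab: i for i, lab in enumerate(X.entity_ids)}
    Xb, Yb = X.binarized(), Y.binarized()
    rows = np.empty((len(training_pairs), Xb.shape[1] * Yb.shape[1]))
    a = np.empty(len(training_pairs))
    for r, (pre, post) in enumerate(training_pairs):
        i, j = idx[pre], idx[post]
        s = signs.signs[i, j]
        if s == 0:
            raise ValidationError(f"training pair ({pre}, {post}) has no known sign")
        rows[r] = np.kron(Xb[i], Yb[j])
        a[r] = s
    return rows, a


def ridge_fit(Kp: np.ndarray, ap: np.ndarray, cfg: RidgeConfig,
              nt_ids: Sequence[str], r_ids: Sequence[str]) -> WiringRuleNetwork:
    """Solve the truncated ridge system for the minimal rule matrix O~."""
    Kp = np.asarray(Kp, dtype=float)
    ap = np.asarray(ap, dtype=float)
    if Kp.shape[0] != ap.shape[0]:
        raise ValidationError("design and sign vector row counts differ")
    p = Kp.shape[1]
    if p != len(nt_ids) * len(r_ids):
        raise ValidationError("design width does not match #NT * #R")
    if cfg.alpha == 0:
        o = np.linalg.pinv(Kp) @ ap
        if np.linalg.matrix_rank(Kp.T @ Kp) < p:
            warnings.warn("normal matrix singular at alpha=0; "
                          "using minimum-norm pseudoinverse solution")
    else:
        o = np.linalg.solve(Kp.T @ Kp + cfg.alpha * np.eye(p), Kp.T @ ap)
    O = o.reshape(len(nt_ids), len(r_ids))
    return WiringRuleNetwork(tuple(nt_ids), tuple(r_ids), O, ternary=False)


def scm_scores(X: ExpressionMatrix, O_tilde: WiringRuleNetwork,
               Y: ExpressionMatrix, mask=None) -> ScoreMatrix:
    """Score all connections with the learned rules: B~ = Xb O~ Yb^T."""
    from .connectome_model import cm_weights

    sm = cm_weights(X, O_tilde, Y, mask=mask)
    return ScoreMatrix(sm.neuron_ids, sm.scores, method="scm")


def fit_scm(X: ExpressionMatrix, Y: ExpressionMatrix,
            known: SignedConnectome,
            training_pairs: Sequence[tuple[str, str]],
            cfg: RidgeConfig) -> WiringRuleNetwork:
    """Convenience wrapper: build the truncated design and ridge-fit O~."""
    Kp, ap = build_design(X, Y, training_pairs, known)
    return ridge_fit(Kp, ap, cfg, X.gene_ids, Y.gene_ids)


def rank_and_threshold(scores: ScoreMatrix,
                       eligible: Sequence[tuple[str, str]],
                       method: str | None = None) -> RankedPredictions:
    """Rank eligible pairs by |score| descending; drop zero scores.

    Ties in |score| are broken by (pre label, post label) so rankings are
    deterministic and independent of input order.
    """
    idx = {lab: i for i, lab in enumerate(scores.neuron_ids)}
    recs = []
    for pre, post in eligible:
        s = scores.scores[idx[pre], idx[post]]
        if s != 0:
            recs.append((pre, post, float(s)))
    recs.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(recs) + 1),
            "pre": [r[0] for r in recs],
            "post": [r[1] for r in recs],
            "score": [r[2] for r in recs],
            "predicted_sign": [1 if r[2] > 0 else -1 for r in recs],
        }
    )
    if not len(recs):
        df = pd.DataFrame(columns=["rank", "pre", "post", "score", "predicted_sign"])
    return RankedPredictions(df, method=method or scores.method)


def select_alpha(X: ExpressionMatrix, Y: ExpressionMatrix,
                 known: SignedConnectome,
                 training_pairs: Sequence[tuple[str, str]],
                 reference: SignedConnectome,
                 reference_pairs: Sequence[tuple[str, str]],
                 cfg: RidgeConfig,
                 precision_target: float = 0.95) -> tuple[float, pd.DataFrame]:
    """Pick alpha maximizing the rank at which the precision target holds.

    Each grid alpha is scored by the largest rank r with running precision
    p(r) >= target on the reference pairs; ties go to the larger alpha
    (stronger regularization at equal performance).  Returns the chosen
    alpha and the per-alpha diagnostic table.
    """
    from .evaluation import precision_curve, threshold_for_precision

    Kp, ap = build_design(X, Y, training_pairs, known)
    rows = []
    best_alpha, best_rank = None, -1
    for alpha in cfg.alpha_grid:
        O_t = ridge_fit(Kp, ap, RidgeConfig(alpha=alpha), X.gene_ids, Y.gene_ids)
        ranked = rank_and_threshold(scm_scores(X, O_t, Y), reference_pairs)
        curve = precision_curve(ranked, reference)
        hit = threshold_for_precision(curve, precision_target)
        rank = hit[0] if hit is not None else 0
        rows.append({"alpha": alpha, "rank_at_target": rank})
        if rank >= best_rank:  # >= breaks ties toward larger alpha
            best_alpha, best_rank = alpha, rank
    logger.info("select_alpha: alpha=%g (rank_at_%g=%d)", best_alpha,
                precision_target, best_rank)
    return float(best_alpha), pd.DataFrame(rows)
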