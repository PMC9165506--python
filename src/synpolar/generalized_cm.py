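"""Generalized connectome model (GCM): polarity inference from signs alone.

Eliminating the expression matrices from the linear polarity model leads to
the self-consistent equation A = A W A in an unknown generalized rule matrix
W over neuron space.  Fitting proceeds as for the spatial model: the
regression row for pair (i, j) is kron(A[i, :], A[:, j]) — so the feature
for slot (k, l) is A[i, k] * A[l, j] and the prediction is (A W A)[i, j] —
truncated to training pairs of known polarity, and solved by ridge
regression.

Because there are N^2 features but only ~N_train samples, the solve uses the
dual (kernel) form: with G the Gram matrix of training rows,

    w = K'^T (G + alpha I)^-1 a'

and the Gram entries factorize without materializing any Kronecker row:
<row(i,j), row(i',j')> = <A[i,:], A[i',:]> * <A[:,j], A[:,j']>.

At alpha = 0 with every nonzero entry as training data the fit reproduces
the input exactly (the pseudoinverse overfitting limit); as alpha -> inf the
solution becomes w ∝ K'^T a', whose prediction ranking coincides with the
signed length-3 score A A^T A (SL3).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data_model import (
    ScoreMatrix,
    SignedConnectome,
    ValidationError,
    logger,
)
from .spatial_cm import RidgeConfig


class GeneralizedRuleMatrix:
    """Real-valued N x N rule matrix W~ over neuron space."""

    def __init__(self, neuron_ids: Sequence[str], weights: np.ndarray):
        weights = np.asarray(weights, dtype=float)
        n = len(neuron_ids)
        if weights.shape != (n, n):
            raise ValidationError("generalized rule matrix must be N x N")
        if not np.isfinite(weights).all():
            raise ValidationError("generalized rule matrix has non-finite entries")
        self.neuron_ids = tuple(neuron_ids)
        self.weights = weights


def _pair_indices(A: SignedConnectome,
                  training_pairs: Sequence[tuple[str, str]]) -> tuple[np.ndarray, np.ndarray]:
    idx = {lab: i for i, lab in enumerate(A.neuron_ids)}
    ii = np.array([idx[p] for p, _ in training_pairs], dtype=int)
    jj = np.array([idx[q] for _, q in training_pairs], dtype=int)
    return ii, jj


def gcm_fit(A: SignedConnectome, training_pairs: Sequence[tuple[str, str]],
            cfg: RidgeConfig) -> GeneralizedRuleMatrix:
    """Fit W~ by truncated ridge regression in the dual form."""
    if not training_pairs:
        raise ValidationError("GCM requires a nonempty training set")
    ii, jj = _pair_indices(A, training_pairs)
    s = A.signs.astype(float)
    a = s[ii, jj]
    if (a == 0).any():
        k = int(np.argmax(a == 0))
        raise ValidationError(f"training pair {training_pairs[k]} has no known sign")

    row_gram = s @ s.T          # <A[i,:], A[i',:]>
    col_gram = s.T @ s          # <A[:,j], A[:,j']>
    G = row_gram[np.ix_(ii, ii)] * col_gram[np.ix_(jj, jj)]
    m = len(training_pairs)
    if cfg.alpha == 0:
        beta = np.linalg.pinv(G) @ a
    else:
        beta = np.linalg.solve(G + cfg.alpha * np.eye(m), a)
    # w = K'^T beta, refolded to W[k, l] = sum_r beta_r A[i_r, k] A[l, j_r]
    W = s[ii].T @ (beta[:, None] * s[:, jj].T)
    logger.info("gcm_fit: %d training pairs, alpha=%g", m, cfg.alpha)
    return GeneralizedRuleMatrix(A.neuron_ids, W)


def gcm_scores(A: SignedConnectome, W: GeneralizedRuleMatrix,
               mask=None) -> ScoreMatrix:
    """Polarity predictions A* = A W~ A, optionally masked to present pairs."""
    if W.neuron_ids != A.neuron_ids:
        raise ValidationError("rule matrix neuron labels do not match connectome")
    scores = A.signs.astype(float) @ W.weights @ A.signs.astype(float)
    if mask is not None:
        scores = scores * mask.present
    return ScoreMatrix(A.neuron_ids, scores, method="gcm")


def gcm_closed_form_rules(A: SignedConnectome, alpha: float) -> GeneralizedRuleMatrix:
    """Closed-form regularization family W(alpha) = (A^T A + alpha I)^-1 A^T.

    This is the analytic GCM family connecting the overfitting pseudoinverse
    limit (alpha -> 0: W = A†, so A W A = A reproduces the input) to the
    network-based predictor limit (alpha -> inf: W ∝ A^T, so the prediction
    ranking is exactly the signed length-3 score A A^T A).  Use it for
    regularization sweeps of the model family itself; use :func:`gcm_fit`
    when learning W~ from a training subset of known polarities.
    """
    if alpha < 0:
        raise ValidationError("alpha must be nonnegative")
    s = A.signs.astype(float)
    n = s.shape[0]
    if alpha == 0:
        W = np.linalg.pinv(s)
    else:
        W = np.linalg.solve(s.T @ s + alpha * np.eye(n), s.T)
    return GeneralizedRuleMatrix(A.neuron_ids, W)


def gcm_sl3_limit(A: SignedConnectome) -> ScoreMatrix:
    """Closed-form heavily regularized GCM: the SL3 score A A^T A.

    This is the default operating point; the finite-alpha path exists for
    regularization sweeps.
    """
    from .signed_predictors import sl3_scores

    sm = sl3_scores(A)
    return ScoreMatrix(sm.neuron_ids, sm.scores, method="gcm_sl3_limit")
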