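"""Connectome model (CM): polarity scores from expression and wiring rules.

The CM assigns each directed neuron pair (i, j) a weight

    B[i, j] = sum_k sum_l X[i, k] * O[k, l] * Y[j, l]        (B = X O Y^T)

where X is the presynaptic neurotransmitter (NT) expression, Y the
postsynaptic receptor (R) expression and O the signed NT-R wiring-rule
matrix.  The inferred polarity is A = sign(B).  Expression is used as
presence/absence: a rule (k, l) contributes to pair (i, j) exactly when
neuron i expresses NT k, neuron j expresses R l, and O[k, l] != 0, so B
counts positive minus negative contributing rules.

Pairs present in the connectome are classified by their contributing rules:
``known_+/-`` when at least one rule contributes and all agree in sign,
``complex`` when rules of both signs contribute, ``unknown`` when both sides
express genes but no rule applies, and ``excluded`` when the presynaptic
neuron expresses no NT or the postsynaptic neuron no R.  The CM resolves a
complex pair whenever its positive and negative rule counts do not cancel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import (
    ConnectomeMask,
    ExpressionMatrix,
    PolarityCatalog,
    ScoreMatrix,
    SignedConnectome,
    ValidationError,
    logger,
)


def _check_alignment(X: ExpressionMatrix, O, Y: ExpressionMatrix) -> None:
    if X.gene_ids != O.nt_ids:
        raise ValidationError("X gene labels do not match rule-network NT labels")
    if Y.gene_ids != O.r_ids:
        raise ValidationError("Y gene labels do not match rule-network R labels")
    if X.entity_ids != Y.entity_ids:
        raise ValidationError("X and Y list different neurons")


def cm_weights(X: ExpressionMatrix, O, Y: ExpressionMatrix,
               mask: ConnectomeMask | None = None) -> ScoreMatrix:
    """CM weight matrix B = Xb O Yb^T with binarized expression.

    When ``mask`` is given, scores of non-present pairs are zeroed out so the
    reported matrix covers only observed connections (the full scores remain
    a single matrix product away for callers that want them).
    """
    _check_alignment(X, O, Y)
    B = X.binarized() @ O.weights @ Y.binarized().T
    if mask is not None:
        if mask.neuron_ids != X.entity_ids:
            raise ValidationError("mask neuron labels do not match expression")
        B = B * mask.present
    return ScoreMatrix(X.entity_ids, B, method="cm")


def cm_sign(B: ScoreMatrix) -> SignedConnectome:
    """Element-wise sign of the CM weights; sign(0) = 0 stays unresolved."""
    return SignedConnectome(B.neuron_ids, np.sign(B.scores).astype(np.int64))


def _rule_counts(X: ExpressionMatrix, O, Y: ExpressionMatrix
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair counts of positive and negative contributing rules."""
    Xb, Yb = X.binarized(), Y.binarized()
    n_pos = Xb @ (O.weights > 0) @ Yb.T
    n_neg = Xb @ (O.weights < 0) @ Yb.T
    return n_pos, n_neg


def classify_pairs(X: ExpressionMatrix, O, Y: ExpressionMatrix,
                   mask: ConnectomeMask) -> PolarityCatalog:
    """Classify every mask-present pair by its contributing wiring rules."""
    if not O.ternary:
        raise ValidationError("classification requires a ternary rule network")
    _check_alignment(X, O, Y)
    if mask.neuron_ids != X.entity_ids:
        raise ValidationError("mask neuron labels do not match expression")

    n_pos, n_neg = _rule_counts(X, O, Y)
    pre_expresses = X.binarized().sum(axis=1) > 0
    post_expresses = Y.binarized().sum(axis=1) > 0

    labels = np.asarray(mask.neuron_ids)
    ii, jj = np.nonzero(mask.present)
    rows = []
    for i, j in zip(ii, jj):
        if not pre_expresses[i] or not post_expresses[j]:
            cat = "excluded"
        elif n_pos[i, j] > 0 and n_neg[i, j] > 0:
            cat = "complex"
        elif n_pos[i, j] > 0:
            cat = "known_positive"
        elif n_neg[i, j] > 0:
            cat = "known_negative"
        else:
            cat = "unknown"
        rows.append((labels[i], labels[j], cat))
    catalog = PolarityCatalog(pd.DataFrame(rows, columns=["pre", "post", "category"]))
    logger.info("classify_pairs: %s", catalog.counts())
    return catalog


def resolve_complex(B: ScoreMatrix, catalog: PolarityCatalog) -> SignedConnectome:
    """Resolve complex-labeled pairs by the sign of their CM weight.

    A complex pair whose positive and negative rule counts cancel exactly
    (B = 0) remains unresolved.  All non-complex pairs are left at 0: the
    result contains CM-resolved complex polarities only.
    """
    idx = {lab: i for i, lab in enumerate(B.neuron_ids)}
    signs = np.zeros_like(B.scores, dtype=np.int64)
    for pre, post in catalog.pairs("complex"):
        s = np.sign(B.scores[idx[pre], idx[post]])
        signs[idx[pre], idx[post]] = int(s)
    resolved = SignedConnectome(B.neuron_ids, signs)
    logger.info("resolve_complex: resolved %d of %d complex pairs",
                int(np.count_nonzero(signs)), len(catalog.pairs("complex")))
    return resolved
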