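"""Closed-form sign predictors on the signed directed network alone.

Given the ternary polarity matrix A (rows presynaptic):

* SL2 (signed paths of length two, structural balance):
  P = A^T A + A A^T, counting shared presynaptic partners (A^T A) plus
  shared postsynaptic partners (A A^T), each path weighted by the product
  of its edge signs.
* SL3 (signed paths of length three): P = A A^T A — forward, backward,
  forward steps; equivalently A * (A^T A) or (A A^T) * A.
* SPA (signed preferential attachment):
  P[i, j] = k_i^{+,out} k_j^{+,in} - k_i^{-,out} k_j^{-,in}, treating the
  positive and negative layers as independent preferential-attachment
  processes.

All arithmetic is integer on ternary inputs, so score thresholds are exact.
Only edges of known sign contribute to degrees and paths; unknown-polarity
edges are zeros in A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ScoreMatrix, SignedConnectome


@dataclass(frozen=True)
class SignedDegrees:
    """Per-neuron counts of signed in/out edges."""

    table: pd.DataFrame  # columns: neuron, k_plus_out, k_minus_out, k_plus_in, k_minus_in


def signed_degrees(A: SignedConnectome) -> SignedDegrees:
    s = A.signs
    return SignedDegrees(pd.DataFrame({
        "neuron": list(A.neuron_ids),
        "k_plus_out": (s > 0).sum(axis=1),
        "k_minus_out": (s < 0).sum(axis=1),
        "k_plus_in": (s > 0).sum(axis=0),
        "k_minus_in": (s < 0).sum(axis=0),
    }))


def sl2_scores(A: SignedConnectome) -> ScoreMatrix:
    s = A.signs
    P = s.T @ s + s @ s.T
    return ScoreMatrix(A.neuron_ids, P.astype(float), method="sl2")


def sl3_scores(A: SignedConnectome) -> ScoreMatrix:
    s = A.signs
    P = s @ s.T @ s
    return ScoreMatrix(A.neuron_ids, P.astype(float), method="sl3")


def spa_scores(A: SignedConnectome) -> ScoreMatrix:
    s = A.signs
    k_pos_out = (s > 0).sum(axis=1)
    k_neg_out = (s < 0).sum(axis=1)
    k_pos_in = (s > 0).sum(axis=0)
    k_neg_in = (s < 0).sum(axis=0)
    P = np.outer(k_pos_out, k_pos_in) - np.outer(k_neg_out, k_neg_in)
    return ScoreMatrix(A.neuron_ids, P.astype(float), method="spa")


SCORERS = {"sl2": sl2_scores, "sl3": sl3_scores, "spa": spa_scores}
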