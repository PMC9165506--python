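"""Precision-ranked validation of polarity predictions.

The central metric is precision at rank: predictions are ordered by |score|
descending, each rank i scores a hit a_i = 1 exactly when the predicted sign
equals the reference sign, and the running precision is

    p(r) = (1/r) * sum_{i<=r} a_i.

On top of that sit the operating-point extraction (largest rank still at a
target precision, and the |score| cutoff there), k-fold cross-validation
with per-rank mean curves, the input-subsampling robustness experiment, the
analytic random baseline p^2 + (1-p)^2 for sign-matched guessing with
positive fraction p, and the union report that merges rule-based and
learned-model resolutions into one signed network tally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ExpressionMatrix,
    RankedPredictions,
    ScoreMatrix,
    SignedConnectome,
    ValidationError,
    logger,
)
from .generalized_cm import gcm_fit, gcm_scores
from .signed_predictors import SCORERS
from .spatial_cm import RidgeConfig, fit_scm, rank_and_threshold, scm_scores


@dataclass(frozen=True)
class PrecisionCurve:
    """Running precision over a ranked prediction list."""

    ranks: np.ndarray        # 1..R
    hits: np.ndarray         # 0/1 per rank
    precision: np.ndarray    # cumulative mean of hits
    score_at_rank: np.ndarray  # |score| per rank

    def __len__(self) -> int:
        return len(self.ranks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rank": self.ranks, "hit": self.hits,
                             "precision": self.precision,
                             "abs_score": self.score_at_rank})


def precision_curve(ranked: RankedPredictions,
                    reference: SignedConnectome) -> PrecisionCurve:
    """Score a ranking against reference signs.

    Pairs without a reference sign are dropped (they cannot be scored) before
    ranks are recounted 1..R in the surviving order.
    """
    idx = {lab: i for i, lab in enumerate(reference.neuron_ids)}
    hits, scores = [], []
    for pre, post, score, sign in zip(ranked.table["pre"], ranked.table["post"],
                                      ranked.table["score"],
                                      ranked.table["predicted_sign"]):
        ref = reference.signs[idx[pre], idx[post]]
        if ref == 0:
            continue
        hits.append(1 if sign == ref else 0)
        scores.append(abs(score))
    if not hits:
        raise ValidationError("no ranked pair has a reference sign")
    hits_arr = np.asarray(hits)
    ranks = np.arange(1, len(hits_arr) + 1)
    return PrecisionCurve(ranks, hits_arr, np.cumsum(hits_arr) / ranks,
                          np.asarray(scores))


def threshold_for_precision(curve: PrecisionCurve, target: float
                            ) -> tuple[int, float] | None:
    """Largest rank r with p(r) >= target and the |score| cutoff at r."""
    if not 0 < target <= 1:
        raise ValidationError("precision target must be in (0, 1]")
    ok = np.nonzero(curve.precision >= target)[0]
    if len(ok) == 0:
        warnings.warn(f"no rank reaches precision {target}")
        return None
    r = int(ok[-1])
    return r + 1, float(curve.score_at_rank[r])


def random_baseline(p_pos: float) -> float:
    """Expected precision of sign-matched random guessing.

    With truths and independent predictions both positive with probability
    p, a prediction is correct with probability p^2 + (1-p)^2.
    """
    if not 0 <= p_pos <= 1:
        raise ValidationError("positive fraction must be in [0, 1]")
    return p_pos ** 2 + (1 - p_pos) ** 2


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Random partition of known-polarity pairs into k near-equal folds."""

    k: int
    assignments: Mapping[tuple[str, str], int]
    seed: int

    def fold_pairs(self, fold: int) -> list[tuple[str, str]]:
        return [p for p, f in self.assignments.items() if f == fold]


def make_folds(pairs: Sequence[tuple[str, str]], k: int, seed: int) -> FoldPlan:
    if k < 2:
        raise ValidationError("cross-validation needs k >= 2")
    if k > len(pairs):
        raise ValidationError("more folds than pairs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    assignments = {tuple(pairs[i]): int(r % k) for r, i in enumerate(order)}
    return FoldPlan(k, assignments, seed)


def _masked_known(known: SignedConnectome,
                  drop: Sequence[tuple[str, str]]) -> SignedConnectome:
    """Copy of the known network with the given pairs zeroed out."""
    idx = {lab: i for i, lab in enumerate(known.neuron_ids)}
    signs = known.signs.copy()
    for pre, post in drop:
        signs[idx[pre], idx[post]] = 0
    return SignedConnectome(known.neuron_ids, signs)


def score_with_method(method: str, known: SignedConnectome,
                      X: ExpressionMatrix | None = None,
                      Y: ExpressionMatrix | None = None,
                      training_pairs: Sequence[tuple[str, str]] | None = None,
                      cfg: RidgeConfig | None = None) -> ScoreMatrix:
    """Dispatch one scoring method on a (possibly truncated) input network.

    ``method``: one of ``scm``, ``gcm``, ``sl2``, ``sl3``, ``spa``.  The SCM
    needs expression matrices; SCM and GCM train on ``training_pairs`` (all
    nonzero pairs of ``known`` when omitted).
    """
    cfg = cfg or RidgeConfig()
    if training_pairs is None:
        ii, jj = np.nonzero(known.signs)
        training_pairs = [(known.neuron_ids[i], known.neuron_ids[j])
                          for i, j in zip(ii, jj)]
    if method == "scm":
        if X is None or Y is None:
            raise ValidationError("SCM requires NT and R expression matrices")
        O_t = fit_scm(X, Y, known, training_pairs, cfg)
        return scm_scores(X, O_t, Y)
    if method == "gcm":
        W = gcm_fit(known, training_pairs, cfg)
        return gcm_scores(known, W)
    if method in SCORERS:
        return SCORERS[method](known)
    raise ValidationError(f"unknown method {method!r}")


def kfold_cv(method: str, known: SignedConnectome, plan: FoldPlan,
             X: ExpressionMatrix | None = None,
             Y: ExpressionMatrix | None = None,
             cfg: RidgeConfig | None = None) -> PrecisionCurve:
    """k-fold cross-validation returning the per-rank mean precision curve.

    Each fold is held out in turn: the method trains on the other k-1 folds
    (the held-out signs are removed from the input network), the test-fold
    pairs are ranked by |score|, and their curve is computed against the
    held-out known signs.  Curves are averaged per rank, truncated to the
    shortest fold.
    """
    curves = []
    for fold in range(plan.k):
        test_pairs = plan.fold_pairs(fold)
        if not test_pairs:
            raise ValidationError(f"fold {fold} has no test pairs")
        train_pairs = [p for p, f in plan.assignments.items() if f != fold]
        truncated = _masked_known(known, test_pairs)
        scores = score_with_method(method, truncated, X=X, Y=Y,
                                   training_pairs=train_pairs, cfg=cfg)
        ranked = rank_and_threshold(scores, test_pairs, method=method)
        curves.append(precision_curve(ranked, known))
    r_min = min(len(c) for c in curves)
    if r_min == 0:
        raise ValidationError("a fold produced no scoreable predictions")
    mean_p = np.mean([c.precision[:r_min] for c in curves], axis=0)
    mean_hits = np.mean([c.hits[:r_min] for c in curves], axis=0)
    mean_score = np.mean([c.score_at_rank[:r_min] for c in curves], axis=0)
    logger.info("kfold_cv: method=%s k=%d mean precision at last rank %.3f",
                method, plan.k, mean_p[-1])
    return PrecisionCurve(np.arange(1, r_min + 1), mean_hits, mean_p, mean_score)


# ---------------------------------------------------------------------------
# Subsampling robustness
# ---------------------------------------------------------------------------

def subsample_experiment(X: ExpressionMatrix, Y: ExpressionMatrix,
                         known: SignedConnectome,
                         reference: SignedConnectome,
                         reference_pairs: Sequence[tuple[str, str]],
                         fraction_grid: Sequence[float],
                         seed: int, reps: int = 25,
                         cfg: RidgeConfig | None = None,
                         precision_target: float = 0.95,
                         score_cutoff: float | None = None) -> pd.DataFrame:
    """Learned-rule robustness to training-set subsampling.

    For each fraction f, ``reps`` random subsets of the known-polarity pairs
    of size f * n_known train the model; predictions on the reference pairs
    are scored against the reference signs.  Returns one row per (fraction,
    rep) with the rank and cutoff at the precision target and the precision
    over the full reference list.  When ``score_cutoff`` is given (e.g. the
    full-data operating point), each row also reports the precision and count
    of predictions with |score| >= cutoff.
    """
    cfg = cfg or RidgeConfig()
    for f in fraction_grid:
        if not 0 < f <= 1:
            raise ValidationError("fractions must be in (0, 1]")
    ii, jj = np.nonzero(known.signs)
    known_pairs = [(known.neuron_ids[i], known.neuron_ids[j])
                   for i, j in zip(ii, jj)]
    rng = np.random.default_rng(seed)
    rows = []
    for f in fraction_grid:
        n_take = max(1, int(round(f * len(known_pairs))))
        for rep in range(reps):
            take = rng.choice(len(known_pairs), size=n_take, replace=False)
            train = [known_pairs[t] for t in take]
            truncated = _masked_known(
                known, [p for t, p in enumerate(known_pairs) if t not in set(take)])
            O_t = fit_scm(X, Y, truncated, train, cfg)
            ranked = rank_and_threshold(scm_scores(X, O_t, Y), reference_pairs)
            curve = precision_curve(ranked, reference)
            hit = threshold_for_precision(curve, precision_target)
            row = {
                "fraction": f, "rep": rep, "n_train": n_take,
                "rank_at_target": hit[0] if hit else 0,
                "cutoff_at_target": hit[1] if hit else np.nan,
                "final_precision": float(curve.precision[-1]),
            }
            if score_cutoff is not None:
                above = curve.score_at_rank >= score_cutoff
                row["n_at_cutoff"] = int(above.sum())
                row["precision_at_cutoff"] = (
                    float(curve.hits[above].mean()) if above.any() else np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Union report
# ---------------------------------------------------------------------------

def _sign_counts(signs: np.ndarray) -> tuple[int, int]:
    return int((signs > 0).sum()), int((signs < 0).sum())


def union_report(known: SignedConnectome,
                 cm_resolved: SignedConnectome,
                 scm_thresholded: SignedConnectome) -> dict:
    """Merge known polarities with rule-resolved and learned-model additions.

    The three contributing sets must be pairwise disjoint; any overlap is an
    error listing the conflicting pairs.  Returns excitatory/inhibitory
    tallies before and after, the added counts, and E:I ratios.
    """
    if not (known.neuron_ids == cm_resolved.neuron_ids == scm_thresholded.neuron_ids):
        raise ValidationError("union inputs must share neuron ordering")
    sets = {"known": known.signs != 0, "cm_resolved": cm_resolved.signs != 0,
            "scm": scm_thresholded.signs != 0}
    names = list(sets)
    conflicts = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            overlap = sets[names[a]] & sets[names[b]]
            for i, j in zip(*np.nonzero(overlap)):
                conflicts.append((names[a], names[b], known.neuron_ids[i],
                                  known.neuron_ids[j]))
    if conflicts:
        raise ValidationError(f"overlapping pairs between contributing sets: "
                              f"{conflicts[:10]}{'...' if len(conflicts) > 10 else ''}")
    merged = known.signs + cm_resolved.signs + scm_thresholded.signs
    pos0, neg0 = _sign_counts(known.signs)
    add_pos, add_neg = _sign_counts(cm_resolved.signs + scm_thresholded.signs)
    pos1, neg1 = _sign_counts(merged)
    report = {
        "known_excitatory": pos0, "known_inhibitory": neg0,
        "added_excitatory": add_pos, "added_inhibitory": add_neg,
        "total_excitatory": pos1, "total_inhibitory": neg1,
        "total_resolved": pos1 + neg1,
        "ei_ratio_before": pos0 / neg0 if neg0 else np.inf,
        "ei_ratio_after": pos1 / neg1 if neg1 else np.inf,
    }
    logger.info("union_report: %s", report)
    return report
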