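"""Planted-rule synthetic data with the structure the polarity models assume.

The generator draws Bernoulli presence/absence expression for presynaptic
neurotransmitters (X) and postsynaptic receptors (Y), plants a sparse ternary
wiring-rule matrix O, draws a directed connectome mask, and derives the true
polarity network A = sign(Xb O Yb^T) on the mask.  Pair categories follow the
same classification used on real data (known / complex / unknown / excluded
from contributing-rule signs).  A configurable share of the known labels is
then hidden (relabeled unknown) to create prediction targets, and optional
label noise flips observed signs.

Defaults emulate a nematode-scale chemical-synapse dataset: 295 neurons,
3 neurotransmitters, 42 receptors, a few percent connection density, and a
positive fraction among known labels near 64%.  Expression is modeled as
independent Bernoulli rather than anatomically clustered neuron classes;
this reproduces the statistical structure the linear polarity model sees,
not the correlated expression of real neuron types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome_model import classify_pairs, cm_sign, cm_weights
from .data_model import (
    ConnectomeMask,
    ExpressionMatrix,
    PolarityCatalog,
    SignedConnectome,
    ValidationError,
    WiringRuleNetwork,
    logger,
)


@dataclass(frozen=True)
class PlantedModel:
    """Parameters of the planted-rule generative model.

    Probabilities are per-entry Bernoulli rates; ``hide_fraction`` is the
    share of known-polarity pairs whose label is hidden (relabeled unknown),
    ``label_noise`` the probability that an observed known sign is flipped.
    ``p_rule_positive`` biases planted rule signs so that known labels come
    out ~64% positive at the defaults (single calibration, then frozen).
    """

    n_neurons: int = 295
    n_nt: int = 3
    n_r: int = 42
    p_express_nt: float = 0.5
    p_express_r: float = 0.1
    rule_density: float = 0.25
    p_rule_positive: float = 0.6
    edge_density: float = 0.05
    hide_fraction: float = 0.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_express_nt", "p_express_r", "rule_density",
                     "p_rule_positive", "edge_density", "hide_fraction",
                     "label_noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_neurons", "n_nt", "n_r"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class SyntheticDataset:
    """One draw of the planted model.

    ``A_full`` carries the true signs of every mask-present pair the planted
    rules determine; ``A_known`` carries only the observed (not hidden,
    possibly noise-flipped) known labels; ``catalog`` categorizes pairs as
    observed, i.e. hidden pairs appear as unknown.  ``hidden_pairs`` lists
    the held-out pairs with their true signs available through ``A_full``.
    """

    model: PlantedModel
    X: ExpressionMatrix
    Y: ExpressionMatrix
    O_true: WiringRuleNetwork
    mask: ConnectomeMask
    A_full: SignedConnectome
    A_known: SignedConnectome
    catalog: PolarityCatalog
    hidden_pairs: tuple[tuple[str, str], ...]


def generate(model: PlantedModel) -> SyntheticDataset:
    """Draw one dataset from the planted model (bit-reproducible per seed)."""
    rng = np.random.default_rng(model.seed)
    neurons = tuple(f"n{i:03d}" for i in range(model.n_neurons))
    nts = tuple(f"nt{k}" for k in range(model.n_nt))
    rs = tuple(f"r{l:02d}" for l in range(model.n_r))

    Xv = (rng.random((model.n_neurons, model.n_nt)) < model.p_express_nt)
    Yv = (rng.random((model.n_neurons, model.n_r)) < model.p_express_r)
    if not Xv.any() or not Yv.any():
        raise ValidationError("degenerate model: no expressed genes drawn")
    X = ExpressionMatrix(neurons, nts, Xv.astype(float))
    Y = ExpressionMatrix(neurons, rs, Yv.astype(float))

    # Fixed rule count and sign composition (random placement): the planted
    # rule set is a design constant of the benchmark, not a random variable,
    # which keeps the positive-label fraction stable across seeds.
    n_slots = model.n_nt * model.n_r
    n_rules = max(1, int(round(model.rule_density * n_slots)))
    n_pos_rules = int(round(model.p_rule_positive * n_rules))
    rule_signs = np.array([1.0] * n_pos_rules + [-1.0] * (n_rules - n_pos_rules))
    slots = rng.choice(n_slots, size=n_rules, replace=False)
    rules = np.zeros(n_slots)
    rules[slots] = rule_signs
    O_true = WiringRuleNetwork(nts, rs, rules.reshape(model.n_nt, model.n_r),
                               ternary=True)

    present = (rng.random((model.n_neurons,) * 2) < model.edge_density).astype(int)
    np.fill_diagonal(present, 0)
    if not present.any():
        raise ValidationError("degenerate model: empty connectome mask")
    mask = ConnectomeMask(neurons, present)

    B = cm_weights(X, O_true, Y, mask=mask)
    A_full = cm_sign(B)
    catalog = classify_pairs(X, O_true, Y, mask)

    # Hide a share of the known labels; they become prediction targets.
    table = catalog.table.copy()
    known_idx = np.nonzero(table["category"].isin(
        ("known_positive", "known_negative")).to_numpy())[0]
    n_hide = int(round(model.hide_fraction * len(known_idx)))
    hide = rng.choice(known_idx, size=n_hide, replace=False) if n_hide else []
    hidden_pairs = tuple(
        (table.at[i, "pre"], table.at[i, "post"]) for i in sorted(hide))
    table.loc[sorted(hide), "category"] = "unknown"

    # Observed labels = known-category pairs only (complex/unknown pairs have
    # no observed polarity even when the planted rules would resolve them).
    nidx = {lab: i for i, lab in enumerate(neurons)}
    observed = np.zeros_like(A_full.signs)
    for i in known_idx:
        pre, post = catalog.table.at[i, "pre"], catalog.table.at[i, "post"]
        observed[nidx[pre], nidx[post]] = A_full.signs[nidx[pre], nidx[post]]
    for pre, post in hidden_pairs:
        observed[nidx[pre], nidx[post]] = 0

    if model.label_noise > 0:
        oi, oj = np.nonzero(observed)
        flip = rng.random(len(oi)) < model.label_noise
        observed[oi[flip], oj[flip]] *= -1
        for i, j, f in zip(oi, oj, flip):
            if f:
                row = (table["pre"] == neurons[i]) & (table["post"] == neurons[j])
                table.loc[row, "category"] = (
                    "known_positive" if observed[i, j] > 0 else "known_negative")
    A_known = SignedConnectome(neurons, observed)
    out_catalog = PolarityCatalog(table)
    logger.info("generate: %d edges, categories %s, %d hidden",
                mask.n_edges, out_catalog.counts(), len(hidden_pairs))
    return SyntheticDataset(model, X, Y, O_true, mask, A_full, A_known,
                            out_catalog, hidden_pairs)


def positive_fraction(ds: SyntheticDataset) -> float:
    """Share of positive signs among the true known-category labels of one draw.

    Reclassifies from the planted truth so that hidden labels still count and
    rule-resolved complex pairs do not.
    """
    truth = classify_pairs(ds.X, ds.O_true, ds.Y, ds.mask)
    counts = truth.counts()
    n_known = counts["known_positive"] + counts["known_negative"]
    if n_known == 0:
        raise ValidationError("dataset has no known-category pairs")
    return counts["known_positive"] / n_known
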