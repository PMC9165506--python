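"""Domain containers and tab-separated file IO for signed connectome analysis.

The containers mirror the objects of the polarity-inference problem:

* :class:`ExpressionMatrix` — nonnegative neuron x gene expression levels,
  used in two roles: neurotransmitter (NT) expression of presynaptic neurons
  (``X``) and receptor (R) expression of postsynaptic neurons (``Y``).
* :class:`WiringRuleNetwork` — a signed NT x R matrix ``O``; curated input
  rules are ternary (-1/0/+1), learned ("minimal") rules are real-valued.
* :class:`SignedConnectome` — an N x N directed matrix of synaptic polarities
  over {-1, 0, +1}; rows are presynaptic.
* :class:`ConnectomeMask` — the binary directed adjacency of which neuron
  pairs are synaptically connected at all.
* :class:`PolarityCatalog` — the per-connection category labels
  (known_positive / known_negative / complex / unknown / excluded).
* :class:`ScoreMatrix` / :class:`RankedPredictions` — real-valued prediction
  scores and their ranking by absolute value.

All files are tab-separated UTF-8 with a header row; lines starting with
``#`` are comments.  The neuron order given in the expression file is
canonical for every matrix; edge files may list pairs in any order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("synpolar")

#: Polarity categories for directed neuron pairs present in the connectome.
CATEGORIES = ("known_positive", "known_negative", "complex", "unknown", "excluded")
KNOWN_CATEGORIES = ("known_positive", "known_negative")


class ValidationError(ValueError):
    """Raised when an input file or container violates its invariants."""


def _check_unique(labels: Sequence[str], what: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(x for x in labels if (x in seen) or seen.add(x))
        raise ValidationError(f"duplicate {what} label: {dup!r}")
    return labels


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative neuron x gene expression table."""

    entity_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "entity_ids", _check_unique(self.entity_ids, "neuron"))
        object.__setattr__(self, "gene_ids", _check_unique(self.gene_ids, "gene"))
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.entity_ids), len(self.gene_ids)):
            raise ValidationError(
                f"expression shape {values.shape} does not match labels "
                f"({len(self.entity_ids)} x {len(self.gene_ids)})"
            )
        if not np.isfinite(values).all():
            raise ValidationError("expression contains non-finite values")
        if (values < 0).any():
            raise ValidationError("expression contains negative values")
        object.__setattr__(self, "values", values)

    def binarized(self) -> np.ndarray:
        """Presence/absence matrix: 1 where expression > 0."""
        return (self.values > 0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.entity_ids),
                            columns=list(self.gene_ids))


@dataclass(frozen=True)
class WiringRuleNetwork:
    """Signed NT x R rule matrix; ternary for curated rules, real for learned."""

    nt_ids: tuple[str, ...]
    r_ids: tuple[str, ...]
    weights: np.ndarray
    ternary: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "nt_ids", _check_unique(self.nt_ids, "NT"))
        object.__setattr__(self, "r_ids", _check_unique(self.r_ids, "receptor"))
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.nt_ids), len(self.r_ids)):
            raise ValidationError("rule matrix shape does not match NT/R labels")
        if not np.isfinite(w).all():
            raise ValidationError("rule matrix contains non-finite values")
        if self.ternary and not np.isin(w, (-1.0, 0.0, 1.0)).all():
            raise ValidationError("ternary rule matrix has entries outside {-1,0,+1}")
        object.__setattr__(self, "weights", w)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.nt_ids),
                            columns=list(self.r_ids))


@dataclass(frozen=True)
class SignedConnectome:
    """N x N directed polarity matrix over {-1, 0, +1}; rows are presynaptic."""

    neuron_ids: tuple[str, ...]
    signs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "neuron_ids", _check_unique(self.neuron_ids, "neuron"))
        s = np.asarray(self.signs)
        n = len(self.neuron_ids)
        if s.shape != (n, n):
            raise ValidationError("signed connectome must be square N x N")
        if not np.isin(s, (-1, 0, 1)).all():
            raise ValidationError("signed connectome entries must be in {-1,0,+1}")
        object.__setattr__(self, "signs", s.astype(np.int64))

    def index_of(self, label: str) -> int:
        return self.neuron_ids.index(label)


@dataclass(frozen=True)
class ConnectomeMask:
    """Binary directed adjacency: which neuron pairs are connected."""

    neuron_ids: tuple[str, ...]
    present: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "neuron_ids", _check_unique(self.neuron_ids, "neuron"))
        m = np.asarray(self.present)
        n = len(self.neuron_ids)
        if m.shape != (n, n):
            raise ValidationError("connectome mask must be square N x N")
        if not np.isin(m, (0, 1)).all():
            raise ValidationError("connectome mask entries must be binary")
        object.__setattr__(self, "present", m.astype(np.int64))

    @property
    def n_edges(self) -> int:
        return int(self.present.sum())


@dataclass(frozen=True)
class PolarityCatalog:
    """Category labels for every directed pair present in the connectome.

    ``table`` has columns ``pre``, ``post``, ``category`` and optionally
    ``source``.  Categories partition the mask-present pairs.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"pre", "post", "category"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"catalog table needs columns {sorted(required)}")
        bad = set(self.table["category"]) - set(CATEGORIES)
        if bad:
            raise ValidationError(f"unknown polarity categories: {sorted(bad)}")
        dup = self.table.duplicated(subset=["pre", "post"])
        if dup.any():
            pair = self.table.loc[dup.idxmax(), ["pre", "post"]].tolist()
            raise ValidationError(f"duplicate pair in catalog: {tuple(pair)}")

    def counts(self) -> dict[str, int]:
        c = self.table["category"].value_counts().to_dict()
        return {cat: int(c.get(cat, 0)) for cat in CATEGORIES}

    def pairs(self, *categories: str) -> list[tuple[str, str]]:
        """Directed pairs belonging to any of the given categories."""
        for cat in categories:
            if cat not in CATEGORIES:
                raise ValidationError(f"unknown category {cat!r}")
        sub = self.table[self.table["category"].isin(categories)]
        return list(zip(sub["pre"], sub["post"]))

    def check_consistency(self, connectome: SignedConnectome,
                          mask: ConnectomeMask) -> None:
        """Verify the catalog invariants against a signed connectome + mask.

        Every catalogued pair must be mask-present, every mask-present pair
        catalogued exactly once, and known_+/- pairs must carry the matching
        sign while all other categories carry sign 0.
        """
        idx = {lab: i for i, lab in enumerate(mask.neuron_ids)}
        cat_pairs = set(zip(self.table["pre"], self.table["post"]))
        present_pairs = {
            (mask.neuron_ids[i], mask.neuron_ids[j])
            for i, j in zip(*np.nonzero(mask.present))
        }
        if cat_pairs != present_pairs:
            missing = present_pairs - cat_pairs
            extra = cat_pairs - present_pairs
            raise ValidationError(
                f"catalog does not partition mask-present pairs "
                f"({len(missing)} missing, {len(extra)} extra)"
            )
        for pre, post, cat in zip(self.table["pre"], self.table["post"],
                                  self.table["category"]):
            s = connectome.signs[idx[pre], idx[post]]
            want = {"known_positive": 1, "known_negative": -1}.get(cat, 0)
            if s != want:
                raise ValidationError(
                    f"pair ({pre}, {post}) category {cat} but sign {s}"
                )


@dataclass(frozen=True)
class ScoreMatrix:
    """Real-valued N x N prediction scores with a method tag."""

    neuron_ids: tuple[str, ...]
    scores: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "neuron_ids", _check_unique(self.neuron_ids, "neuron"))
        s = np.asarray(self.scores, dtype=float)
        n = len(self.neuron_ids)
        if s.shape != (n, n):
            raise ValidationError("score matrix must be square N x N")
        if not np.isfinite(s).all():
            raise ValidationError("score matrix contains non-finite values")
        object.__setattr__(self, "scores", s)


@dataclass(frozen=True)
class RankedPredictions:
    """Predictions ordered by |score| descending with deterministic ties.

    ``table`` columns: ``rank`` (1-based), ``pre``, ``post``, ``score``,
    ``predicted_sign``.  Zero-score pairs are excluded (no sign to predict).
    """

    table: pd.DataFrame
    method: str = ""

    def __post_init__(self) -> None:
        required = ["rank", "pre", "post", "score", "predicted_sign"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"ranked predictions missing columns {missing}")
        t = self.table
        if len(t):
            if not (t["rank"].to_numpy() == np.arange(1, len(t) + 1)).all():
                raise ValidationError("ranks must be 1..R in order")
            a = np.abs(t["score"].to_numpy())
            if (np.diff(a) > 1e-12).any():
                raise ValidationError("|score| must be non-increasing with rank")
            if not np.isin(t["predicted_sign"].to_numpy(), (-1, 1)).all():
                raise ValidationError("predicted signs must be -1 or +1")

    def __len__(self) -> int:
        return len(self.table)

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.table["pre"], self.table["post"]))


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

_READ_KW = dict(sep="\t", comment="#", dtype=str, keep_default_na=False)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    # pandas silently renames duplicate header fields; reject them up front
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                _check_unique(line.rstrip("\n").split("\t"), "header")
                break
    return pd.read_csv(path, **_READ_KW)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a neuron x gene expression TSV (first column = neuron labels)."""
    df = _read_tsv(path)
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise ValidationError(f"{path}: expression table needs >=1 neuron row "
                              "and >=1 gene column")
    neurons = list(df.iloc[:, 0])
    genes = list(df.columns[1:])
    body = df.iloc[:, 1:]
    if (body == "").any().any():
        raise ValidationError(f"{path}: missing cell in expression body")
    try:
        values = body.astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"{path}: malformed number in expression body: {exc}")
    em = ExpressionMatrix(tuple(neurons), tuple(genes), values)
    logger.info("read_expression: %d neurons x %d genes from %s",
                len(neurons), len(genes), path)
    return em


def write_expression(em: ExpressionMatrix, path: str | Path,
                     index_label: str = "neuron") -> None:
    em.to_frame().to_csv(path, sep="\t", index_label=index_label)


def read_wiring_rules(path: str | Path, ternary: bool | None = None) -> WiringRuleNetwork:
    """Read an NT x R rule matrix TSV (first column = NT labels)."""
    df = _read_tsv(path)
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise ValidationError(f"{path}: rule table needs >=1 NT row and >=1 R column")
    nts = tuple(df.iloc[:, 0])
    rs = tuple(df.columns[1:])
    try:
        w = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"{path}: malformed number in rule table: {exc}")
    if ternary is None:
        ternary = bool(np.isin(w, (-1.0, 0.0, 1.0)).all())
    wrn = WiringRuleNetwork(nts, rs, w, ternary=ternary)
    logger.info("read_wiring_rules: %d NTs x %d Rs (%d nonzero) from %s",
                len(nts), len(rs), int(np.count_nonzero(w)), path)
    return wrn


def write_wiring_rules(wrn: WiringRuleNetwork, path: str | Path) -> None:
    wrn.to_frame().to_csv(path, sep="\t", index_label="nt")


_SIGN_STR = {1: "+1", -1: "-1"}


def read_signed_edges(path: str | Path, neuron_ids: Sequence[str]
                      ) -> tuple[SignedConnectome, ConnectomeMask, PolarityCatalog]:
    """Read a directed edge list with polarity categories.

    Columns: ``pre``, ``post``, ``category``, ``sign`` (empty unless the
    category is known_positive / known_negative).  Neuron order is taken from
    ``neuron_ids`` (the canonical expression-file order), not the edge file.
    """
    df = _read_tsv(path)
    required = ["pre", "post", "category", "sign"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: edge list missing columns {missing}")
    neuron_ids = _check_unique(neuron_ids, "neuron")
    idx = {lab: i for i, lab in enumerate(neuron_ids)}
    n = len(neuron_ids)
    signs = np.zeros((n, n), dtype=np.int64)
    present = np.zeros((n, n), dtype=np.int64)
    rows = []
    seen: set[tuple[str, str]] = set()
    for rec in df.itertuples(index=False):
        pre, post, cat, sign = rec.pre, rec.post, rec.category, rec.sign
        if pre not in idx or post not in idx:
            raise ValidationError(f"{path}: unknown neuron label in edge "
                                  f"({pre}, {post})")
        if (pre, post) in seen:
            raise ValidationError(f"{path}: duplicate edge ({pre}, {post})")
        seen.add((pre, post))
        if cat not in CATEGORIES:
            raise ValidationError(f"{path}: unknown category {cat!r}")
        if cat in KNOWN_CATEGORIES:
            want = 1 if cat == "known_positive" else -1
            if sign == "" or int(float(sign)) != want:
                raise ValidationError(
                    f"{path}: pair ({pre}, {post}) category {cat} needs sign {want:+d}")
            signs[idx[pre], idx[post]] = want
        elif sign not in ("", "0"):
            raise ValidationError(
                f"{path}: sign given for non-known category on ({pre}, {post})")
        present[idx[pre], idx[post]] = 1
        rows.append({"pre": pre, "post": post, "category": cat})
    connectome = SignedConnectome(neuron_ids, signs)
    mask = ConnectomeMask(neuron_ids, present)
    catalog = PolarityCatalog(pd.DataFrame(rows, columns=["pre", "post", "category"]))
    catalog.check_consistency(connectome, mask)
    logger.info("read_signed_edges: %d edges (%s) from %s", len(rows),
                ", ".join(f"{k}={v}" for k, v in catalog.counts().items() if v), path)
    return connectome, mask, catalog


def write_signed_edges(connectome: SignedConnectome, mask: ConnectomeMask,
                       catalog: PolarityCatalog, path: str | Path) -> None:
    idx = {lab: i for i, lab in enumerate(connectome.neuron_ids)}
    out = []
    for pre, post, cat in zip(catalog.table["pre"], catalog.table["post"],
                              catalog.table["category"]):
        s = connectome.signs[idx[pre], idx[post]]
        out.append({"pre": pre, "post": post, "category": cat,
                    "sign": _SIGN_STR.get(int(s), "")})
    pd.DataFrame(out, columns=["pre", "post", "category", "sign"]).to_csv(
        path, sep="\t", index=False)


def write_predictions(ranked: RankedPredictions, path: str | Path,
                      header_comments: Iterable[str] = ()) -> None:
    """Write ranked predictions as TSV (rank, pre, post, score, sign)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        ranked.table.to_csv(fh, sep="\t", index=False)


def read_predictions(path: str | Path, method: str = "") -> RankedPredictions:
    df = _read_tsv(path)
    if len(df) == 0:
        df = pd.DataFrame(columns=["rank", "pre", "post", "score", "predicted_sign"])
    else:
        df = df.astype({"rank": int, "score": float, "predicted_sign": int})
    return RankedPredictions(df, method=method)


def export_graphml(connectome: SignedConnectome, path: str | Path,
                   scores: ScoreMatrix | None = None) -> None:
    """Export the signed network as GraphML with 'sign' (and 'score') edge attrs."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(connectome.neuron_ids)
    ii, jj = np.nonzero(connectome.signs)
    for i, j in zip(ii, jj):
        attrs = {"sign": int(connectome.signs[i, j])}
        if scores is not None:
            attrs["score"] = float(scores.scores[i, j])
        g.add_edge(connectome.neuron_ids[i], connectome.neuron_ids[j], **attrs)
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Dataset bundle loading (config-driven adapter)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetBundle:
    """All inputs for one analysis, loaded and cross-validated."""

    X: ExpressionMatrix
    Y: ExpressionMatrix
    rules: WiringRuleNetwork | None
    connectome: SignedConnectome
    mask: ConnectomeMask
    catalog: PolarityCatalog


def load_dataset_bundle(paths: Mapping[str, str | Path]) -> DatasetBundle:
    """Load a full input bundle from a path mapping.

    ``paths`` keys: ``nt_expression``, ``r_expression``, ``edges`` and
    optionally ``rules``.  This doubles as the adapter for externally
    deposited datasets once their files are mapped onto these TSV schemas;
    the mapping is configuration, not code, because deposit-internal layouts
    vary.
    """
    X = read_expression(paths["nt_expression"])
    Y = read_expression(paths["r_expression"])
    if X.entity_ids != Y.entity_ids:
        raise ValidationError("NT and R expression files list different neurons")
    rules = read_wiring_rules(paths["rules"]) if "rules" in paths and paths["rules"] else None
    connectome, mask, catalog = read_signed_edges(paths["edges"], X.entity_ids)
    return DatasetBundle(X, Y, rules, connectome, mask, catalog)
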