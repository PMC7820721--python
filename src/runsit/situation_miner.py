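"""Weighted frequent item mining of running situations.

A *transaction* is one run: the 29 categorical (feature, value) items plus a
weight — the run's normalized distance in [-1, 1]. The weighted support of an
itemset X is the sum of weights over transactions containing X; its sign says
whether the situation is predominantly associated with above-average (+) or
below-average (-) running distance. Itemsets are reported when the *absolute*
weighted support reaches the threshold sigma.

Because weights are signed, |w| is not anti-monotone (a superset's support can
exceed a subset's in absolute value), so threshold pruning inside the search
is a heuristic. Two modes are provided:

* ``"exhaustive"`` (default): enumerates, via the weighted FP-tree, every
  itemset of surviving header items (up to ``max_len``) that occurs in at
  least one transaction, and reports those with |w(X)| >= sigma. This is the
  declarative semantics and is oracle-testable against brute-force subset
  enumeration.
* ``"pruned"``: classic FP-Growth behavior that also prunes items inside
  conditional trees by |w| — faster but possibly incomplete.

Items are strings ``"feature=value"``; header order is descending |w(item)|
with ties broken by item name.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ALL_FEATURES, FEATURE_CATEGORY
from .geo_context import BinningScheme

ITEM_SEP = "="


def make_item(feature: str, value: str) -> str:
    return f"{feature}{ITEM_SEP}{value}"


def item_feature(item: str) -> str:
    return item.split(ITEM_SEP, 1)[0]


def transactions_from_dataframe(df: pd.DataFrame):
    """Convert a transaction table (weight + 29 feature columns) to item form.

    Returns ``(itemlists, weights)`` where ``itemlists`` is a list of tuples
    of ``"feature=value"`` strings.
    """
    feats = [c for c in df.columns if c in ALL_FEATURES]
    weights = df["weight"].to_numpy(dtype=float)
    cols = [df[f].astype(str).to_numpy() for f in feats]
    itemlists = [
        tuple(make_item(f, col[i]) for f, col in zip(feats, cols)) for i in range(len(df))
    ]
    return itemlists, weights


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset
    weight: float
    count: int

    @property
    def sign(self) -> int:
        return int(np.sign(self.weight))


def weighted_support(itemset, itemlists, weights) -> tuple[float, int]:
    """(sum of weights, count) over transactions containing all of ``itemset``.

    The empty itemset is contained in every transaction, so it returns the
    total weight and total count.
    """
    target = frozenset(itemset)
    w = 0.0
    n = 0
    for t, wt in zip(itemlists, weights):
        if target <= frozenset(t):
            w += wt
            n += 1
    return w, n


def item_supports(itemlists, weights) -> pd.DataFrame:
    """Single-item weighted supports and counts over the transaction set."""
    sup: dict[str, float] = {}
    cnt: dict[str, int] = {}
    for t, w in zip(itemlists, weights):
        for item in t:
            sup[item] = sup.get(item, 0.0) + w
            cnt[item] = cnt.get(item, 0) + 1
    items = sorted(sup)
    return pd.DataFrame(
        {"item": items, "weight": [sup[i] for i in items], "count": [cnt[i] for i in items]}
    )


def build_header(itemlists, weights, sigma: float) -> pd.DataFrame:
    """Surviving items (|w| >= sigma) ordered by descending |w|, ties by name."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sup = item_supports(itemlists, weights)
    keep = sup[np.abs(sup["weight"]) >= sigma].copy()
    keep["abs_w"] = keep["weight"].abs()
    keep = keep.sort_values(["abs_w", "item"], ascending=[False, True], kind="mergesort")
    return keep.drop(columns="abs_w").reset_index(drop=True)


class _Node:
    __slots__ = ("item", "weight", "count", "parent", "children")

    def __init__(self, item, parent):
        self.item = item
        self.weight = 0.0
        self.count = 0
        self.parent = parent
        self.children = {}


class WeightedFPTree:
    """Prefix tree over rank-ordered transactions, accumulating signed weights.

    Each node carries the summed weight and count of the transactions routed
    through it; per-item node chains live in ``node_lists``. For any item, the
    node weights sum to the item's weighted support within the inserted set.
    """

    def __init__(self, rank: dict):
        self.rank = rank
        self.root = _Node(None, None)
        self.node_lists: dict[str, list[_Node]] = {}

    def insert(self, items, weight: float, count: int = 1) -> None:
        ordered = sorted((i for i in items if i in self.rank), key=self.rank.__getitem__)
        node = self.root
        for item in ordered:
            child = node.children.get(item)
            if child is None:
                child = _Node(item, node)
                node.children[item] = child
                self.node_lists.setdefault(item, []).append(child)
            child.weight += weight
            child.count += count
            node = child

    def prefix_paths(self, item: str):
        """Conditional pattern base of ``item``: (path items, weight, count) triples."""
        out = []
        for node in self.node_lists.get(item, []):
            path = []
            p = node.parent
            while p is not None and p.item is not None:
                path.append(p.item)
                p = p.parent
            out.append((tuple(reversed(path)), node.weight, node.count))
        return out

    def item_support(self, item: str) -> tuple[float, int]:
        nodes = self.node_lists.get(item, [])
        return sum(n.weight for n in nodes), sum(n.count for n in nodes)


def _grow(tree: WeightedFPTree, suffix: tuple, sigma: float, mode: str, max_len, results: list):
    # header items of this (conditional) tree, in rank order, processed bottom-up
    items = sorted(tree.node_lists, key=tree.rank.__getitem__)
    for item in reversed(items):
        w, c = tree.item_support(item)
        newset = suffix + (item,)
        if abs(w) >= sigma:
            results.append(FrequentItemset(frozenset(newset), w, c))
        if max_len is not None and len(newset) >= max_len:
            continue
        base = tree.prefix_paths(item)
        if not any(path for path, _, _ in base):
            continue
        if mode == "pruned":
            cond_sup: dict[str, float] = {}
            for path, pw, _ in base:
                for i in path:
                    cond_sup[i] = cond_sup.get(i, 0.0) + pw
            allowed = {i for i, cw in cond_sup.items() if abs(cw) >= sigma}
        else:
            allowed = None
        cond = WeightedFPTree(tree.rank)
        for path, pw, pc in base:
            keep = path if allowed is None else tuple(i for i in path if i in allowed)
            if keep:
                cond.insert(keep, pw, pc)
        if cond.node_lists:
            _grow(cond, newset, sigma, mode, max_len, results)


def mine(
    itemlists,
    weights,
    sigma: float,
    mode: str = "exhaustive",
    max_len: int | None = 4,
) -> list[FrequentItemset]:
    """Mine itemsets with |weighted support| >= sigma via the weighted FP-tree.

    Results are sorted by descending |weight|, ties by the sorted item tuple.
    See the module docstring for the ``exhaustive`` / ``pruned`` semantics.
    """
    if mode not in ("exhaustive", "pruned"):
        raise ValueError("mode must be 'exhaustive' or 'pruned'")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if max_len is not None and max_len < 1:
        raise ValueError("max_len must be >= 1 or None")
    header = build_header(itemlists, weights, sigma)
    rank = {item: i for i, item in enumerate(header["item"])}
    tree = WeightedFPTree(rank)
    for t, w in zip(itemlists, weights):
        tree.insert(t, w)
    results: list[FrequentItemset] = []
    _grow(tree, (), sigma, mode, max_len, results)
    results.sort(key=lambda s: (-abs(s.weight), tuple(sorted(s.items))))
    return results


def feature_variability(df: pd.DataFrame, normalize: bool = False) -> pd.DataFrame:
    """Per-feature standard deviation of single-item weighted supports.

    For each feature, the weighted supports of its *observed* categories are
    collected and their population standard deviation is reported; a larger
    value means the feature's values differentiate running distance more.
    With ``normalize=True`` supports are divided by the number of
    transactions (so the statistic vanishes as n grows under a null of no
    situation effects, instead of growing like sqrt(n)).
    """
    n = len(df)
    rows = []
    feats = [c for c in df.columns if c in ALL_FEATURES]
    for f in feats:
        sup = df.groupby(f, sort=True)["weight"].sum().to_numpy(dtype=float)
        if normalize and n > 0:
            sup = sup / n
        rows.append(
            {
                "feature": f,
                "std_weighted_support": float(np.std(sup)),
                "n_categories": len(sup),
            }
        )
    return pd.DataFrame(rows)


def permutation_null(
    df: pd.DataFrame, n_perm: int = 100, seed: int = 0, normalize: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Null distribution of the variability statistic by weight permutation.

    Randomly reassigning the weights to transactions breaks any association
    between situations and normalized distance while preserving both the
    weight distribution and the category frequencies. Returns

    * per-feature null mean and SD of the variability statistic (optionally
      normalized by the number of transactions, see
      :func:`feature_variability`), and
    * per single item, the null SD of its (raw) weighted support — the scale
      against which a mining threshold sigma can be calibrated.
    """
    rng = np.random.default_rng(seed)
    w = df["weight"].to_numpy(dtype=float)
    n = len(df)
    feats = [c for c in df.columns if c in ALL_FEATURES]
    codes = {}
    cats = {}
    for f in feats:
        c, u = pd.factorize(df[f])
        codes[f], cats[f] = c, u
    var_draws = {f: np.empty(n_perm) for f in feats}
    sup_draws = {f: np.empty((n_perm, len(cats[f]))) for f in feats}
    for p in range(n_perm):
        wp = rng.permutation(w)
        for f in feats:
            s = np.bincount(codes[f], weights=wp, minlength=len(cats[f]))
            sup_draws[f][p] = s
            var_draws[f][p] = np.std(s / n if normalize else s)
    variability = pd.DataFrame(
        {
            "feature": feats,
            "null_mean": [var_draws[f].mean() for f in feats],
            "null_sd": [var_draws[f].std() for f in feats],
        }
    )
    item_rows = []
    for f in feats:
        sds = sup_draws[f].std(axis=0)
        for cat, sd in zip(cats[f], sds):
            item_rows.append({"item": make_item(f, str(cat)), "null_support_sd": float(sd)})
    return variability, pd.DataFrame(item_rows)


def value_histogram(df: pd.DataFrame, feature: str, scheme: BinningScheme | None = None) -> pd.DataFrame:
    """Per-category run counts and weighted supports for one feature.

    When a :class:`BinningScheme` is given, all categories of the feature are
    listed (zeros for unobserved ones) in vocabulary order; otherwise the
    observed categories are listed in sorted order. Counts sum to the number
    of transactions and supports to the total weight.
    """
    if feature not in ALL_FEATURES:
        raise ValueError(f"unknown feature {feature!r}")
    grouped = df.groupby(feature)["weight"].agg(["size", "sum"])
    if scheme is not None:
        cats = list(scheme.categories(feature))
        grouped = grouped.reindex(cats, fill_value=0)
    return pd.DataFrame(
        {
            "category": grouped.index.to_list(),
            "count": grouped["size"].astype(int).to_numpy(),
            "weighted_support": grouped["sum"].astype(float).to_numpy(),
        }
    )


def top_situations(
    itemsets: list[FrequentItemset], category_filter: str = "all", k: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k positive and negative situations within one feature category.

    ``category_filter`` is one of temporal / weather / topographical /
    demographical / all; an itemset qualifies only if *every* item's feature
    belongs to the filter category. Both lists are ranked by |weighted
    support| descending.
    """
    valid = {"temporal", "weather", "topographical", "demographical", "all"}
    if category_filter not in valid:
        raise ValueError(f"category_filter must be one of {sorted(valid)}")
    if k < 0:
        raise ValueError("k must be >= 0")

    def qualifies(s: FrequentItemset) -> bool:
        if category_filter == "all":
            return True
        return all(FEATURE_CATEGORY[item_feature(i)] == category_filter for i in s.items)

    selected = [s for s in itemsets if qualifies(s)]
    selected.sort(key=lambda s: (-abs(s.weight), tuple(sorted(s.items))))
    pos = [s for s in selected if s.weight > 0][:k]
    neg = [s for s in selected if s.weight < 0][:k]

    def table(rows):
        return pd.DataFrame(
            {
                "items": ["|".join(sorted(s.items)) for s in rows],
                "weighted_support": [s.weight for s in rows],
                "count": [s.count for s in rows],
            }
        )

    return table(pos), table(neg)


def itemsets_to_dataframe(itemsets: list[FrequentItemset]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "items": ["|".join(sorted(s.items)) for s in itemsets],
            "weight": [s.weight for s in itemsets],
            "count": [s.count for s in itemsets],
            "sign": [s.sign for s in itemsets],
        }
    )


def itemsets_to_csv(path: str | Path, itemsets: list[FrequentItemset]) -> None:
    itemsets_to_dataframe(itemsets).to_csv(path, index=False)
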