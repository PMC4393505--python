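"""Class-constrained representative association-rule mining.

Frequent itemsets are found with a frequency-pattern (FP) tree: items below
the support floor are pruned before the tree is built (the bounded portion),
remaining items are ordered by descending support (ties broken
lexicographically), and conditional trees are grown recursively.  Supports
are exact transaction counts.

Rule derivation is class-constrained: candidate rules split a frequent
itemset into a keyword-free body and a nonempty all-keyword head, keeping
splits whose confidence meets the floor.  The representative filter then
removes every rule that lies in the *cover* of another candidate, where

    cover(X -> Y) = { X u Z -> V : Z subset of Y, V nonempty subset of Y \\ Z },

so the retained rules form an antichain from which all confident candidates
are derivable.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import numpy as np


def _key(item) -> str:
    return f"{item!r}" if not isinstance(item, str) else item


# ---------------------------------------------------------------------------
# FP-growth
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict = {}


@dataclass
class FrequentItemsets:
    counts: dict[frozenset, int]
    n_transactions: int

    def support(self, itemset: Iterable) -> float:
        return self.counts[frozenset(itemset)] / self.n_transactions

    def __len__(self) -> int:
        return len(self.counts)


def mine_frequent(transactions: Sequence[Iterable[Hashable]], minsup: float,
                  max_len: int | None = None) -> FrequentItemsets:
    """All itemsets with support >= minsup, with exact counts.

    ``max_len`` bounds the pattern growth to itemsets of at most that many
    items (the bounded portion of the tree); ``None`` mines exhaustively.
    Within the bound, counts are exact.
    """
    if not (0.0 < minsup <= 1.0):
        raise ValueError("minsup must lie in (0, 1]")
    if len(transactions) == 0:
        raise ValueError("empty transaction list")
    if max_len is not None and max_len < 1:
        raise ValueError("max_len must be >= 1")
    n = len(transactions)
    min_count = max(1, int(np.ceil(minsup * n - 1e-9)))

    sets = [frozenset(t) for t in transactions]
    item_counts = Counter(i for t in sets for i in t)
    frequent_items = {i for i, c in item_counts.items() if c >= min_count}

    # global item order: descending support, ties lexicographic
    def order(i):
        return (-item_counts[i], _key(i))

    weighted = [(sorted((i for i in t if i in frequent_items), key=order), 1)
                for t in sets]
    out: dict[frozenset, int] = {}
    _fp_growth(weighted, min_count, frozenset(), out, max_len)
    return FrequentItemsets(counts=out, n_transactions=n)


def _fp_growth(weighted_transactions, min_count, suffix, out, max_len):
    if max_len is not None and len(suffix) >= max_len:
        return
    counts = Counter()
    for items, w in weighted_transactions:
        for i in set(items):
            counts[i] += w
    frequent = {i: c for i, c in counts.items() if c >= min_count}
    if not frequent:
        return

    def order(i):
        return (-frequent[i], _key(i))

    # build the tree over pruned, re-ordered transactions
    root = _Node(None, None)
    header: dict = {}
    for items, w in weighted_transactions:
        node = root
        for i in sorted((x for x in items if x in frequent), key=order):
            child = node.children.get(i)
            if child is None:
                child = _Node(i, node)
                node.children[i] = child
                header.setdefault(i, []).append(child)
            child.count += w
            node = child

    # grow patterns from least-frequent item upward
    for item in sorted(frequent, key=order, reverse=True):
        new_suffix = suffix | {item}
        out[frozenset(new_suffix)] = frequent[item]
        conditional = []
        for node in header[item]:
            path = []
            p = node.parent
            while p is not None and p.item is not None:
                path.append(p.item)
                p = p.parent
            if path:
                conditional.append((path, node.count))
        if conditional:
            _fp_growth(conditional, min_count, new_suffix, out, max_len)


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationRule:
    body: frozenset
    head: frozenset
    support: float
    confidence: float

    def __post_init__(self):
        assert self.body and self.head, "body and head must be nonempty"
        assert not (self.body & self.head), "body and head must be disjoint"
        assert 0.0 < self.support <= 1.0 and 0.0 < self.confidence <= 1.0


@dataclass
class RuleBase:
    rules: list[AssociationRule]
    minsup: float
    minconf: float
    items: list = field(default_factory=list)     # item vocabulary

    def __len__(self) -> int:
        return len(self.rules)

    def heads(self) -> list[frozenset]:
        seen, out = set(), []
        for r in self.rules:
            if r.head not in seen:
                seen.add(r.head)
                out.append(r.head)
        return out


def in_cover(rule: AssociationRule, other: AssociationRule) -> bool:
    """True when ``rule`` is derivable from ``other`` by the cover operator:
    rule = other.body u Z -> V with Z subset of other.head and V a nonempty
    subset of other.head \\ Z."""
    if rule == other:
        return False
    if not rule.body >= other.body:
        return False
    z = rule.body - other.body
    if not z <= other.head:
        return False
    return bool(rule.head) and rule.head <= (other.head - z)


def derive_representative(frequent: FrequentItemsets, minconf: float,
                          keywords: frozenset[str], minsup: float | None = None
                          ) -> RuleBase:
    """Representative class-constrained rules from the frequent itemsets.

    Candidates are all splits of a frequent itemset into keyword-free body and
    all-keyword head with confidence >= minconf; any candidate in the cover of
    another candidate is dropped.  Output order: support desc, confidence
    desc, body size asc, then lexicographic (deterministic).
    """
    if not (0.0 < minconf <= 1.0):
        raise ValueError("minconf must lie in (0, 1]")
    n = frequent.n_transactions
    candidates: list[AssociationRule] = []
    for itemset, count in frequent.counts.items():
        head = frozenset(i for i in itemset if i in keywords)
        body = itemset - head
        if not head or not body:
            continue
        body_count = frequent.counts.get(body)
        if body_count is None:      # cannot happen for exact mining; guard anyway
            continue
        conf = count / body_count
        if conf >= minconf - 1e-12:
            candidates.append(AssociationRule(body=body, head=head,
                                              support=count / n, confidence=conf))

    # For class-constrained rules (keyword-free bodies, keyword-only heads)
    # a cover relation r in C(r') forces r.body == r'.body: any body items
    # added by the operator would have to come from r'.head, which holds only
    # keywords.  The filter therefore reduces to head-maximality per body,
    # which grouping computes in near-linear time (in_cover is the reference
    # predicate and is asserted equivalent in the tests).
    by_body: dict[frozenset, list[AssociationRule]] = {}
    for r in candidates:
        by_body.setdefault(r.body, []).append(r)
    kept = []
    for group in by_body.values():
        for r in group:
            if not any(r.head < other.head for other in group):
                kept.append(r)
    kept.sort(key=lambda r: (-r.support, -r.confidence, len(r.body),
                             sorted(map(_key, r.body)), sorted(map(_key, r.head))))
    vocab = sorted({i for r in kept for i in r.body | r.head}, key=_key)
    return RuleBase(rules=kept, minsup=minsup if minsup is not None else 0.0,
                    minconf=minconf, items=vocab)


def mine_rules(transactions: Sequence[Iterable[Hashable]], keywords: frozenset[str],
               minsup: float = 0.05, minconf: float = 0.8,
               max_len: int | None = None) -> RuleBase:
    """Convenience: frequent itemsets then representative rules."""
    freq = mine_frequent(transactions, minsup, max_len=max_len)
    return derive_representative(freq, minconf, keywords, minsup=minsup)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _item_to_json(item):
    if isinstance(item, tuple):
        return list(item)
    return item


def _item_from_json(x):
    return tuple(x) if isinstance(x, list) else x


def save_rulebase(rb: RuleBase, path: str | Path) -> None:
    payload = {
        "items": [_item_to_json(i) for i in rb.items],
        "minsup": rb.minsup,
        "minconf": rb.minconf,
        "rules": [{
            "body": sorted((_item_to_json(i) for i in r.body), key=str),
            "head": sorted(r.head),
            "support": r.support,
            "confidence": r.confidence,
        } for r in rb.rules],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_rulebase(path: str | Path) -> RuleBase:
    text = Path(path).read_text()
    try:
        d = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed rule base at line {exc.lineno}: {exc.msg}") from exc
    try:
        rules = []
        for k, r in enumerate(d["rules"]):
            body = frozenset(_item_from_json(i) for i in r["body"])
            head = frozenset(_item_from_json(i) for i in r["head"])
            try:
                rules.append(AssociationRule(body=body, head=head,
                                             support=r["support"],
                                             confidence=r["confidence"]))
            except AssertionError as exc:
                raise ValueError(f"{path}: rule {k} violates invariants: {exc}") from exc
        return RuleBase(rules=rules, minsup=d["minsup"], minconf=d["minconf"],
                        items=[_item_from_json(i) for i in d["items"]])
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: malformed rule base: {exc}") from exc
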