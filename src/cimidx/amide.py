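"""AMIDE: the associative diagnosis engine.

A test itemset is scored against every distinct rule head h in the rule base.
For the rules carrying head h, a rule is a *full* match when its whole body is
contained in the test itemset, a *partial* match when only part of the body
is, and a *non-match* when the body and the test itemset are disjoint.  With
nM/nP/nN the counts of full / partial / non-matches:

* Condition 1 accepts h with weight w1 = nM / (nM + nN) when w1 >= alpha;
* otherwise Condition 2 accepts h with weight w2 = (nM + nP) / (nM + nP + nN)
  when w2 >= delta.

A zero denominator scores 0 (reject): a head without even one match cannot
enter the suggested diagnosis.  The engine can return multiple keyword sets,
sorted by weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from .rulemine import AssociationRule, RuleBase, _key


class MatchStatus(Enum):
    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"


@dataclass(frozen=True)
class MatchCounts:
    n_full: int = 0
    n_partial: int = 0
    n_none: int = 0

    def __post_init__(self):
        assert min(self.n_full, self.n_partial, self.n_none) >= 0

    @property
    def total(self) -> int:
        return self.n_full + self.n_partial + self.n_none


@dataclass(frozen=True)
class HeadScore:
    head: frozenset
    accepted: bool
    weight: float
    condition: int | None          # 1 or 2 when accepted, else None
    counts: MatchCounts


@dataclass
class Diagnosis:
    accepted: list[HeadScore]
    alpha: float
    delta: float

    def heads(self) -> list[frozenset]:
        return [s.head for s in self.accepted]

    def to_json(self, path: str | Path | None = None, test_id: str = "") -> dict:
        payload = {
            "test_id": test_id,
            "alpha": self.alpha,
            "delta": self.delta,
            "accepted": [{
                "head": sorted(s.head),
                "weight": s.weight,
                "condition": s.condition,
                "nM": s.counts.n_full,
                "nP": s.counts.n_partial,
                "nN": s.counts.n_none,
            } for s in self.accepted],
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=1))
        return payload


def match_status(rule: AssociationRule, test: frozenset) -> MatchStatus:
    """full iff body is a subset of the test itemset; partial iff a proper,
    nonempty part of the body is; none iff they are disjoint."""
    if not rule.body:
        raise ValueError("rule with empty body")
    inter = len(rule.body & test)
    if inter == len(rule.body):
        return MatchStatus.FULL
    if inter > 0:
        return MatchStatus.PARTIAL
    return MatchStatus.NONE


def count_matches(rb: RuleBase, head: frozenset, test: frozenset) -> MatchCounts:
    nm = np_ = nn = 0
    for rule in rb.rules:
        if rule.head != head:
            continue
        status = match_status(rule, test)
        if status is MatchStatus.FULL:
            nm += 1
        elif status is MatchStatus.PARTIAL:
            np_ += 1
        else:
            nn += 1
    return MatchCounts(n_full=nm, n_partial=np_, n_none=nn)


def score_head(rb: RuleBase, head: frozenset, test: frozenset,
               alpha: float = 0.5, delta: float = 0.5) -> HeadScore:
    """Score one candidate head; Condition 1 short-circuits Condition 2."""
    if not (0.0 < alpha <= 1.0) or not (0.0 < delta <= 1.0):
        raise ValueError("alpha and delta must lie in (0, 1]")
    counts = count_matches(rb, head, test)
    d1 = counts.n_full + counts.n_none
    w1 = counts.n_full / d1 if d1 else 0.0
    if w1 >= alpha:
        return HeadScore(head=head, accepted=True, weight=w1, condition=1, counts=counts)
    d2 = counts.total
    w2 = (counts.n_full + counts.n_partial) / d2 if d2 else 0.0
    if w2 >= delta:
        return HeadScore(head=head, accepted=True, weight=w2, condition=2, counts=counts)
    return HeadScore(head=head, accepted=False, weight=max(w1, w2), condition=None,
                     counts=counts)


def diagnose(rb: RuleBase, test: frozenset, alpha: float = 0.5,
             delta: float = 0.5) -> Diagnosis:
    """Score every distinct rule head; accepted heads are sorted by weight
    descending (ties: Condition 1 before 2, smaller head, lexicographic)."""
    scores = [score_head(rb, h, test, alpha, delta) for h in rb.heads()]
    accepted = [s for s in scores if s.accepted]
    accepted.sort(key=lambda s: (-s.weight, s.condition, len(s.head),
                                 sorted(map(_key, s.head))))
    return Diagnosis(accepted=accepted, alpha=alpha, delta=delta)
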