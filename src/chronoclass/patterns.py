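"""Mean-pattern (model-class) enumeration for three age-category means.

A *mean pattern* is a weak ordering of the fetal (F), young (Y) and adult (A)
mean expression levels: an assignment of the three categories to ordered
equality groups, e.g. ``F<Y=A`` (fetal below young and adult, which coincide)
or ``F=Y=A`` (no difference).  There are exactly 13 weak orderings of three
labelled items; the canonical numbering used throughout the package puts the
six one-equality patterns first (classes 1-6, paired up/down per partition),
then the six strict orderings (7-12), with the all-equal pattern last (13).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

CATEGORIES = ("F", "Y", "A")


@dataclass(frozen=True)
class MeanPattern:
    """A weak ordering of the three category means.

    Parameters
    ----------
    label : str
        Canonical label such as ``"F<Y=A"`` or ``"F=Y=A"``.
    groups : tuple of frozenset
        Equality groups ordered by ascending mean.  ``("F",)`` before
        ``("Y", "A")`` encodes F below Y=A.
    """

    label: str
    groups: tuple[frozenset, ...]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def partition(self) -> frozenset:
        """The unordered equality partition (directions forgotten)."""
        return frozenset(self.groups)

    @property
    def is_null(self) -> bool:
        return self.n_groups == 1

    def rank_of(self, category: str) -> int:
        """0-based rank (ascending mean) of a category's equality group."""
        for i, g in enumerate(self.groups):
            if category in g:
                return i
        raise KeyError(category)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _sorted_members(group) -> list:
    """Members of an equality group in fixed F, Y, A display order."""
    return [c for c in CATEGORIES if c in group]


def canonical_label(groups: tuple[frozenset, ...]) -> str:
    """Canonical label for ordered (ascending-mean) equality groups.

    Conventions match the field's class tables: the group containing F is
    written first for two-group patterns (``F>Y=A`` rather than ``Y=A<F``),
    the fully reversed strict ordering is written descending (``F>Y>A``),
    and all other strict orderings are written as ascending chains.
    """
    if len(groups) == 1:
        return "F=Y=A"
    if len(groups) == 2:
        lo, hi = groups
        f_first, other, op = (lo, hi, "<") if "F" in lo else (hi, lo, ">")
        return "=".join(_sorted_members(f_first)) + op + "=".join(_sorted_members(other))
    # strict ordering
    chain = [next(iter(g)) for g in groups]
    if chain == ["A", "Y", "F"]:
        return "F>Y>A"
    return "<".join(chain)


@lru_cache(maxsize=1)
def _all_patterns() -> tuple[MeanPattern, ...]:
    """Brute-force generation of every weak ordering of F, Y, A."""
    seen = {}
    for ranks in itertools.product(range(3), repeat=3):
        # normalize ranks to dense 0..k-1
        levels = sorted(set(ranks))
        dense = tuple(levels.index(r) for r in ranks)
        if dense in seen:
            continue
        groups = tuple(
            frozenset(c for c, r in zip(CATEGORIES, dense) if r == level)
            for level in range(len(levels))
        )
        seen[dense] = MeanPattern(canonical_label(groups), groups)
    return tuple(seen.values())


#: Canonical class order: 1-6 one-equality pairs, 7-12 strict, 13 all-equal.
CANONICAL_LABELS = (
    "F<Y=A",
    "F>Y=A",
    "F=Y<A",
    "F=Y>A",
    "F=A<Y",
    "F=A>Y",
    "F<Y<A",
    "F>Y>A",
    "F<A<Y",
    "Y<F<A",
    "Y<A<F",
    "A<F<Y",
    "F=Y=A",
)


def enumerate_model_classes() -> list[MeanPattern]:
    """All 13 mean patterns in canonical class order (class 1 first)."""
    by_label = {p.label: p for p in _all_patterns()}
    ordered = [by_label[lab] for lab in CANONICAL_LABELS]
    if len(ordered) != len(by_label):  # pragma: no cover - internal guard
        raise AssertionError("canonical label list does not cover all weak orderings")
    return ordered


def pattern_by_label(label: str) -> MeanPattern:
    """Look up a pattern by its canonical label."""
    for p in enumerate_model_classes():
        if p.label == label:
            return p
    raise KeyError(f"unknown mean-pattern label: {label!r}")


def class_index(pattern: MeanPattern | str) -> int:
    """1-based canonical class number of a pattern."""
    label = pattern if isinstance(pattern, str) else pattern.label
    return CANONICAL_LABELS.index(label) + 1


def pattern_from_ordered_groups(groups) -> MeanPattern:
    """Build the canonical pattern from ascending-ordered equality groups."""
    groups = tuple(frozenset(g) for g in groups)
    return pattern_by_label(canonical_label(groups))
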