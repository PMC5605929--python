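"""Group-distinct ADR term mining over reviews with demographic metadata.

Given ADR terms extracted per review (e.g., by the tagger) and per-review
demographic tags (gender, age group), reports, for each group, the terms
that (a) appear in strictly more than four of that group's reviews and
(b) whose exact normalized form never appears in any review carrying a
different tag of the same dimension.  The "all authors" view applies
only the frequency threshold, with no exclusivity filter.

Counting is review-level by default: a term occurring three times inside
one review counts once.  Normalization before exact matching is
lowercasing plus whitespace collapse — no stemming, by design, since the
rule is an exact string match.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass

__all__ = [
    "ReviewRecord",
    "GroupTermReport",
    "normalize_term",
    "distinct_terms",
    "all_authors_terms",
    "DEFAULT_MIN_REVIEWS",
]

#: "more than four times" -> a term must appear in at least 5 reviews.
DEFAULT_MIN_REVIEWS = 5

_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class ReviewRecord:
    review_id: str
    text: str = ""
    drug: str = ""
    condition: str = ""
    gender: str = "unknown"      # "female" | "male" | "unknown"
    age_group: str = "unknown"


@dataclass(frozen=True)
class GroupTermReport:
    """Per-group (term, review-count) lists, exclusivity already applied."""

    grouping: str  # "gender" | "age_group"
    groups: dict[str, list[tuple[str, int]]]


def normalize_term(term: str) -> str:
    return _WS_RE.sub(" ", term.strip().lower())


def _term_review_counts(extracted: dict[str, list[str]],
                        review_ids, per_review_once: bool) -> Counter:
    counts: Counter = Counter()
    for rid in review_ids:
        terms = [normalize_term(t) for t in extracted.get(rid, []) if t.strip()]
        counts.update(set(terms) if per_review_once else terms)
    return counts


def distinct_terms(extracted: dict[str, list[str]],
                   metadata: dict[str, ReviewRecord],
                   grouping: str = "gender",
                   min_reviews: int = DEFAULT_MIN_REVIEWS,
                   per_review_once: bool = True,
                   skip_unknown: bool = True) -> GroupTermReport:
    """Mine terms distinctive of each demographic group.

    For each group ``g`` along ``grouping``: candidates are terms
    counted in at least ``min_reviews`` reviews of ``g``; a candidate is
    kept only if its exact normalized string never occurs in any review
    of a different group.  Output lists are ordered by descending count,
    then lexicographically — deterministic for a given input.
    """
    if grouping not in ("gender", "age_group"):
        raise ValueError(f"unknown grouping {grouping!r}")
    missing = sorted(set(extracted) - set(metadata))
    if missing:
        raise KeyError(f"reviews lacking metadata: {missing}")

    by_group: dict[str, list[str]] = defaultdict(list)
    for rid in extracted:
        tag = getattr(metadata[rid], grouping)
        if skip_unknown and tag == "unknown":
            continue
        by_group[tag].append(rid)

    group_counts = {g: _term_review_counts(extracted, rids, per_review_once)
                    for g, rids in by_group.items()}
    report: dict[str, list[tuple[str, int]]] = {}
    for g, counts in group_counts.items():
        others = set()
        for other, oc in group_counts.items():
            if other != g:
                others.update(oc)
        kept = [(t, c) for t, c in counts.items()
                if c >= min_reviews and t not in others]
        kept.sort(key=lambda tc: (-tc[1], tc[0]))
        report[g] = kept
    return GroupTermReport(grouping, report)


def all_authors_terms(extracted: dict[str, list[str]],
                      min_reviews: int = DEFAULT_MIN_REVIEWS,
                      per_review_once: bool = True) -> list[tuple[str, int]]:
    """Threshold-only term list over the whole collection (no exclusivity)."""
    counts = _term_review_counts(extracted, list(extracted), per_review_once)
    kept = [(t, c) for t, c in counts.items() if c >= min_reviews]
    kept.sort(key=lambda tc: (-tc[1], tc[0]))
    return kept
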