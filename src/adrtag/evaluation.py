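"""Span-level evaluation: exact (CoNLL-style) and partial matching.

Two regimes are provided:

* **exact** — a predicted span counts as a true positive only if its
  (start, end, label) triple is identical to a gold span; precision,
  recall and F1 come from corpus-level (micro) counts, CoNLL-style.  A
  per-sentence macro-averaged exact variant is available behind a flag.
* **partial** — token-overlap-proportional credit.  For every predicted
  term :math:`t_s` intersecting a gold term :math:`t`, precision
  accumulates :math:`|t \\cap t_s| / |t_s|` and recall accumulates
  :math:`|t \\cap t_s| / |t|`, with lengths measured in tokens.  The
  per-term ratios are capped at 1 (a prediction intersecting several
  gold terms cannot earn more than full credit).  Partial P and R are
  computed per sentence and macro-averaged over sentences; F is the
  harmonic mean of the averaged P and R.

Division conventions: a sentence with no gold and no predicted terms
contributes (1.0, 1.0) in partial mode — a sentence handled perfectly
should not lower the macro average; a 0/0 on one side only is scored 0.
Both conventions are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EvalCounts",
    "EvalReport",
    "exact_counts",
    "prf",
    "partial_sentence",
    "evaluate_corpus",
]


@dataclass(frozen=True)
class EvalCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.TP + other.TP, self.FP + other.FP,
                          self.FN + other.FN)


@dataclass(frozen=True)
class EvalReport:
    mode: str  # "exact" | "partial"
    precision: float
    recall: float
    f1: float
    per_sentence: tuple[tuple[float, float], ...] | None = None

    def format(self) -> str:
        return (f"{self.mode:8s} P={self.precision:.4f} "
                f"R={self.recall:.4f} F={self.f1:.4f}")


def exact_counts(gold, pred) -> EvalCounts:
    """TP/FP/FN under exact span identity (start, end, label)."""
    gold, pred = set(gold), set(pred)
    tp = len(gold & pred)
    return EvalCounts(tp, len(pred) - tp, len(gold) - tp)


def prf(counts: EvalCounts) -> tuple[float, float, float]:
    """Precision, recall, F1 with the zero-denominator -> 0 convention."""
    p = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    r = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def partial_sentence(gold_terms, pred_terms,
                     empty_sentence_score: float = 1.0):
    """Token-overlap precision and recall for one sentence.

    ``gold_terms``/``pred_terms`` are half-open token-index intervals
    ``(first, last+1)``.  Each predicted term earns precision credit
    ``overlap / len(pred_term)`` summed over the gold terms it
    intersects (capped at 1); each gold term earns recall credit
    ``overlap / len(gold_term)`` over the predictions it intersects
    (capped at 1).

    Division conventions: a sentence with neither gold nor predicted
    terms scores ``(empty_sentence_score, empty_sentence_score)``; with
    gold but no predictions, P is 0/0 and returned as ``None`` (excluded
    from the macro average) while R = 0; symmetrically for predictions
    without gold.
    """
    gold_terms, pred_terms = list(gold_terms), list(pred_terms)
    if not gold_terms and not pred_terms:
        return empty_sentence_score, empty_sentence_score
    if not pred_terms:
        return None, 0.0
    if not gold_terms:
        return 0.0, None
    p_credit = 0.0
    for ts in pred_terms:
        overlap = sum(_interval_overlap(t, ts) for t in gold_terms)
        p_credit += min(overlap / (ts[1] - ts[0]), 1.0)
    r_credit = 0.0
    for t in gold_terms:
        overlap = sum(_interval_overlap(t, ts) for ts in pred_terms)
        r_credit += min(overlap / (t[1] - t[0]), 1.0)
    return p_credit / len(pred_terms), r_credit / len(gold_terms)


def evaluate_corpus(gold_sentences, pred_sentences, mode: str = "exact",
                    macro_exact: bool = False,
                    empty_sentence_score: float = 1.0) -> EvalReport:
    """Score predictions against gold over a corpus of sentences.

    Both arguments map a sentence key to its terms: an ordered mapping
    ``{sentence_key: list of (start, end) intervals}``.  Exact mode uses
    exact identity on the intervals with corpus-level micro counts (or
    per-sentence macro averaging when ``macro_exact`` is set); partial
    mode applies :func:`partial_sentence` per sentence and averages.
    The two mappings must cover identical sentence sets; the report is
    invariant to sentence order.
    """
    if set(gold_sentences) != set(pred_sentences):
        missing = set(gold_sentences) ^ set(pred_sentences)
        raise ValueError(f"gold/pred sentence sets differ: {sorted(missing)!r}")
    keys = sorted(gold_sentences)
    if mode == "exact":
        if macro_exact:
            pairs = []
            for k in keys:
                p, r, _ = prf(exact_counts(gold_sentences[k], pred_sentences[k]))
                g, q = gold_sentences[k], pred_sentences[k]
                if not g and not q:
                    p = r = empty_sentence_score
                pairs.append((p, r))
            return _macro_report("exact", pairs)
        counts = EvalCounts(0, 0, 0)
        for k in keys:
            counts = counts + exact_counts(gold_sentences[k], pred_sentences[k])
        p, r, f = prf(counts)
        return EvalReport("exact", p, r, f)
    if mode == "partial":
        pairs = [partial_sentence(gold_sentences[k], pred_sentences[k],
                                  empty_sentence_score)
                 for k in keys]
        return _macro_report("partial", pairs)
    raise ValueError(f"unknown mode {mode!r}")


def _macro_report(mode: str, pairs) -> EvalReport:
    """Average per-sentence (P, R); ``None`` entries (0/0) are excluded."""
    ps = [x for x, _ in pairs if x is not None]
    rs = [y for _, y in pairs if y is not None]
    p = sum(ps) / len(ps) if ps else 0.0
    r = sum(rs) / len(rs) if rs else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return EvalReport(mode, p, r, f, tuple(pairs))
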