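"""Evaluation of predicted protein complexes against a reference catalogue.

A predicted cluster K matches a reference complex R when their Jaccard
overlap

    MatchScore(K, R) = |K ∩ R| / |K ∪ R|

reaches the match threshold (0.25 by default).  Complex-level recall is
the fraction of reference complexes matched by some prediction,
precision the fraction of predictions matched by some reference, and
the F-measure their harmonic mean.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .core import ComplexSet

__all__ = ["EvalResult", "match_score", "evaluate"]


@dataclasses.dataclass
class EvalResult:
    precision: float
    recall: float
    f_measure: float
    match_threshold: float
    n_predicted: int
    n_reference: int
    per_complex_best_scores: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "match_threshold": self.match_threshold,
            "n_predicted": self.n_predicted,
            "n_reference": self.n_reference,
        }


def match_score(predicted: frozenset[str] | set[str], reference: frozenset[str] | set[str]) -> float:
    """Jaccard overlap between two gene sets."""
    if not predicted or not reference:
        raise ValueError("match_score requires non-empty gene sets")
    inter = len(set(predicted) & set(reference))
    if inter == 0:
        return 0.0
    return inter / len(set(predicted) | set(reference))


def evaluate(
    predicted: ComplexSet,
    reference: ComplexSet,
    threshold: float = 0.25,
    *,
    strict: bool = False,
    restrict_to_reference_universe: bool = False,
) -> EvalResult:
    """Complex-level precision / recall / F-measure at a match threshold.

    A comparison passes at ``score >= threshold`` (``>`` with
    ``strict=True``).  With ``restrict_to_reference_universe`` predicted
    complexes are first intersected with the reference catalogue's gene
    universe (predictions shrinking below 2 members are dropped) — a
    sensitivity analysis, off by default.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if len(predicted) == 0 or len(reference) == 0:
        raise ValueError("both complex sets must be non-empty")
    pred_items = list(predicted.complexes.items())
    if restrict_to_reference_universe:
        universe = reference.members()
        pred_items = [
            (name, mem & universe) for name, mem in pred_items if len(mem & universe) >= 2
        ]
        if not pred_items:
            raise ValueError("no predicted complex survives the reference-universe restriction")
    ref_items = list(reference.complexes.items())

    # inverted member index over references keeps this linear in shared members
    by_gene: dict[str, list[int]] = {}
    for j, (_, rmem) in enumerate(ref_items):
        for g in rmem:
            by_gene.setdefault(g, []).append(j)

    passes = (lambda s: s > threshold) if strict else (lambda s: s >= threshold)
    best_pred = [0.0] * len(pred_items)
    best_ref = [0.0] * len(ref_items)
    for i, (_, kmem) in enumerate(pred_items):
        touched: set[int] = set()
        for g in kmem:
            touched.update(by_gene.get(g, ()))
        for j in touched:
            s = match_score(kmem, ref_items[j][1])
            if s > best_pred[i]:
                best_pred[i] = s
            if s > best_ref[j]:
                best_ref[j] = s

    precision = sum(1 for s in best_pred if passes(s)) / len(pred_items)
    recall = sum(1 for s in best_ref if passes(s)) / len(ref_items)
    f = 2.0 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    scores = pd.DataFrame(
        {
            "name": [n for n, _ in pred_items] + [n for n, _ in ref_items],
            "side": ["predicted"] * len(pred_items) + ["reference"] * len(ref_items),
            "best_match_score": best_pred + best_ref,
        }
    )
    return EvalResult(
        precision=precision,
        recall=recall,
        f_measure=f,
        match_threshold=threshold,
        n_predicted=len(pred_items),
        n_reference=len(ref_items),
        per_complex_best_scores=scores,
    )
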