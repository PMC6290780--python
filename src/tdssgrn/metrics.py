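"""Confusion-matrix evaluation of inferred networks, plus the speedup ratio.

Sensitivity and specificity are computed over ordered (regulator, target)
gene pairs.  By default self-pairs are excluded and an edge counts as a
true positive whenever the pair is predicted, regardless of its delay; a
strict mode additionally requires the predicted delay class (instantaneous
vs delayed) to match, with mismatches counted as misses.
"""

from __future__ import annotations

from dataclasses import dataclass

from .inference import EdgeSet

__all__ = ["UndefinedMetricError", "ConfusionCounts", "confusion",
           "sensitivity", "specificity", "speedup"]


class UndefinedMetricError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    FP: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


def confusion(predicted: EdgeSet, truth: EdgeSet, n_genes: int,
              include_self: bool = False,
              strict_delay: bool = False) -> ConfusionCounts:
    """Count TP/FN/FP/TN over every ordered gene pair.

    In strict mode a true pair predicted with the wrong delay class counts
    as a miss (FN), never as a spurious prediction, so strict sensitivity
    is bounded above by the lenient one.
    """
    for es, name in ((predicted, "predicted"), (truth, "truth")):
        for e in es:
            if not (0 <= e.regulator < n_genes and 0 <= e.target < n_genes):
                raise IndexError(
                    f"{name} edge {e.regulator}->{e.target} outside "
                    f"[0, {n_genes})")
    tp = fn = fp = tn = 0
    for j in range(n_genes):
        for i in range(n_genes):
            if j == i and not include_self:
                continue
            in_pred = (j, i) in predicted
            in_true = (j, i) in truth
            if in_true and in_pred and strict_delay:
                pe = predicted.get(j, i)
                te = truth.get(j, i)
                if pe.delay_class != te.delay_class:
                    in_pred = False  # wrong kind of edge: counts as missed
            if in_true and in_pred:
                tp += 1
            elif in_true:
                fn += 1
            elif in_pred:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, FN=fn, FP=fp, TN=tn)


def sensitivity(c: ConfusionCounts) -> float:
    """``TP / (TP + FN)``."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: no true edges")
    return c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float:
    """``TN / (FP + TN)``."""
    if c.FP + c.TN == 0:
        raise UndefinedMetricError("specificity undefined: no true non-edges")
    return c.TN / (c.FP + c.TN)


def speedup(runtime_single: float, runtime_cluster: float) -> float:
    """Single-node runtime divided by cluster runtime (informational)."""
    if runtime_single <= 0 or runtime_cluster <= 0:
        raise ValueError("runtimes must be positive")
    return runtime_single / runtime_cluster
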