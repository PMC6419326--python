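"""Segmentation quality metrics against ground-truth masks.

Dice = 2|O∩G| / (|O|+|G|), Jaccard = |O∩G| / |O∪G|, and the border error

    BE = (FN + FP) / (TN + TP),

i.e. misclassified over correctly classified pixels.  This denominator is
deliberately not the more common |G|; ``xor_over_gt`` provides the
conventional (FN+FP)/|G| as a separate, explicitly-named metric.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from leeac.errors import ParameterError

__all__ = ["EvalScores", "dice", "jaccard", "border_error", "xor_over_gt", "evaluate_masks"]


@dataclass(frozen=True)
class EvalScores:
    dice: float
    jaccard: float
    border_error: float
    tp: int
    fp: int
    fn: int
    tn: int

    def to_dict(self) -> dict:
        return asdict(self)


def _as_bool_pair(o: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(o).astype(bool)
    g = np.asarray(g).astype(bool)
    if o.shape != g.shape:
        raise ParameterError(f"mask shapes differ: {o.shape} vs {g.shape}")
    return o, g


def dice(o: np.ndarray, g: np.ndarray) -> float:
    """Dice coefficient 2|O∩G|/(|O|+|G|)."""
    o, g = _as_bool_pair(o, g)
    denom = int(o.sum()) + int(g.sum())
    if denom == 0:
        raise ParameterError("both masks are empty: Dice undefined")
    return 2.0 * int((o & g).sum()) / denom


def jaccard(o: np.ndarray, g: np.ndarray) -> float:
    """Jaccard index |O∩G|/|O∪G|."""
    o, g = _as_bool_pair(o, g)
    union = int((o | g).sum())
    if union == 0:
        raise ParameterError("both masks are empty: Jaccard undefined")
    return int((o & g).sum()) / union


def confusion_counts(o: np.ndarray, g: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) pixel counts of prediction O against truth G."""
    o, g = _as_bool_pair(o, g)
    tp = int((o & g).sum())
    fp = int((o & ~g).sum())
    fn = int((~o & g).sum())
    tn = int((~o & ~g).sum())
    return tp, fp, fn, tn


def border_error(o: np.ndarray, g: np.ndarray) -> float:
    """Border error (FN+FP)/(TN+TP)."""
    tp, fp, fn, tn = confusion_counts(o, g)
    if tn + tp == 0:
        raise ParameterError("TN+TP = 0: border error undefined (masks are complementary)")
    return (fn + fp) / (tn + tp)


def xor_over_gt(o: np.ndarray, g: np.ndarray) -> float:
    """Conventional border error (FN+FP)/|G|; requires a non-empty truth."""
    tp, fp, fn, _ = confusion_counts(o, g)
    if tp + fn == 0:
        raise ParameterError("empty ground truth")
    return (fn + fp) / (tp + fn)


def evaluate_masks(o: np.ndarray, g: np.ndarray) -> EvalScores:
    """All metrics plus the confusion counts in one record."""
    tp, fp, fn, tn = confusion_counts(o, g)
    return EvalScores(
        dice=dice(o, g),
        jaccard=jaccard(o, g),
        border_error=border_error(o, g),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )
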