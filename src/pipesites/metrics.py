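"""Distance Measure (DM) between predicted and lab-confirmed site pairs.

Per protein, the distance is the clamped maximum boundary overshoot of the
prediction beyond the lab range:

    delta = max(0, start_lab - start_pred, end_pred - end_lab)

so a prediction contained in the lab range scores 0 — accommodating lab
ranges that over-estimate the true site. Each delta is scaled by
(protein length - 1) and the two are combined vectorially:

    DM = sqrt(ratio_A^2 + ratio_B^2) / sqrt(2)

giving a value in [0, 1]: 0 for containment on both proteins, 1 when
single-residue sites sit at opposite ends of both proteins. Boundary
errors are weighed inversely with protein length, so DM is comparable
across proteins of arbitrary length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io_formats import Interval, ValidationError, validate_interval

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class DMBreakdown:
    """DM with its per-protein contributions."""

    delta_a: int
    delta_b: int
    ratio_a: float
    ratio_b: float
    dm: float


def delta_protein(lab: Interval, pred: Interval) -> int:
    """Clamped boundary overshoot of ``pred`` beyond ``lab`` on one protein.

    Zero exactly when the prediction is contained in the lab range.
    """
    validate_interval(lab, what="lab range")
    validate_interval(pred, what="predicted range")
    return max(0, lab[0] - pred[0], pred[1] - lab[1])


def _ratio(delta: int, length: int) -> float:
    # length-1 normalization: opposite single-residue ends give exactly 1
    if length <= 1:
        return 0.0
    return delta / (length - 1)


def dm(
    lab_a: Interval,
    pred_a: Interval,
    lab_b: Interval,
    pred_b: Interval,
    len_a: int,
    len_b: int,
) -> DMBreakdown:
    """Distance Measure between a predicted and a lab-confirmed site pair.

    All intervals are 1-based inclusive and must lie within their protein
    lengths. Symmetric in the two protein roles.
    """
    for rng, length, what in (
        (lab_a, len_a, "lab range A"),
        (pred_a, len_a, "predicted range A"),
        (lab_b, len_b, "lab range B"),
        (pred_b, len_b, "predicted range B"),
    ):
        validate_interval(rng, length, what)
    da = delta_protein(lab_a, pred_a)
    db = delta_protein(lab_b, pred_b)
    ra = _ratio(da, len_a)
    rb = _ratio(db, len_b)
    value = math.sqrt(ra * ra + rb * rb) / _SQRT2
    return DMBreakdown(delta_a=da, delta_b=db, ratio_a=ra, ratio_b=rb, dm=value)


def best_of_k(dms: list[float], k: int) -> float | None:
    """Minimum DM among the first k ranked values; None for an empty list.

    Fewer than k values available -> minimum of what exists. Models wet-lab
    validation of the k highest-ranked candidate sites.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not dms:
        return None
    return min(dms[:k])
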