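"""Published reference metrics for the original clinical cohort.

The study this pipeline reimplements reported per-class precision,
recall and Sørensen–Dice for fifteen Wilms-tumor tissue components on a
private national whole-slide-image cohort, plus micro-pooled scores for
the two clinical groups and overall.  Those printed values are kept here
as reference data: they are inputs (the private cohort itself is not
available), useful for consistency checks — every printed Dice must
equal the harmonic mean of its printed precision and recall after
rounding — and for comparing synthetic-cohort runs against the reported
operating point.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "REFERENCE_COHORT_METRICS",
    "REFERENCE_ENSEMBLE_DICE",
    "dice_from_pr",
    "round_half_up",
]

# row label -> (precision, recall, dice) as printed, 2 decimals.
REFERENCE_COHORT_METRICS: dict[str, tuple[float, float, float]] = {
    "WT-blastema": (0.71, 0.96, 0.82),
    "WT-stroma": (0.77, 0.59, 0.67),
    "WT-epithelium": (0.65, 0.38, 0.48),
    "Necrosis": (0.98, 0.99, 0.98),
    "Bleeding": (0.23, 0.92, 0.37),
    "Regression": (0.62, 0.77, 0.69),
    "Glomeruli": (0.69, 1.00, 0.82),
    "Tubules": (0.98, 0.96, 0.97),
    "Fat": (1.00, 0.89, 0.94),
    "Mesenchyme": (0.57, 0.67, 0.62),
    "Vessels": (0.85, 0.77, 0.81),
    "Nerves": (0.85, 0.77, 0.81),
    "Lymph nodes": (0.99, 0.99, 0.99),
    "Urothelium": (0.46, 0.96, 0.62),
    "Nephrogenic rests": (0.82, 0.98, 0.89),
    "Chemotherapy-induced changes": (0.79, 0.90, 0.84),
    "Vital tumor components": (0.74, 0.66, 0.70),
    "Overall score": (0.85, 0.85, 0.85),
}

# Reported overall Dice of the two individual networks and their
# per-pixel softmax average on the clinical cohort.
REFERENCE_ENSEMBLE_DICE: dict[str, float] = {
    "densenet": 0.7721,
    "u-net": 0.7083,
    "ensemble": 0.7767,
}


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, the convention used for printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def dice_from_pr(precision: float, recall: float) -> float:
    """Dice as the harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
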