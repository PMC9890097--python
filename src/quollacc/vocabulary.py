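"""Behaviour vocabulary shared across the pipeline.

Twelve behaviours scored from enclosure video of northern quolls
(*Dasyurus hallucatus*) form the classification vocabulary. Two of them
(Lying/Resting and Sitting) are stationary postures; three are the gaits
used for speed calibration and distance accumulation.
"""

from __future__ import annotations

LYING = "Lying/Resting"
SITTING = "Sitting"

#: The 12-class behaviour vocabulary, in a fixed canonical order.
BEHAVIORS: tuple[str, ...] = (
    "Climbing",
    LYING,
    SITTING,
    "Vigilance",
    "Standing Vigilance",
    "Vigilant Walking",
    "Walking",
    "Turning",
    "Galloping",
    "Bounding",
    "Jumping",
    "Scurrying",
)

#: Postures merged into one stationary state for rest-bout extraction.
STATIONARY: frozenset[str] = frozenset({LYING, SITTING})

#: Gaits whose bouts enter the speed/distance analysis. Vigilant Walking is
#: excluded by default (configurable at call sites).
LOCOMOTOR: tuple[str, ...] = ("Walking", "Galloping", "Bounding")

#: Energy classes by typical per-epoch peak vectorial body acceleration.
#: Low and high membership follows the observed VBAmax ranking of postures
#: vs. ballistic behaviours; the medium class is the residual set.
DEFAULT_ENERGY_CLASS: dict[str, str] = {
    LYING: "low",
    SITTING: "low",
    "Vigilance": "low",
    "Standing Vigilance": "low",
    "Walking": "medium",
    "Vigilant Walking": "medium",
    "Scurrying": "medium",
    "Climbing": "medium",
    "Bounding": "high",
    "Jumping": "high",
    "Turning": "high",
    "Galloping": "high",
}


def validate_labels(labels) -> None:
    """Raise ``ValueError`` naming the first label outside the vocabulary."""
    vocab = set(BEHAVIORS)
    for lab in labels:
        if lab not in vocab:
            raise ValueError(f"unknown behaviour label: {lab!r}")
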