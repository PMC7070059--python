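"""Confocal laser endomicroscopy (CLE) severity scoring.

In vivo endomicroscopy of acriflavine-stained colonic mucosa co-imaged with a
neutrophil-elastase-activated probe (NE680) shows a reproducible progression
of disease features: luminal NE680 signal appears first, then collapsed
crypts, then loss of acriflavine staining with NE680-positive cells inside
erosions, and finally frank crypt loss.  The rubric maps a frame's categorical
feature annotation to an ordinal 0-5 severity grade, and per-animal scores
aggregate a minimum of three video frames covering the distal colon.

The grade ladder is evaluated from 5 down to 0 so that overlapping
descriptions resolve to the most severe matching grade, the convention of
clinical severity indices.  Each grade's conditions involve only
severity-monotone feature comparisons, so worsening any single feature can
never lower the grade.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

__all__ = ["FrameAnnotation", "AnimalScore", "score_frame", "score_animal"]

# ordinal vocabularies, least to most severe
COLLAPSED = ("none", "present", "significant")
LUMEN = ("absent", "present", "high")
AREA = ("low", "high")
EROSION_CELLS = ("none", "present", "exclusive")
CRYPT_LOSS = ("none", "present", "significant")
ARCH = ("none", "present")


class AnnotationError(ValueError):
    """Frame annotation violates the feature vocabulary or its invariants."""


@dataclass(frozen=True)
class FrameAnnotation:
    """Categorical disease features of a single CLE video frame.

    Fractions are in [0, 1]; categorical fields use the module-level
    vocabularies.  A frame with unchanged crypt architecture cannot also have
    collapsed crypts or crypt loss.
    """

    healthy_crypt_fraction: float = 1.0
    crypt_architecture_change: str = "none"
    collapsed_crypts: str = "none"
    ne680_lumen: str = "absent"
    ne680_area: str = "low"
    acriflavine_unstained_fraction: float = 0.0
    ne680_cells_in_erosions: str = "none"
    crypt_loss: str = "none"

    def __post_init__(self) -> None:
        for name, vocab in (
            ("crypt_architecture_change", ARCH),
            ("collapsed_crypts", COLLAPSED),
            ("ne680_lumen", LUMEN),
            ("ne680_area", AREA),
            ("ne680_cells_in_erosions", EROSION_CELLS),
            ("crypt_loss", CRYPT_LOSS),
        ):
            if getattr(self, name) not in vocab:
                raise AnnotationError(f"{name}={getattr(self, name)!r} not in {vocab}")
        for name in ("healthy_crypt_fraction", "acriflavine_unstained_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise AnnotationError(f"{name} must be in [0, 1], got {v}")
        if self.crypt_architecture_change == "none":
            if self.collapsed_crypts != "none" or self.crypt_loss != "none":
                raise AnnotationError(
                    "unchanged crypt architecture excludes collapsed crypts and crypt loss"
                )


def _rank(value: str, vocab: tuple) -> int:
    return vocab.index(value)


def score_frame(annotation: FrameAnnotation) -> int:
    """Ordinal severity grade 0-5 for one frame.

    Grades, checked most severe first:

    5. only NE680-positive cells within erosions, with significant crypt loss
    4. >50% of crypts lack acriflavine staining, high luminal NE680, and
       NE680-positive cells present within erosions
    3. significant presence of collapsed crypts with high NE680-positive area
    2. high NE680 signal in the crypt lumen with collapsed crypts present
       (typically still >50% healthy crypt structure)
    1. healthy crypt architecture with NE680 signal in the crypt lumen
    0. unchanged crypt architecture and no NE680 signal

    A frame matching none of these (architecture changed but no graded
    combination) falls back to 1 if it shows any NE680 signal, else 0.
    """
    a = annotation
    if (
        a.ne680_cells_in_erosions == "exclusive"
        and a.crypt_loss == "significant"
    ):
        return 5
    if (
        a.acriflavine_unstained_fraction > 0.5
        and a.ne680_lumen == "high"
        and _rank(a.ne680_cells_in_erosions, EROSION_CELLS) >= 1
    ):
        return 4
    if a.collapsed_crypts == "significant" and a.ne680_area == "high":
        return 3
    if a.ne680_lumen == "high" and _rank(a.collapsed_crypts, COLLAPSED) >= 1:
        return 2
    if (
        a.crypt_architecture_change == "none"
        and _rank(a.ne680_lumen, LUMEN) >= 1
    ):
        return 1
    if a.crypt_architecture_change == "none" and a.ne680_lumen == "absent":
        return 0
    # architecture changed but no ladder rule matched
    any_signal = (
        _rank(a.ne680_lumen, LUMEN) >= 1
        or a.ne680_area == "high"
        or _rank(a.ne680_cells_in_erosions, EROSION_CELLS) >= 1
    )
    return 1 if any_signal else 0


@dataclass
class AnimalScore:
    """Aggregate severity for one animal over its scored frames."""

    animal_id: str
    frame_scores: list[int]
    score: int
    method: str
    low_coverage: bool = False  # fewer than the recommended 3 frames


def score_animal(
    frames: Iterable[FrameAnnotation],
    animal_id: str = "",
    method: Literal["mode", "max", "median"] = "mode",
) -> AnimalScore:
    """Aggregate per-frame grades to one animal-level score.

    Default is the modal frame score with ties broken toward the higher
    (more severe) grade; ``max`` and ``median`` are available alternatives.
    Fewer than three frames is allowed but flagged as low coverage.
    """
    scores = [score_frame(f) for f in frames]
    if not scores:
        raise AnnotationError("score_animal requires at least one frame")

    if method == "mode":
        counts = Counter(scores)
        top = max(counts.values())
        agg = max(s for s, c in counts.items() if c == top)
    elif method == "max":
        agg = max(scores)
    elif method == "median":
        agg = int(round(float(np.median(scores))))
    else:
        raise AnnotationError(f"unknown aggregation method {method!r}")

    return AnimalScore(animal_id=animal_id, frame_scores=scores, score=agg,
                       method=method, low_coverage=len(scores) < 3)
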