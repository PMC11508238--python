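"""Reference inventory of the ICU ambient-monitoring dataset the pipeline
was designed around, with the arithmetic used for sanity checks.

The image data themselves are not distributed; these printed summary
figures (annotation counts per category, image-cleaning yield, the 80/20
train/test split, and assessment subgroup sizes after the clock-alignment
exclusion) are the fixed facts the acceptance checks verify.
"""

from __future__ import annotations

#: Annotated person instances per category across the cleaned image set.
ANNOTATED_OBJECTS = {"patient": 2062, "clinician": 2048, "visitor": 1564}

#: Printed total of annotated objects (should equal the category sum).
ANNOTATED_TOTAL = 5674

#: Images removed during quality cleaning and the cleaned remainder.
IMAGES_REMOVED = 244
IMAGES_CLEANED = 2130

#: Train fraction of the cleaned images.
TRAIN_FRACTION = 0.8

#: Printed train/test sizes.
TRAIN_SIZE = 1704
TEST_SIZE = 426

#: Delirium assessments retained after excluding clock offsets > 30 min.
ASSESSMENTS = {"non_delirious": 125, "delirious": 29}
ASSESSMENTS_TOTAL = 154

#: Enrolled patients contributing image data.
N_PATIENTS = 52


def annotation_total() -> int:
    """Sum of the per-category annotation counts."""
    return sum(ANNOTATED_OBJECTS.values())


def train_test_sizes(n_images: int = IMAGES_CLEANED, train_fraction: float = TRAIN_FRACTION) -> tuple[int, int]:
    """Deterministic train/test sizes for an n-image pool: the training
    set takes floor(n * fraction) images, the test set the rest."""
    train = int(n_images * train_fraction)
    return train, n_images - train


def assessments_total() -> int:
    """Sum of the assessment subgroup sizes."""
    return sum(ASSESSMENTS.values())
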