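"""On-tissue screening of ion images.

Distributions that overlap the tissue are kept as biomolecules; those that
are (near-)homogeneous across tissue and slide, or brighter off tissue than
on it, are discarded as artefacts (matrix clusters, slide background,
chemical noise). The published screening this automates was manual; here the
decision is a mean-intensity enrichment ratio with a configurable threshold,
recorded in the report for audit.

Labels are invariant to uniform scaling of an image, since only the
inside/outside mean ratio enters the decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msdata_io import IonImage, ROI

__all__ = [
    "BIOMOLECULE",
    "ARTEFACT_HOMOGENEOUS",
    "ARTEFACT_OFF_TISSUE",
    "ScreenReport",
    "classify_distribution",
    "screen_dataset",
]

BIOMOLECULE = "biomolecule"
ARTEFACT_HOMOGENEOUS = "artefact_homogeneous"
ARTEFACT_OFF_TISSUE = "artefact_off_tissue"
_LABELS = (BIOMOLECULE, ARTEFACT_HOMOGENEOUS, ARTEFACT_OFF_TISSUE)


@dataclass
class ScreenReport:
    """Per-image screening outcome: label, on/off-tissue means and the
    enrichment ratio, plus the threshold used."""

    table: pd.DataFrame
    enrichment_threshold: float

    def counts(self) -> dict[str, int]:
        c = self.table["label"].value_counts()
        return {label: int(c.get(label, 0)) for label in _LABELS}


def classify_distribution(
    image: IonImage, roi: ROI, enrichment_threshold: float = 2.0
) -> str:
    """Label one ion image as biomolecule / homogeneous artefact / off-tissue
    artefact.

    Means are taken over all pixels inside vs outside the ROI, zeros
    included, so sparse images are not inflated. The image is off-tissue if
    the outside mean exceeds the inside mean, homogeneous if the
    inside/outside enrichment ratio is below ``enrichment_threshold``, and a
    biomolecule otherwise.
    """
    label, _ = _classify(image, roi, enrichment_threshold)
    return label


def _classify(image: IonImage, roi: ROI, threshold: float):
    if roi.mask.shape != image.shape:
        raise ValueError(
            f"ROI shape {roi.mask.shape} does not match image shape {image.shape}"
        )
    if threshold <= 1:
        raise ValueError("enrichment threshold must exceed 1")
    inside = float(image.values[roi.mask].mean())
    n_out = (~roi.mask).sum()
    outside = float(image.values[~roi.mask].mean()) if n_out else 0.0
    # relative tolerance so an exactly homogeneous image is not pushed into
    # the off-tissue class by float rounding
    if outside > inside * (1 + 1e-9):
        label = ARTEFACT_OFF_TISSUE
        ratio = inside / outside if outside > 0 else np.inf
    else:
        ratio = inside / outside if outside > 0 else np.inf
        label = BIOMOLECULE if ratio >= threshold else ARTEFACT_HOMOGENEOUS
        if inside == 0:  # blank image: nothing anywhere
            label = ARTEFACT_HOMOGENEOUS
            ratio = 1.0
    return label, (inside, outside, ratio)


def screen_dataset(
    images: list[IonImage], roi: ROI, enrichment_threshold: float = 2.0
) -> tuple[list[IonImage], ScreenReport]:
    """Screen a stack of ion images; return the kept biomolecule images (in
    input order) and the full report."""
    rows = []
    kept = []
    for image in images:
        label, (inside, outside, ratio) = _classify(image, roi, enrichment_threshold)
        rows.append(
            {
                "label_mz": image.label,
                "label": label,
                "mean_on_tissue": inside,
                "mean_off_tissue": outside,
                "enrichment_ratio": ratio,
            }
        )
        if label == BIOMOLECULE:
            kept.append(image)
    report = ScreenReport(pd.DataFrame(rows), enrichment_threshold)
    return kept, report
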