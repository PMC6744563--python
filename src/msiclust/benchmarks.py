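"""Phantom recovery experiments.

The real dataset behind this analysis style is not publicly deposited, so
the package's quantitative guarantees are stated as recovery experiments on
seeded phantoms: PCA must recover planted spatial archetypes, similarity
clustering must reproduce the planted grouping, and screening must discard
planted artefacts without losing genuine biomolecule distributions. These
functions run each experiment end-to-end (render → average spectrum → peak
picking → ion images → stage under test) and return the measured metrics.

Experiment conditions (grid 64×48 at 50 µm, 100 molecules, log-normal
multiplicative noise sigma 0.2, 5 spurious peaks per spectrum) are fixed
package-level study conditions, not tuning knobs; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .decompose import run_pca
from .lipid_annot import default_lipid_library
from .peakpick import average_spectrum, ion_image, pick_peaks
from .phantom import (
    NOISELESS,
    NoiseModel,
    archetype_templates,
    make_ground_truth,
    make_region_masks,
    match_mz_to_truth,
    render_dataset,
)
from .screening import BIOMOLECULE, screen_dataset
from .simcluster import cosine_similarity_matrix, extract_groups, order_by_clustering

__all__ = [
    "phantom_images",
    "pca_archetype_recovery",
    "clustering_archetype_recovery",
    "screening_recovery",
]

GRID = (64, 48)
N_MOLECULES = 100
#: Archetype mix for the three-pattern PCA experiment: three mutually
#: disjoint spatial patterns (grey-matter band, fibre-tract band, brainstem)
#: with distinctly different group sizes. Disjoint supports and separated
#: sizes keep the top eigenvalues non-degenerate, which is what makes
#: PC-to-template matching identifiable; the size ordering (grey most
#: numerous) follows the relative abundance order reported for brain tissue.
PCA_WEIGHTS = {"I": 0.55, "IV": 0.30, "X": 0.15}
#: "Low noise": clean spatial patterns (multiplicative sigma 0.05) over the
#: usual spurious-peak background, which supplies the instrument-like noise
#: floor that the S/N threshold is measured against.
LOW_NOISE = NoiseModel(baseline=5.0, multiplicative_sigma=0.05, spurious_rate=5.0)


def phantom_images(
    seed: int,
    archetype_weights=None,
    n_molecules: int = N_MOLECULES,
    noise: NoiseModel = NoiseModel(),
    grid: tuple[int, int] = GRID,
    screen: bool = True,
):
    """Render a phantom and run it through peak picking and ion-image
    extraction. Returns (masks, truth, kept ion images, screening report,
    archetype label per kept image or None for unmatched)."""
    masks = make_region_masks(*grid)
    truth = make_ground_truth(
        n_molecules, archetype_weights, default_lipid_library(), seed=seed
    )
    dataset = render_dataset(truth, masks, noise)
    peaks = pick_peaks(average_spectrum(dataset))
    images = [ion_image(dataset, mz) for mz in peaks.mz]
    if screen:
        kept, report = screen_dataset(images, masks.roi())
    else:
        kept, report = images, None
    matched = match_mz_to_truth([img.center_mz for img in kept], truth)
    labels = [
        a if isinstance(a, str) else None for a in matched.get("archetype", [])
    ]
    return masks, truth, kept, report, labels


def pca_archetype_recovery(seed: int, n_molecules: int = N_MOLECULES) -> dict:
    """Three planted spatial archetypes (grey-matter band, fibre-tract band,
    brainstem) at low noise; measures how well the top-3 PC score images
    match the planted templates.

    Components and templates are paired by maximising total |Pearson r|
    (PC sign is arbitrary); returns the per-template correlations and their
    minimum.
    """
    masks, truth, kept, _report, _labels = phantom_images(
        seed,
        archetype_weights=PCA_WEIGHTS,
        n_molecules=n_molecules,
        noise=LOW_NOISE,
        screen=False,
    )
    templates = archetype_templates(masks)
    stack = np.column_stack([img.values.ravel() for img in kept])
    result = run_pca(stack, n_components=5)
    names = list(PCA_WEIGHTS)
    corr = np.zeros((3, 3))
    for i in range(3):
        score = result.scores[:, i]
        for j, name in enumerate(names):
            corr[i, j] = abs(np.corrcoef(score, templates[name].ravel())[0, 1])
    rows, cols = linear_sum_assignment(-corr)
    matched = {names[c]: float(corr[r, c]) for r, c in zip(rows, cols)}
    return {
        "correlations": matched,
        "min_abs_r": min(matched.values()),
        "n_images": len(kept),
        "contributions_pct": [float(c) for c in result.contributions[:3]],
    }


def clustering_archetype_recovery(seed: int, n_molecules: int = N_MOLECULES) -> dict:
    """Ten planted on-tissue archetypes at default noise; measures the
    adjusted Rand index between the extracted diagonal groups and the planted
    archetype labels of the truth-matched kept images (ungrouped images count
    as singleton clusters)."""
    weights = {a: 0.1 for a in ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")}
    masks, truth, kept, _report, labels = phantom_images(
        seed, archetype_weights=weights, n_molecules=n_molecules
    )
    matrix = cosine_similarity_matrix(kept, roi=masks.roi())
    ordering, _ = order_by_clustering(matrix)
    groups = extract_groups(matrix, ordering)
    member_group = {}
    for g in groups:
        if g.kind == "diagonal":
            for m in g.members:
                member_group[m] = g.name
    true_labels, pred_labels = [], []
    for img, archetype in zip(kept, labels):
        if archetype is None:
            continue
        true_labels.append(archetype)
        pred_labels.append(member_group.get(img.label, f"singleton:{img.label}"))
    return {
        "ari": float(adjusted_rand_score(true_labels, pred_labels)),
        "n_groups": sum(g.kind == "diagonal" for g in groups),
        "n_images": len(true_labels),
    }


def screening_recovery(seed: int, n_molecules: int = N_MOLECULES, noise=None) -> dict:
    """All twelve archetypes at default (or given) noise; measures the
    fraction of planted-artefact images discarded and of planted-biomolecule
    images kept."""
    masks = make_region_masks(*GRID)
    truth = make_ground_truth(
        n_molecules, None, default_lipid_library(), seed=seed
    )
    dataset = render_dataset(truth, masks, NoiseModel() if noise is None else noise)
    peaks = pick_peaks(average_spectrum(dataset))
    images = [ion_image(dataset, mz) for mz in peaks.mz]
    _kept, report = screen_dataset(images, masks.roi())
    matched = match_mz_to_truth([img.center_mz for img in images], truth)
    is_artefact = matched["archetype"].isin(["artefact_homogeneous", "artefact_off_tissue"])
    is_biomol = matched["archetype"].notna() & ~is_artefact
    decided = report.table["label"].to_numpy()
    n_artefact = int(is_artefact.sum())
    n_biomol = int(is_biomol.sum())
    artefacts_discarded = int((decided[is_artefact] != BIOMOLECULE).sum())
    biomol_kept = int((decided[is_biomol] == BIOMOLECULE).sum())
    return {
        "n_artefact_images": n_artefact,
        "artefact_discard_rate": artefacts_discarded / n_artefact if n_artefact else 1.0,
        "n_biomolecule_images": n_biomol,
        "biomolecule_loss_rate": 1.0 - biomol_kept / n_biomol if n_biomol else 0.0,
    }
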