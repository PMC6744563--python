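"""Cosine-similarity clustering of ion images.

Pairwise cosine similarities between ion-image intensity vectors (over ROI
pixels) form a similarity heat map; hierarchical clustering (average-linkage
UPGMA on distance 1 − similarity) orders it; groups are then extracted as
contiguous blocks in leaf order whose mean pairwise similarity exceeds a
threshold (default 0.5) with at least ``min_size`` members (default 7) —
"diagonal" groups — plus "off-diagonal" groups: pairs of distinct blocks
whose mean cross-block similarity also exceeds the threshold.

Cosine similarity is scale-free per image, so the matrix (and everything
downstream) is invariant to per-image positive rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .lipid_annot import round_half_away
from .msdata_io import IonImage, ROI

__all__ = [
    "SimilarityMatrix",
    "MoleculeGroup",
    "cosine_similarity_matrix",
    "order_by_clustering",
    "extract_groups",
    "occupancy_table",
]


@dataclass
class SimilarityMatrix:
    """Symmetric cosine-similarity matrix with image labels."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count must match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("similarity matrix diagonal must be 1")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 1.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MoleculeGroup:
    """One extracted group of co-distributed molecules."""

    name: str
    members: tuple[str, ...]
    kind: str  # "diagonal" | "off_diagonal"

    def __post_init__(self) -> None:
        if self.kind not in ("diagonal", "off_diagonal"):
            raise ValueError(f"unknown group kind {self.kind!r}")
        if len(set(self.members)) != len(self.members):
            raise ValueError("group members must be unique")

    @property
    def size(self) -> int:
        return len(self.members)


def cosine_similarity_matrix(
    images: list[IonImage] | np.ndarray,
    roi: ROI | None = None,
    labels: list[str] | None = None,
) -> SimilarityMatrix:
    """Pairwise cosine similarities of ion images over ROI pixels.

    ``images`` may be a list of :class:`IonImage` or a pixels × images
    matrix. With an ROI, only on-tissue pixels enter the dot products.
    """
    if isinstance(images, np.ndarray):
        X = np.asarray(images, dtype=np.float64)
        if labels is None:
            labels = [str(i) for i in range(X.shape[1])]
    else:
        if labels is None:
            labels = [img.label for img in images]
        X = np.column_stack([img.values.ravel() for img in images])
        if roi is not None:
            X = np.column_stack(
                [img.values[roi.mask] for img in images]
            )
            roi = None
    if roi is not None:
        X = X[np.asarray(roi.mask).ravel()]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 images")
    norms = np.linalg.norm(X, axis=0)
    dead = np.nonzero(norms == 0)[0]
    if dead.size:
        raise ValueError(f"image {labels[dead[0]]} has zero norm over selected pixels")
    sim = (X / norms).T @ (X / norms)
    np.clip(sim, -1.0, 1.0, out=sim)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(sim, list(labels))


def order_by_clustering(matrix: SimilarityMatrix, linkage: str = "average"):
    """Agglomerative clustering on distance 1 − similarity.

    Returns ``(ordering, Z)``: the dendrogram leaf order (a permutation of
    image indices) and the scipy linkage matrix. scipy's linkage is
    deterministic; equal distances are resolved by its stable pair ordering.
    """
    if linkage not in ("single", "complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if matrix.n == 1:
        return np.array([0]), np.empty((0, 4))
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    Z = sch.linkage(squareform(dist, checks=False), method=linkage)
    return sch.leaves_list(Z), Z


def _block_mean(sim: np.ndarray, block: list[int]) -> float:
    """Mean pairwise (off-diagonal) similarity within a block."""
    if len(block) < 2:
        return 1.0
    sub = sim[np.ix_(block, block)]
    n = len(block)
    return float((sub.sum() - np.trace(sub)) / (n * (n - 1)))


def _cross_mean(sim: np.ndarray, a: list[int], b: list[int]) -> float:
    return float(sim[np.ix_(a, b)].mean())


def extract_groups(
    matrix: SimilarityMatrix,
    ordering: np.ndarray,
    threshold: float = 0.5,
    min_size: int = 7,
    criterion: str = "mean",
    linkage: str = "average",
) -> list[MoleculeGroup]:
    """Extract molecule groups from the ordered similarity matrix.

    Candidate blocks are the clusters obtained by cutting the average-linkage
    dendrogram at distance 1 − threshold: every merge inside a block happened
    at mean pairwise similarity above ``threshold``, and blocks are contiguous
    runs in leaf order. Blocks must additionally satisfy the block criterion —
    mean pairwise similarity > threshold (``criterion="mean"``, default) or
    all pairwise similarities > threshold (``criterion="all"``) — and have at
    least ``min_size`` members to be reported as diagonal groups, named I,
    II, ... in leaf order. Off-diagonal groups are pairs of distinct diagonal
    blocks whose mean cross-block similarity exceeds the threshold, reported
    as the union of the pair.

    With average linkage the cut guarantees every pair of final blocks has
    mean cross similarity below the threshold, so off-diagonal groups cannot
    occur; they can with single or complete linkage, where block separation
    is driven by extreme rather than mean pairwise distances.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if criterion not in ("mean", "all"):
        raise ValueError(f"unknown block criterion {criterion!r}")
    if linkage not in ("single", "complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    order = list(np.asarray(ordering, dtype=int))
    if sorted(order) != list(range(matrix.n)):
        raise ValueError("ordering must be a permutation of image indices")
    sim = matrix.values

    if matrix.n == 1:
        flat = np.array([1])
    else:
        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        Z = sch.linkage(squareform(np.maximum(dist, 0.0), checks=False), method=linkage)
        flat = sch.fcluster(Z, t=1.0 - threshold, criterion="distance")
    position = {idx: pos for pos, idx in enumerate(order)}
    by_label: dict[int, list[int]] = {}
    for idx, label in enumerate(flat):
        by_label.setdefault(int(label), []).append(idx)
    blocks = [sorted(members, key=position.get) for members in by_label.values()]
    blocks.sort(key=lambda b: position[b[0]])
    if criterion == "mean":
        blocks = [b for b in blocks if _block_mean(sim, b) > threshold or len(b) == 1]
    else:
        blocks = [
            b
            for b in blocks
            if len(b) == 1
            or (sim[np.ix_(b, b)] + np.eye(len(b))).min() > threshold
        ]

    roman = [
        "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
        "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX",
    ]
    groups: list[MoleculeGroup] = []
    diagonal_blocks = [b for b in blocks if len(b) >= min_size]
    for i, block in enumerate(diagonal_blocks):
        name = roman[i] if i < len(roman) else f"D{i + 1}"
        groups.append(
            MoleculeGroup(name, tuple(matrix.labels[j] for j in block), "diagonal")
        )
    n_diag = len(groups)
    pair_idx = 0
    for i in range(len(diagonal_blocks)):
        for j in range(i + 1, len(diagonal_blocks)):
            if _cross_mean(sim, diagonal_blocks[i], diagonal_blocks[j]) > threshold:
                k = n_diag + pair_idx
                name = roman[k] if k < len(roman) else f"O{pair_idx + 1}"
                members = tuple(
                    matrix.labels[m] for m in diagonal_blocks[i] + diagonal_blocks[j]
                )
                groups.append(MoleculeGroup(name, members, "off_diagonal"))
                pair_idx += 1
    return groups


def occupancy_table(groups: list[MoleculeGroup], total: int) -> pd.DataFrame:
    """Per-group size and occupancy (% of ``total`` molecules, 1 decimal),
    with a grouped-total row summing the diagonal groups."""
    if total <= 0:
        raise ValueError("total molecule count must be positive")
    sizes = [g.size for g in groups]
    if sum(s for g, s in zip(groups, sizes) if g.kind == "diagonal") > total:
        raise ValueError("group sizes exceed the stated total")
    rows = [
        {
            "group": g.name,
            "kind": g.kind,
            "n": g.size,
            "ratio_pct": round_half_away(100.0 * g.size / total, 1),
        }
        for g in groups
    ]
    grouped = sum(g.size for g in groups if g.kind == "diagonal")
    rows.append(
        {
            "group": "Grouped total",
            "kind": "diagonal",
            "n": grouped,
            "ratio_pct": round_half_away(100.0 * grouped / total, 1),
        }
    )
    return pd.DataFrame(rows)
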