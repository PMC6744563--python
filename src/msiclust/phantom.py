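"""Synthetic brain-phantom generator for imaging-MS benchmarking.

Real MALDI-FT-ICR imaging datasets of brain tissue are large and rarely
deposited, so every stage of this package is exercised against a phantom: a
rectangular pixel grid partitioned into brain-like regions (grey matter,
fibre tracts, cerebellar cortex, brainstem, off-tissue margin), populated
with glycerophospholipid species whose spatial distribution follows one of
twelve archetypes — ten on-tissue molecule groups (I–X) plus two artefact
classes (homogeneous everywhere, enriched off tissue). Each molecule is
emitted as a ¹³C isotopologue series under one or two positive-mode adducts,
with log-normal multiplicative noise on true peaks and Poisson-rate spurious
peaks at random m/z.

The ten on-tissue archetypes are rendered on spatially *disjoint* sub-zones
(bands within the anatomical regions). Real molecule groups overlap
spatially; disjoint supports are used here so that clustering-recovery
experiments have an unambiguous ground truth.

A fixed integer seed fully determines the rendered dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lipid_annot import (
    C13_MASS_SHIFT,
    adduct_mz,
    get_adduct,
    isotope_envelope,
    monoisotopic_mass,
    parse_lipid_shorthand,
)
from .msdata_io import IMSDataset, ROI, Spectrum

__all__ = [
    "REGION_LABELS",
    "ARCHETYPES",
    "ON_TISSUE_ARCHETYPES",
    "ARTEFACT_ARCHETYPES",
    "RegionMasks",
    "Molecule",
    "GroundTruth",
    "NoiseModel",
    "make_region_masks",
    "archetype_templates",
    "make_ground_truth",
    "render_dataset",
    "truth_peak_table",
    "match_mz_to_truth",
    "write_ground_truth",
    "read_ground_truth",
]

REGION_LABELS = (
    "grey_matter",
    "fibre_tract",
    "cerebellar_cortex",
    "brainstem",
    "off_tissue",
)

ON_TISSUE_ARCHETYPES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")
ARTEFACT_ARCHETYPES = ("artefact_homogeneous", "artefact_off_tissue")
ARCHETYPES = ON_TISSUE_ARCHETYPES + ARTEFACT_ARCHETYPES


@dataclass
class RegionMasks:
    """Mutually exclusive per-pixel region labels on a (height, width) grid.

    Every pixel carries exactly one label; ``off_tissue`` is the complement
    of the tissue union.
    """

    masks: dict[str, np.ndarray]
    shape: tuple[int, int]  # (width, height)

    def __post_init__(self) -> None:
        if set(self.masks) != set(REGION_LABELS):
            raise ValueError(f"masks must cover exactly the labels {REGION_LABELS}")
        total = np.zeros(self.masks["off_tissue"].shape, dtype=int)
        for mask in self.masks.values():
            total += mask.astype(int)
        if not np.all(total == 1):
            raise ValueError("region masks must partition the grid (one label per pixel)")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.masks[label]

    @property
    def tissue(self) -> np.ndarray:
        return ~self.masks["off_tissue"]

    def roi(self) -> ROI:
        """The whole-tissue region of interest used for screening."""
        return ROI(self.tissue)


@dataclass(frozen=True)
class Molecule:
    """One planted molecule: lipid species, spatial archetype, adducts and a
    base intensity in arbitrary units."""

    name: str
    archetype: str
    adducts: tuple[str, ...]
    base_intensity: float

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if not self.adducts:
            raise ValueError(f"molecule {self.name} has no adducts")
        if self.base_intensity <= 0:
            raise ValueError("base intensity must be positive")

    @property
    def formula(self) -> str:
        return parse_lipid_shorthand(self.name).formula()


@dataclass
class GroundTruth:
    """Phantom manifest: the planted molecules plus generation metadata."""

    molecules: list[Molecule]
    seed: int
    raster_um: float = 50.0
    mz_range: tuple[float, float] = (700.0, 900.0)
    n_isotopologues: int = 3


@dataclass(frozen=True)
class NoiseModel:
    """Noise plumbing for the renderer.

    baseline
        Intensity scale (a.u.) of spurious peaks (exponentially distributed).
    multiplicative_sigma
        Log-normal sigma applied to every true peak intensity.
    spurious_rate
        Expected spurious peak count per spectrum (Poisson), at uniform
        random m/z across the dataset range.

    All parameters are non-negative; all-zero parameters give noiseless data.
    """

    baseline: float = 5.0
    multiplicative_sigma: float = 0.2
    spurious_rate: float = 5.0

    def __post_init__(self) -> None:
        if min(self.baseline, self.multiplicative_sigma, self.spurious_rate) < 0:
            raise ValueError("noise parameters must be non-negative")


NOISELESS = NoiseModel(baseline=0.0, multiplicative_sigma=0.0, spurious_rate=0.0)


def make_region_masks(width: int, height: int, layout: str = "default") -> RegionMasks:
    """Deterministic brain-like partition of a (width × height) pixel grid.

    The tissue is an ellipse with an off-tissue margin; inside it sit a
    cerebellar disc (posterior-dorsal), a brainstem band (ventral), an
    elliptical fibre-tract annulus, and grey matter as the remainder.
    """
    if layout != "default":
        raise ValueError(f"unknown layout {layout!r}")
    if width < 16 or height < 16:
        raise ValueError("grid too small: need width and height >= 16")
    ys, xs = np.mgrid[0:height, 0:width].astype(float)
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    a, b = 0.44 * width, 0.42 * height
    r_ell = np.sqrt(((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2)
    tissue = r_ell <= 1.0

    cb_cx, cb_cy = 0.78 * (width - 1), 0.32 * (height - 1)
    cb_r = 0.10 * min(width, height)
    cerebellar = (np.hypot(xs - cb_cx, ys - cb_cy) <= cb_r) & tissue

    brainstem = (ys >= 0.76 * (height - 1)) & tissue & ~cerebellar
    fibre = (r_ell >= 0.45) & (r_ell <= 0.72) & tissue & ~cerebellar & ~brainstem
    grey = tissue & ~cerebellar & ~brainstem & ~fibre
    masks = {
        "grey_matter": grey,
        "fibre_tract": fibre,
        "cerebellar_cortex": cerebellar,
        "brainstem": brainstem,
        "off_tissue": ~tissue,
    }
    for label, mask in masks.items():
        if not mask.any():
            raise ValueError(f"grid too small to place region {label!r}")
    return RegionMasks(masks, (width, height))


def _x_bands(mask: np.ndarray, n_bands: int) -> list[np.ndarray]:
    """Split a region mask into n roughly equal-population vertical bands."""
    ys, xs = np.nonzero(mask)
    edges = np.quantile(xs, np.linspace(0, 1, n_bands + 1)[1:-1]) if n_bands > 1 else []
    band_idx = np.digitize(xs, edges)
    bands = []
    for i in range(n_bands):
        band = np.zeros_like(mask)
        band[ys[band_idx == i], xs[band_idx == i]] = True
        bands.append(band)
    return bands


def archetype_templates(
    masks: RegionMasks, gradient: float = 0.2
) -> dict[str, np.ndarray]:
    """Spatial intensity template (values in [0, ~1.1]) per archetype.

    Binary sub-zone indicators modulated by a smooth left-to-right gradient
    of amplitude ``gradient`` (default 20%). Archetypes I, II, VII, IX are
    grey-matter bands; IV, V, VIII fibre-tract bands; III the cerebellar
    cortex; X the brainstem; VI is homogeneous over the whole tissue
    section (the "uniform throughout the brain" molecule class).
    ``artefact_homogeneous`` covers the whole slide (tissue *and* margin);
    ``artefact_off_tissue`` only the margin.

    All supports except VI (and the artefacts) are pairwise disjoint; VI
    nests the others, but its raw-image cosine against any sub-zone
    archetype is √(zone/tissue pixel fraction) < 0.5, so groups stay
    separable at the standard similarity threshold.
    """
    height, width = masks["off_tissue"].shape
    xs = np.tile(np.arange(width, dtype=float), (height, 1))
    ramp = 1.0 - gradient / 2.0 + gradient * xs / max(width - 1, 1)

    grey_bands = _x_bands(masks["grey_matter"], 4)
    fibre_bands = _x_bands(masks["fibre_tract"], 3)
    supports = {
        "I": grey_bands[0],
        "II": grey_bands[1],
        "VII": grey_bands[2],
        "IX": grey_bands[3],
        "III": masks["cerebellar_cortex"],
        "IV": fibre_bands[0],
        "V": fibre_bands[1],
        "VIII": fibre_bands[2],
        "VI": masks.tissue,
        "X": masks["brainstem"],
        "artefact_homogeneous": np.ones_like(masks["off_tissue"]),
        "artefact_off_tissue": masks["off_tissue"],
    }
    for archetype, support in supports.items():
        if not support.any():
            raise ValueError(f"grid too small for archetype {archetype!r} support")
    return {k: support * ramp for k, support in supports.items()}


def make_ground_truth(
    n_molecules: int,
    archetype_weights: Mapping[str, float] | Sequence[float] | None,
    formula_table: pd.DataFrame,
    seed: int,
    mz_range: tuple[float, float] = (700.0, 900.0),
    raster_um: float = 50.0,
    n_isotopologues: int = 3,
    base_intensity_range: tuple[float, float] = (200.0, 2000.0),
) -> GroundTruth:
    """Draw a reproducible molecule manifest.

    Each molecule gets a distinct lipid species from ``formula_table``
    (restricted to species with at least one adduct ion inside ``mz_range``),
    an archetype drawn from ``archetype_weights`` (uniform over all twelve
    when None), 1–2 admissible adducts and a log-uniform base intensity.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if formula_table is None or len(formula_table) == 0:
        raise ValueError("empty formula table")
    if archetype_weights is None:
        archetypes = list(ARCHETYPES)
        weights = np.full(len(archetypes), 1.0 / len(archetypes))
    elif isinstance(archetype_weights, Mapping):
        archetypes = list(archetype_weights)
        weights = np.array([archetype_weights[a] for a in archetypes], dtype=float)
    else:
        weights = np.asarray(archetype_weights, dtype=float)
        archetypes = list(ARCHETYPES[: len(weights)])
    unknown = set(archetypes) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes {sorted(unknown)}")
    if weights.min() < 0 or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("archetype weights must be non-negative and sum to 1")

    lo, hi = mz_range
    span = (n_isotopologues - 1) * C13_MASS_SHIFT
    admissible: list[tuple[str, list[str]]] = []
    for name in formula_table["name"]:
        mass = monoisotopic_mass(parse_lipid_shorthand(name))
        ok = [
            alias
            for alias in ("H", "NH4", "Na", "K")
            if lo <= adduct_mz(mass, alias) and adduct_mz(mass, alias) + span <= hi
        ]
        if ok:
            admissible.append((name, ok))
    if len(admissible) < n_molecules:
        raise ValueError(
            f"formula table supplies only {len(admissible)} species with adduct "
            f"ions inside m/z {mz_range}; {n_molecules} requested"
        )

    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(admissible), size=n_molecules, replace=False)
    drawn_archetypes = rng.choice(len(archetypes), size=n_molecules, p=weights)
    log_lo, log_hi = np.log(base_intensity_range)
    intensities = np.exp(rng.uniform(log_lo, log_hi, size=n_molecules))
    molecules = []
    for i, pick in enumerate(chosen):
        name, ok_adducts = admissible[pick]
        n_adducts = int(rng.integers(1, min(2, len(ok_adducts)) + 1))
        adduct_pick = rng.choice(len(ok_adducts), size=n_adducts, replace=False)
        adducts = tuple(get_adduct(ok_adducts[j]).name for j in sorted(adduct_pick))
        molecules.append(
            Molecule(name, archetypes[drawn_archetypes[i]], adducts, float(intensities[i]))
        )
    return GroundTruth(
        molecules,
        seed=seed,
        raster_um=raster_um,
        mz_range=mz_range,
        n_isotopologues=n_isotopologues,
    )


def truth_peak_table(truth: GroundTruth) -> pd.DataFrame:
    """Every theoretical peak the phantom plants: one row per
    (molecule, adduct, isotopologue) with its m/z and envelope fraction
    (relative to the base peak, base = 1)."""
    rows = []
    for mol in truth.molecules:
        comp = parse_lipid_shorthand(mol.name)
        env = isotope_envelope(comp, "carbon", truth.n_isotopologues)
        mass = monoisotopic_mass(comp)
        for adduct in mol.adducts:
            base = adduct_mz(mass, adduct)
            for k, rel in enumerate(env.relative_intensity):
                rows.append(
                    {
                        "molecule": mol.name,
                        "archetype": mol.archetype,
                        "adduct": adduct,
                        "isotopologue": k,
                        "mz": base + k * C13_MASS_SHIFT,
                        "fraction": rel / 100.0,
                        "base_intensity": mol.base_intensity,
                    }
                )
    columns = [
        "molecule", "archetype", "adduct", "isotopologue", "mz", "fraction",
        "base_intensity",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows).sort_values("mz", ignore_index=True)


def match_mz_to_truth(
    mz_values: Sequence[float], truth: GroundTruth, tol: float = 0.005
) -> pd.DataFrame:
    """Match m/z values to the nearest planted theoretical peak within
    ``tol`` Da. Returns a frame aligned with the input (NaN/None where
    unmatched)."""
    peaks = truth_peak_table(truth)
    theo = peaks["mz"].to_numpy()
    out = []
    for mz in mz_values:
        idx = np.searchsorted(theo, mz)
        best, best_err = None, tol
        for j in (idx - 1, idx):
            if 0 <= j < len(theo) and abs(theo[j] - mz) <= best_err:
                best, best_err = j, abs(theo[j] - mz)
        if best is None:
            out.append({"mz": mz, "molecule": None, "archetype": None, "isotopologue": -1})
        else:
            row = peaks.iloc[best]
            out.append(
                {
                    "mz": mz,
                    "molecule": row["molecule"],
                    "archetype": row["archetype"],
                    "isotopologue": int(row["isotopologue"]),
                }
            )
    return pd.DataFrame(out)


def render_dataset(
    truth: GroundTruth,
    masks: RegionMasks,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
    gradient: float = 0.2,
) -> IMSDataset:
    """Render a phantom manifest to a centroided :class:`IMSDataset`.

    At every pixel each molecule contributes one peak per isotopologue per
    adduct with intensity ``base × template(pixel) × envelope fraction``,
    multiplied by log-normal noise; spurious peaks are added at Poisson rate
    per spectrum, uniform in m/z. ``seed`` defaults to the manifest's seed.
    """
    templates = archetype_templates(masks, gradient=gradient)
    peaks = truth_peak_table(truth)
    lo, hi = truth.mz_range
    bad = peaks[(peaks["mz"] < lo) | (peaks["mz"] > hi)]
    if len(bad):
        raise ValueError(
            f"molecule {bad.iloc[0]['molecule']} has a peak at m/z "
            f"{bad.iloc[0]['mz']:.4f} outside the range {truth.mz_range}"
        )
    peak_mz = peaks["mz"].to_numpy()
    peak_base = (peaks["base_intensity"] * peaks["fraction"]).to_numpy() if len(peaks) else np.empty(0)
    # per-peak spatial template, stacked (n_peaks, height, width)
    height_, width_ = masks["off_tissue"].shape
    peak_template = (
        np.stack([templates[a] for a in peaks["archetype"]])
        if len(peaks)
        else np.empty((0, height_, width_))
    )

    rng = np.random.default_rng(truth.seed if seed is None else seed)
    width, height = masks.shape
    spectra = []
    for y in range(height):
        for x in range(width):
            amp = peak_base * peak_template[:, y, x]
            live = amp > 0
            mz = peak_mz[live]
            inten = amp[live]
            if noise.multiplicative_sigma > 0 and inten.size:
                inten = inten * rng.lognormal(0.0, noise.multiplicative_sigma, inten.size)
            if noise.spurious_rate > 0:
                n_spur = rng.poisson(noise.spurious_rate)
                if n_spur:
                    mz = np.concatenate([mz, rng.uniform(lo, hi, n_spur)])
                    inten = np.concatenate(
                        [inten, rng.exponential(max(noise.baseline, 1e-12), n_spur)]
                    )
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
            # merge exact m/z collisions to keep spectra strictly ascending
            if mz.size > 1 and np.any(np.diff(mz) == 0):
                uniq, idx = np.unique(mz, return_inverse=True)
                summed = np.zeros_like(uniq)
                np.add.at(summed, idx, inten)
                mz, inten = uniq, summed
            spectra.append(Spectrum(mz, inten, (x, y)))
    return IMSDataset(
        spectra, masks.shape, raster_um=truth.raster_um, mz_range=truth.mz_range
    )


def write_ground_truth(truth: GroundTruth, path) -> Path:
    """Write the manifest as TSV (name, formula, archetype, adducts,
    base_intensity) with generation metadata in '#' header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# seed={truth.seed}\traster_um={truth.raster_um}\t")
        fh.write(f"mz_range={truth.mz_range[0]},{truth.mz_range[1]}\t")
        fh.write(f"n_isotopologues={truth.n_isotopologues}\n")
        fh.write("name\tformula\tarchetype\tadducts\tbase_intensity\n")
        for mol in truth.molecules:
            fh.write(
                f"{mol.name}\t{mol.formula}\t{mol.archetype}\t"
                f"{','.join(mol.adducts)}\t{mol.base_intensity:.6g}\n"
            )
    return path


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("manifest missing metadata header")
        meta = dict(item.split("=", 1) for item in header[1:].split())
        table = pd.read_csv(fh, sep="\t")
    lo, hi = (float(v) for v in meta["mz_range"].split(","))
    molecules = [
        Molecule(
            row["name"],
            row["archetype"],
            tuple(row["adducts"].split(",")),
            float(row["base_intensity"]),
        )
        for _, row in table.iterrows()
    ]
    return GroundTruth(
        molecules,
        seed=int(meta["seed"]),
        raster_um=float(meta["raster_um"]),
        mz_range=(lo, hi),
        n_isotopologues=int(meta["n_isotopologues"]),
    )
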