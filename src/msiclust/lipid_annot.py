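"""Phospholipid annotation: shorthand parsing, monoisotopic masses, isotope
envelopes, adduct m/z, ppm matching and isotopologue-series detection.

The module reproduces the arithmetic used to assign high-mass-accuracy
positive-mode MALDI-FT-ICR ions to glycerophospholipid species: a lipid
shorthand such as ``PS(39:0)`` is expanded to an elemental composition, its
monoisotopic mass and ¹³C isotopologue masses are computed, adduct ions
([M+H]⁺, [M+NH4]⁺, [M+Na]⁺, [M+K]⁺) are formed, and observed m/z values are
matched within a ppm tolerance.

Two conventions are provided throughout:

``neutral``/``carbon``
    Adduct m/z adds the neutral-atom masses with no electron correction, and
    isotope envelopes use a carbon-only binomial model with a fixed
    1.0034 Da isotopologue spacing. This is the arithmetic convention of the
    published assignment tables this package reproduces.
``standard``/``full``
    Electron-corrected adduct masses and a full multi-element isotope
    convolution, for users who want the physically complete numbers.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ElementalComposition",
    "IsotopeEnvelope",
    "AdductSpec",
    "Assignment",
    "ADDUCTS",
    "get_adduct",
    "MONOISOTOPIC_MASS",
    "C13_MASS_SHIFT",
    "NOMINAL_ISOTOPE_SPACING",
    "parse_lipid_shorthand",
    "monoisotopic_mass",
    "adduct_mz",
    "isotope_envelope",
    "ppm_error",
    "detect_isotopologue_series",
    "assign_candidates",
    "match_envelope",
    "round_half_away",
    "load_lipid_library",
    "default_lipid_library",
    "cerebellar_assignment_table",
]

# Monoisotopic atomic masses, Da (CODATA/AME2020, truncated well below 1e-6).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

ELECTRON_MASS = 0.00054857990

#: Exact ¹³C − ¹²C mass difference, Da.
C13_MASS_SHIFT = 13.0033548378 - 12.0
#: Rounded isotopologue spacing used in carbon-mode envelopes and series detection.
NOMINAL_ISOTOPE_SPACING = 1.0034

#: Natural isotope tables: element -> list of (mass shift vs lightest in
#: integer nucleons, exact mass, abundance). Abundances are IUPAC
#: representative values.
_ISOTOPES: dict[str, list[tuple[int, float, float]]] = {
    "H": [(0, 1.00782503207, 0.999885), (1, 2.01410177785, 0.000115)],
    "C": [(0, 12.0, 0.9893), (1, 13.0033548378, 0.0107)],
    "N": [(0, 14.0030740048, 0.99636), (1, 15.0001088989, 0.00364)],
    "O": [
        (0, 15.9949146196, 0.99757),
        (1, 16.9991317012, 0.00038),
        (2, 17.9991596129, 0.00205),
    ],
    "P": [(0, 30.97376163, 1.0)],
    "S": [
        (0, 31.97207100, 0.9499),
        (1, 32.97145876, 0.0075),
        (2, 33.96786690, 0.0425),
        (4, 35.96708076, 0.0001),
    ],
    "Na": [(0, 22.9897692809, 1.0)],
    "K": [
        (0, 38.96370668, 0.932581),
        (1, 39.96399848, 0.000117),
        (2, 40.96182576, 0.067302),
    ],
}

_SUPPORTED_ELEMENTS = tuple(MONOISOTOPIC_MASS)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed report tables),
    unlike Python's banker's rounding."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ElementalComposition:
    """Integer atom counts per element (C, H, N, O, P, S, Na, K supported)."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, n in self.counts.items():
            if element not in _SUPPORTED_ELEMENTS:
                raise ValueError(
                    f"unsupported element {element!r}; supported: "
                    f"{', '.join(_SUPPORTED_ELEMENTS)}"
                )
            if n != int(n) or n < 0:
                raise ValueError(f"atom count for {element} must be a non-negative integer")
            if n > 0:
                clean[element] = int(n)
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return ElementalComposition(merged)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def formula(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        order = ["C", "H"] + sorted(set(self.counts) - {"C", "H"})
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] != 1 else ''}"
            for el in order
            if el in self.counts
        )

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        counts: dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"malformed formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula) or not counts:
            raise ValueError(f"malformed formula {formula!r}")
        return cls(counts)


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Isotopologue list: m/z ascending with relative intensities, base = 100."""

    mz: tuple[float, ...]
    relative_intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.relative_intensity):
            raise ValueError("mz and intensity lengths differ")
        if len(self.mz) == 0:
            raise ValueError("empty envelope")
        if any(b <= a for a, b in zip(self.mz, self.mz[1:])):
            raise ValueError("envelope m/z must be strictly ascending")
        if abs(max(self.relative_intensity) - 100.0) > 1e-9:
            raise ValueError("base peak must have relative intensity 100")
        if any(not 0 < i <= 100 for i in self.relative_intensity):
            raise ValueError("relative intensities must lie in (0, 100]")

    def fractions(self) -> np.ndarray:
        """Intensities normalised to sum 1 (per-isotopologue signal fractions)."""
        arr = np.asarray(self.relative_intensity, dtype=float)
        return arr / arr.sum()

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class AdductSpec:
    """A positive-mode adduct: name plus the composition of the added atoms."""

    name: str
    added: ElementalComposition

    def mass_shift(self, convention: str = "neutral") -> float:
        shift = monoisotopic_mass(self.added)
        if convention == "standard":
            shift -= ELECTRON_MASS
        elif convention != "neutral":
            raise ValueError(f"unknown adduct convention {convention!r}")
        return shift


ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", ElementalComposition({"H": 1})),
    "[M+NH4]+": AdductSpec("[M+NH4]+", ElementalComposition({"N": 1, "H": 4})),
    "[M+Na]+": AdductSpec("[M+Na]+", ElementalComposition({"Na": 1})),
    "[M+K]+": AdductSpec("[M+K]+", ElementalComposition({"K": 1})),
}

_ADDUCT_ALIASES = {
    "H": "[M+H]+",
    "NH4": "[M+NH4]+",
    "Na": "[M+Na]+",
    "K": "[M+K]+",
}


def get_adduct(name: str) -> AdductSpec:
    key = _ADDUCT_ALIASES.get(name, name)
    try:
        return ADDUCTS[key]
    except KeyError:
        raise ValueError(
            f"unknown adduct {name!r}; supported: {', '.join(ADDUCTS)}"
        ) from None


@dataclass(frozen=True)
class Assignment:
    """One candidate identity for an observed ion."""

    observed_mz: float
    molecule: str
    isotopologue: int  # 0 = monoisotopic, 1 = one ¹³C, ...
    adduct: str
    theoretical_mz: float
    delta_ppm: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_ppm):
            raise ValueError("delta_ppm must be finite")
        if self.theoretical_mz <= 0:
            raise ValueError("theoretical m/z must be positive")


# Diacyl glycerophospholipid head-group rules: class -> (dC, dH, dN, dO, dP)
# offsets applied to (carbons, 2*carbons - 2*double_bonds) of the two acyl
# chains plus glycerophosphate backbone. Written as full formulas:
#   PX(c:d) = C(c+a) H(2c+b-2d) N(n) O(o) P
_HEADGROUPS: dict[str, tuple[int, int, int, int]] = {
    # class: (carbon offset a, hydrogen offset b, nitrogens, oxygens)
    "PA": (3, 5, 0, 8),
    "PC": (8, 16, 1, 8),
    "PE": (5, 10, 1, 8),
    "PG": (6, 11, 0, 10),
    "PS": (6, 10, 1, 10),
    "PI": (9, 15, 0, 13),
}

_SHORTHAND_RE = re.compile(r"^\s*([A-Za-z]+)\((\d+):(\d+)\)\s*$")


def parse_lipid_shorthand(name: str) -> ElementalComposition:
    """Expand diacyl lipid shorthand ``CLASS(carbons:double_bonds)`` to an
    elemental composition.

    Supported classes: PA, PC, PE, PG, PS, PI (diacyl species only). The
    carbon count is the total over both acyl chains.

    >>> parse_lipid_shorthand("PS(39:0)").formula()
    'C45H88NO10P'
    """
    m = _SHORTHAND_RE.match(name)
    if m is None:
        raise ValueError(
            f"malformed lipid shorthand {name!r}; expected CLASS(carbons:doublebonds)"
        )
    cls, carbons, dbonds = m.group(1).upper(), int(m.group(2)), int(m.group(3))
    if cls not in _HEADGROUPS:
        raise ValueError(
            f"unknown lipid class {cls!r}; supported classes: "
            f"{', '.join(sorted(_HEADGROUPS))}"
        )
    a, b, n_nitrogen, n_oxygen = _HEADGROUPS[cls]
    n_hydrogen = 2 * carbons + b - 2 * dbonds
    if n_hydrogen <= 0:
        raise ValueError(f"{name}: double-bond count too large for carbon count")
    counts = {"C": carbons + a, "H": n_hydrogen, "O": n_oxygen, "P": 1}
    if n_nitrogen:
        counts["N"] = n_nitrogen
    return ElementalComposition(counts)


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Sum of atom counts times monoisotopic atomic masses, Da.

    The empty composition has mass 0 by convention.
    """
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in composition.counts.items())


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str, convention: str = "neutral") -> float:
    """m/z of the singly charged adduct ion of a neutral molecule.

    The ``neutral`` convention adds the neutral-atom masses of the adduct with
    no electron correction; ``standard`` subtracts one electron mass.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return neutral_mass + adduct.mass_shift(convention)


def _carbon_binomial(n_carbon: int, n_isotopologues: int) -> np.ndarray:
    """Unnormalised carbon-only isotopologue abundances C(n,k) r^k."""
    r = _ISOTOPES["C"][1][2] / _ISOTOPES["C"][0][2]
    ks = np.arange(min(n_isotopologues, n_carbon + 1))
    return np.array([math.comb(n_carbon, int(k)) * r**k for k in ks])


def _full_convolution(composition: ElementalComposition, n_isotopologues: int):
    """Aggregate the exact multi-element isotope distribution to nominal-mass
    (integer nucleon shift) centroids. Returns (centroid masses, probabilities).
    """
    n_max = n_isotopologues
    # per shift bin: total probability and probability-weighted mass
    prob = np.zeros(n_max)
    wmass = np.zeros(n_max)
    prob[0] = 1.0
    for element, count in composition.counts.items():
        isotopes = _ISOTOPES[element]
        base_mass = isotopes[0][1]
        # distribution over shift for `count` atoms of this element
        el_prob = np.zeros(n_max)
        el_wshift = np.zeros(n_max)  # probability-weighted extra mass vs all-light
        el_prob[0] = 1.0
        for _ in range(count):
            new_prob = np.zeros(n_max)
            new_wshift = np.zeros(n_max)
            for shift, mass, abundance in isotopes:
                extra = mass - base_mass
                for s in range(n_max - shift if shift < n_max else 0):
                    p = el_prob[s] * abundance
                    new_prob[s + shift] += p
                    new_wshift[s + shift] += el_wshift[s] * abundance + p * extra
            el_prob, el_wshift = new_prob, new_wshift
        new_prob = np.zeros(n_max)
        new_wmass = np.zeros(n_max)
        for s in range(n_max):
            if el_prob[s] == 0:
                continue
            cond_extra = el_wshift[s] / el_prob[s]
            for t in range(n_max - s):
                p = prob[t] * el_prob[s]
                new_prob[s + t] += p
                new_wmass[s + t] += (wmass[t] + prob[t] * cond_extra) * el_prob[s]
        prob, wmass = new_prob, new_wmass
    mono = monoisotopic_mass(composition)
    keep = prob > 0
    masses = mono + np.where(keep, wmass / np.where(keep, prob, 1.0), 0.0)
    return masses[keep], prob[keep]


def isotope_envelope(
    composition: ElementalComposition,
    mode: str = "carbon",
    n_isotopologues: int = 3,
    charge_carrier_mass: float = 0.0,
) -> IsotopeEnvelope:
    """Theoretical isotope envelope of a molecule (or ion).

    ``carbon`` mode is a carbon-only binomial: the k-th isotopologue carries k
    ¹³C atoms, with relative abundance C(n_C, k)·r^k (r = 0.0107/0.9893)
    normalised to base peak 100, and a fixed 1.0034 Da spacing. ``full`` mode
    convolves the natural isotope distributions of every element and
    aggregates to nominal-mass centroids.

    ``charge_carrier_mass`` is added to every isotopologue m/z (use the adduct
    mass shift to get the envelope of an adduct ion; the adducts supported
    here contribute no carbon, so carbon-mode intensities are unchanged).
    """
    if n_isotopologues < 1:
        raise ValueError("n_isotopologues must be >= 1")
    if composition.n_atoms == 0:
        raise ValueError("composition must contain at least one atom")
    mono = monoisotopic_mass(composition) + charge_carrier_mass
    if mode == "carbon":
        n_carbon = composition["C"]
        if n_carbon == 0:
            import warnings

            warnings.warn(
                "carbon-mode envelope of a carbon-free molecule is a single peak",
                stacklevel=2,
            )
            return IsotopeEnvelope((mono,), (100.0,))
        abund = _carbon_binomial(n_carbon, n_isotopologues)
        mz = tuple(mono + k * NOMINAL_ISOTOPE_SPACING for k in range(len(abund)))
    elif mode == "full":
        masses, prob = _full_convolution(composition, n_isotopologues)
        mz = tuple(m + charge_carrier_mass for m in masses)
        abund = prob
    else:
        raise ValueError(f"unknown envelope mode {mode!r}")
    rel = tuple(100.0 * a / abund.max() for a in abund)
    return IsotopeEnvelope(mz, rel)


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error, parts per million: (obs − theo)/theo × 10⁶."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def detect_isotopologue_series(
    mz_values: Sequence[float],
    delta: float = NOMINAL_ISOTOPE_SPACING,
    tol: float = 0.01,
) -> list[list[float]]:
    """Chain peaks separated by ~`delta` Da into isotopologue series.

    Greedy left-to-right chaining: a peak extends the series ending at m/z x
    if |mz − x − delta| ≤ tol; each peak joins at most one series; maximal
    chains are returned, singletons included as length-1 series.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    mzs = sorted(float(x) for x in mz_values)
    series: list[list[float]] = []
    for mz in mzs:
        for chain in series:
            if abs(mz - chain[-1] - delta) <= tol:
                chain.append(mz)
                break
        else:
            series.append([mz])
    return series


def assign_candidates(
    observed: float,
    library: pd.DataFrame | Iterable[str],
    adducts: Iterable[AdductSpec | str] = ("H", "NH4", "Na", "K"),
    ppm_threshold: float = 10.0,
    convention: str = "neutral",
    n_isotopologues: int = 3,
) -> list[Assignment]:
    """All (molecule, adduct, isotopologue) identities matching an observed
    m/z within a ppm tolerance, sorted by |ppm| (ties by molecule, adduct).

    ``library`` is either a lipid-library table (see :func:`load_lipid_library`)
    or an iterable of shorthand names. Isotopologue theoretical m/z values use
    the exact ¹³C mass shift.
    """
    if isinstance(library, pd.DataFrame):
        names = list(library["name"])
        compositions = [
            ElementalComposition.from_formula(f) if isinstance(f, str) and f else parse_lipid_shorthand(n)
            for n, f in zip(names, library.get("formula", [None] * len(names)))
        ]
    else:
        names = list(library)
        compositions = [parse_lipid_shorthand(n) for n in names]
    if not names:
        raise ValueError("empty molecule library")
    specs = [get_adduct(a) if isinstance(a, str) else a for a in adducts]
    hits: list[Assignment] = []
    for name, comp in zip(names, compositions):
        mass = monoisotopic_mass(comp)
        for spec in specs:
            base = adduct_mz(mass, spec, convention)
            for k in range(n_isotopologues):
                theo = base + k * C13_MASS_SHIFT
                delta = ppm_error(observed, theo)
                if abs(delta) <= ppm_threshold:
                    hits.append(Assignment(observed, name, k, spec.name, theo, delta))
    hits.sort(key=lambda a: (abs(a.delta_ppm), a.molecule, a.adduct, a.isotopologue))
    return hits


def match_envelope(
    observed_intensities: Sequence[float], envelope: IsotopeEnvelope
) -> float:
    """Cosine similarity between observed and theoretical relative-intensity
    vectors, truncated to the common isotopologue count. Result in [0, 1]."""
    obs = np.asarray(list(observed_intensities), dtype=float)
    if obs.size == 0:
        raise ValueError("empty observed intensity vector")
    theo = np.asarray(envelope.relative_intensity, dtype=float)
    n = min(obs.size, theo.size)
    obs, theo = obs[:n], theo[:n]
    norm = np.linalg.norm(obs)
    if norm == 0:
        raise ValueError("observed intensity vector is all zero")
    return float(obs @ theo / (norm * np.linalg.norm(theo)))


# ---------------------------------------------------------------------------
# Bundled formula library (local stand-in for a metabolome-database query)

def load_lipid_library(path) -> pd.DataFrame:
    """Read a lipid formula table (TSV: name, class, carbons, double_bonds,
    formula) and validate each row's formula against its shorthand."""
    table = pd.read_csv(path, sep="\t", dtype={"name": str, "formula": str})
    required = {"name", "class", "carbons", "double_bonds", "formula"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"lipid library missing columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("empty lipid library")
    for name, formula in zip(table["name"], table["formula"]):
        if parse_lipid_shorthand(name).formula() != formula:
            raise ValueError(f"library formula mismatch for {name}: {formula}")
    return table


def default_lipid_library() -> pd.DataFrame:
    """The bundled diacyl glycerophospholipid library (all supported classes,
    total acyl carbons 30–44, 0–6 double bonds)."""
    from importlib import resources

    with resources.as_file(
        resources.files("msiclust").joinpath("data/lipid_library.tsv")
    ) as path:
        return load_lipid_library(path)


# ---------------------------------------------------------------------------
# End-to-end reproduction of the cerebellar-cortex assignment table

#: Observed cerebellar-cortex ions (m/z printed to 3 decimals) with their
#: estimated molecule, isotopologue index and adduct. These observed values
#: and identities are measurement inputs; every other column is computed.
CEREBELLAR_OBSERVED: tuple[tuple[float, str, int, str], ...] = (
    (834.614, "PS(39:0)", 0, "[M+H]+"),
    (835.617, "PS(39:0)", 1, "[M+H]+"),
    (856.597, "PI(34:0)", 0, "[M+NH4]+"),
    (857.600, "PI(34:0)", 1, "[M+NH4]+"),
    (872.573, "PS(39:0)", 0, "[M+K]+"),
    (873.577, "PS(39:0)", 1, "[M+K]+"),
    (874.576, "PS(39:0)", 2, "[M+K]+"),
)


def cerebellar_assignment_table(
    observed: Sequence[tuple[float, str, int, str]] = CEREBELLAR_OBSERVED,
) -> pd.DataFrame:
    """Regenerate the cerebellar-cortex ion assignment table from lipid names
    and observed m/z alone.

    Theoretical masses are rounded to the 4 decimals of the printed report
    before the ppm computation, matching the printed delta values; ppm deltas
    are rounded half away from zero to 2 decimals.
    """
    rows = []
    for obs_mz, molecule, k, adduct in observed:
        mono = monoisotopic_mass(parse_lipid_shorthand(molecule))
        neutral = round_half_away(mono + k * C13_MASS_SHIFT, 4)
        theo = round_half_away(mono + k * C13_MASS_SHIFT + get_adduct(adduct).mass_shift("neutral"), 4)
        rows.append(
            {
                "observed_mz": obs_mz,
                "molecule": molecule + (" isotopic" if k else ""),
                "theoretical_mass": neutral,
                "adduct": adduct,
                "adduct_mz": theo,
                "delta_ppm": round_half_away(ppm_error(obs_mz, theo), 2),
            }
        )
    return pd.DataFrame(rows)
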