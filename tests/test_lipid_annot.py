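"""Chemistry layer: shorthand parsing, masses, envelopes, adducts, ppm
matching and isotopologue-series detection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msiclust.lipid_annot import (
    C13_MASS_SHIFT,
    NOMINAL_ISOTOPE_SPACING,
    ElementalComposition,
    IsotopeEnvelope,
    adduct_mz,
    assign_candidates,
    cerebellar_assignment_table,
    detect_isotopologue_series,
    get_adduct,
    isotope_envelope,
    match_envelope,
    monoisotopic_mass,
    parse_lipid_shorthand,
    ppm_error,
    round_half_away,
)
from msiclust.lipid_annot import _ISOTOPES


@pytest.mark.parametrize(
    "name, formula",
    [
        ("PS(39:0)", "C45H88NO10P"),
        ("PI(34:0)", "C43H83O13P"),
        ("PS(36:0)", "C42H82NO10P"),
        ("PC(34:1)", "C42H82NO8P"),
        ("PE(36:2)", "C41H78NO8P"),
        ("PG(34:0)", "C40H79O10P"),
        ("PA(34:0)", "C37H73O8P"),
    ],
)
def test_shorthand_expands_to_known_formula(name, formula):
    assert parse_lipid_shorthand(name).formula() == formula


@pytest.mark.parametrize("bad", ["XX(34:0)", "PS34:0", "PS(34)", "PS(a:b)", ""])
def test_malformed_or_unknown_shorthand_rejected(bad):
    with pytest.raises(ValueError):
        parse_lipid_shorthand(bad)


@pytest.mark.parametrize(
    "name, mass",
    [("PS(39:0)", 833.6146), ("PI(34:0)", 838.5571)],
)
def test_monoisotopic_mass_of_assigned_species(name, mass):
    assert round_half_away(monoisotopic_mass(parse_lipid_shorthand(name)), 4) == mass


def test_empty_composition_has_zero_mass():
    assert monoisotopic_mass(ElementalComposition({})) == 0.0


def test_ch2_homology_across_all_classes():
    """Adding one acyl carbon adds exactly one CH2 (14.01565 Da)."""
    for cls in ("PA", "PC", "PE", "PG", "PS", "PI"):
        for c, d in [(34, 0), (36, 2), (40, 6)]:
            lighter = monoisotopic_mass(parse_lipid_shorthand(f"{cls}({c}:{d})"))
            heavier = monoisotopic_mass(parse_lipid_shorthand(f"{cls}({c + 1}:{d})"))
            assert heavier - lighter == pytest.approx(14.01565, abs=1e-6)


@pytest.mark.parametrize(
    "mass, adduct, expected",
    [
        (833.6146, "[M+H]+", 834.6224),
        (838.5571, "[M+NH4]+", 856.5915),
        (833.6146, "[M+K]+", 872.5783),
    ],
)
def test_adduct_mz_matches_reported_values(mass, adduct, expected):
    assert round_half_away(adduct_mz(mass, adduct), 4) == expected


def test_standard_convention_subtracts_electron_mass():
    delta = adduct_mz(800.0, "[M+H]+", "neutral") - adduct_mz(800.0, "[M+H]+", "standard")
    assert delta == pytest.approx(0.00054858, abs=1e-8)


def test_unknown_adduct_rejected():
    with pytest.raises(ValueError, match="adduct"):
        get_adduct("[M+Cs]+")


class TestIsotopeEnvelope:
    def test_reported_envelopes_after_rounding(self):
        ps = isotope_envelope(
            parse_lipid_shorthand("PS(39:0)"), "carbon", 3,
            charge_carrier_mass=get_adduct("H").mass_shift(),
        )
        assert [round_half_away(i) for i in ps.relative_intensity] == [100, 49, 12]
        pi = isotope_envelope(
            parse_lipid_shorthand("PI(34:0)"), "carbon", 3,
            charge_carrier_mass=get_adduct("NH4").mass_shift(),
        )
        assert [round_half_away(i) for i in pi.relative_intensity] == [100, 47, 11]

    def test_carbon_mode_spacing_is_fixed(self):
        env = isotope_envelope(parse_lipid_shorthand("PS(39:0)"), "carbon", 4)
        assert np.allclose(np.diff(env.mz), NOMINAL_ISOTOPE_SPACING)

    def test_base_peak_is_100_and_carbon_mode_decreasing(self):
        env = isotope_envelope(parse_lipid_shorthand("PC(34:1)"), "carbon", 5)
        assert env.relative_intensity[0] == 100.0
        assert all(
            a > b for a, b in itertools.pairwise(env.relative_intensity)
        )

    def test_carbon_free_molecule_warns_and_gives_single_peak(self):
        with pytest.warns(UserWarning):
            env = isotope_envelope(ElementalComposition({"H": 3, "P": 1}), "carbon", 3)
        assert len(env) == 1

    @pytest.mark.parametrize(
        "counts", [{"C": 1, "H": 4}, {"K": 1, "S": 1}, {"C": 2, "O": 2, "H": 2}]
    )
    def test_full_mode_matches_exhaustive_enumeration(self, counts):
        """Oracle: enumerate every isotope placement for <=6-atom molecules."""
        n = 4
        atoms = [el for el, c in counts.items() for _ in range(c)]
        bins: dict[int, tuple[float, float]] = {}
        for combo in itertools.product(*[_ISOTOPES[a] for a in atoms]):
            shift = sum(c[0] for c in combo)
            mass = sum(c[1] for c in combo)
            p = math.prod(c[2] for c in combo)
            if shift < n:
                wm, q = bins.get(shift, (0.0, 0.0))
                bins[shift] = (wm + p * mass, q + p)
        expected = sorted((s, wm / q, q) for s, (wm, q) in bins.items())
        env = isotope_envelope(ElementalComposition(counts), "full", n)
        probs = np.array([q for _, _, q in expected])
        rel = 100 * probs / probs.max()
        assert len(env) == len(expected)
        for (mz, ri), (_s, m, _q), r in zip(
            zip(env.mz, env.relative_intensity), expected, rel
        ):
            assert mz == pytest.approx(m, abs=1e-10)
            assert ri == pytest.approx(r, abs=1e-8)

    def test_envelope_invariants_enforced(self):
        with pytest.raises(ValueError):
            IsotopeEnvelope((800.0, 799.0), (100.0, 50.0))
        with pytest.raises(ValueError):
            IsotopeEnvelope((800.0, 801.0), (90.0, 50.0))


@pytest.mark.parametrize(
    "observed, theoretical, expected",
    [(834.614, 834.6224, -10.06), (856.597, 856.5915, 6.42)],
)
def test_ppm_error_matches_reported_deltas(observed, theoretical, expected):
    assert round_half_away(ppm_error(observed, theoretical), 2) == expected


def test_ppm_error_sign_and_zero():
    assert ppm_error(700.0, 700.0) == 0.0
    assert ppm_error(700.01, 700.0) > 0 > ppm_error(699.99, 700.0)
    # antisymmetric to first order
    assert ppm_error(700.01, 700.0) == pytest.approx(
        -ppm_error(700.0, 700.01), rel=1e-4
    )


class TestSeriesDetection:
    def test_observed_pairs_and_triples_chain(self):
        assert detect_isotopologue_series([834.614, 835.617]) == [[834.614, 835.617]]
        assert detect_isotopologue_series([872.573, 873.577, 874.576]) == [
            [872.573, 873.577, 874.576]
        ]

    def test_distant_peaks_stay_singletons(self):
        assert detect_isotopologue_series([700.0, 705.0]) == [[700.0], [705.0]]

    def test_tolerance_must_be_positive(self):
        with pytest.raises(ValueError):
            detect_isotopologue_series([700.0], tol=0.0)


class TestAssignment:
    def test_single_molecule_ammonium_hit(self):
        hits = assign_candidates(856.597, ["PI(34:0)"])
        assert hits and hits[0].adduct == "[M+NH4]+" and hits[0].isotopologue == 0
        assert round_half_away(hits[0].delta_ppm, 2) == 6.42

    def test_exact_match_gives_zero_ppm(self):
        theo = adduct_mz(monoisotopic_mass(parse_lipid_shorthand("PS(39:0)")), "H")
        hits = assign_candidates(theo, ["PS(39:0)"])
        assert hits[0].delta_ppm == 0.0

    def test_far_mass_gives_empty_list(self):
        assert assign_candidates(700.0, ["PS(39:0)"]) == []

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            assign_candidates(800.0, [])

    def test_results_sorted_by_absolute_ppm(self, library):
        hits = assign_candidates(834.614, library, ppm_threshold=10)
        ppms = [abs(h.delta_ppm) for h in hits]
        assert ppms == sorted(ppms)


class TestEnvelopeFit:
    def test_identical_vectors_fit_perfectly(self):
        env = IsotopeEnvelope((834.62, 835.63, 836.63), (100.0, 49.0, 12.0))
        assert match_envelope([100, 49, 12], env) == pytest.approx(1.0)

    def test_truncated_fit_equals_hand_cosine(self):
        env = isotope_envelope(
            parse_lipid_shorthand("PS(39:0)"), "carbon", 2,
            charge_carrier_mass=get_adduct("H").mass_shift(),
        )
        obs = np.array([100.0, 40.0])
        theo = np.array(env.relative_intensity)
        expected = obs @ theo / (np.linalg.norm(obs) * np.linalg.norm(theo))
        assert match_envelope(obs, env) == pytest.approx(expected, abs=1e-12)

    def test_reversed_vector_scores_lower(self):
        env = IsotopeEnvelope((834.62, 835.63, 836.63), (100.0, 49.0, 12.0))
        assert match_envelope([12, 49, 100], env) < match_envelope([100, 49, 12], env)

    def test_zero_vector_rejected(self):
        env = IsotopeEnvelope((834.62,), (100.0,))
        with pytest.raises(ValueError):
            match_envelope([0.0], env)


# Printed assignment table, frozen: observed m/z, neutral mass, adduct m/z,
# delta ppm for the seven cerebellar-cortex ions.
_EXPECTED_TABLE = [
    (834.614, 833.6146, 834.6224, -10.06),
    (835.617, 834.6179, 835.6258, -10.53),
    (856.597, 838.5571, 856.5915, 6.42),
    (857.600, 839.5605, 857.5949, 5.95),
    (872.573, 833.6146, 872.5783, -6.07),
    (873.577, 834.6179, 873.5816, -5.27),
    (874.576, 835.6213, 874.5850, -10.29),
]


def test_cerebellar_assignment_table_round_trip():
    """Names plus observed m/z regenerate every numeric column of the
    published assignment table after printed-decimal rounding."""
    table = cerebellar_assignment_table()
    assert len(table) == len(_EXPECTED_TABLE)
    for row, (obs, mass, mz, ppm) in zip(table.itertuples(), _EXPECTED_TABLE):
        assert row.observed_mz == obs
        assert row.theoretical_mass == pytest.approx(mass, abs=5e-5)
        assert row.adduct_mz == pytest.approx(mz, abs=5e-5)
        assert row.delta_ppm == pytest.approx(ppm, abs=5e-3)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    c=st.integers(30, 44),
    d=st.integers(0, 6),
    cls=st.sampled_from(["PA", "PC", "PE", "PG", "PS", "PI"]),
)
def test_double_bond_removes_h2(cls, c, d):
    """Each double bond removes exactly H2 from the formula."""
    base = parse_lipid_shorthand(f"{cls}({c}:0)")
    unsat = parse_lipid_shorthand(f"{cls}({c}:{d})")
    assert base["H"] - unsat["H"] == 2 * d
    assert base["C"] == unsat["C"] and base["O"] == unsat["O"]
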