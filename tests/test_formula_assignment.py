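"""Formula assignment: mass arithmetic, enumeration vs brute force, disambiguation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from domphoto.core_io import Peak, PeakList
from domphoto.formula_assignment import (
    MASS_H,
    MASS_N,
    MASS_O,
    MASS_PROTON,
    MASS_S,
    FilterRules,
    MolecularFormula,
    assign_peaklist,
    disambiguate,
    enumerate_candidates,
    filter_candidates,
    formula_mass,
    neutral_mass_from_mz,
    replicate_consistency_filter,
)
from domphoto.synthetic_data import synthesize_lake_pair


def brute_force_candidates(neutral_mass: float, tol_ppm: float) -> set[tuple]:
    """Independent oracle: explicit loop over every atom count including H.

    No mass-balance solve: hydrogen is enumerated exhaustively, so this
    shares no shortcut with the implementation under test.
    """
    out = set()
    tol = tol_ppm * 1e-6 * neutral_mass
    for n in (0, 1):
        for s in (0, 1):
            for o in range(0, int(neutral_mass / 15.994) + 1):
                for c in range(1, int(neutral_mass / 12.0) + 1):
                    h = np.arange(0, int(neutral_mass / MASS_H) + 2)
                    mass = 12.0 * c + MASS_H * h + MASS_O * o + MASS_N * n + MASS_S * s
                    for hi in h[np.abs(mass - neutral_mass) <= tol]:
                        out.add((c, int(hi), o, n, s))
    return out


class TestNeutralMass:
    def test_conversion_is_mz_plus_proton(self):
        assert neutral_mass_from_mz(255.2329554) == pytest.approx(
            255.2329554 + MASS_PROTON, abs=1e-12
        )
        assert neutral_mass_from_mz(1.00727647) == pytest.approx(2.01455294, abs=1e-7)

    def test_exact_ion_mass_of_palmitic_acid(self):
        # C16H32O2 ion [M-H]-: 16*12 + 32*MASS_H + 2*MASS_O - proton
        ion = formula_mass(16, 32, 2, 0, 0) - MASS_PROTON
        assert ion == pytest.approx(255.23295380, abs=1e-6)
        assert neutral_mass_from_mz(ion) == pytest.approx(256.24023027, abs=1e-6)

    def test_gallic_acid_neutral_mass(self):
        ion = formula_mass(7, 6, 5, 0, 0) - MASS_PROTON
        assert neutral_mass_from_mz(ion) == pytest.approx(170.02152329, abs=1e-6)

    def test_multiply_charged_unsupported(self):
        with pytest.raises(NotImplementedError):
            neutral_mass_from_mz(255.2, charge=2)


class TestEnumerate:
    def test_contains_generating_formula(self):
        cands = enumerate_candidates(formula_mass(16, 32, 2, 0, 0), 0.5)
        assert MolecularFormula(16, 32, 2) in cands

    @pytest.mark.parametrize("mass,tol", [
        (formula_mass(16, 32, 2, 0, 0), 0.5),
        (170.02152329, 1.0),
        (400.0000, 0.2),
        (123.456, 1.0),
        (777.777, 0.3),
    ])
    def test_matches_brute_force_oracle(self, mass, tol):
        got = {(f.c, f.h, f.o, f.n, f.s) for f in enumerate_candidates(mass, tol)}
        assert got == brute_force_candidates(mass, tol)

    def test_out_of_domain_mass_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidates(12.0, 1.0)
        with pytest.raises(ValueError):
            enumerate_candidates(400.0, 3.0)

    @given(st.floats(min_value=100, max_value=790),
           st.floats(min_value=0.1, max_value=1.0),
           st.floats(min_value=1.01, max_value=2.0))
    @settings(max_examples=30, deadline=None)
    def test_shrinking_tolerance_never_adds_candidates(self, mass, tol, widen):
        small = set(map(str, enumerate_candidates(mass, tol)))
        large = set(map(str, enumerate_candidates(mass, min(tol * widen, 2.0))))
        assert small <= large


class TestFilterAndDisambiguate:
    def test_plausibility_rules(self):
        keep = MolecularFormula(16, 32, 2)          # H/C 2.0, O/C 0.125, 256 Da
        drop_hc = MolecularFormula(1, 4)            # H/C 4.0 (and below 100 Da)
        drop_oc = MolecularFormula(20, 10, 30)      # O/C 1.5
        out = filter_candidates([keep, drop_hc, drop_oc])
        assert out == [keep]

    def test_boundaries_exclusive_for_hc_oc_inclusive_for_mass(self):
        rules = FilterRules()
        assert not rules.passes(MolecularFormula(10, 22, 2))   # H/C exactly 2.2
        assert not rules.passes(MolecularFormula(10, 3, 4))    # H/C exactly 0.3
        assert not rules.passes(MolecularFormula(10, 12, 12))  # O/C exactly 1.2
        f = MolecularFormula(37, 52, 9)
        assert 100 <= f.neutral_mass_Da <= 800 and rules.passes(f)

    def test_least_heteroatom_rule_wins(self):
        cho = MolecularFormula(18, 20, 5)
        chons = MolecularFormula(13, 19, 6, 1, 1)
        picked, reason = disambiguate([chons, cho])
        assert picked == cho and reason is None

    def test_empty_candidates(self):
        picked, reason = disambiguate([])
        assert picked is None and reason == "no_candidate"

    def test_tie_broken_by_smaller_mass_error(self):
        a = MolecularFormula(20, 24, 5)
        b = MolecularFormula(19, 28, 6)  # different CHO formula nearby
        target = a.neutral_mass_Da * (1 + 0.1e-6)  # a is 0.1 ppm away
        picked, _ = disambiguate([b, a], neutral_mass=target)
        assert picked == a

    def test_exact_tie_is_ambiguous(self):
        a = MolecularFormula(20, 24, 5)
        b = MolecularFormula(19, 28, 6)
        mid = (a.neutral_mass_Da + b.neutral_mass_Da) / 2
        # symmetric placement: identical relative errors on both sides
        picked, reason = disambiguate([a, b], neutral_mass=mid)
        if picked is None:
            assert reason == "ambiguous"
        else:  # floating-point midpoint may not be exactly symmetric
            assert picked in (a, b)


class TestAssignPeaklist:
    def test_all_low_snr_yields_empty_annotation(self):
        pl = PeakList("x", [Peak(255.23295, 10.0, 3.0), Peak(400.1, 5.0, 3.0)])
        ann = assign_peaklist(pl)
        assert not ann.intensities
        assert all(a.rejection_reason == "low_snr" for a in ann.assignments)

    def test_single_palmitate_peak(self):
        ion = formula_mass(16, 32, 2, 0, 0) - MASS_PROTON
        ann = assign_peaklist(PeakList("x", [Peak(ion, 123.0, 10.0)]))
        assert ann.intensities == {MolecularFormula(16, 32, 2): 123.0}

    def test_assigned_formulas_respect_filters(self, small_study):
        ann = assign_peaklist(small_study.pairs[0].dark)
        rules = FilterRules()
        assert ann.intensities
        for f in ann.intensities:
            assert rules.passes(f)

    def test_recovery_on_200_known_formulas(self, small_cfg):
        pair = synthesize_lake_pair(0, small_cfg)
        ann = assign_peaklist(pair.dark)
        qualifying = [a for a in ann.assignments if a.rejection_reason != "low_snr"]
        hits = sum(a.formula == pair.dark_truth[a.peak.mz] for a in qualifying)
        assert len(qualifying) > 100
        assert hits / len(qualifying) >= 0.99

    def test_mass_error_within_tolerance(self, small_study):
        ann = assign_peaklist(small_study.pairs[0].dark, tol_ppm=1.0)
        for a in ann.assignments:
            if a.formula is not None:
                assert abs(a.mass_error_ppm) <= 1.0


def test_replicate_consistency_filter():
    a, b, c = (MolecularFormula(10, 14, 4), MolecularFormula(12, 16, 5),
               MolecularFormula(9, 10, 3))
    sets = [{a, b}, {a, c}, {a}]
    assert replicate_consistency_filter(sets, k=2) == {a}
    assert replicate_consistency_filter(sets, k=1) == {a, b, c}


def test_formula_invariants():
    with pytest.raises(ValueError):
        MolecularFormula(0, 4)
    with pytest.raises(ValueError):
        MolecularFormula(5, 8, 0, 2, 0)
    f = MolecularFormula(16, 32, 2, 1, 1)
    assert str(MolecularFormula(16, 32, 2)) == "C16H32O2"
    assert str(f) == "C16H32NO2S"
    assert f.heteroatoms == 2
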