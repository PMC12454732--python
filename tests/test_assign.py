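"""Formula enumeration: completeness vs brute force, soundness, assignment."""

import numpy as np
import pytest

from ms1class import (
    ElementBounds,
    FilterOptions,
    PeakRecord,
    assign_peaks,
    enumerate_formulas,
    monoisotopic_mass,
    parse_formula,
)
from ms1class.formula import ElementComposition, format_formula

from _oracles import brute_force_formulas as brute_force


SMALL = ElementBounds({"C": (0, 8), "H": (0, 16), "N": (0, 3), "O": (0, 5)})


def test_water_exact_hit():
    cands = enumerate_formulas(
        18.010565, 2.0, ElementBounds({"C": (0, 2), "H": (0, 6), "N": (0, 2), "O": (0, 2)})
    )
    assert [c.formula for c in cands] == ["H2O"]


def test_caffeine_mass_includes_true_formula():
    cands = enumerate_formulas(
        194.080376, 2.0,
        ElementBounds({"C": (0, 20), "H": (0, 30), "N": (0, 6), "O": (0, 10)}),
    )
    assert "C8H10N4O2" in [c.formula for c in cands]
    assert cands[0].formula == "C8H10N4O2"  # smallest |ppm| ranks first


@pytest.mark.parametrize("bad_mass", [-5.0, 0.0])
def test_nonpositive_mass_rejected(bad_mass):
    with pytest.raises(ValueError):
        enumerate_formulas(bad_mass, 2.0, SMALL)


def test_volume_guard_refuses_huge_lattices():
    huge = ElementBounds({"C": (0, 1000), "H": (0, 2000), "O": (0, 1000)})
    with pytest.raises(ValueError, match="narrow"):
        enumerate_formulas(100.0, 2.0, huge)


def test_bounds_spec_parser():
    b = ElementBounds.from_spec("C0-70H0-120N0-6O0-35")
    assert b.bounds == {"C": (0, 70), "H": (0, 120), "N": (0, 6), "O": (0, 35)}
    with pytest.raises(ValueError):
        ElementBounds.from_spec("C0-70 garbage")
    with pytest.raises(ValueError):
        ElementBounds({"C": (5, 2)})


def test_enumerator_matches_bruteforce_on_random_instances():
    """Completeness + soundness against the naive oracle, 100 instances."""
    rng = np.random.default_rng(7)
    loose = FilterOptions(integer_dbe_only=False, nonnegative_dbe=False)
    for _ in range(100):
        mass = float(rng.uniform(30.0, 160.0))
        tol = float(rng.choice([2.0, 5.0, 20.0]))
        filt = FilterOptions() if rng.random() < 0.5 else loose
        ours = {c.formula for c in enumerate_formulas(mass, tol, SMALL, filt)}
        assert ours == brute_force(mass, tol, SMALL, filt)


def test_every_candidate_within_tolerance_recomputed():
    cands = enumerate_formulas(302.042653, 5.0)
    assert cands, "expected at least one candidate near quercetin's mass"
    for c in cands:
        ppm = (monoisotopic_mass(c.composition) - 302.042653) / 302.042653 * 1e6
        assert abs(ppm) <= 5.0
        assert c.ppm_error == pytest.approx(ppm, abs=1e-9)
    assert [c.rank for c in cands] == list(range(1, len(cands) + 1))


def test_self_recovery_of_random_compositions():
    """Enumerating at a composition's own mass always returns it (500 draws)."""
    rng = np.random.default_rng(11)
    n_checked = 0
    while n_checked < 500:
        c = int(rng.integers(1, 41))
        n = int(rng.integers(0, 5))
        d = int(rng.integers(0, c + n // 2 + 2))
        h = 2 * c + n + 2 - 2 * d
        if not (0 <= h <= 120 and 0.2 <= h / c <= 3.2):
            continue
        o = int(rng.integers(0, min(20, int(1.5 * c)) + 1))
        comp = ElementComposition({k: v for k, v in
                                   {"C": c, "H": h, "N": n, "O": o}.items() if v})
        cands = enumerate_formulas(monoisotopic_mass(comp), 2.0)
        assert comp in [x.composition for x in cands], format_formula(comp)
        n_checked += 1


def test_tolerance_monotonicity():
    for mass in (194.080376, 302.042653, 426.386166):
        narrow = {c.formula for c in enumerate_formulas(mass, 2.0)}
        wide = {c.formula for c in enumerate_formulas(mass, 10.0)}
        assert narrow <= wide


def test_integer_dbe_filter_drops_radical_compositions():
    # CH3 (DBE -0.5 as a "molecule") only appears when the filter is off
    mass = monoisotopic_mass(parse_formula("CH3"))
    b = ElementBounds({"C": (0, 2), "H": (0, 6), "N": (0, 1), "O": (0, 1)})
    strict = [c.formula for c in enumerate_formulas(mass, 10.0, b)]
    loose = [c.formula for c in enumerate_formulas(
        mass, 10.0, b, FilterOptions(integer_dbe_only=False, nonnegative_dbe=False))]
    assert "CH3" not in strict
    assert "CH3" in loose


def test_assign_peaks_caffeine_protonated():
    peaks = [PeakRecord(mz=195.087652)]
    out = assign_peaks(peaks, "[M+H]+", 2.0,
                       ElementBounds({"C": (0, 20), "H": (0, 30), "N": (0, 6), "O": (0, 10)}))
    assert out[0].assigned is not None
    assert out[0].assigned.formula == "C8H10N4O2"


def test_assign_peaks_flags_unmatched_but_keeps_them():
    b = ElementBounds({"C": (0, 2), "H": (0, 4), "O": (0, 1)})
    out = assign_peaks([PeakRecord(mz=500.0)], "[M+H]+", 2.0, b)
    assert len(out) == 1
    assert out[0].assigned is None
    assert out[0].n_candidates == 0


def test_assign_peaks_input_validation():
    with pytest.raises(ValueError):
        PeakRecord(mz=-0.5)
    with pytest.raises(ValueError, match="neutral"):
        # m/z 0.5 is below the proton mass: no neutral molecule can yield it
        assign_peaks([PeakRecord(mz=0.5)], "[M+H]+", 2.0)
    with pytest.raises(Exception):
        assign_peaks([PeakRecord(mz=100.0)], "[M+Xx]+", 2.0)
    assert assign_peaks([], "[M+H]+", 2.0) == []
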