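"""Independent brute-force oracles shared by the test modules."""

import itertools

from ms1class import FilterOptions
from ms1class.elements import MONOISOTOPIC_MASS
from ms1class.formula import ElementComposition, format_formula


def brute_force_formulas(neutral_mass, tol_ppm, bounds, filters=FilterOptions()):
    """Naive nested-loop enumeration over the full bound lattice."""
    tol = tol_ppm * neutral_mass * 1e-6
    els = sorted(bounds.bounds)
    hits = set()
    for counts in itertools.product(
        *(range(lo, hi + 1) for el in els for lo, hi in [bounds.bounds[el]])
    ):
        d = {el: n for el, n in zip(els, counts) if n}
        if not d:
            continue
        mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in d.items())
        if abs(mass - neutral_mass) <= tol:
            comp = ElementComposition(d)
            if filters.accept(comp):
                hits.add(format_formula(comp))
    return hits
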