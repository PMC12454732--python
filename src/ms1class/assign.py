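"""Molecular formula enumeration for accurate MS1 masses.

Given a neutral monoisotopic mass and element count bounds, enumerate
*every* CHNOPS composition whose mass falls within a ppm tolerance (the
standard acceptance rule is 2 ppm), then rank candidates by |ppm error|.
The search is a depth-first walk over element counts ordered heavy-first,
pruned by the residual mass window; hydrogen, the lightest element, is
resolved arithmetically at the leaves so the loop depth stays small.
Completeness is what the test suite checks against a brute-force oracle.

ppm is defined relative to the neutral monoisotopic mass
(``tol_da = tolerance_ppm * neutral_mass * 1e-6``), the common vendor
convention; pass ``ppm_reference="mz"`` to :func:`assign_peaks` for the
m/z-relative alternative.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .adducts import Adduct, get_adduct, neutral_mass_from_mz
from .descriptors import dbe as _dbe
from .elements import MONOISOTOPIC_MASS
from .formula import ElementComposition, format_formula, monoisotopic_mass

__all__ = [
    "ElementBounds",
    "FormulaCandidate",
    "PeakRecord",
    "enumerate_formulas",
    "assign_peaks",
    "FilterOptions",
]

#: refuse searches whose raw bound lattice exceeds this many combinations
DEFAULT_VOLUME_GUARD = int(5e8)


@dataclass(frozen=True)
class ElementBounds:
    """Per-element (min, max) count bounds for the enumeration."""

    bounds: dict = field(default_factory=lambda: {
        "C": (0, 70), "H": (0, 120), "N": (0, 6),
        "O": (0, 35), "S": (0, 2), "P": (0, 2),
    })

    def __post_init__(self):
        for el, (lo, hi) in self.bounds.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element {el!r} in bounds")
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid bounds for {el}: ({lo}, {hi})")

    @property
    def volume(self) -> int:
        v = 1
        for lo, hi in self.bounds.values():
            v *= hi - lo + 1
        return v

    @classmethod
    def from_spec(cls, spec: str) -> "ElementBounds":
        """Parse a compact bound string like ``"C0-70H0-120N0-6O0-35"``."""
        pat = re.compile(r"([A-Z][a-z]?)(\d+)-(\d+)")
        pos, bounds = 0, {}
        for m in pat.finditer(spec):
            if m.start() != pos:
                raise ValueError(f"unparseable bounds spec near {spec[pos:]!r}")
            bounds[m.group(1)] = (int(m.group(2)), int(m.group(3)))
            pos = m.end()
        if pos != len(spec) or not bounds:
            raise ValueError(f"unparseable bounds spec {spec!r}")
        return cls(bounds)


@dataclass(frozen=True)
class FilterOptions:
    """Chemical plausibility filters applied to enumerated compositions."""

    integer_dbe_only: bool = True   # neutral molecules have integer DBE
    nonnegative_dbe: bool = True
    hc_range: tuple[float, float] | None = None  # e.g. (0.2, 3.2)
    oc_max: float | None = None                  # e.g. 1.5

    def accept(self, comp: ElementComposition) -> bool:
        d = _dbe(comp)
        if self.nonnegative_dbe and d < 0:
            return False
        if self.integer_dbe_only and abs(d - round(d)) > 1e-9:
            return False
        c = comp.get("C", 0)
        if c > 0:
            hc = comp.get("H", 0) / c
            oc = comp.get("O", 0) / c
            if self.hc_range is not None and not (
                self.hc_range[0] <= hc <= self.hc_range[1]
            ):
                return False
            if self.oc_max is not None and oc > self.oc_max:
                return False
        return True


@dataclass(frozen=True)
class FormulaCandidate:
    composition: ElementComposition
    theoretical_mass: float
    ppm_error: float
    rank: int = 0

    @property
    def formula(self) -> str:
        return format_formula(self.composition)


@dataclass
class PeakRecord:
    """One centroided MS1 peak, optionally with its best assignment."""

    mz: float
    intensity: float | None = None
    assigned: FormulaCandidate | None = None
    n_candidates: int = 0

    def __post_init__(self):
        if not (self.mz > 0):
            raise ValueError(f"peak m/z must be positive, got {self.mz}")


def _heteroatom_count(comp: ElementComposition) -> int:
    return sum(n for el, n in comp.items() if el not in ("C", "H"))


def enumerate_formulas(
    neutral_mass: float,
    tolerance_ppm: float = 2.0,
    bounds: ElementBounds | None = None,
    filters: FilterOptions = FilterOptions(),
    volume_guard: int = DEFAULT_VOLUME_GUARD,
) -> list[FormulaCandidate]:
    """All compositions within ``bounds`` matching ``neutral_mass`` at tolerance.

    Returns candidates sorted by |ppm error|, ties broken by fewer
    heteroatoms then formula string; ``rank`` starts at 1.
    """
    if not (neutral_mass > 0):
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if not (tolerance_ppm > 0):
        raise ValueError(f"tolerance must be positive, got {tolerance_ppm}")
    bounds = bounds if bounds is not None else ElementBounds()
    if bounds.volume > volume_guard:
        raise ValueError(
            f"bounds lattice has {bounds.volume:.2e} combinations "
            f"(guard {volume_guard:.0e}); narrow the element bounds"
        )
    tol_da = tolerance_ppm * neutral_mass * 1e-6
    lo_target = neutral_mass - tol_da
    hi_target = neutral_mass + tol_da

    # heavy elements first; hydrogen handled analytically at the leaf
    elems = sorted(
        (el for el in bounds.bounds if el != "H"),
        key=lambda el: -MONOISOTOPIC_MASS[el],
    )
    h_lo, h_hi = bounds.bounds.get("H", (0, 0))
    m_h = MONOISOTOPIC_MASS["H"]
    masses = [MONOISOTOPIC_MASS[el] for el in elems]
    # max mass attainable from elements[i:] plus hydrogen
    tail_max = [0.0] * (len(elems) + 1)
    tail_max[len(elems)] = h_hi * m_h
    for i in range(len(elems) - 1, -1, -1):
        tail_max[i] = tail_max[i + 1] + bounds.bounds[elems[i]][1] * masses[i]

    found: list[tuple[ElementComposition, float]] = []
    counts: dict[str, int] = {}

    def walk(i: int, mass_so_far: float) -> None:
        if i == len(elems):
            # choose hydrogen counts landing inside the window
            lo_h = max(h_lo, math.ceil((lo_target - mass_so_far) / m_h - 1e-12))
            hi_h = min(h_hi, math.floor((hi_target - mass_so_far) / m_h + 1e-12))
            for nh in range(lo_h, hi_h + 1):
                total = mass_so_far + nh * m_h
                if lo_target <= total <= hi_target:
                    c = dict(counts)
                    if nh:
                        c["H"] = nh
                    if not c:
                        continue
                    found.append((ElementComposition(c), total))
            return
        el, m = elems[i], masses[i]
        lo_n, hi_n = bounds.bounds[el]
        for n in range(lo_n, hi_n + 1):
            mass = mass_so_far + n * m
            if mass > hi_target:
                break
            if mass + tail_max[i + 1] < lo_target:
                continue
            if n:
                counts[el] = n
            walk(i + 1, mass)
        counts.pop(el, None)

    walk(0, 0.0)

    cands = []
    for comp, mass in found:
        if not filters.accept(comp):
            continue
        ppm = (mass - neutral_mass) / neutral_mass * 1e6
        cands.append(FormulaCandidate(comp, mass, ppm))
    cands.sort(key=lambda c: (abs(c.ppm_error), _heteroatom_count(c.composition), c.formula))
    return [replace(c, rank=i + 1) for i, c in enumerate(cands)]


def assign_peaks(
    peaks: list[PeakRecord],
    adduct: str | Adduct = "[M+H]+",
    tolerance_ppm: float = 2.0,
    bounds: ElementBounds | None = None,
    filters: FilterOptions = FilterOptions(),
    ppm_reference: str = "neutral",
) -> list[PeakRecord]:
    """Assign the best candidate formula to each peak.

    Each m/z is converted to a neutral mass via the adduct (electron mass
    included), enumerated, and the rank-1 candidate stored.  Peaks with no
    candidate keep ``assigned=None`` and are not dropped.
    """
    add = adduct if isinstance(adduct, Adduct) else get_adduct(adduct)
    if ppm_reference not in ("neutral", "mz"):
        raise ValueError("ppm_reference must be 'neutral' or 'mz'")
    out: list[PeakRecord] = []
    for pk in peaks:
        neutral = neutral_mass_from_mz(pk.mz, add)
        if neutral <= 0:
            raise ValueError(
                f"peak m/z {pk.mz} implies non-positive neutral mass for {add.label}"
            )
        tol = tolerance_ppm
        if ppm_reference == "mz":
            tol = tolerance_ppm * pk.mz / neutral
        cands = enumerate_formulas(neutral, tol, bounds, filters)
        out.append(PeakRecord(
            mz=pk.mz,
            intensity=pk.intensity,
            assigned=cands[0] if cands else None,
            n_candidates=len(cands),
        ))
    return out


def peaks_to_frame(peaks: list[PeakRecord], adduct: str | Adduct = "[M+H]+") -> pd.DataFrame:
    """Tabulate assigned peaks: mz, intensity, formula, ppm_error, n_candidates."""
    from .adducts import ion_mz

    add = adduct if isinstance(adduct, Adduct) else get_adduct(adduct)
    rows = []
    for pk in peaks:
        row = {
            "mz": pk.mz,
            "intensity": pk.intensity if pk.intensity is not None else "",
            "formula": "",
            "theoretical_mz": "",
            "ppm_error": "",
            "n_candidates": pk.n_candidates,
        }
        if pk.assigned is not None:
            row["formula"] = pk.assigned.formula
            row["theoretical_mz"] = ion_mz(pk.assigned.theoretical_mass, add)
            row["ppm_error"] = pk.assigned.ppm_error
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["mz", "intensity", "formula", "theoretical_mz", "ppm_error", "n_candidates"],
    )
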