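"""Class-consistent synthetic molecular formulas and peak lists.

Two generation modes emulate how a curated class dataset is assembled:

* ``window_sampled`` — draw an integer (C, N, H, O) lattice point whose
  H/C, O/C, DBE and carbon count all fall inside the named class's
  knowledge-base windows.  Because DBE is linear in H, the feasible H set
  is computed directly (with the parity that makes neutral DBE an
  integer), so sampling is constructive; a verification pass re-checks
  every record against the windows.  Classes whose windows admit no
  integer lattice point raise :class:`UnsatisfiableWindowError`.
* ``scaffold_built`` — start from a canonical core scaffold (e.g. coumarin
  C9H6O2, tropane C8H15N, lupeol C30H50O) and attach 0-3 random
  substituents from the natural-product vocabulary (hydroxyl, methoxyl,
  methyl, prenyl, methylenedioxy, glycosyl).  These records mimic real
  homologue series and need not stay inside the windows.

Synthetic peak lists ionize each record under a chosen adduct and apply
Gaussian ppm noise; intensities are log-uniform.  Everything is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adducts import ion_mz
from .assign import PeakRecord
from .descriptors import profile
from .formula import ElementComposition, monoisotopic_mass, parse_formula
from .knowledge_base import ClassDefinition, KnowledgeBase, default_kb

__all__ = [
    "SyntheticRecord",
    "UnsatisfiableWindowError",
    "generate_class_formulas",
    "generate_peaklist",
    "SCAFFOLDS",
    "SUBSTITUENTS",
]


class UnsatisfiableWindowError(ValueError):
    """The class's windows admit no integer composition."""


@dataclass(frozen=True)
class SyntheticRecord:
    true_class: str
    composition: ElementComposition
    generation_mode: str
    seed: int


# canonical core scaffolds (neutral formulas) per class
SCAFFOLDS: dict[str, str] = {
    "flavonoid": "C15H10O2",       # flavone core
    "phenolic_acid": "C7H6O2",     # benzoic acid
    "tannin": "C27H24O18",         # trigalloyl glucose
    "coumarin": "C9H6O2",
    "stilbene": "C14H12",
    "lignan": "C20H22O6",          # pinoresinol
    "anthraquinone": "C14H8O2",
    "isoquinoline": "C9H7N",
    "indole": "C12H10N2",          # harman (beta-carboline)
    "quinolizidine": "C15H24N2O",  # matrine
    "tropane": "C8H15N",
    "quinoline": "C19H22N2O",      # cinchonine
    "protoalkaloid": "C8H11NO",    # tyramine
    "purine": "C5H4N4O2",          # xanthine
    "pyrrolizidine": "C8H13NO2",   # retronecine
    "piperidine": "C5H11N",
    "pyrrolidine": "C8H15NO",      # hygrine
    "steroid": "C27H46O",          # cholesterol
    "triterpene": "C30H50O",       # lupeol
    "saponin": "C36H58O8",         # oleanolic acid monoglucoside
}

# substituent vocabulary: net elemental deltas for replacing one H
SUBSTITUENTS: dict[str, dict[str, int]] = {
    "hydroxyl": {"O": 1},
    "methoxyl": {"C": 1, "H": 2, "O": 1},
    "methyl": {"C": 1, "H": 2},
    "prenyl": {"C": 5, "H": 8},
    "methylenedioxy": {"C": 1, "O": 2},  # bridges two adjacent positions
    "glycosyl": {"C": 6, "H": 10, "O": 5},
}

# fallback windows used when a class leaves an axis open
_FALLBACK = {"hc": (0.2, 3.2), "oc": (0.0, 1.5), "dbe": (0.0, 40.0), "c": (5.0, 60.0)}

_MAX_ATTEMPTS = 100_000


def _effective_window(cdef: ClassDefinition, axis: str) -> tuple[float, float]:
    lo, hi = cdef.window(axis)
    if lo is None:
        return _FALLBACK[axis]
    return float(lo), float(hi)


def _nitrogen_choices(cdef: ClassDefinition) -> list[int]:
    if not cdef.requires_nitrogen:
        return [0]
    if cdef.name == "purine":
        return [3, 4]
    return [1, 2]


def _sample_window(
    cdef: ClassDefinition, rng: np.random.Generator
) -> ElementComposition | None:
    """One constructive draw from the class's integer lattice, or None."""
    c_lo, c_hi = _effective_window(cdef, "c")
    hc_lo, hc_hi = _effective_window(cdef, "hc")
    oc_lo, oc_hi = _effective_window(cdef, "oc")
    dbe_lo, dbe_hi = _effective_window(cdef, "dbe")
    c = int(rng.integers(int(np.ceil(c_lo)), int(np.floor(c_hi)) + 1))
    n = int(rng.choice(_nitrogen_choices(cdef)))
    # H window from the DBE window: DBE = C - H/2 + N/2 + 1
    h_from_dbe_lo = 2.0 * (c + n / 2.0 + 1.0 - dbe_hi)
    h_from_dbe_hi = 2.0 * (c + n / 2.0 + 1.0 - dbe_lo)
    h_lo = max(0.0, hc_lo * c, h_from_dbe_lo)
    h_hi = min(hc_hi * c, h_from_dbe_hi)
    # parity: neutral integer DBE needs H = N (mod 2)
    hs = [
        h for h in range(int(np.ceil(h_lo - 1e-9)), int(np.floor(h_hi + 1e-9)) + 1)
        if h % 2 == n % 2
    ]
    if not hs:
        return None
    h = int(rng.choice(hs))
    o_lo = int(np.ceil(oc_lo * c - 1e-9))
    o_hi = int(np.floor(oc_hi * c + 1e-9))
    if o_hi < o_lo:
        return None
    o = int(rng.integers(o_lo, o_hi + 1))
    counts = {"C": c, "H": h, "N": n, "O": o}
    return ElementComposition({k: v for k, v in counts.items() if v})


def _inside_windows(comp: ElementComposition, cdef: ClassDefinition) -> bool:
    d = profile(comp)
    vals = {"hc": d.hc_ratio, "oc": d.oc_ratio, "dbe": d.dbe, "c": float(d.carbon_count)}
    for axis in cdef.defined_axes():
        lo, hi = cdef.window(axis)
        if not (lo - 1e-9 <= vals[axis] <= hi + 1e-9):  # type: ignore[operator]
            return False
    return True


def generate_class_formulas(
    class_name: str,
    n: int,
    seed: int = 0,
    kb: KnowledgeBase | None = None,
    mode: str = "window_sampled",
) -> list[SyntheticRecord]:
    """Generate ``n`` synthetic formulas labelled with their true class."""
    if n < 1:
        raise ValueError("n must be >= 1")
    kb = kb if kb is not None else default_kb()
    try:
        cdef = kb.get(class_name)
    except KeyError as e:
        raise ValueError(str(e)) from e
    if mode not in ("window_sampled", "scaffold_built"):
        raise ValueError(f"unknown generation mode {mode!r}")
    rng = np.random.default_rng(seed)
    records: list[SyntheticRecord] = []
    if mode == "window_sampled":
        attempts = 0
        while len(records) < n:
            attempts += 1
            if attempts > _MAX_ATTEMPTS:
                raise UnsatisfiableWindowError(
                    f"could not sample a composition inside the windows of "
                    f"class {class_name!r} after {_MAX_ATTEMPTS} attempts "
                    "(empty or near-empty integer lattice)"
                )
            comp = _sample_window(cdef, rng)
            if comp is None or not _inside_windows(comp, cdef):
                continue
            records.append(SyntheticRecord(class_name, comp, mode, seed))
    else:
        core = parse_formula(SCAFFOLDS[class_name])
        sub_names = sorted(SUBSTITUENTS)
        for _ in range(n):
            comp = core
            for _ in range(int(rng.integers(0, 4))):
                sub = SUBSTITUENTS[sub_names[int(rng.integers(0, len(sub_names)))]]
                comp = comp + sub
            records.append(SyntheticRecord(class_name, comp, mode, seed))
    return records


def generate_peaklist(
    records: list[SyntheticRecord],
    adduct: str = "[M+H]+",
    ppm_noise_sd: float = 0.5,
    seed: int = 0,
) -> list[PeakRecord]:
    """Ionize records into a synthetic centroided peak list.

    m/z = theoretical adduct m/z x (1 + eps), eps ~ N(0, sd x 1e-6);
    intensities are drawn log-uniformly over 1e4-1e7 counts.
    """
    if ppm_noise_sd < 0:
        raise ValueError("ppm_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    peaks: list[PeakRecord] = []
    for rec in records:
        mz = ion_mz(monoisotopic_mass(rec.composition), adduct)
        eps = rng.normal(0.0, ppm_noise_sd * 1e-6) if ppm_noise_sd > 0 else 0.0
        intensity = float(10.0 ** rng.uniform(4, 7))
        peaks.append(PeakRecord(mz=mz * (1.0 + eps), intensity=intensity))
    return peaks
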