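"""Electrospray adducts: ion <-> neutral interconversion.

Class range windows are defined on neutral molecular formulas, while ESI
MS1 observes adduct ions such as [M+H]+.  This module holds the supported
adduct registry and the exact (electron-mass aware) arithmetic between a
neutral monoisotopic mass and the observed m/z.
"""

from __future__ import annotations

from dataclasses import dataclass

from .elements import ELECTRON_MASS, MONOISOTOPIC_MASS
from .formula import ElementComposition, FormulaError

__all__ = [
    "Adduct",
    "ADDUCTS",
    "get_adduct",
    "IonSpecies",
    "neutralize",
    "apply_adduct",
    "ion_mz",
    "neutral_mass_from_mz",
]


@dataclass(frozen=True)
class Adduct:
    """A supported ESI adduct: atoms added to M, and the resulting charge."""

    label: str
    delta: dict  # element -> signed count added to the neutral molecule
    charge: int

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative" if self.charge < 0 else "neutral"

    @property
    def delta_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.delta.items())


_ADDUCT_LIST = [
    Adduct("[M]", {}, 0),
    Adduct("[M+H]+", {"H": 1}, +1),
    Adduct("[M+Na]+", {"Na": 1}, +1),
    Adduct("[M+K]+", {"K": 1}, +1),
    Adduct("[M+NH4]+", {"N": 1, "H": 4}, +1),
    Adduct("[M-H]-", {"H": -1}, -1),
]

ADDUCTS: dict[str, Adduct] = {a.label: a for a in _ADDUCT_LIST}


def get_adduct(label: str) -> Adduct:
    """Look up an adduct, tolerating the typographic minus sign."""
    norm = label.replace("−", "-").strip()
    try:
        return ADDUCTS[norm]
    except KeyError:
        raise FormulaError(
            f"unsupported adduct {label!r}; supported: {sorted(ADDUCTS)}"
        ) from None


@dataclass(frozen=True)
class IonSpecies:
    """An intact ion: its full atomic composition plus adduct bookkeeping."""

    composition: ElementComposition
    adduct_label: str = "[M]"
    charge: int = 0

    def __post_init__(self):
        add = get_adduct(self.adduct_label)
        if self.charge != add.charge:
            raise FormulaError(
                f"charge {self.charge} inconsistent with adduct {self.adduct_label}"
            )

    @property
    def polarity(self) -> str:
        return get_adduct(self.adduct_label).polarity


def apply_adduct(neutral: ElementComposition, adduct: str | Adduct) -> IonSpecies:
    """Build the intact-ion species for a neutral molecule M and an adduct."""
    add = adduct if isinstance(adduct, Adduct) else get_adduct(adduct)
    gains = {el: n for el, n in add.delta.items() if n > 0}
    losses = {el: -n for el, n in add.delta.items() if n < 0}
    comp = neutral
    if gains:
        comp = comp + gains
    if losses:
        comp = comp.subtract(losses)
    return IonSpecies(comp, add.label, add.charge)


def neutralize(ion: IonSpecies) -> ElementComposition:
    """Recover the neutral molecule M from an ion species.

    Inverse of :func:`apply_adduct`; raises :class:`FormulaError` when the
    ion cannot have come from the claimed adduct (e.g. [M+H]+ with no H).
    """
    add = get_adduct(ion.adduct_label)
    gains = {el: n for el, n in add.delta.items() if n > 0}
    losses = {el: -n for el, n in add.delta.items() if n < 0}
    comp = ion.composition
    if gains:
        comp = comp.subtract(gains)
    if losses:
        comp = comp + losses
    return comp


def ion_mz(neutral_mass: float, adduct: str | Adduct) -> float:
    """Theoretical m/z of the adduct ion of a neutral of given mass."""
    add = adduct if isinstance(adduct, Adduct) else get_adduct(adduct)
    if add.charge == 0:
        return neutral_mass + add.delta_mass
    return (neutral_mass + add.delta_mass - add.charge * ELECTRON_MASS) / abs(add.charge)


def neutral_mass_from_mz(mz: float, adduct: str | Adduct) -> float:
    """Neutral monoisotopic mass implied by an observed m/z and adduct."""
    add = adduct if isinstance(adduct, Adduct) else get_adduct(adduct)
    if add.charge == 0:
        return mz - add.delta_mass
    return mz * abs(add.charge) - add.delta_mass + add.charge * ELECTRON_MASS
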