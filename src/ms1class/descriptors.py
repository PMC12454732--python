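"""Formula-derived descriptors: H/C, O/C, DBE, modified aromaticity index.

These four quantities, plus the carbon and nitrogen counts and the
monoisotopic mass, define the chemical space in which metabolite classes
are annotated.  All are pure functions of the elemental composition.

DBE convention
--------------
The ring-plus-double-bond equivalent of a CHNOS(P) composition is

    DBE = C - (H + halogens)/2 + N/2 + 1

Oxygen, sulfur and phosphorus do not enter; halogens count like hydrogen.
Applied to a *neutral* formula of a valid molecule the result is a
non-negative integer.  Applied to the intact composition of a protonated
even-electron ion with a single nitrogen it is a half-integer (e.g. 5.5) —
a diagnostic the classifier exploits for alkaloids.  Every descriptor set
records which convention produced it.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .elements import HALOGENS
from .formula import (
    ElementComposition,
    FormulaError,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "DescriptorSet",
    "elemental_ratios",
    "dbe",
    "ai_mod",
    "profile",
    "DescriptorCalculator",
    "DESCRIPTOR_COLUMNS",
]


@dataclass(frozen=True)
class DescriptorSet:
    """Per-formula descriptor vector."""

    hc_ratio: float
    oc_ratio: float
    dbe: float
    ai_mod: float
    carbon_count: int
    nitrogen_count: int
    monoisotopic_mass: float
    dbe_convention: str = "neutral"  # "neutral" | "ion"


def elemental_ratios(comp: Mapping[str, int]) -> tuple[float, float]:
    """Atomic H/C and O/C ratios (the Van Krevelen coordinates).

    Raises :class:`FormulaError` when the composition has no carbon, since
    the ratios are then undefined.
    """
    c = comp.get("C", 0)
    if c == 0:
        raise FormulaError("H/C and O/C are undefined for carbon-free compositions")
    return comp.get("H", 0) / c, comp.get("O", 0) / c


def dbe(comp: Mapping[str, int]) -> float:
    """Ring-plus-double-bond equivalent, halogens counted as hydrogen.

    Negative values are returned as-is (chemically implausible input is a
    validation concern, not a computation error).
    """
    h_like = comp.get("H", 0) + sum(comp.get(x, 0) for x in HALOGENS)
    return comp.get("C", 0) - h_like / 2.0 + comp.get("N", 0) / 2.0 + 1.0


def ai_mod(comp: Mapping[str, int]) -> float:
    """Modified aromaticity index of Koch & Dittmar.

        AI_mod = (1 + C - O/2 - S - (N + P + H)/2) / (C - O/2 - S - N - P)

    clamped to [0, 1]; defined as 0 when the denominator is <= 0 or the
    numerator is negative (fully saturated or heteroatom-dominated
    compositions carry no aromatic signal).
    """
    c = comp.get("C", 0)
    h = comp.get("H", 0)
    n = comp.get("N", 0)
    o = comp.get("O", 0)
    s = comp.get("S", 0)
    p = comp.get("P", 0)
    denom = c - 0.5 * o - s - n - p
    if denom <= 0:
        return 0.0
    num = 1.0 + c - 0.5 * o - s - 0.5 * (n + p + h)
    if num < 0:
        return 0.0
    return min(num / denom, 1.0)


def profile(comp: Mapping[str, int] | str, convention: str = "neutral") -> DescriptorSet:
    """Compute the full descriptor set for one composition.

    ``comp`` may be an :class:`ElementComposition` or a formula string.
    With ``convention="ion"`` the caller passes the intact ion composition
    and the (possibly half-integer) DBE is recorded under that convention.
    """
    if isinstance(comp, str):
        comp = parse_formula(comp)
    if convention not in ("neutral", "ion"):
        raise ValueError(f"convention must be 'neutral' or 'ion', got {convention!r}")
    hc, oc = elemental_ratios(comp)
    return DescriptorSet(
        hc_ratio=hc,
        oc_ratio=oc,
        dbe=dbe(comp),
        ai_mod=ai_mod(comp),
        carbon_count=comp.get("C", 0),
        nitrogen_count=comp.get("N", 0),
        monoisotopic_mass=monoisotopic_mass(comp),
        dbe_convention=convention,
    )


DESCRIPTOR_COLUMNS = ["hc", "oc", "dbe", "ai_mod", "c", "n", "mass"]


def _as_row(d: DescriptorSet) -> list[float]:
    return [
        d.hc_ratio,
        d.oc_ratio,
        d.dbe,
        d.ai_mod,
        float(d.carbon_count),
        float(d.nitrogen_count),
        d.monoisotopic_mass,
    ]


class DescriptorCalculator(TransformerMixin, BaseEstimator):
    """scikit-learn transformer: formula strings -> descriptor matrix.

    ``transform`` accepts a 1-d sequence of formula strings (or a single
    column 2-d array) and returns an ``(n, 7)`` float array with columns
    ``hc, oc, dbe, ai_mod, c, n, mass``.  Stateless; ``fit`` only records
    the input width so the estimator composes with sklearn pipelines.
    """

    def __init__(self, convention: str = "neutral"):
        self.convention = convention

    @staticmethod
    def _flatten(X) -> list[str]:
        arr = np.asarray(X, dtype=object)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr[:, 0]
        if arr.ndim != 1:
            raise ValueError("expected a 1-d sequence of formula strings")
        return [str(x) for x in arr]

    def fit(self, X, y=None) -> "DescriptorCalculator":
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        rows = [_as_row(profile(f, self.convention)) for f in self._flatten(X)]
        return np.asarray(rows, dtype=float).reshape(-1, len(DESCRIPTOR_COLUMNS))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(DESCRIPTOR_COLUMNS, dtype=object)
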