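"""Range-membership class annotation with DBE/carbon/nitrogen resolution.

A descriptor profile is scored against every class window in the knowledge
base.  The score of a class is the mean, over its *defined* axes (H/C,
O/C, DBE, carbon count), of a per-axis membership that is 1 inside the
window and decays as ``exp(-d / sigma)`` with the distance ``d`` to the
nearest bound outside it.  Inside all windows therefore means a score of
exactly 1.  Three chemical gates sharpen the ranking:

* alkaloid classes require nitrogen; nitrogen-free profiles never match
  them (strict mode also bars nitrogen-containing profiles from
  non-alkaloid classes, since phenolic and isoprenoid windows were curated
  from CHO formulas);
* a half-integer DBE — the signature of an even-electron single-nitrogen
  adduct ion — restricts eligibility to the nitrogenous group, where that
  pattern is diagnostic;
* ties at equal score are resolved by proximity of DBE to the class DBE
  midpoint (the primary discriminator), then carbon count to the carbon
  midpoint, then class name.

The result is a class-level (MSI Level 3) annotation: a ranked candidate
list, never a single-compound identification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .descriptors import DescriptorSet, profile
from .knowledge_base import ClassDefinition, KnowledgeBase, default_kb

__all__ = [
    "ClassifyOptions",
    "CandidateScore",
    "ClassAnnotation",
    "membership_score",
    "classify",
    "classify_table",
    "VanKrevelenClassifier",
    "ANNOTATION_COLUMNS",
]

MSI_LEVEL = "3"


@dataclass(frozen=True)
class ClassifyOptions:
    """Tunable knobs of the annotator.

    sigma_* control the softness of each axis outside its window (0 gives
    hard, in-or-out membership); ``strict_nitrogen`` bars nitrogen-bearing
    profiles from non-alkaloid classes instead of merely demoting them.
    """

    top_k: int = 3
    min_score: float = 0.5
    strict_nitrogen: bool = True
    sigma_ratio: float = 0.1
    sigma_dbe: float = 1.0
    sigma_carbon: float = 2.0
    nitrogen_demotion: float = 0.5  # multiplier in non-strict mode


@dataclass(frozen=True)
class CandidateScore:
    name: str
    score: float
    inside: dict  # axis -> bool, for the class's defined axes


@dataclass
class ClassAnnotation:
    """Ranked candidate classes for one profile (MSI Level 3)."""

    candidates: list[CandidateScore]
    msi_level: str = MSI_LEVEL
    rationale: list[str] = field(default_factory=list)
    unclassified_reason: str | None = None

    @property
    def top(self) -> CandidateScore | None:
        return self.candidates[0] if self.candidates else None


def _axis_value(desc: DescriptorSet, axis: str) -> float:
    return {
        "hc": desc.hc_ratio,
        "oc": desc.oc_ratio,
        "dbe": desc.dbe,
        "c": float(desc.carbon_count),
    }[axis]


def _axis_sigma(axis: str, opts: ClassifyOptions) -> float:
    if axis in ("hc", "oc"):
        return opts.sigma_ratio
    return opts.sigma_dbe if axis == "dbe" else opts.sigma_carbon


def _axis_membership(value: float, lo: float, hi: float, sigma: float) -> float:
    if lo <= value <= hi:
        return 1.0
    d = lo - value if value < lo else value - hi
    if sigma <= 0:
        return 0.0
    return math.exp(-d / sigma)


def membership_score(
    desc: DescriptorSet,
    cdef: ClassDefinition,
    opts: ClassifyOptions = ClassifyOptions(),
) -> float:
    """Score in [0, 1] of one profile against one class window set."""
    score, _ = _score_with_flags(desc, cdef, opts)
    return score


def _score_with_flags(
    desc: DescriptorSet, cdef: ClassDefinition, opts: ClassifyOptions
) -> tuple[float, dict]:
    axes = cdef.defined_axes()
    if not axes:
        raise ValueError(f"class {cdef.name!r} defines no axes")
    # nitrogen gates
    n = desc.nitrogen_count
    demote = 1.0
    if cdef.requires_nitrogen and n == 0:
        return 0.0, {}
    if n >= 1 and cdef.group != "nitrogenous":
        if opts.strict_nitrogen:
            return 0.0, {}
        demote = opts.nitrogen_demotion
    memberships = []
    inside: dict = {}
    for axis in axes:
        lo, hi = cdef.window(axis)
        v = _axis_value(desc, axis)
        m = _axis_membership(v, lo, hi, _axis_sigma(axis, opts))  # type: ignore[arg-type]
        memberships.append(m)
        inside[axis] = bool(lo <= v <= hi)  # type: ignore[operator]
    return demote * float(np.mean(memberships)), inside


def _is_half_integer(x: float) -> bool:
    twice = 2.0 * x
    return abs(twice - round(twice)) < 1e-9 and round(twice) % 2 == 1


def _tie_key(desc: DescriptorSet, cdef: ClassDefinition) -> tuple:
    dbe_mid = cdef.midpoint("dbe")
    c_mid = cdef.midpoint("c")
    return (
        abs(desc.dbe - dbe_mid) if dbe_mid is not None else math.inf,
        abs(desc.carbon_count - c_mid) if c_mid is not None else math.inf,
        cdef.name,
    )


def classify(
    desc: DescriptorSet,
    kb: KnowledgeBase | None = None,
    opts: ClassifyOptions = ClassifyOptions(),
) -> ClassAnnotation:
    """Annotate one descriptor profile with ranked candidate classes."""
    kb = kb if kb is not None else default_kb()
    if not kb.classes:
        raise ValueError("empty knowledge base")
    rationale: list[str] = []
    eligible = list(kb.classes)
    if _is_half_integer(desc.dbe):
        eligible = [c for c in eligible if c.group == "nitrogenous"]
        rationale.append(
            f"half-integer DBE {desc.dbe:g} (even-electron single-N ion "
            "signature): only nitrogenous classes considered"
        )
    scored = []
    for cdef in eligible:
        s, inside = _score_with_flags(desc, cdef, opts)
        scored.append((s, _tie_key(desc, cdef), cdef, inside))
    scored.sort(key=lambda t: (-t[0], t[1]))
    candidates = [
        CandidateScore(cdef.name, s, inside)
        for s, _, cdef, inside in scored[: opts.top_k]
        if s >= opts.min_score
    ]
    unclassified_reason = None
    if not candidates:
        if desc.nitrogen_count >= 1:
            unclassified_reason = (
                "nitrogenous, no alkaloid window matched (possibly an amino "
                "acid or other primary metabolite)"
            )
        else:
            unclassified_reason = (
                f"no class reached min_score {opts.min_score:g}"
            )
        rationale.append(unclassified_reason)
    else:
        top = candidates[0]
        rationale.append(
            f"top candidate {top.name} (score {top.score:.3f}; axes inside: "
            + ", ".join(a for a, ok in top.inside.items() if ok) + ")"
        )
    return ClassAnnotation(
        candidates=candidates,
        rationale=rationale,
        unclassified_reason=unclassified_reason,
    )


ANNOTATION_COLUMNS = [
    "formula", "mass", "hc", "oc", "dbe", "ai_mod", "c", "n",
    "top1_class", "top1_score", "candidates", "msi_level", "flags",
]


def classify_table(
    formulas,
    kb: KnowledgeBase | None = None,
    opts: ClassifyOptions = ClassifyOptions(),
    convention: str = "neutral",
) -> pd.DataFrame:
    """Annotate a sequence of formula strings; returns one row per input.

    Unparseable rows are flagged in the ``flags`` column and left
    unannotated rather than aborting the run; a run in which *every* row
    fails raises, with the per-row messages.
    """
    kb = kb if kb is not None else default_kb()
    rows = []
    errors: list[str] = []
    n_failed = 0
    formulas = list(formulas)
    for f in formulas:
        base = {c: "" for c in ANNOTATION_COLUMNS}
        base["formula"] = f
        base["msi_level"] = MSI_LEVEL
        try:
            desc = profile(f, convention)
        except Exception as e:  # parse or ratio error: isolate the row
            base["flags"] = f"error: {e}"
            errors.append(f"{f!r}: {e}")
            n_failed += 1
            rows.append(base)
            continue
        ann = classify(desc, kb, opts)
        base.update({
            "mass": desc.monoisotopic_mass,
            "hc": desc.hc_ratio,
            "oc": desc.oc_ratio,
            "dbe": desc.dbe,
            "ai_mod": desc.ai_mod,
            "c": desc.carbon_count,
            "n": desc.nitrogen_count,
            "top1_class": ann.top.name if ann.top else "unclassified",
            "top1_score": ann.top.score if ann.top else 0.0,
            "candidates": ";".join(
                f"{c.name}:{c.score:.4f}" for c in ann.candidates
            ),
            "flags": ann.unclassified_reason or "",
        })
        rows.append(base)
    if formulas and n_failed == len(formulas):
        raise ValueError(
            "no input row could be parsed: " + "; ".join(errors)
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


class VanKrevelenClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn estimator wrapping the range-membership annotator.

    ``X`` is a 1-d sequence of molecular formula strings (or a single
    column array).  ``fit`` validates the knowledge base and exposes
    ``classes_``; ``predict`` returns the top-candidate class name per
    formula (``"unclassified"`` when no class reaches ``min_score``);
    ``predict_candidates`` returns the full :class:`ClassAnnotation` list.
    The annotator is rule-based, so ``fit`` learns nothing from ``X``;
    it exists for pipeline and model-selection compatibility.
    """

    def __init__(
        self,
        kb: KnowledgeBase | None = None,
        top_k: int = 3,
        min_score: float = 0.5,
        strict_nitrogen: bool = True,
        sigma_ratio: float = 0.1,
        sigma_dbe: float = 1.0,
        sigma_carbon: float = 2.0,
        convention: str = "neutral",
    ):
        self.kb = kb
        self.top_k = top_k
        self.min_score = min_score
        self.strict_nitrogen = strict_nitrogen
        self.sigma_ratio = sigma_ratio
        self.sigma_dbe = sigma_dbe
        self.sigma_carbon = sigma_carbon
        self.convention = convention

    def _opts(self) -> ClassifyOptions:
        return ClassifyOptions(
            top_k=self.top_k,
            min_score=self.min_score,
            strict_nitrogen=self.strict_nitrogen,
            sigma_ratio=self.sigma_ratio,
            sigma_dbe=self.sigma_dbe,
            sigma_carbon=self.sigma_carbon,
        )

    def fit(self, X, y=None) -> "VanKrevelenClassifier":
        kb = self.kb if self.kb is not None else default_kb()
        if not kb.classes:
            raise ValueError("empty knowledge base")
        self.kb_ = kb
        self.classes_ = np.asarray(kb.names() + ["unclassified"], dtype=object)
        self.n_features_in_ = 1
        return self

    def _check_fitted(self):
        if not hasattr(self, "kb_"):
            raise RuntimeError("this VanKrevelenClassifier is not fitted yet")

    def predict_candidates(self, X) -> list[ClassAnnotation]:
        self._check_fitted()
        opts = self._opts()
        out = []
        for f in np.asarray(X, dtype=object).ravel():
            out.append(classify(profile(str(f), self.convention), self.kb_, opts))
        return out

    def predict(self, X) -> np.ndarray:
        anns = self.predict_candidates(X)
        return np.asarray(
            [a.top.name if a.top else "unclassified" for a in anns],
            dtype=object,
        )
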