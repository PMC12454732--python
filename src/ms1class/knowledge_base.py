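"""Built-in metabolite-class range windows and their JSON serialization.

Each :class:`ClassDefinition` holds optional [min, max] windows on four
descriptor axes — H/C, O/C, DBE and carbon count — plus a nitrogen
requirement.  Every individual bound carries a provenance tag:

* ``"paper"``   — a range printed in the source literature for that class;
* ``"derived"`` — reconstructed here from canonical member compounds
  (scaffolds plus common substituted/glycosylated forms), shipped as data
  in :data:`CANONICAL_MEMBERS` so the derivation is reproducible;
* ``"user"``    — loaded from a user knowledge-base file.

The built-in table covers seven phenolic classes, ten alkaloid subclasses
and three isoprenoid classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .descriptors import dbe as _dbe, elemental_ratios as _ratios
from .formula import parse_formula

__all__ = [
    "ClassDefinition",
    "KnowledgeBase",
    "KBValidationError",
    "CANONICAL_MEMBERS",
    "default_kb",
    "load_kb",
    "save_kb",
    "validate_kb",
    "KB_VERSION",
]

KB_VERSION = "1.0"

AXES = ("hc", "oc", "dbe", "c")

GROUPS = ("phenolic", "nitrogenous", "isoprenoid")


class KBValidationError(ValueError):
    """Raised for a structurally invalid knowledge base; carries all failures."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass(frozen=True)
class ClassDefinition:
    """One metabolite class's descriptor windows.

    Bounds are inclusive; ``None`` means the axis is not used for this
    class.  ``provenance`` maps bound names (``"hc_min"`` ... ``"c_max"``)
    to their tag.
    """

    name: str
    group: str
    hc_min: float | None = None
    hc_max: float | None = None
    oc_min: float | None = None
    oc_max: float | None = None
    dbe_min: float | None = None
    dbe_max: float | None = None
    c_min: float | None = None
    c_max: float | None = None
    requires_nitrogen: bool = False
    provenance: dict = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self):
        if self.group not in GROUPS:
            raise KBValidationError([f"{self.name}: unknown group {self.group!r}"])
        problems = []
        for axis in AXES:
            lo, hi = self.window(axis)
            if (lo is None) != (hi is None):
                problems.append(f"{self.name}: half-open {axis} window")
            if lo is not None and hi is not None and lo > hi:
                problems.append(f"{self.name}: {axis}_min {lo} > {axis}_max {hi}")
        if not self.defined_axes():
            problems.append(f"{self.name}: no bound pair defined")
        if problems:
            raise KBValidationError(problems)

    def window(self, axis: str) -> tuple[float | None, float | None]:
        return getattr(self, f"{axis}_min"), getattr(self, f"{axis}_max")

    def defined_axes(self) -> tuple[str, ...]:
        return tuple(a for a in AXES if self.window(a)[0] is not None)

    def midpoint(self, axis: str) -> float | None:
        lo, hi = self.window(axis)
        return None if lo is None else (lo + hi) / 2.0


@dataclass
class KnowledgeBase:
    """An ordered collection of class definitions with unique names."""

    classes: list[ClassDefinition]
    version: str = KB_VERSION
    source: str = "built-in"

    def __post_init__(self):
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise KBValidationError([f"duplicate class names: {dupes}"])

    def get(self, name: str) -> ClassDefinition:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(f"no class named {name!r} in knowledge base")

    def names(self) -> list[str]:
        return [c.name for c in self.classes]

    def by_group(self, group: str) -> list[ClassDefinition]:
        return [c for c in self.classes if c.group == group]


# ---------------------------------------------------------------------------
# Canonical member compounds used to derive ranges not printed in the source
# literature.  Ten or more members per class, spanning the bare scaffold and
# common hydroxylated / methoxylated / glycosylated forms.
# ---------------------------------------------------------------------------

CANONICAL_MEMBERS: dict[str, list[tuple[str, str]]] = {
    "phenolic_acid": [
        ("gallic acid", "C7H6O5"),
        ("protocatechuic acid", "C7H6O4"),
        ("4-hydroxybenzoic acid", "C7H6O3"),
        ("gentisic acid", "C7H6O4"),
        ("vanillic acid", "C8H8O4"),
        ("syringic acid", "C9H10O5"),
        ("methyl gallate", "C8H8O5"),
        ("caffeic acid", "C9H8O4"),
        ("ferulic acid", "C10H10O4"),
        ("p-coumaric acid", "C9H8O3"),
        ("sinapic acid", "C11H12O5"),
    ],
    "coumarin": [
        ("coumarin", "C9H6O2"),
        ("umbelliferone", "C9H6O3"),
        ("esculetin", "C9H6O4"),
        ("daphnetin", "C9H6O4"),
        ("scopoletin", "C10H8O4"),
        ("herniarin", "C10H8O3"),
        ("fraxetin", "C10H8O5"),
        ("psoralen", "C11H6O3"),
        ("bergapten", "C12H8O4"),
        ("esculin", "C15H16O9"),
    ],
    "stilbene": [
        ("trans-stilbene", "C14H12"),
        ("pinosylvin", "C14H12O2"),
        ("resveratrol", "C14H12O3"),
        ("piceatannol", "C14H12O4"),
        ("oxyresveratrol", "C14H12O4"),
        ("pterostilbene", "C16H16O4"),
        ("rhapontigenin", "C15H14O4"),
        ("isorhapontigenin", "C15H14O4"),
        ("piceid", "C20H22O8"),
        ("astringin", "C20H22O9"),
    ],
    "lignan": [
        ("pinoresinol", "C20H22O6"),
        ("matairesinol", "C20H22O6"),
        ("secoisolariciresinol", "C20H26O6"),
        ("lariciresinol", "C20H24O6"),
        ("sesamin", "C20H18O6"),
        ("hinokinin", "C20H18O6"),
        ("syringaresinol", "C22H26O8"),
        ("podophyllotoxin", "C22H22O8"),
        ("arctigenin", "C21H24O6"),
        ("enterolactone", "C18H18O4"),
    ],
    "anthraquinone": [
        ("9,10-anthraquinone", "C14H8O2"),
        ("alizarin", "C14H8O4"),
        ("quinizarin", "C14H8O4"),
        ("danthron", "C14H8O4"),
        ("purpurin", "C14H8O5"),
        ("chrysophanol", "C15H10O4"),
        ("emodin", "C15H10O5"),
        ("aloe-emodin", "C15H10O5"),
        ("physcion", "C16H12O5"),
        ("rhein", "C15H8O6"),
    ],
    "isoquinoline": [
        ("papaverine", "C20H21NO4"),
        ("morphine", "C17H19NO3"),
        ("codeine", "C18H21NO3"),
        ("thebaine", "C19H21NO3"),
        ("boldine", "C19H21NO4"),
        ("reticuline", "C19H23NO4"),
        ("canadine", "C20H21NO4"),
        ("tetrahydropalmatine", "C21H25NO4"),
        ("hydrastine", "C21H21NO6"),
        ("noscapine", "C22H23NO7"),
        ("emetine", "C29H40N2O4"),
    ],
    "indole": [
        ("tryptamine", "C10H12N2"),
        ("serotonin", "C10H12N2O"),
        ("harmine", "C13H12N2O"),
        ("harmaline", "C13H14N2O"),
        ("ibogaine", "C20H26N2O"),
        ("yohimbine", "C21H26N2O3"),
        ("ajmalicine", "C21H24N2O3"),
        ("vincamine", "C21H26N2O3"),
        ("strychnine", "C21H22N2O2"),
        ("brucine", "C23H26N2O4"),
        ("reserpine", "C33H40N2O9"),
    ],
    "quinolizidine": [
        ("lupinine", "C10H19NO"),
        ("epilupinine", "C10H19NO"),
        ("sparteine", "C15H26N2"),
        ("lupanine", "C15H24N2O"),
        ("anagyrine", "C15H20N2O"),
        ("thermopsine", "C15H20N2O"),
        ("cytisine", "C11H14N2O"),
        ("matrine", "C15H24N2O"),
        ("oxymatrine", "C15H24N2O2"),
        ("angustifoline", "C14H22N2O"),
    ],
    "tropane": [
        ("tropane", "C8H15N"),
        ("tropine", "C8H15NO"),
        ("tropinone", "C8H13NO"),
        ("atropine", "C17H23NO3"),
        ("littorine", "C17H23NO3"),
        ("scopolamine", "C17H21NO4"),
        ("anisodamine", "C17H23NO4"),
        ("cocaine", "C17H21NO4"),
        ("homatropine", "C16H21NO3"),
        ("tropacocaine", "C15H19NO2"),
    ],
    "quinoline": [
        ("quinoline", "C9H7N"),
        ("quinine", "C20H24N2O2"),
        ("quinidine", "C20H24N2O2"),
        ("cinchonine", "C19H22N2O"),
        ("cinchonidine", "C19H22N2O"),
        ("camptothecin", "C20H16N2O4"),
        ("dictamnine", "C12H9NO2"),
        ("skimmianine", "C14H13NO4"),
        ("kokusaginine", "C14H13NO4"),
        ("graveoline", "C17H13NO3"),
    ],
    "protoalkaloid": [
        ("tyramine", "C8H11NO"),
        ("N-methyltyramine", "C9H13NO"),
        ("hordenine", "C10H15NO"),
        ("2-phenylethylamine", "C8H11N"),
        ("synephrine", "C9H13NO2"),
        ("octopamine", "C8H11NO2"),
        ("ephedrine", "C10H15NO"),
        ("pseudoephedrine", "C10H15NO"),
        ("norephedrine", "C9H13NO"),
        ("cathine", "C9H13NO"),
        ("mescaline", "C11H17NO3"),
    ],
    "purine": [
        ("caffeine", "C8H10N4O2"),
        ("theobromine", "C7H8N4O2"),
        ("theophylline", "C7H8N4O2"),
        ("paraxanthine", "C7H8N4O2"),
        ("xanthine", "C5H4N4O2"),
        ("hypoxanthine", "C5H4N4O"),
        ("1-methylxanthine", "C6H6N4O2"),
        ("3-methylxanthine", "C6H6N4O2"),
        ("7-methylxanthine", "C6H6N4O2"),
        ("theacrine", "C9H12N4O3"),
    ],
    "pyrrolizidine": [
        ("retronecine", "C8H13NO2"),
        ("heliotridine", "C8H13NO2"),
        ("platynecine", "C8H15NO2"),
        ("senecionine", "C18H25NO5"),
        ("seneciphylline", "C18H23NO5"),
        ("retrorsine", "C18H25NO6"),
        ("monocrotaline", "C16H23NO6"),
        ("heliotrine", "C16H27NO5"),
        ("lycopsamine", "C15H25NO5"),
        ("echimidine", "C20H31NO7"),
    ],
    "piperidine": [
        ("piperidine", "C5H11N"),
        ("coniine", "C8H17N"),
        ("pelletierine", "C8H15NO"),
        ("sedamine", "C14H21NO"),
        ("anabasine", "C10H14N2"),
        ("piperine", "C17H19NO3"),
        ("piperlongumine", "C17H19NO5"),
        ("lobeline", "C22H27NO2"),
        ("lobelanine", "C22H25NO2"),
        ("solenopsin", "C17H35N"),
    ],
    "pyrrolidine": [
        ("pyrrolidine", "C4H9N"),
        ("N-methylpyrrolidine", "C5H11N"),
        ("hygrine", "C8H15NO"),
        ("hygroline", "C8H17NO"),
        ("cuscohygrine", "C13H24N2O"),
        ("nicotine", "C10H14N2"),
        ("nornicotine", "C9H12N2"),
        ("stachydrine", "C7H13NO2"),
        ("betonicine", "C7H13NO3"),
        ("codonopsine", "C14H21NO4"),
    ],
}


def _member_ranges(class_name: str) -> dict[str, tuple[float, float]]:
    """Observed (min, max) per axis over the canonical members of a class."""
    vals: dict[str, list[float]] = {a: [] for a in AXES}
    for _, f in CANONICAL_MEMBERS[class_name]:
        comp = parse_formula(f)
        hc, oc = _ratios(comp)
        vals["hc"].append(hc)
        vals["oc"].append(oc)
        vals["dbe"].append(_dbe(comp))
        vals["c"].append(float(comp.get("C", 0)))
    return {a: (min(v), max(v)) for a, v in vals.items()}


# per-class build recipe: axis -> ("paper", lo, hi) | ("derived",)
# mixed provenance within one axis is expressed with explicit bound tuples.
_P = "paper"
_D = "derived"


def _entry(name, group, axes, requires_nitrogen=False, notes="", overrides=None):
    """Assemble a ClassDefinition from paper windows + member-derived axes."""
    derived = _member_ranges(name) if any(v == _D for v in axes.values()) else {}
    kwargs: dict = {}
    prov: dict[str, str] = {}
    for axis, spec in axes.items():
        if spec == _D:
            lo, hi = derived[axis]
            tag_lo = tag_hi = _D
        else:
            tag, lo, hi = spec[0], spec[1], spec[2]
            tag_lo = tag_hi = tag
        kwargs[f"{axis}_min"], kwargs[f"{axis}_max"] = lo, hi
        prov[f"{axis}_min"], prov[f"{axis}_max"] = tag_lo, tag_hi
    for bound, (value, tag) in (overrides or {}).items():
        kwargs[bound] = value
        prov[bound] = tag
    return ClassDefinition(
        name=name, group=group, requires_nitrogen=requires_nitrogen,
        provenance=prov, notes=notes, **kwargs,
    )


def default_kb() -> KnowledgeBase:
    """The built-in knowledge base: 20 classes across the three major groups.

    Bounds printed in the source literature are reproduced verbatim and
    tagged ``"paper"``; axes described there only qualitatively are derived
    from :data:`CANONICAL_MEMBERS` and tagged ``"derived"``.
    """
    classes = [
        # ---- phenolics ----
        _entry("flavonoid", "phenolic", {
            "hc": (_P, 0.600, 1.692), "oc": (_P, 0.133, 0.750),
            "dbe": (_P, 7.0, 20.0), "c": (_P, 15.0, 25.0)},
            notes="DBE window is the union of the two printed ranges 9-20 "
                  "and 7-17; covers aglycone and glycosidic forms."),
        _entry("phenolic_acid", "phenolic", {
            "hc": _D, "oc": _D,
            "dbe": (_P, 5.0, 11.0), "c": (_P, 7.0, 11.0)},
            notes="DBE window is the union of the printed 5-11 and 5-7 "
                  "ranges; benzoic- and cinnamic-acid derivatives."),
        _entry("tannin", "phenolic", {
            "hc": (_P, 0.519, 0.917), "oc": (_P, 0.370, 0.500),
            "dbe": (_P, 14.0, 37.0)},
            overrides={"c_min": (30.0, _P), "c_max": (120.0, _D)},
            notes="Carbon described as '30 to over 100'; upper bound 120 "
                  "is a configurable cap."),
        _entry("coumarin", "phenolic", {
            "hc": _D, "oc": _D, "dbe": (_P, 7.0, 9.0), "c": _D}),
        _entry("stilbene", "phenolic", {
            "hc": _D, "oc": _D, "dbe": (_P, 9.0, 10.0), "c": _D}),
        _entry("lignan", "phenolic", {
            "hc": _D, "oc": _D, "dbe": (_P, 8.0, 17.0), "c": _D}),
        _entry("anthraquinone", "phenolic", {
            "hc": _D, "oc": _D, "dbe": (_P, 11.0, 13.0), "c": _D},
            notes="Covers the quinone class of the phenolic group; the "
                  "literature uses 'quinones' and 'anthraquinones' "
                  "interchangeably for these tricyclic cores."),
        # ---- alkaloids (nitrogenous) ----
        _entry("isoquinoline", "nitrogenous", {
            "hc": (_P, 0.44, 1.38), "oc": (_P, 0.00, 0.33),
            "dbe": (_P, 6.0, 14.0), "c": _D}, requires_nitrogen=True),
        _entry("indole", "nitrogenous", {
            "hc": _D, "oc": _D, "dbe": (_P, 6.5, 19.5), "c": _D},
            requires_nitrogen=True),
        _entry("quinolizidine", "nitrogenous", {
            "hc": _D, "oc": _D, "dbe": (_P, 4.5, 7.0), "c": _D},
            requires_nitrogen=True),
        _entry("tropane", "nitrogenous", {
            "hc": _D, "oc": _D, "dbe": (_P, 2.0, 8.5), "c": _D},
            requires_nitrogen=True),
        _entry("quinoline", "nitrogenous", {
            "hc": _D, "oc": _D, "dbe": (_P, 9.0, 10.0), "c": _D},
            requires_nitrogen=True),
        _entry("protoalkaloid", "nitrogenous", {
            "hc": _D, "oc": _D, "dbe": (_P, 5.5, 6.5), "c": _D},
            requires_nitrogen=True),
        _entry("purine", "nitrogenous", {
            "hc": _D, "oc": _D, "dbe": (_P, 6.0, 7.0), "c": _D},
            requires_nitrogen=True),
        _entry("pyrrolizidine", "nitrogenous", {
            "hc": _D, "oc": _D, "dbe": (_P, 6.5, 7.5), "c": _D},
            requires_nitrogen=True),
        _entry("piperidine", "nitrogenous", {
            "hc": (_P, 1.06, 2.13), "oc": _D,
            "dbe": (_P, 1.5, 6.5), "c": _D}, requires_nitrogen=True),
        _entry("pyrrolidine", "nitrogenous", {
            "hc": _D, "oc": _D, "dbe": (_P, 5.5, 8.5), "c": _D},
            requires_nitrogen=True),
        # ---- isoprenoids ----
        _entry("steroid", "isoprenoid", {
            "hc": (_P, 0.647, 1.704), "oc": (_P, 0.000, 0.250),
            "dbe": (_P, 5.0, 10.0)},
            overrides={"c_min": (10.0, _D), "c_max": (28.0, _P)},
            notes="Described as fewer than 29 carbons; lower bound 10 "
                  "excludes trivially small molecules."),
        _entry("triterpene", "isoprenoid", {
            "hc": (_P, 1.154, 1.733), "oc": (_P, 0.033, 0.308),
            "dbe": (_P, 5.0, 12.0), "c": (_P, 30.0, 30.0)},
            notes="Triterpenes consistently contain 30 carbon atoms."),
        _entry("saponin", "isoprenoid", {
            "hc": (_P, 1.476, 1.704), "oc": (_P, 0.074, 0.518),
            "dbe": (_P, 7.0, 13.0), "c": (_P, 35.0, 60.0)}),
    ]
    return KnowledgeBase(classes=classes, version=KB_VERSION, source="built-in")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    """Write a knowledge base to a JSON document (schema in docs/kb.schema.json)."""
    doc = {
        "version": kb.version,
        "source": kb.source,
        "classes": [
            {k: v for k, v in asdict(c).items()} for c in kb.classes
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


_CLASS_FIELDS = {
    "name", "group", "hc_min", "hc_max", "oc_min", "oc_max",
    "dbe_min", "dbe_max", "c_min", "c_max", "requires_nitrogen",
    "provenance", "notes",
}


def load_kb(path: str | Path) -> KnowledgeBase:
    """Load and validate a knowledge base from JSON.

    All schema violations are collected and reported together, with the
    path of each offending field.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise KBValidationError([f"malformed JSON: {e}"]) from e
    problems: list[str] = []
    if not isinstance(doc, dict):
        raise KBValidationError(["top-level document must be a JSON object"])
    if "classes" not in doc:
        raise KBValidationError(["missing required key 'classes'"])
    if not isinstance(doc["classes"], list):
        raise KBValidationError(["'classes' must be a list"])
    classes: list[ClassDefinition] = []
    for i, raw in enumerate(doc["classes"]):
        where = f"classes[{i}]"
        if not isinstance(raw, dict):
            problems.append(f"{where}: must be an object")
            continue
        unknown = set(raw) - _CLASS_FIELDS
        if unknown:
            problems.append(f"{where}: unknown fields {sorted(unknown)}")
        missing = {"name", "group"} - set(raw)
        if missing:
            problems.append(f"{where}: missing fields {sorted(missing)}")
            continue
        kwargs = {k: raw[k] for k in _CLASS_FIELDS if k in raw}
        kwargs.setdefault("provenance", {})
        for axis in AXES:  # bounds without an explicit tag default to "user"
            for bound in (f"{axis}_min", f"{axis}_max"):
                if kwargs.get(bound) is not None:
                    kwargs["provenance"].setdefault(bound, "user")
        try:
            classes.append(ClassDefinition(**kwargs))
        except KBValidationError as e:
            problems.extend(f"{where}: {p}" for p in e.problems)
    if problems:
        raise KBValidationError(problems)
    try:
        return KnowledgeBase(
            classes=classes,
            version=str(doc.get("version", KB_VERSION)),
            source=str(doc.get("source", str(path))),
        )
    except KBValidationError as e:
        raise KBValidationError([f"classes: {p}" for p in e.problems]) from e


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def _overlap_fraction(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Intersection length relative to the narrower window (1.0 = nested)."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    if lo > hi:
        return 0.0
    inter = hi - lo
    narrow = min(a[1] - a[0], b[1] - b[0])
    if narrow <= 0:
        return 1.0  # a point window inside the other
    return inter / narrow


def validate_kb(kb: KnowledgeBase) -> list[dict]:
    """Report window overlaps between classes of the same group.

    Returns one diagnostic per (class pair, axis) with a nonzero overlap:
    ``{"class_a", "class_b", "axis", "overlap_fraction", "a_window",
    "b_window", "message"}``.  Overlaps are expected in this chemical
    space (several classes partially converge); they flag where the
    classifier must fall back on the other axes and the tie-breakers.
    """
    diagnostics: list[dict] = []
    for group in GROUPS:
        members = kb.by_group(group)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                for axis in AXES:
                    wa, wb = a.window(axis), b.window(axis)
                    if wa[0] is None or wb[0] is None:
                        continue
                    frac = _overlap_fraction(wa, wb)  # type: ignore[arg-type]
                    if frac > 0:
                        diagnostics.append({
                            "class_a": a.name,
                            "class_b": b.name,
                            "axis": axis,
                            "overlap_fraction": frac,
                            "a_window": wa,
                            "b_window": wb,
                            "message": (
                                f"{a.name}/{b.name}: {axis} windows overlap "
                                f"({wa[0]:g}-{wa[1]:g} vs {wb[0]:g}-{wb[1]:g}, "
                                f"fraction {frac:.2f})"
                            ),
                        })
    return diagnostics
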