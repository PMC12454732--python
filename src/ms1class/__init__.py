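"""ms1class: class-level annotation of specialized metabolites from MS1 data.

Annotates molecular formulas (or accurate MS1 masses) with natural-product
class candidates — phenolics, alkaloid subclasses, isoprenoids — using
formula-derived descriptors: Van Krevelen H/C and O/C ratios, the double
bond equivalent (DBE), the modified aromaticity index, and carbon count.
Annotations are class-level (MSI Level 3) by construction.
"""

from .adducts import (
    ADDUCTS,
    Adduct,
    IonSpecies,
    apply_adduct,
    get_adduct,
    ion_mz,
    neutral_mass_from_mz,
    neutralize,
)
from .assign import (
    ElementBounds,
    FilterOptions,
    FormulaCandidate,
    PeakRecord,
    assign_peaks,
    enumerate_formulas,
)
from .classify import (
    ClassAnnotation,
    ClassifyOptions,
    VanKrevelenClassifier,
    classify,
    classify_table,
    membership_score,
)
from .descriptors import (
    DescriptorCalculator,
    DescriptorSet,
    ai_mod,
    dbe,
    elemental_ratios,
    profile,
)
from .formula import (
    ElementComposition,
    FormulaError,
    format_formula,
    monoisotopic_mass,
    parse_formula,
)
from .knowledge_base import (
    ClassDefinition,
    KnowledgeBase,
    default_kb,
    load_kb,
    save_kb,
    validate_kb,
)
from .synthetic import (
    SyntheticRecord,
    UnsatisfiableWindowError,
    generate_class_formulas,
    generate_peaklist,
)
from .viz import PlotDataset, dbe_distribution, render, vk_points

__version__ = "0.1.0"

__all__ = [
    "ADDUCTS", "Adduct", "IonSpecies", "apply_adduct", "get_adduct",
    "ion_mz", "neutral_mass_from_mz", "neutralize",
    "ElementBounds", "FilterOptions", "FormulaCandidate", "PeakRecord",
    "assign_peaks", "enumerate_formulas",
    "ClassAnnotation", "ClassifyOptions", "VanKrevelenClassifier",
    "classify", "classify_table", "membership_score",
    "DescriptorCalculator", "DescriptorSet", "ai_mod", "dbe",
    "elemental_ratios", "profile",
    "ElementComposition", "FormulaError", "format_formula",
    "monoisotopic_mass", "parse_formula",
    "ClassDefinition", "KnowledgeBase", "default_kb", "load_kb",
    "save_kb", "validate_kb",
    "SyntheticRecord", "UnsatisfiableWindowError",
    "generate_class_formulas", "generate_peaklist",
    "PlotDataset", "dbe_distribution", "render", "vk_points",
    "__version__",
]
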