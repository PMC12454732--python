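"""Knowledge-base table integrity, serialization and overlap diagnostics."""

import json

import pytest

from ms1class import (
    ClassDefinition,
    KnowledgeBase,
    default_kb,
    load_kb,
    save_kb,
    validate_kb,
)
from ms1class.descriptors import dbe as _dbe, elemental_ratios as _ratios
from ms1class.formula import parse_formula
from ms1class.knowledge_base import CANONICAL_MEMBERS, KBValidationError


def test_default_kb_shape(kb):
    assert len(kb.classes) == 20
    assert len(kb.by_group("phenolic")) == 7
    assert len(kb.by_group("nitrogenous")) == 10
    assert len(kb.by_group("isoprenoid")) == 3
    for c in kb.classes:
        assert c.requires_nitrogen == (c.group == "nitrogenous")


def test_selected_windows(kb):
    flav = kb.get("flavonoid")
    assert (flav.oc_min, flav.oc_max) == (0.133, 0.750)
    sap = kb.get("saponin")
    assert (sap.oc_min, sap.oc_max) == (0.074, 0.518)
    tan = kb.get("tannin")
    assert (tan.dbe_min, tan.dbe_max) == (14.0, 37.0)


def test_derived_bounds_cover_their_members(kb):
    """Every canonical member lies inside its class's derived H/C, O/C, C bounds."""
    for name, members in CANONICAL_MEMBERS.items():
        cdef = kb.get(name)
        for _, f in members:
            comp = parse_formula(f)
            hc, oc = _ratios(comp)
            vals = {"hc": hc, "oc": oc, "c": comp.get("C", 0)}
            for axis, v in vals.items():
                lo, hi = cdef.window(axis)
                if lo is not None and cdef.provenance.get(f"{axis}_min") == "derived":
                    assert lo <= v + 1e-12, (name, f, axis)
                if hi is not None and cdef.provenance.get(f"{axis}_max") == "derived":
                    assert v <= hi + 1e-12, (name, f, axis)


def test_member_formulas_parse_and_alkaloids_have_nitrogen(kb):
    for name, members in CANONICAL_MEMBERS.items():
        group = kb.get(name).group
        assert len(members) >= 10
        for _, f in members:
            comp = parse_formula(f)
            if group == "nitrogenous":
                assert comp.get("N", 0) >= 1, (name, f)
            else:
                assert comp.get("N", 0) == 0, (name, f)


def test_save_load_roundtrip(kb, tmp_path):
    path = tmp_path / "kb.json"
    save_kb(kb, path)
    assert load_kb(path) == kb


def test_load_reports_all_violations(tmp_path):
    doc = {
        "version": "x", "source": "test",
        "classes": [
            {"name": "bad1", "group": "phenolic", "dbe_min": 10, "dbe_max": 9},
            {"name": "bad1", "group": "phenolic", "dbe_min": 1, "dbe_max": 2},
        ],
    }
    p = tmp_path / "bad.json"
    p.write_text(json.dumps(doc))
    with pytest.raises(KBValidationError) as e:
        load_kb(p)
    assert "dbe_min" in str(e.value)

    p2 = tmp_path / "nokey.json"
    p2.write_text(json.dumps({"version": "x"}))
    with pytest.raises(KBValidationError, match="classes"):
        load_kb(p2)

    p3 = tmp_path / "garbage.json"
    p3.write_text("{not json")
    with pytest.raises(KBValidationError, match="malformed"):
        load_kb(p3)


def test_duplicate_class_names_rejected():
    c = ClassDefinition(name="a", group="phenolic", dbe_min=1.0, dbe_max=2.0)
    with pytest.raises(KBValidationError, match="duplicate"):
        KnowledgeBase(classes=[c, c])


def test_class_definition_invariants():
    with pytest.raises(KBValidationError):
        ClassDefinition(name="x", group="phenolic")  # no bound pair at all
    with pytest.raises(KBValidationError):
        ClassDefinition(name="x", group="phenolic", hc_min=2.0, hc_max=1.0)
    with pytest.raises(KBValidationError):
        ClassDefinition(name="x", group="nope", dbe_min=1.0, dbe_max=2.0)


def test_overlap_diagnostics(kb):
    diags = validate_kb(kb)
    # lignan DBE 8-17 nested inside flavonoid 7-20
    hit = [d for d in diags
           if {d["class_a"], d["class_b"]} == {"flavonoid", "lignan"} and d["axis"] == "dbe"]
    assert hit and hit[0]["overlap_fraction"] == pytest.approx(1.0)
    # triterpene vs steroid H/C windows intersect over 1.154-1.704
    hit = [d for d in diags
           if {d["class_a"], d["class_b"]} == {"triterpene", "steroid"} and d["axis"] == "hc"]
    assert hit
    frac = (1.704 - 1.154) / min(1.704 - 0.647, 1.733 - 1.154)
    assert hit[0]["overlap_fraction"] == pytest.approx(frac)


def test_single_class_kb_has_no_overlaps():
    c = ClassDefinition(name="only", group="phenolic", dbe_min=1.0, dbe_max=2.0)
    assert validate_kb(KnowledgeBase(classes=[c])) == []


def test_scaffold_dbe_matches_printed_lower_bounds(kb):
    """Bare scaffolds sit at the lower edge of their class DBE windows."""
    for name, formula in [("coumarin", "C9H6O2"), ("stilbene", "C14H12")]:
        cdef = kb.get(name)
        assert _dbe(parse_formula(formula)) == cdef.dbe_min
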