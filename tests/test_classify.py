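"""Range-membership scoring, ranking, gates and the sklearn estimator."""

import numpy as np
import pytest

from ms1class import (
    ClassifyOptions,
    KnowledgeBase,
    VanKrevelenClassifier,
    classify,
    classify_table,
    membership_score,
    profile,
)
from ms1class.knowledge_base import ClassDefinition


def test_full_window_membership_is_exactly_one(kb):
    q = profile("C15H10O7")  # quercetin: inside all four flavonoid windows
    assert membership_score(q, kb.get("flavonoid")) == 1.0


def test_partial_membership_hard_and_soft(kb):
    q = profile("C15H10O7")
    tri = kb.get("triterpene")
    hard = ClassifyOptions(sigma_ratio=0.0, sigma_dbe=0.0, sigma_carbon=0.0)
    # only DBE (11 in [5, 12]) of the four triterpene axes contains quercetin
    assert membership_score(q, tri, hard) == pytest.approx(0.25)
    soft = membership_score(q, tri)
    assert 0.25 < soft < 0.5


def test_lupeol_is_triterpene(kb):
    ann = classify(profile("C30H50O"), kb)
    assert ann.top.name == "triterpene"
    assert ann.top.score == 1.0
    assert ann.msi_level == "3"


def test_caffeine_is_purine(kb):
    ann = classify(profile("C8H10N4O2"), kb)
    assert ann.top.name == "purine"
    assert ann.top.score == 1.0


def test_methane_unclassified(kb):
    ann = classify(profile("CH4"), kb)
    assert ann.candidates == []
    assert ann.unclassified_reason is not None


def test_score_bounded_and_sorted(kb):
    opts = ClassifyOptions(top_k=20, min_score=0.0)
    ann = classify(profile("C15H10O7"), kb, opts)
    scores = [c.score for c in ann.candidates]
    assert all(0.0 <= s <= 1.0 for s in scores)
    assert scores == sorted(scores, reverse=True)


def test_nitrogen_gate_is_bidirectional(kb):
    # no alkaloid candidate for a nitrogen-free profile
    for f in ("C15H10O7", "C30H50O", "C9H6O2"):
        ann = classify(profile(f), kb, ClassifyOptions(top_k=20, min_score=0.0))
        nitro = {c.name for c in kb.by_group("nitrogenous")}
        assert all(c.score == 0.0 for c in ann.candidates if c.name in nitro)
    # strict mode: no phenolic/isoprenoid candidate for a nitrogenous profile
    ann = classify(profile("C8H10N4O2"), kb, ClassifyOptions(top_k=30, min_score=0.0))
    non_nitro = {c.name for c in kb.classes if c.group != "nitrogenous"}
    assert all(c.score == 0.0 for c in ann.candidates if c.name in non_nitro)


def test_non_strict_mode_demotes_instead_of_excluding(kb):
    opts = ClassifyOptions(strict_nitrogen=False, top_k=30, min_score=0.0)
    ann = classify(profile("C8H10N4O2"), kb, opts)
    by_name = {c.name: c.score for c in ann.candidates}
    # caffeine still tops out as an alkaloid, but phenolics score > 0 now
    assert ann.top.name == "purine"
    assert any(s > 0 for n, s in by_name.items()
               if kb.get(n).group != "nitrogenous")


def test_half_integer_dbe_restricts_to_alkaloids(kb):
    # protonated tropane as an intact-ion profile: DBE 1.5
    ann = classify(profile("C8H16N", convention="ion"), kb,
                   ClassifyOptions(top_k=30, min_score=0.0))
    assert any("half-integer" in line for line in ann.rationale)
    names = {c.name for c in ann.candidates}
    assert names <= {c.name for c in kb.by_group("nitrogenous")}


def test_empty_kb_is_an_error(kb):
    with pytest.raises(Exception):
        classify(profile("C6H6"), KnowledgeBase(classes=[]))


def test_tie_break_prefers_nearest_dbe_midpoint(kb):
    # caffeine scores 1.0 for purine and piperidine alike; purine's DBE
    # midpoint (6.5) is nearer to 6 than piperidine's (4.0)
    ann = classify(profile("C8H10N4O2"), kb, ClassifyOptions(top_k=5, min_score=0.99))
    names = [c.name for c in ann.candidates]
    assert names.index("purine") < names.index("piperidine")


def test_classify_table_roundtrip(kb):
    df = classify_table(["C15H10O7", "C30H50O", "C8H10N4O2"], kb)
    assert list(df["top1_class"]) == ["flavonoid", "triterpene", "purine"]
    assert set(df["msi_level"]) == {"3"}
    assert df["dbe"].tolist() == [11.0, 6.0, 6.0]


def test_classify_table_isolates_bad_rows(kb):
    df = classify_table(["C15H10O7", "notaformula", "C30H50O"], kb)
    assert len(df) == 3
    assert df.loc[1, "flags"].startswith("error")
    assert df.loc[0, "top1_class"] == "flavonoid"
    assert df.loc[2, "top1_class"] == "triterpene"


def test_classify_table_all_bad_raises(kb):
    with pytest.raises(ValueError, match="no input row"):
        classify_table(["nope", "alsonope"], kb)


def test_classify_table_empty_input(kb):
    df = classify_table([], kb)
    assert len(df) == 0
    assert "top1_class" in df.columns


def test_classify_table_deterministic(kb):
    rows = ["C15H10O7", "C30H50O", "C8H10N4O2", "C9H6O2", "C14H12"] * 3
    a = classify_table(rows, kb)
    b = classify_table(rows, kb)
    assert a.equals(b)


def test_sklearn_estimator_api(kb):
    from sklearn.base import clone
    from sklearn.pipeline import Pipeline

    clf = VanKrevelenClassifier(top_k=2)
    clone(clf)  # get_params/set_params contract
    clf.fit(["C6H6"])
    assert "flavonoid" in clf.classes_
    pred = clf.predict(["C15H10O7", "CH4"])
    assert list(pred) == ["flavonoid", "unclassified"]
    anns = clf.predict_candidates(["C8H10N4O2"])
    assert anns[0].top.name == "purine"
    # composes in a pipeline (identity passthrough ahead of it)
    pipe = Pipeline([("clf", VanKrevelenClassifier())]).fit(["C6H6"])
    assert pipe.predict(["C30H50O"])[0] == "triterpene"


def test_score_error_for_axisless_class(kb):
    with pytest.raises(Exception):
        ClassDefinition(name="empty", group="phenolic")
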