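"""Pattern-matching classifier: normalization, guard, precedence,
conflict handling, per-patient resolution, and oracle equivalence."""
import datetime as dt
import re

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from emrsmoke import (
    PatternLexicon,
    RiskFactorRecord,
    classify_corpus,
    classify_record,
    latest_status,
    match_field,
    normalize_text,
)
from emrsmoke.classifier import NEGATION_CATEGORIES, FIELD_ORDER


# --------------------------------------------------------------------------
# normalization

@pytest.mark.parametrize(
    "raw,expected",
    [
        ("  Smoker: QUIT ", "smoker: quit"),
        ("", ""),
        ("a\t b\n c", "a b c"),
        ("Émigré Café", "émigré café"),  # accents preserved
    ],
)
def test_normalize_examples(raw, expected):
    assert normalize_text(raw) == expected


@given(st.text(max_size=60))
def test_normalize_idempotent(s):
    assert normalize_text(normalize_text(s)) == normalize_text(s)


# --------------------------------------------------------------------------
# field matching

@pytest.mark.parametrize(
    "text,expected",
    [
        ("non-smoker", {"not_current"}),
        ("father smokes 2ppd", set()),  # relationship guard
        ("blister pack meds", set()),  # no pattern fires
        ("never", {"never"}),
        ("smoker: quit", {"past"}),  # cessation outranks affirmative
        ("ex-smoker", {"past"}),
        ("up to 2ppd", {"current"}),  # letter boundary: ppd inside 2ppd
        ("smokes socially", {"current"}),
        ("never smoked, quit 2010", {"never", "past"}),  # real conflict
        ("", set()),
    ],
)
def test_match_field(text, expected, lexicon):
    assert match_field(normalize_text(text), lexicon) == expected


def _rec(status="", value="", name="Smoking", date=None):
    return RiskFactorRecord("p1", date, name, value, status)


# --------------------------------------------------------------------------
# record classification

@pytest.mark.parametrize(
    "record,status,decisive,conflict",
    [
        # cross-field conflict: Status precedence wins, flagged for audit
        (_rec(status="Current", value="non smoker"), "current", "status", True),
        # bare risk-factor name carries no status
        (_rec(), "unknown", "none", False),
        (_rec(status="never"), "never", "status", False),
        # intra-field resolution: quit-type outranks smoker-type
        (_rec(value="smoker: quit"), "past", "value", False),
        # intra-field multi-match among cessation categories -> unknown
        (_rec(value="never smoked, quit 2010"), "unknown", "value", True),
        # guard nullifies the field, lower-precedence field decides
        (_rec(status="husband smokes", value="quit 1999"), "past", "value", False),
    ],
)
def test_classify_record(record, status, decisive, conflict, lexicon):
    cr = classify_record(record, lexicon)
    assert cr.calculated_status == status
    assert cr.decisive_field == decisive
    assert cr.conflict_flag == conflict


_WORDS = st.sampled_from(
    ["current", "smoker", "quit", "never", "non-smoker", "yes", "no",
     "blister pack", "1 ppd", "", "tobacco", "socially", "assessment"]
)
_TEXT = st.lists(_WORDS, max_size=3).map(" ".join)


@given(status=st.sampled_from(["current", "never", "quit", "non smoker"]),
       value=_TEXT, name=_TEXT)
def test_status_field_dominance(status, value, name, lexicon):
    """When the Status field alone resolves to one category, the other
    fields can never change the outcome."""
    baseline = classify_record(_rec(status=status), lexicon)
    assert len(match_field(normalize_text(status), lexicon)) == 1
    perturbed = classify_record(_rec(status=status, value=value, name=name), lexicon)
    assert perturbed.calculated_status == baseline.calculated_status
    assert perturbed.decisive_field == "status"


@given(value=_TEXT, name=_TEXT,
       kin=st.sampled_from(["aunt", "father", "mother", "husband"]))
def test_guard_equals_blanked_field(value, name, kin, lexicon):
    """Inserting a relationship word into a field removes that field's
    influence: classification equals the record with the field blanked."""
    with_kin = classify_record(
        _rec(status="", value=f"{kin} {value}".strip(), name=name), lexicon
    )
    blanked = classify_record(_rec(status="", value="", name=name), lexicon)
    assert with_kin.calculated_status == blanked.calculated_status


@given(status=_TEXT, value=_TEXT, name=_TEXT)
def test_totality_and_zero_multi_rule(status, value, name, lexicon):
    """Every record gets exactly one of the five statuses; zero matches
    everywhere means unknown with no decisive field."""
    cr = classify_record(_rec(status=status, value=value, name=name), lexicon)
    assert cr.calculated_status in (
        "current", "past", "never", "not_current", "unknown"
    )
    cands = [match_field(normalize_text(t), lexicon) for t in (status, value, name)]
    if all(len(c) == 0 for c in cands):
        assert cr.calculated_status == "unknown"
        assert cr.decisive_field == "none"


# --------------------------------------------------------------------------
# oracle equivalence on a hand-labelled corpus

FIXTURE = [
    # (status_text, value_text, name_text, expected)
    ("current", "", "Smoking", "current"),
    ("smoker", "", "Smoking", "current"),
    ("", "up to 2ppd", "Smoking", "current"),
    ("", "smokes socially", "Smoking", "current"),
    ("", "yes", "Smoking", "current"),
    ("", "3 packs/day", "Smoking", "current"),
    ("past", "", "Smoking", "past"),
    ("", "smoker: quit", "Smoking", "past"),
    ("", "quit 2014", "Smoking", "past"),
    ("ex-smoker", "", "Smoking", "past"),
    ("", "former smoker", "Smoking", "past"),
    ("never", "", "Smoking", "never"),
    ("", "never smoked", "Smoking", "never"),
    ("", "never a smoker", "Smoking", "never"),
    ("non-smoker", "", "Smoking", "not_current"),
    ("", "non smoker", "Smoking", "not_current"),
    ("", "no", "Smoking", "not_current"),
    ("not current", "", "Smoking", "not_current"),
    ("", "father smokes", "Smoking", "unknown"),
    ("aunt is a smoker", "", "Smoking", "unknown"),
    ("", "blister pack medications", "Smoking", "unknown"),
    ("", "tobacco use assessment", "Smoking", "unknown"),
    ("", "etoh socially, poor diet", "Unknown", "unknown"),
    ("", "", "Smoking", "unknown"),
    ("Current", "non smoker", "Smoking", "current"),  # cross-field conflict
    ("", "never smoked, quit 2010", "Smoking", "unknown"),  # intra-field
]


def _oracle(status, value, name, lexicon):
    """Brute-force reference matcher: test every pattern against every
    field with the same letter-boundary rule, apply the guard, the
    negation-over-affirmative suppression, then field precedence."""
    def cats(text):
        t = normalize_text(text)
        if not t:
            return set()
        for w in lexicon.relationship_words:
            if re.search(rf"(?<![a-z]){re.escape(w)}(?![a-z])", t):
                return set()
        got = set()
        for cat, pats in lexicon.patterns.items():
            for p in pats:
                if re.search(rf"(?<![a-z]){re.escape(p)}(?![a-z])", t):
                    got.add(cat)
        if "current" in got and got & NEGATION_CATEGORIES:
            got.discard("current")
        return got

    for text in (status, value, name):
        c = cats(text)
        if len(c) == 1:
            return next(iter(c))
        if len(c) >= 2:
            return "unknown"
    return "unknown"


def test_fixture_corpus_against_oracle(lexicon):
    for status, value, name, expected in FIXTURE:
        cr = classify_record(_rec(status=status, value=value, name=name), lexicon)
        assert cr.calculated_status == expected, (status, value, name)
        assert _oracle(status, value, name, lexicon) == expected


@given(status=_TEXT, value=_TEXT, name=_TEXT)
def test_oracle_equivalence_fuzzed(status, value, name, lexicon):
    cr = classify_record(_rec(status=status, value=value, name=name), lexicon)
    assert cr.calculated_status == _oracle(status, value, name, lexicon)


# --------------------------------------------------------------------------
# per-patient resolution

def _classified(date, status, lexicon=None):
    text = {"current": "current", "past": "past", "never": "never",
            "unknown": ""}[status]
    rec = _rec(status=text, date=date)
    lex = lexicon or PatternLexicon.default()
    return classify_record(rec, lex)


class TestLatestStatus:
    def test_max_date_rule(self, lexicon):
        recs = [_classified(dt.date(2015, 1, 1), "current", lexicon),
                _classified(dt.date(2018, 1, 1), "past", lexicon)]
        assert latest_status(recs) == "past"

    def test_tie_prefers_informative(self, lexicon):
        recs = [_classified(dt.date(2018, 1, 1), "unknown", lexicon),
                _classified(dt.date(2018, 1, 1), "never", lexicon)]
        # verified against brute-force enumeration of both orderings
        assert latest_status(recs) == "never"
        assert latest_status(recs[::-1]) == "never"

    def test_single_record_identity(self, lexicon):
        assert latest_status([_classified(dt.date(2017, 1, 1), "current",
                                          lexicon)]) == "current"

    def test_undated_sorts_before_dated(self, lexicon):
        recs = [_classified(None, "current", lexicon),
                _classified(dt.date(2010, 1, 1), "never", lexicon)]
        assert latest_status(recs) == "never"

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            latest_status([])


# --------------------------------------------------------------------------
# corpus level

def test_classify_corpus_statuses_and_audit(lexicon):
    rf = pd.DataFrame(
        {
            "patient_id": ["a", "a", "b", "c"],
            "entry_date": [dt.date(2015, 1, 1), dt.date(2017, 1, 1),
                           dt.date(2016, 5, 1), dt.date(2016, 6, 1)],
            "name_text": ["Smoking"] * 4,
            "value_text": ["", "quit 2016", "never smoked", "mother smokes"],
            "status_text": ["current", "", "", ""],
        }
    )
    statuses, audit = classify_corpus(rf, lexicon)
    got = statuses.set_index("patient_id")["smoking"]
    assert got["a"] == "past"  # most recent record wins
    assert got["b"] == "never"
    assert got["c"] == "unknown"  # relationship distractor
    assert len(audit) == 4
    assert set(audit.columns) >= {"calculated_status", "decisive_field",
                                  "conflict_flag"}


def test_classify_corpus_deterministic(lexicon):
    rf = pd.DataFrame(
        {
            "patient_id": ["a", "b"],
            "entry_date": [dt.date(2017, 1, 1)] * 2,
            "name_text": ["Smoking"] * 2,
            "value_text": ["smoker: quit", "1 ppd"],
            "status_text": ["", ""],
        }
    )
    s1, a1 = classify_corpus(rf, lexicon)
    s2, a2 = classify_corpus(rf, lexicon)
    pd.testing.assert_frame_equal(s1, s2)
    pd.testing.assert_frame_equal(a1, a2)


def test_lexicon_invariants():
    with pytest.raises(ValueError, match="relationship_words"):
        PatternLexicon(
            patterns={"current": ["x"], "past": ["y"], "never": ["z"],
                      "not_current": ["w"]},
            relationship_words=[],
        )
    with pytest.raises(ValueError, match="no patterns"):
        PatternLexicon(
            patterns={"current": [], "past": ["y"], "never": ["z"],
                      "not_current": ["w"]},
            relationship_words=["aunt"],
        )
    with pytest.raises(ValueError, match="duplicate"):
        PatternLexicon(
            patterns={"current": ["x", "X"], "past": ["y"], "never": ["z"],
                      "not_current": ["w"]},
            relationship_words=["aunt"],
        )
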