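"""Rule-based pattern-matching classifier for free-text smoking records.

Each risk-factor record carries three free-text fields (Status, Value,
Name).  The classifier evaluates them in that precedence order: the
first field whose pattern matches resolve to exactly one category fixes
the calculated status; a field whose matches resolve to two or more
distinct categories yields ``unknown`` (intra-field conflict) and stops;
if no field matches anything the record is ``unknown`` with no decisive
field.  A field containing a kinship term ("father smokes 2ppd") is
treated as non-informative, because such text is family history, not
the patient's own status.

Intra-field conflict resolution
-------------------------------
Affirmative smoking mentions are routinely modified by cessation or
negation wording in the same field ("ex-smoker", "smoker: quit",
"non-smoker").  A raw multi-match rule would send all of these to
``unknown``, so before the zero/multi rule is applied, a match for the
``current`` category is suppressed whenever a cessation/negation
category (``past``, ``never``, ``not_current``) also matched the same
field.  Conflicts *among* the cessation/negation categories (e.g.
"never smoked, quit 2010") still resolve to ``unknown``.

Cross-field conflicts (Status says "current", Value says "non smoker")
are resolved by field precedence; the record keeps its classification
and is flagged for audit via ``conflict_flag``.
"""
from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .types import ASSIGNABLE_CATEGORIES, RiskFactorRecord

log = logging.getLogger(__name__)

#: categories whose presence in a field suppresses an affirmative match
NEGATION_CATEGORIES = frozenset({"past", "never", "not_current"})

#: precedence order of the three record fields
FIELD_ORDER = ("status", "value", "name")

_WS = re.compile(r"\s+")


def normalize_text(raw: object) -> str:
    """Canonicalize free text: lowercase, trim, collapse internal
    whitespace.  Accents are preserved (bilingual lexicons rely on them).
    Idempotent and total."""
    if raw is None:
        return ""
    return _WS.sub(" ", str(raw).strip()).lower()


def _compile_pattern(pat: str) -> re.Pattern:
    # letter-only boundaries: "ppd" must fire inside "2ppd" but "no"
    # must not fire inside "non".
    return re.compile(r"(?<![a-z])" + re.escape(pat) + r"(?![a-z])")


@dataclass
class PatternLexicon:
    """Ordered per-category pattern sets plus a relationship-word guard.

    ``patterns`` maps each assignable category (current, past, never,
    not_current) to a non-empty list of unique, case-insensitive text
    patterns; ``relationship_words`` is a non-empty kinship-term list.
    """

    patterns: dict[str, list[str]]
    relationship_words: list[str]
    language_tag: str = "en"
    _compiled: dict[str, list[tuple[str, re.Pattern]]] = field(
        init=False, repr=False, default_factory=dict
    )
    _guard: re.Pattern = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        for cat in ASSIGNABLE_CATEGORIES:
            pats = self.patterns.get(cat) or []
            if not pats:
                raise ValueError(f"lexicon category {cat!r} has no patterns")
            norm = [normalize_text(p) for p in pats]
            if len(set(norm)) != len(norm):
                raise ValueError(f"duplicate patterns in category {cat!r}")
            self.patterns[cat] = norm
        extra = set(self.patterns) - set(ASSIGNABLE_CATEGORIES)
        if extra:
            raise ValueError(f"unexpected lexicon categories: {sorted(extra)}")
        if not self.relationship_words:
            raise ValueError("relationship_words must be non-empty")
        self.relationship_words = [normalize_text(w) for w in self.relationship_words]
        self._compiled = {
            cat: [(p, _compile_pattern(p)) for p in self.patterns[cat]]
            for cat in ASSIGNABLE_CATEGORIES
        }
        self._guard = re.compile(
            r"(?<![a-z])(?:"
            + "|".join(re.escape(w) for w in self.relationship_words)
            + r")(?![a-z])"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PatternLexicon":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(
            patterns={k: list(v) for k, v in data["patterns"].items()},
            relationship_words=list(data["relationship_words"]),
            language_tag=str(data.get("language", "en")),
        )

    @classmethod
    def default(cls) -> "PatternLexicon":
        """The shipped English lexicon (an editable approximation of the
        production one, which was never published)."""
        ref = resources.files("emrsmoke").joinpath("data/default_lexicon.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


def field_matches(text: str, lexicon: PatternLexicon) -> list[tuple[str, str]]:
    """All (category, pattern) pairs matching normalized ``text``,
    before guard and conflict resolution.  For audit trails."""
    return [
        (cat, pat)
        for cat in ASSIGNABLE_CATEGORIES
        for pat, rx in lexicon._compiled[cat]
        if rx.search(text)
    ]


def match_field(text: str, lexicon: PatternLexicon) -> set[str]:
    """Candidate categories for one normalized field.

    Returns the empty set when the field contains a relationship word
    (family-history guard) or matches nothing.  An affirmative
    (``current``) match is suppressed when a cessation/negation category
    matched the same field (see module docstring)."""
    if not text:
        return set()
    if lexicon._guard.search(text):
        return set()
    cats = {cat for cat, _ in field_matches(text, lexicon)}
    if "current" in cats and cats & NEGATION_CATEGORIES:
        cats.discard("current")
    return cats


@dataclass
class ClassifiedRecord:
    """A risk-factor record plus its calculated status and audit trail."""

    record: RiskFactorRecord
    calculated_status: str
    decisive_field: str  # status | value | name | none
    matched_patterns: list[tuple[str, str, str]]  # (field, category, pattern)
    conflict_flag: bool


def classify_record(record: RiskFactorRecord,
                    lexicon: PatternLexicon) -> ClassifiedRecord:
    """Assign a calculated status to one record by field precedence."""
    texts = {
        "status": normalize_text(record.status_text),
        "value": normalize_text(record.value_text),
        "name": normalize_text(record.name_text),
    }
    candidates = {f: match_field(texts[f], lexicon) for f in FIELD_ORDER}
    audit = [
        (f, cat, pat)
        for f in FIELD_ORDER
        if texts[f] and not lexicon._guard.search(texts[f])
        for cat, pat in field_matches(texts[f], lexicon)
    ]

    status = "unknown"
    decisive = "none"
    intra_conflict = False
    for f in FIELD_ORDER:
        cs = candidates[f]
        if len(cs) == 1:
            status = next(iter(cs))
            decisive = f
            break
        if len(cs) >= 2:
            status = "unknown"
            decisive = f
            intra_conflict = True
            break

    singles = {next(iter(cs)) for cs in candidates.values() if len(cs) == 1}
    conflict = intra_conflict or len(singles) >= 2
    return ClassifiedRecord(record, status, decisive, audit, conflict)


def latest_status(records: Sequence[ClassifiedRecord]) -> str:
    """Resolve one patient's status: the most recently dated record wins.

    Undated records sort before any dated record.  Date ties prefer an
    informative (non-unknown) status, then the earliest record in input
    order (stable)."""
    if not records:
        raise ValueError("latest_status requires at least one record")
    best = None
    best_key = None
    for rec in records:
        d = rec.record.entry_date or dt.date.min
        key = (d, rec.calculated_status != "unknown")
        if best is None or key > best_key:
            best, best_key = rec, key
    return best.calculated_status


def classify_corpus(
    risk_factors: pd.DataFrame, lexicon: PatternLexicon
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every record and resolve one status per patient.

    ``risk_factors`` follows the documented column contract
    (patient_id, entry_date, name_text, value_text, status_text).
    Returns ``(status_table, audit_table)``: one row per patient with the
    resolved status, and one row per record with decisive field, matched
    patterns and conflict flag.  Pure function of its inputs."""
    classified: list[ClassifiedRecord] = []
    audit_rows = []
    for row in risk_factors.itertuples(index=False):
        entry = getattr(row, "entry_date", None)
        if pd.isna(entry):
            entry = None
        elif isinstance(entry, pd.Timestamp):
            entry = entry.date()
        rec = RiskFactorRecord(
            patient_id=str(row.patient_id),
            entry_date=entry,
            name_text=str(getattr(row, "name_text", "") or ""),
            value_text=str(getattr(row, "value_text", "") or ""),
            status_text=str(getattr(row, "status_text", "") or ""),
        )
        cr = classify_record(rec, lexicon)
        classified.append(cr)
        audit_rows.append(
            {
                "patient_id": rec.patient_id,
                "entry_date": rec.entry_date,
                "name_text": rec.name_text,
                "value_text": rec.value_text,
                "status_text": rec.status_text,
                "calculated_status": cr.calculated_status,
                "decisive_field": cr.decisive_field,
                "matched_patterns": ";".join(
                    f"{f}:{c}:{p}" for f, c, p in cr.matched_patterns
                ),
                "conflict_flag": cr.conflict_flag,
            }
        )

    audit = pd.DataFrame(
        audit_rows,
        columns=[
            "patient_id", "entry_date", "name_text", "value_text",
            "status_text", "calculated_status", "decisive_field",
            "matched_patterns", "conflict_flag",
        ],
    )

    per_patient: dict[str, list[ClassifiedRecord]] = {}
    order: list[str] = []
    for cr in classified:
        pid = cr.record.patient_id
        if pid not in per_patient:
            per_patient[pid] = []
            order.append(pid)
        per_patient[pid].append(cr)

    status_table = pd.DataFrame(
        {
            "patient_id": order,
            "smoking": [latest_status(per_patient[p]) for p in order],
            "n_records": [len(per_patient[p]) for p in order],
        }
    )
    if len(status_table):
        counts = status_table["smoking"].value_counts().to_dict()
        log.info("per-patient status counts: %s", counts)
    return status_table, audit
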