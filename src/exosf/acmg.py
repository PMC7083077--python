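"""ACMG-AMP evidence combination engine.

Combines the 28 standard evidence codes (PVS1; PS1-4; PM1-6; PP1-5; BA1;
BS1-4; BP1-7) into the five-tier verdict pathogenic / likely_pathogenic /
vus / likely_benign / benign using the published combining criteria:

Pathogenic
  P.i.a  PVS1 + >=1 PS          P.iii.a  1 PS + >=3 PM
  P.i.b  PVS1 + >=2 PM          P.iii.b  1 PS + 2 PM + >=2 PP
  P.i.c  PVS1 + 1 PM + 1 PP     P.iii.c  1 PS + 1 PM + >=4 PP
  P.i.d  PVS1 + >=2 PP
  P.ii   >=2 PS

Likely pathogenic
  LP.i   PVS1 + 1 PM            LP.iv  >=3 PM
  LP.ii  1 PS + 1-2 PM          LP.v   2 PM + >=2 PP
  LP.iii 1 PS + >=2 PP          LP.vi  1 PM + >=4 PP

Benign: B.i BA1 stand-alone; B.ii >=2 BS.
Likely benign: LB.i 1 BS + 1 BP; LB.ii >=2 BP.
Otherwise: VUS.

Conflict handling (``conflict_mode``):

``combination`` (default)
    A verdict is pathogenic-side only if a pathogenic-side combination
    fires and no benign-side combination fires (and symmetrically);
    combinations firing on both sides yield VUS.  A lone benign code that
    completes no benign combination does not veto a pathogenic verdict —
    the behaviour required to reproduce curated calls that carry e.g. a
    stray BS2 next to PVS1 evidence.
``strict``
    Same verdicts, but when any code from the opposite side is present the
    fired rule is annotated with ``+conflicting_evidence`` so downstream
    review can flag the row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .errors import ValidationError

STRENGTH_CLASSES = ("pvs", "ps", "pm", "pp", "ba", "bs", "bp")

VALID_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

VERDICTS = ("benign", "likely_benign", "vus", "likely_pathogenic", "pathogenic")

_PATHOGENIC_SIDE = ("pvs", "ps", "pm", "pp")
_BENIGN_SIDE = ("ba", "bs", "bp")


def strength_class(code: str) -> str:
    """Strength class of a code, derived from its prefix (PVS1 -> 'pvs')."""
    m = re.match(r"^(PVS|PS|PM|PP|BA|BS|BP)\d+$", code)
    if not m or code not in VALID_CODES:
        raise ValidationError(f"unknown ACMG-AMP evidence code: {code!r}")
    return m.group(1).lower()


class EvidenceSet(frozenset):
    """A set of valid evidence codes (frozenset of upper-case tokens)."""

    def __new__(cls, codes: Iterable[str] = ()):
        normalized = {c.strip().upper() for c in codes if c.strip()}
        for code in normalized:
            if code not in VALID_CODES:
                raise ValidationError(f"unknown ACMG-AMP evidence code: {code!r}")
        return super().__new__(cls, normalized)

    def counts(self) -> dict[str, int]:
        tally = dict.fromkeys(STRENGTH_CLASSES, 0)
        for code in self:
            tally[strength_class(code)] += 1
        return tally

    def __str__(self) -> str:
        return ",".join(sorted(self))


def parse_evidence(text: str) -> EvidenceSet:
    """Parse a whitespace- or comma-separated code list (case-insensitive)."""
    tokens = re.split(r"[,\s;]+", text.strip()) if text and text.strip() else []
    return EvidenceSet(tokens)


@dataclass(frozen=True)
class Classification:
    verdict: str
    fired_rule: str

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValidationError(f"invalid verdict: {self.verdict!r}")


# Each rule: (label, predicate over the strength-count dict).
_PATHOGENIC_RULES = (
    ("P.i.a", lambda c: c["pvs"] >= 1 and c["ps"] >= 1),
    ("P.i.b", lambda c: c["pvs"] >= 1 and c["pm"] >= 2),
    ("P.i.c", lambda c: c["pvs"] >= 1 and c["pm"] == 1 and c["pp"] >= 1),
    ("P.i.d", lambda c: c["pvs"] >= 1 and c["pp"] >= 2),
    ("P.ii", lambda c: c["ps"] >= 2),
    ("P.iii.a", lambda c: c["ps"] == 1 and c["pm"] >= 3),
    ("P.iii.b", lambda c: c["ps"] == 1 and c["pm"] == 2 and c["pp"] >= 2),
    ("P.iii.c", lambda c: c["ps"] == 1 and c["pm"] == 1 and c["pp"] >= 4),
)

_LIKELY_PATHOGENIC_RULES = (
    ("LP.i", lambda c: c["pvs"] >= 1 and c["pm"] == 1),
    ("LP.ii", lambda c: c["ps"] == 1 and 1 <= c["pm"] <= 2),
    ("LP.iii", lambda c: c["ps"] == 1 and c["pp"] >= 2),
    ("LP.iv", lambda c: c["pm"] >= 3),
    ("LP.v", lambda c: c["pm"] == 2 and c["pp"] >= 2),
    ("LP.vi", lambda c: c["pm"] == 1 and c["pp"] >= 4),
)

_BENIGN_RULES = (
    ("B.i", lambda c: c["ba"] >= 1),
    ("B.ii", lambda c: c["bs"] >= 2),
)

_LIKELY_BENIGN_RULES = (
    ("LB.i", lambda c: c["bs"] == 1 and c["bp"] >= 1),
    ("LB.ii", lambda c: c["bp"] >= 2),
)


def _first_firing(rules, counts) -> str | None:
    for label, pred in rules:
        if pred(counts):
            return label
    return None


def classify(evidence: EvidenceSet, conflict_mode: str = "combination") -> Classification:
    """Combine an evidence set into a five-tier classification.

    See the module docstring for the rule table and conflict semantics.
    """
    if conflict_mode not in ("combination", "strict"):
        raise ValidationError(f"unknown conflict_mode: {conflict_mode!r}")
    if not isinstance(evidence, EvidenceSet):
        evidence = EvidenceSet(evidence)
    counts = evidence.counts()

    p_rule = _first_firing(_PATHOGENIC_RULES, counts)
    lp_rule = _first_firing(_LIKELY_PATHOGENIC_RULES, counts)
    b_rule = _first_firing(_BENIGN_RULES, counts)
    lb_rule = _first_firing(_LIKELY_BENIGN_RULES, counts)

    path_fires = p_rule or lp_rule
    benign_fires = b_rule or lb_rule

    if path_fires and benign_fires:
        return Classification("vus", "conflict_both_sides")
    if path_fires:
        verdict = "pathogenic" if p_rule else "likely_pathogenic"
        rule = p_rule or lp_rule
        has_opposite = any(counts[s] for s in _BENIGN_SIDE)
        if conflict_mode == "strict" and has_opposite:
            rule += "+conflicting_evidence"
        return Classification(verdict, rule)
    if benign_fires:
        verdict = "benign" if b_rule else "likely_benign"
        rule = b_rule or lb_rule
        has_opposite = any(counts[s] for s in _PATHOGENIC_SIDE)
        if conflict_mode == "strict" and has_opposite:
            rule += "+conflicting_evidence"
        return Classification(verdict, rule)
    return Classification("vus", "default_vus")


@dataclass(frozen=True)
class ConcordanceRow:
    evidence: EvidenceSet
    expected: str
    computed: str
    fired_rule: str

    @property
    def concordant(self) -> bool:
        return self.expected == self.computed


@dataclass(frozen=True)
class ConcordanceReport:
    rows: tuple[ConcordanceRow, ...]

    @property
    def n_concordant(self) -> int:
        return sum(r.concordant for r in self.rows)

    @property
    def n_discordant(self) -> int:
        return len(self.rows) - self.n_concordant

    def discordant_rows(self) -> list[ConcordanceRow]:
        return [r for r in self.rows if not r.concordant]


def verify_table(
    rows: Iterable[tuple[EvidenceSet, str]], conflict_mode: str = "combination"
) -> ConcordanceReport:
    """Re-classify (evidence, expected-verdict) pairs and report concordance."""
    out = []
    for evidence, expected in rows:
        result = classify(evidence, conflict_mode=conflict_mode)
        out.append(ConcordanceRow(EvidenceSet(evidence), expected, result.verdict, result.fired_rule))
    return ConcordanceReport(tuple(out))
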