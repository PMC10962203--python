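"""The fixed 15-member roster of potential interprofessional-team members.

Respondents choosing team members for a round-table consultation pick from
a fixed list of 15 options grouped as family, nursing, medical, other
(health and social professionals) and external (extramural professionals).
Free-text "other ..." entries in a questionnaire map onto their fixed
roster slot, so the roster is closed.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RosterMember:
    name: str
    group: str  # family | nursing | medical | other | external


ROSTER: tuple[RosterMember, ...] = (
    RosterMember("parent", "family"),
    RosterMember("paediatric nurse", "nursing"),
    RosterMember("nurse specialist urology", "nursing"),
    RosterMember("other paediatric nurse specialist", "nursing"),
    RosterMember("paediatrician", "medical"),
    RosterMember("paediatric urologist", "medical"),
    RosterMember("other medical specialist", "medical"),
    RosterMember("dietician", "other"),
    RosterMember("physiotherapist", "other"),
    RosterMember("social worker", "other"),
    RosterMember("medical pedagogical care provider", "other"),
    RosterMember("psychologist", "other"),
    RosterMember("other health professional", "other"),
    RosterMember("general practitioner", "external"),
    RosterMember("other external professional", "external"),
)

ROSTER_NAMES: tuple[str, ...] = tuple(m.name for m in ROSTER)

GROUP_SIZES = {"family": 1, "nursing": 3, "medical": 3, "other": 6, "external": 2}

assert len(ROSTER) == 15
assert {g: sum(m.group == g for m in ROSTER) for g in GROUP_SIZES} == GROUP_SIZES
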