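"""Catalog of the 20 lifetime diagnostic entities and their owning instruments.

Four structured diagnostic instruments are modelled purely as outcome
sources: the M.I.N.I. (general psychiatric modules), ADDIS (substance use),
NODS (gambling) and IGDS (gaming).  Two composite outcomes are defined on
top of the primary entities: ``any_anxiety`` (union of the six anxiety
entities) and ``at_least_one`` (union of all 20).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Instrument(str, Enum):
    MINI = "mini"
    ADDIS = "addis"
    NODS = "nods"
    IGDS = "igds"


@dataclass(frozen=True)
class DiagnosisEntity:
    key: str
    label: str
    instrument: Instrument


ENTITIES: tuple[DiagnosisEntity, ...] = (
    DiagnosisEntity("suicidality", "Suicidality", Instrument.MINI),
    DiagnosisEntity("depression", "Depression", Instrument.MINI),
    DiagnosisEntity("mania", "Mania", Instrument.MINI),
    DiagnosisEntity("panic_disorder", "Panic disorder", Instrument.MINI),
    DiagnosisEntity("agoraphobia", "Agoraphobia", Instrument.MINI),
    DiagnosisEntity("social_anxiety", "Social anxiety", Instrument.MINI),
    DiagnosisEntity("ocd", "Obsessive compulsive disorder (OCD)", Instrument.MINI),
    DiagnosisEntity("ptsd", "Post traumatic stress disorder (PTSD)", Instrument.MINI),
    DiagnosisEntity("gad", "Generalized anxiety disorder (GAD)", Instrument.MINI),
    DiagnosisEntity("psychotic_syndrome", "Psychotic syndrome", Instrument.MINI),
    DiagnosisEntity("affective_psychosis", "Affective psychosis", Instrument.MINI),
    DiagnosisEntity("bulimia", "Bulimia", Instrument.MINI),
    DiagnosisEntity("anorexia", "Anorexia", Instrument.MINI),
    DiagnosisEntity("aspd", "Antisocial personality disorder (ASPD)", Instrument.MINI),
    DiagnosisEntity("adhd", "Attention deficit hyperactivity disorder (ADHD)", Instrument.MINI),
    DiagnosisEntity("add", "Attention deficit disorder (ADD)", Instrument.MINI),
    DiagnosisEntity("alcohol", "Dependence/harmful use of alcohol", Instrument.ADDIS),
    DiagnosisEntity("drugs", "Dependence/harmful use of drugs", Instrument.ADDIS),
    DiagnosisEntity("gambling", "Gambling problem or disorder", Instrument.NODS),
    DiagnosisEntity("gaming", "Gaming disorder", Instrument.IGDS),
)

ENTITY_KEYS: tuple[str, ...] = tuple(e.key for e in ENTITIES)
ENTITY_BY_KEY: dict[str, DiagnosisEntity] = {e.key: e for e in ENTITIES}

#: entities whose Phase-1 screening was asymmetric between the two school
#: sub-cohorts (questionnaire-screened in sub-cohort 2 only).
SUBCOHORT_ASYMMETRIC: frozenset[str] = frozenset({"gambling", "gaming"})

ANY_ANXIETY_MEMBERS: tuple[str, ...] = (
    "panic_disorder",
    "agoraphobia",
    "social_anxiety",
    "ocd",
    "ptsd",
    "gad",
)

COMPOSITES: dict[str, tuple[str, ...]] = {
    "any_anxiety": ANY_ANXIETY_MEMBERS,
    "at_least_one": ENTITY_KEYS,
}


def instrument_entities(instrument: Instrument) -> tuple[str, ...]:
    """Entity keys owned by one instrument, in catalog order."""
    return tuple(e.key for e in ENTITIES if e.instrument is instrument)


def owning_instrument(entity_key: str) -> Instrument:
    try:
        return ENTITY_BY_KEY[entity_key].instrument
    except KeyError:
        raise KeyError(f"unknown diagnosis entity: {entity_key!r}") from None
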