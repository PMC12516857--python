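"""Synthetic-cohort generator mirroring the two-phase sampling design.

Each participant gets a legal gender, a latent sexual orientation, a latent
gender-discontent status, a school sub-cohort, latent true lifetime
diagnosis statuses per entity, imperfect per-entity screens, and a
person-level interview-response draw.  Diagnoses are revealed (as the true
status) only for screen-positive entities whose owning instrument was
interviewed — Phase 2 opens a module only on screening indication, and
screen-negatives are assumed free of the diagnosis downstream.

Sub-cohort asymmetry: sub-cohort 2 carried the gambling/gaming screens in
the questionnaire; sub-cohort 1 was screened for them by the interviewer
only when reached for a M.I.N.I. or ADDIS interview, and a positive
interviewer screen led to the NODS/IGDS interview in the same call.

RNG contract: one root seed; independent child streams are derived in a
fixed documented order (demographics, identity items, missingness,
response, then per-entity truth and screen streams appended in catalog
order), so adding entities to the catalog does not perturb earlier draws.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import reference as ref
from .catalog import ENTITIES, ENTITY_KEYS, Instrument, instrument_entities
from .cohort import ALL_COLUMNS

ORIENTATIONS = ("asexual", "homosexual", "bisexual", "heterosexual")
STRATA = tuple(f"{g}:{o}" for g in ("female", "male") for o in ORIENTATIONS)

_N_INST_ENTITIES = {i: len(instrument_entities(i)) for i in Instrument}


class SyntheticCohortConfig(BaseModel):
    """Full generative specification of a synthetic cohort.

    Defaults (see :func:`default_study_config`) reproduce the sampling
    conditions of the adolescent study the package emulates.
    """

    N: int = Field(gt=0)
    female_fraction: float = Field(ge=0, le=1)
    orientation_probs: dict[str, dict[str, float]]
    gd_prob: float = Field(ge=0, le=1)
    gd_doubts_fraction: float = Field(default=15 / 16, ge=0, le=1)
    item_missing_probs: dict[str, float] = Field(
        default_factory=lambda: {"attraction": 0.0, "contentment": 0.0}
    )
    true_prevalence: dict[str, dict[str, float]]
    gd_true_prevalence: Optional[dict[str, float]] = None
    screening_sensitivity: dict[str, float]
    screening_specificity: dict[str, float]
    interview_response_prob: float = Field(ge=0, le=1)
    response_odds_multiplier_cases: float = Field(default=1.0, gt=0)
    subcohort1_fraction: float = Field(ge=0, le=1, default=0.5)
    seed: int = 0

    @field_validator("orientation_probs")
    @classmethod
    def _check_orientation(cls, v):
        for gender in ("female", "male"):
            if gender not in v:
                raise ValueError(f"orientation_probs missing gender {gender!r}")
            probs = v[gender]
            if set(probs) != set(ORIENTATIONS):
                raise ValueError(f"orientation_probs[{gender!r}] must cover {ORIENTATIONS}")
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ValueError("orientation probabilities must be in [0,1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"orientation_probs[{gender!r}] must sum to 1")
        return v

    @field_validator("true_prevalence")
    @classmethod
    def _check_prevalence(cls, v):
        missing = [s for s in STRATA if s not in v]
        if missing:
            raise ValueError(f"true_prevalence missing strata: {missing}")
        for stratum, m in v.items():
            absent = [e for e in ENTITY_KEYS if e not in m]
            if absent:
                raise ValueError(f"true_prevalence[{stratum!r}] missing entities: {absent}")
            if any(not 0 <= p <= 1 for p in m.values()):
                raise ValueError(f"true_prevalence[{stratum!r}] out of [0,1]")
        return v

    @model_validator(mode="after")
    def _check_instruments(self):
        for name, m in (
            ("screening_sensitivity", self.screening_sensitivity),
            ("screening_specificity", self.screening_specificity),
        ):
            for i in Instrument:
                if i.value not in m:
                    raise ValueError(f"{name} missing instrument {i.value!r}")
                if not 0 <= m[i.value] <= 1:
                    raise ValueError(f"{name}[{i.value!r}] out of [0,1]")
        if self.gd_true_prevalence is not None:
            absent = [e for e in ENTITY_KEYS if e not in self.gd_true_prevalence]
            if absent:
                raise ValueError(f"gd_true_prevalence missing entities: {absent}")
        for k in ("attraction", "contentment"):
            p = self.item_missing_probs.get(k, 0.0)
            if not 0 <= p <= 1:
                raise ValueError(f"item_missing_probs[{k!r}] out of [0,1]")
        return self

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCohortConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def default_study_config(seed: int = 0, N: int | None = None) -> SyntheticCohortConfig:
    """Configuration calibrated to the emulated study's printed margins:
    N = 949 with 56% female legal gender, orientation cell frequencies
    proportional to the published counts, 1.7% gender discontent, published
    column prevalences as latent truth, 51.1% interview response, and the
    two-sub-cohort gambling/gaming screening asymmetry."""
    orientation_probs = {}
    for gender, cells in ref.ORIENTATION_CELL_N.items():
        total = sum(cells.values())
        orientation_probs[gender] = {o: cells[o] / total for o in ORIENTATIONS}

    col_of_stratum = {
        "female:asexual": None,
        "female:homosexual": "f_hom",
        "female:bisexual": "f_bi",
        "female:heterosexual": "f_het",
        "male:asexual": None,
        "male:homosexual": None,  # all-zero column dropped by the study
        "male:bisexual": "m_bi",
        "male:heterosexual": "m_het",
    }
    true_prev = {}
    for stratum, col in col_of_stratum.items():
        true_prev[stratum] = {
            e: (0.0 if col is None else ref.PREVALENCE_PCT[e][col] / 100.0)
            for e in ENTITY_KEYS
        }
    gd_prev = {e: ref.PREVALENCE_PCT[e]["gd"] / 100.0 for e in ENTITY_KEYS}

    # both attraction items answered by 923/949; contentment by 941/949
    p_attr = 1.0 - (ref.ORIENTATION_RESPONDERS / ref.TOTAL_N) ** 0.5
    p_cont = 1.0 - ref.GD_RESPONDERS / ref.TOTAL_N

    return SyntheticCohortConfig(
        N=N if N is not None else ref.TOTAL_N,
        female_fraction=ref.FEMALE_N / ref.TOTAL_N,
        orientation_probs=orientation_probs,
        gd_prob=ref.GD_N / ref.GD_RESPONDERS,
        gd_doubts_fraction=ref.GD_DOUBTS_N / ref.GD_N,
        item_missing_probs={"attraction": p_attr, "contentment": p_cont},
        true_prevalence=true_prev,
        gd_true_prevalence=gd_prev,
        screening_sensitivity={i.value: 0.95 for i in Instrument},
        screening_specificity={i.value: 0.70 for i in Instrument},
        interview_response_prob=ref.INTERVIEWED_N / ref.SELECTED_N,
        subcohort1_fraction=0.5,
        seed=seed,
    )


def no_noise_config(seed: int = 0, N: int = 1000) -> SyntheticCohortConfig:
    """No-noise limit of the default configuration: perfect screens, full
    interview response, no item non-response, and every member questionnaire-
    screened (sub-cohort 2 only), so the adjusted prevalence must equal the
    exact latent-case proportion in every cell."""
    cfg = default_study_config(seed=seed, N=N)
    return cfg.model_copy(
        update={
            "screening_sensitivity": {i.value: 1.0 for i in Instrument},
            "screening_specificity": {i.value: 1.0 for i in Instrument},
            "interview_response_prob": 1.0,
            "item_missing_probs": {"attraction": 0.0, "contentment": 0.0},
            "subcohort1_fraction": 0.0,
        }
    )


def inject_informative_attrition(
    config: SyntheticCohortConfig, effect: float
) -> SyntheticCohortConfig:
    """Multiply the interview-response odds for latent cases by ``effect``
    (effect < 1: cases respond less — the estimator's MAR-given-screen
    assumption is then violated).  effect = 1 is the identity."""
    if effect <= 0:
        raise ValueError("effect must be a positive odds multiplier")
    return config.model_copy(update={"response_odds_multiplier_cases": effect})


# ---------------------------------------------------------------------------
# generation

def _streams(seed: int) -> dict[str, np.random.Generator]:
    keys = [
        "legal_gender",
        "orientation",
        "attraction_level",
        "gd",
        "subcohort",
        "missing_attraction_opposite",
        "missing_attraction_same",
        "missing_contentment",
        "response",
    ]
    for e in ENTITY_KEYS:
        keys.append(f"true:{e}")
        keys.append(f"screen:{e}")
    children = np.random.SeedSequence(seed).spawn(len(keys))
    return {k: np.random.default_rng(c) for k, c in zip(keys, children)}


def generate_cohort(
    config: SyntheticCohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort.  Returns ``(cohort, truth)``: the cohort frame in the
    canonical dialect, and an id-aligned truth frame with the latent
    orientation, GD status, response draw and per-entity true statuses."""
    rng = _streams(config.seed if seed is None else seed)
    n = config.N

    female = rng["legal_gender"].random(n) < config.female_fraction
    gender = np.where(female, "female", "male")

    probs = np.empty((n, len(ORIENTATIONS)))
    for g in ("female", "male"):
        row = np.array([config.orientation_probs[g][o] for o in ORIENTATIONS])
        probs[gender == g] = row
    u = rng["orientation"].random(n)
    orient_idx = (u[:, None] >= probs.cumsum(axis=1)).sum(axis=1).clip(max=len(ORIENTATIONS) - 1)
    orientation = np.array(ORIENTATIONS)[orient_idx]

    # attraction items consistent with the latent orientation; the
    # somewhat/strongly split is irrelevant to classification, drawn 50/50
    lvl = rng["attraction_level"].random((n, 2))
    same_at_all = np.isin(orientation, ("homosexual", "bisexual"))
    opp_at_all = np.isin(orientation, ("heterosexual", "bisexual"))
    attraction_same = np.where(
        same_at_all, np.where(lvl[:, 0] < 0.5, "somewhat", "strongly"), "not_at_all"
    )
    attraction_opposite = np.where(
        opp_at_all, np.where(lvl[:, 1] < 0.5, "somewhat", "strongly"), "not_at_all"
    )

    u_gd = rng["gd"].random((n, 2))
    gd = u_gd[:, 0] < config.gd_prob
    contentment = np.where(
        gd,
        np.where(u_gd[:, 1] < config.gd_doubts_fraction, "doubts", "not_at_all_comfortable"),
        "happy",
    )

    sub_cohort = np.where(rng["subcohort"].random(n) < config.subcohort1_fraction, 1, 2)

    p_attr = config.item_missing_probs.get("attraction", 0.0)
    p_cont = config.item_missing_probs.get("contentment", 0.0)
    miss_opp = rng["missing_attraction_opposite"].random(n) < p_attr
    miss_same = rng["missing_attraction_same"].random(n) < p_attr
    miss_cont = rng["missing_contentment"].random(n) < p_cont

    # latent truth per entity, from the gender x orientation stratum (GD
    # override where configured)
    stratum = np.char.add(np.char.add(gender.astype(str), ":"), orientation.astype(str))
    true_status: dict[str, np.ndarray] = {}
    for e in ENTITY_KEYS:
        p = np.empty(n)
        for s in STRATA:
            p[stratum == s] = config.true_prevalence[s][e]
        if config.gd_true_prevalence is not None:
            p[gd] = config.gd_true_prevalence[e]
        true_status[e] = rng[f"true:{e}"].random(n) < p

    # per-entity screens; instrument specificity is split across its
    # entities so the instrument-level false-positive rate matches config
    screen_pos: dict[str, np.ndarray] = {}
    for ent in ENTITIES:
        sens = config.screening_sensitivity[ent.instrument.value]
        spec_inst = config.screening_specificity[ent.instrument.value]
        spec_e = spec_inst ** (1.0 / _N_INST_ENTITIES[ent.instrument])
        us = rng[f"screen:{ent.key}"].random(n)
        screen_pos[ent.key] = np.where(true_status[ent.key], us < sens, us < 1.0 - spec_e)

    any_true = np.zeros(n, dtype=bool)
    for e in ENTITY_KEYS:
        any_true |= true_status[e]
    p_resp = np.full(n, config.interview_response_prob)
    eff = config.response_odds_multiplier_cases
    if eff != 1.0:
        base = p_resp[any_true]
        odds = np.where(base < 1.0, base / (1.0 - base) * eff, np.inf)
        p_resp[any_true] = np.where(np.isinf(odds), 1.0, odds / (1.0 + odds))
    responded = rng["response"].random(n) < p_resp

    def selected(instrument: Instrument) -> np.ndarray:
        sel = np.zeros(n, dtype=bool)
        for e in instrument_entities(instrument):
            sel |= screen_pos[e]
        return sel

    interviewed: dict[Instrument, np.ndarray] = {}
    interviewed[Instrument.MINI] = selected(Instrument.MINI) & responded
    interviewed[Instrument.ADDIS] = selected(Instrument.ADDIS) & responded
    reached = interviewed[Instrument.MINI] | interviewed[Instrument.ADDIS]

    in_sc1 = sub_cohort == 1
    gg_screened = ~in_sc1 | reached  # sub-cohort 2 questionnaire, or interviewer
    for inst, ent in ((Instrument.NODS, "gambling"), (Instrument.IGDS, "gaming")):
        pos = screen_pos[ent]
        # questionnaire-screened positives need a response; interviewer-
        # screened positives are already on the phone
        interviewed[inst] = (~in_sc1 & pos & responded) | (in_sc1 & reached & pos)

    cohort = pd.DataFrame(
        {
            "participant_id": [f"p{i:05d}" for i in range(n)],
            "legal_gender": gender,
            "attraction_opposite": np.where(miss_opp, None, attraction_opposite),
            "attraction_same": np.where(miss_same, None, attraction_same),
            "gender_contentment": np.where(miss_cont, None, contentment),
            "sub_cohort": sub_cohort,
        }
    )
    for e in ENTITY_KEYS:
        if e in ("gambling", "gaming"):
            col = np.where(
                gg_screened, np.where(screen_pos[e], "positive", "negative"), "not_screened"
            )
        else:
            col = np.where(screen_pos[e], "positive", "negative")
        cohort[f"screen_{e}"] = col
    for i in Instrument:
        cohort[f"interviewed_{i.value}"] = interviewed[i].astype(int)
    for ent in ENTITIES:
        revealed = (
            (cohort[f"screen_{ent.key}"] == "positive").to_numpy()
            & interviewed[ent.instrument]
        )
        cohort[f"dx_{ent.key}"] = np.where(
            revealed, np.where(true_status[ent.key], "present", "absent"), "unknown"
        )
    cohort = cohort[ALL_COLUMNS]

    truth = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"],
            "legal_gender": gender,
            "orientation": orientation,
            "gd": gd,
            "responded": responded,
        }
    )
    for e in ENTITY_KEYS:
        truth[f"true_{e}"] = true_status[e]
    return cohort, truth
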