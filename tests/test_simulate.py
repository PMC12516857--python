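"""Synthetic-cohort generator: determinism, validity, calibration and the
directional effects of screening noise and informative attrition."""

from __future__ import annotations

import numpy as np
import pytest
from pydantic import ValidationError

from screenprev import (
    ENTITY_KEYS,
    build_analysis_groups,
    default_study_config,
    estimate_entity,
    generate_cohort,
    inject_informative_attrition,
    no_noise_config,
    validate_frame,
)
from screenprev.catalog import Instrument
from screenprev.simulate import SyntheticCohortConfig


def test_seed_determinism():
    cfg = default_study_config(seed=7, N=500)
    a, ta = generate_cohort(cfg)
    b, tb = generate_cohort(cfg)
    assert a.equals(b) and ta.equals(tb)
    c, _ = generate_cohort(cfg, seed=8)
    assert not a.equals(c)


def test_invalid_configs_rejected_before_sampling():
    cfg = default_study_config()
    bad = cfg.model_dump()
    bad["orientation_probs"]["female"]["asexual"] += 0.5
    with pytest.raises(ValidationError, match="sum to 1"):
        SyntheticCohortConfig.model_validate(bad)
    bad2 = cfg.model_dump()
    del bad2["true_prevalence"]["female:bisexual"]["depression"]
    with pytest.raises(ValidationError, match="missing entities"):
        SyntheticCohortConfig.model_validate(bad2)
    bad3 = cfg.model_dump()
    del bad3["screening_sensitivity"]["nods"]
    with pytest.raises(ValidationError, match="nods"):
        SyntheticCohortConfig.model_validate(bad3)


def test_generated_cohorts_validate(tmp_path):
    for seed in (0, 3):
        cohort, truth = generate_cohort(default_study_config(seed=seed))
        validate_frame(cohort)
        assert (truth["participant_id"] == cohort["participant_id"]).all()


def test_no_noise_limit_recovers_latent_prevalence_exactly():
    cohort, truth = generate_cohort(no_noise_config(seed=5, N=1500))
    groups = build_analysis_groups(cohort)
    for (g, o), mask in groups.orientation_cells.items():
        sub = cohort[mask]
        if len(sub) == 0:
            continue
        tsub = truth[mask.to_numpy()]
        for e in ENTITY_KEYS:
            assert estimate_entity(sub, e).P == tsub[f"true_{e}"].mean()


def test_imperfect_sensitivity_biases_downward():
    """With screen sensitivity s < 1 the design assumes no diagnosis for the
    unscreened-positive, so estimates undershoot truth by about (1-s)*prev."""
    base = no_noise_config(seed=0, N=4000)
    lossy = base.model_copy(
        update={"screening_sensitivity": {i.value: 0.7 for i in Instrument}}
    )
    diffs = []
    for seed in range(15):
        cohort, _ = generate_cohort(lossy, seed=100 + seed)
        groups = build_analysis_groups(cohort)
        sub = cohort[groups.orientation_cells[("female", "heterosexual")]]
        diffs.append(estimate_entity(sub, "depression").P)
    truth_p = lossy.true_prevalence["female:heterosexual"]["depression"]
    mean_est = float(np.mean(diffs))
    assert mean_est < truth_p
    assert mean_est == pytest.approx(0.7 * truth_p, rel=0.15)


def test_inject_informative_attrition_identity_and_validation():
    cfg = default_study_config(seed=1, N=400)
    same = inject_informative_attrition(cfg, 1.0)
    assert same == cfg
    a, _ = generate_cohort(cfg)
    b, _ = generate_cohort(same)
    assert a.equals(b)
    with pytest.raises(ValueError):
        inject_informative_attrition(cfg, 0.0)
    skewed = inject_informative_attrition(cfg, 0.5)
    assert skewed.response_odds_multiplier_cases == 0.5


def test_informative_attrition_lowers_case_response():
    cfg = default_study_config(seed=2, N=20000).model_copy(
        update={"interview_response_prob": 0.5}
    )
    skewed = inject_informative_attrition(cfg, 0.25)
    _, truth = generate_cohort(skewed)
    any_true = truth[[f"true_{e}" for e in ENTITY_KEYS]].any(axis=1)
    resp_cases = truth.loc[any_true, "responded"].mean()
    resp_noncases = truth.loc[~any_true, "responded"].mean()
    assert resp_cases < resp_noncases
    # odds(resp_cases) should be about a quarter of odds(resp_noncases)
    odds = lambda p: p / (1 - p)  # noqa: E731
    assert odds(resp_cases) / odds(resp_noncases) == pytest.approx(0.25, rel=0.2)


def test_selection_rate_matches_design_margin():
    """About 80% of the cohort should be selected for at least one interview
    under the default operating characteristics (published margin 758/949)."""
    cohort, _ = generate_cohort(default_study_config(seed=9, N=20000))
    screen_cols = [f"screen_{e}" for e in ENTITY_KEYS]
    selected = (cohort[screen_cols] == "positive").any(axis=1).mean()
    assert selected == pytest.approx(758 / 949, abs=0.03)


def test_subcohort_rule_shapes_screen_availability():
    cohort, _ = generate_cohort(default_study_config(seed=4, N=5000))
    sc1 = cohort[cohort["sub_cohort"] == 1]
    sc2 = cohort[cohort["sub_cohort"] == 2]
    reached = sc1["interviewed_mini"].astype(bool) | sc1["interviewed_addis"].astype(bool)
    assert (sc1.loc[~reached, "screen_gambling"] == "not_screened").all()
    assert (sc1.loc[reached, "screen_gambling"] != "not_screened").all()
    assert (sc2["screen_gambling"] != "not_screened").all()


def test_config_yaml_roundtrip(tmp_path):
    cfg = default_study_config(seed=11)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = SyntheticCohortConfig.from_yaml(path)
    assert back == cfg
    a, _ = generate_cohort(cfg)
    b, _ = generate_cohort(back)
    assert a.equals(b)


def test_default_config_expectations():
    cfg = default_study_config()
    assert cfg.N == 949
    assert cfg.interview_response_prob == pytest.approx(0.511, abs=0.0005)
    assert cfg.gd_prob * 941 == pytest.approx(16, abs=0.01)
    # orientation expectations proportional to published counts (25/28/124/746 of 923)
    exp = {
        o: sum(
            cfg.orientation_probs[g][o]
            * (cfg.female_fraction if g == "female" else 1 - cfg.female_fraction)
            for g in ("female", "male")
        )
        for o in ("asexual", "homosexual", "bisexual", "heterosexual")
    }
    for o, n in (("asexual", 25), ("homosexual", 28), ("bisexual", 124), ("heterosexual", 746)):
        assert exp[o] == pytest.approx(n / 923, abs=0.002)
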