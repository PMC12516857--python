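"""Published results of the adolescent two-phase interview study this
package emulates, used (a) to calibrate the default synthetic-cohort
configuration and (b) as printed inputs for worked-example checks.

The study screened a school cohort of 949 adolescents (528 girls, 421 boys,
mean age 17) with high-sensitivity instruments; 758 screen-positives were
selected for structured diagnostic telephone interviews and 387 (51.1%)
completed one.  923 answered the two attraction items and 941 the
gender-contentment item; 16 (1.7%) reported gender discontent.

Prevalences below are the study's attrition-adjusted lifetime estimates in
percent, by analysis column.  Columns for the 11 female and 14 male
asexuals and the 10 male homosexuals were dropped by the study because no
member met any diagnosis (all-zero prevalence).
"""

from __future__ import annotations

# participant flow
TOTAL_N = 949
FEMALE_N = 528
MALE_N = 421
SELECTED_N = 758
INTERVIEWED_N = 387
ORIENTATION_RESPONDERS = 923
GD_RESPONDERS = 941
GD_N = 16
GD_DOUBTS_N = 15

# orientation cell sizes by legal gender (asexual, homosexual, bisexual, heterosexual)
ORIENTATION_CELL_N = {
    "female": {"asexual": 11, "homosexual": 18, "bisexual": 101, "heterosexual": 385},
    "male": {"asexual": 14, "homosexual": 10, "bisexual": 23, "heterosexual": 361},
}

# adjusted lifetime prevalence (%) per reported column
COLUMNS = ("f_hom", "f_bi", "f_het", "m_bi", "m_het", "gd", "non_gd")
COLUMN_N = {"f_hom": 18, "f_bi": 101, "f_het": 385, "m_bi": 23, "m_het": 361, "gd": 16, "non_gd": 925}

_PCT_ROWS = {
    #                     f_hom  f_bi  f_het  m_bi  m_het   gd  non_gd
    "suicidality":        (13.9,  9.3,  2.7, 31.6,  4.0,  9.7,  4.5),
    "depression":         (13.9, 34.9, 19.9, 20.2,  5.2,  0.0,  4.5),
    "mania":              ( 0.0,  6.9,  0.4,  5.9,  2.0,  0.0,  1.8),
    "panic_disorder":     (19.4, 20.5,  8.3, 22.1,  1.3, 27.1,  6.6),
    "agoraphobia":        ( 0.6,  6.5,  1.1,  0.0,  0.3,  9.0,  1.3),
    "social_anxiety":     (19.4, 11.8,  3.7,  0.0,  1.0, 18.1,  3.4),
    "ocd":                ( 2.8, 11.8,  3.5, 23.7,  1.3,  8.3,  4.1),
    "ptsd":               ( 0.0,  2.5,  0.0,  0.0,  0.0,  0.0,  0.3),
    "gad":                ( 0.0,  2.6,  2.1,  0.0,  0.3,  9.7,  1.3),
    "psychotic_syndrome": ( 0.0,  6.4,  1.7,  5.5,  2.1,  0.0,  2.8),
    "affective_psychosis":( 0.0,  1.3,  0.3,  0.0,  0.0,  0.0,  0.3),
    "bulimia":            ( 0.0,  1.3,  0.7,  0.0,  0.0,  0.0,  0.3),
    "anorexia":           ( 6.9,  0.0,  0.4,  0.0,  0.0,  0.0,  0.4),
    "aspd":               ( 0.0,  1.3,  0.4,  5.9,  0.8,  9.0,  0.7),
    "adhd":               ( 0.0,  5.1,  0.7, 11.9,  0.7,  9.0,  1.3),
    "add":                ( 6.9,  1.3,  1.5,  5.9,  0.4,  0.0,  1.2),
    "alcohol":            ( 0.0, 22.3, 15.3,  0.0, 11.9,  0.0, 14.3),
    "drugs":              ( 0.0,  4.4,  0.6,  0.0,  2.4,  0.0,  1.8),
    "gambling":           ( 0.0,  2.2,  0.0,  7.0,  6.2,  0.0,  2.9),
    "gaming":             ( 0.0,  0.0,  0.0,  8.7,  4.0,  0.0,  1.9),
}

PREVALENCE_PCT: dict[str, dict[str, float]] = {
    entity: dict(zip(COLUMNS, row)) for entity, row in _PCT_ROWS.items()
}

#: published RR cells whose printed value equals the ratio of the printed
#: prevalence pair rounded to 2 dp (the study's other RRs were computed from
#: unrounded internal values not recoverable from the printed table).
PRINTED_RR_CELLS: list[dict] = [
    {"entity": "suicidality", "column": "f_hom", "ref": "f_het", "rr": 5.15},
    {"entity": "suicidality", "column": "f_bi", "ref": "f_het", "rr": 3.44},
    {"entity": "depression", "column": "f_hom", "ref": "f_het", "rr": 0.70},
    {"entity": "mania", "column": "f_bi", "ref": "f_het", "rr": 17.25},
    {"entity": "social_anxiety", "column": "f_hom", "ref": "f_het", "rr": 5.24},
    {"entity": "anorexia", "column": "f_hom", "ref": "f_het", "rr": 17.25},
    {"entity": "panic_disorder", "column": "m_bi", "ref": "m_het", "rr": 17.00},
    {"entity": "adhd", "column": "m_bi", "ref": "m_het", "rr": 17.00},
]
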