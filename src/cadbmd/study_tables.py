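"""Published quantal dose-group tables for the cadmium cohort.

The headline benchmark-dose reproduction needs no subject-level data: the
published prevalence tables give, per biomarker and sex, the five UCd bands,
their geometric-mean doses (µg/g Cr), group sizes, and positive counts at
both the 90% and 95% cut-offs, plus the prevalence percentages as printed.
These tables ship with the package as its reference fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grouping import DoseGroupTable

__all__ = ["StudyTable", "get", "all_tables", "as_dose_group_table",
           "BIOMARKERS", "SEXES", "LABELS"]

BIOMARKERS = ("rbp", "b2mg", "nag")
SEXES = ("male", "female")
LABELS = ("<=0.49", "0.50-0.99", "1.00-1.49", "1.50-1.99", ">=2.00")

_MALE_DOSES = (0.0, 0.69, 1.20, 1.67, 3.43)
_FEMALE_DOSES = (0.0, 0.70, 1.20, 1.74, 3.53)


@dataclass(frozen=True)
class StudyTable:
    """One biomarker/sex stratification exactly as published."""

    biomarker: str
    sex: str
    doses: tuple
    n: tuple
    positives: dict          # cutoff percentile -> per-group positives
    printed_prevalence: dict  # cutoff percentile -> per-group %, as printed
    printed_total_prevalence: dict  # cutoff percentile -> overall %, as printed


_TABLES = {
    ("rbp", "male"): StudyTable(
        "rbp", "male", _MALE_DOSES, (159, 127, 62, 24, 35),
        {90: (14, 5, 9, 3, 8), 95: (5, 5, 7, 2, 1)},
        {90: (8.8, 3.9, 14.5, 12.5, 22.9), 95: (3.1, 3.9, 11.3, 8.3, 2.9)},
        {90: 9.6, 95: 4.9}),
    ("rbp", "female"): StudyTable(
        "rbp", "female", _FEMALE_DOSES, (127, 123, 57, 35, 59),
        {90: (7, 8, 4, 4, 14), 95: (2, 3, 3, 3, 8)},
        {90: (5.5, 6.5, 7.0, 11.4, 23.7), 95: (1.6, 2.4, 5.3, 8.6, 13.6)},
        {90: 9.2, 95: 4.7}),
    ("b2mg", "male"): StudyTable(
        "b2mg", "male", _MALE_DOSES, (163, 131, 66, 26, 38),
        {90: (10, 7, 9, 4, 8), 95: (5, 2, 6, 1, 4)},
        {90: (6.1, 5.3, 13.6, 15.4, 21.1), 95: (3.1, 1.5, 9.1, 3.8, 10.5)},
        {90: 9.0, 95: 4.2}),
    ("b2mg", "female"): StudyTable(
        "b2mg", "female", _FEMALE_DOSES, (133, 130, 60, 38, 62),
        {90: (6, 9, 3, 6, 15), 95: (1, 4, 2, 3, 10)},
        {90: (4.5, 6.9, 5.0, 15.8, 24.2), 95: (0.8, 3.1, 3.3, 7.9, 16.1)},
        {90: 9.2, 95: 4.7}),
    ("nag", "male"): StudyTable(
        "nag", "male", _MALE_DOSES, (164, 133, 68, 26, 38),
        {90: (9, 11, 13, 4, 6), 95: (2, 5, 6, 3, 4)},
        {90: (5.5, 8.3, 19.1, 15.4, 15.8), 95: (1.2, 3.8, 8.8, 11.5, 10.5)},
        {90: 10.0, 95: 4.7}),
    ("nag", "female"): StudyTable(
        "nag", "female", _FEMALE_DOSES, (136, 131, 62, 38, 62),
        {90: (10, 9, 7, 7, 13), 95: (3, 4, 2, 5, 7)},
        {90: (7.4, 6.9, 11.3, 18.4, 21.0), 95: (2.2, 3.1, 3.2, 13.2, 11.3)},
        {90: 10.7, 95: 4.9}),
}


def get(biomarker: str, sex: str) -> StudyTable:
    """The published table for one biomarker ('rbp', 'b2mg', 'nag') and sex."""
    try:
        return _TABLES[(biomarker.lower(), sex.lower())]
    except KeyError:
        raise KeyError(f"no study table for ({biomarker!r}, {sex!r})") from None


def all_tables():
    """All six published stratifications, in biomarker-major order."""
    return [_TABLES[(b, s)] for b in BIOMARKERS for s in SEXES]


def as_dose_group_table(biomarker: str, sex: str,
                        percentile: int = 90) -> DoseGroupTable:
    """Published counts repackaged as a DoseGroupTable ready for fitting."""
    t = get(biomarker, sex)
    if percentile not in t.positives:
        raise KeyError(f"no {percentile}% cut-off column in the study table")
    return DoseGroupTable(biomarker=t.biomarker, sex=t.sex,
                          cutoff_percentile=percentile, labels=LABELS,
                          doses=t.doses, n=t.n, positives=t.positives[percentile])
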