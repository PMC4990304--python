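"""Creatinine adjustment, percentile cut-offs, and abnormality classification.

Urinary analytes are diluted by diuresis, so raw concentrations (per litre)
are divided by urinary creatinine (g/L) to give per-g-creatinine values.
Reference cut-offs for "abnormal" tubular function are empirical upper
percentiles (90th or 95th) of the study population, derived per sex; a value
strictly above the cut-off is classified positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "AdjustedValues",
    "CutoffSet",
    "adjust_for_creatinine",
    "compute_cutoff",
    "classify_abnormal",
    "population_cutoffs",
]

BIOMARKERS = ("rbp", "b2mg", "nag")
BIOMARKER_UNITS = {"rbp": "ug/g Cr", "b2mg": "mg/g Cr", "nag": "U/g Cr"}


class AdjustedValues(NamedTuple):
    """Creatinine-adjusted values plus a usability mask.

    Records with nonpositive or missing creatinine are flagged unusable
    (value NaN) rather than dropped.
    """

    values: np.ndarray
    usable: np.ndarray


def adjust_for_creatinine(raw, creatinine) -> AdjustedValues:
    """Convert per-litre concentrations to per-g-creatinine.

    ``raw`` in analyte units per litre, ``creatinine`` in g per litre; the
    result is analyte units per g creatinine.
    """
    r = np.asarray(raw, dtype=float)
    c = np.asarray(creatinine, dtype=float)
    if np.any(r[~np.isnan(r)] < 0):
        raise ValueError("raw concentrations must be nonnegative")
    usable = np.isfinite(c) & (c > 0) & np.isfinite(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(usable, r / np.where(usable, c, 1.0), np.nan)
    if out.ndim == 0:
        return AdjustedValues(float(out), bool(usable))
    return AdjustedValues(out, usable)


@dataclass(frozen=True)
class CutoffSet:
    """One upper-percentile cut-off for a biomarker within one sex."""

    biomarker: str
    sex: str
    percentile: int
    value: float
    unit: str = ""

    def __post_init__(self):
        if not 0 < self.percentile < 100:
            raise ValueError(f"percentile must lie in (0, 100), got {self.percentile}")


def compute_cutoff(values, percentile, *, biomarker: str = "", sex: str = "",
                   min_n: int = 20, method: str = "linear") -> CutoffSet:
    """Empirical upper-percentile cut-off of a biomarker distribution.

    The percentile convention defaults to linear interpolation between order
    statistics (numpy's default) and is exposed because different conventions
    shift cut-offs on small samples.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < min_n:
        stratum = "/".join(s for s in (biomarker, sex) if s) or "input"
        raise ValueError(
            f"cutoff for {stratum}: need at least {min_n} non-missing values, "
            f"got {arr.size}")
    value = float(np.percentile(arr, percentile, method=method))
    return CutoffSet(biomarker=biomarker, sex=sex, percentile=int(percentile),
                     value=value, unit=BIOMARKER_UNITS.get(biomarker, ""))


def classify_abnormal(values, cutoff):
    """True where the value is strictly above the cut-off ("higher than").

    A value exactly at the cut-off is normal.  Missing values propagate as
    missing (pandas NA) so they can be excluded from denominators, never
    counted as normal.
    """
    cut = cutoff.value if isinstance(cutoff, CutoffSet) else float(cutoff)
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0:
        if np.isnan(arr):
            return pd.NA
        return bool(arr > cut)
    out = pd.array(arr > cut, dtype="boolean")
    out[np.isnan(arr)] = pd.NA
    return out


def population_cutoffs(records: pd.DataFrame, biomarkers=BIOMARKERS,
                       percentiles=(90, 95), method: str = "linear") -> pd.DataFrame:
    """Per-sex, per-biomarker cut-off table over all enrolled subjects.

    Cut-offs are derived from every subject of a sex with a non-missing
    value for the biomarker, not from any dose-grouped subset.
    """
    rows = []
    for biomarker in biomarkers:
        for sex in sorted(records["sex"].unique()):
            vals = records.loc[records["sex"] == sex, biomarker]
            for pct in percentiles:
                cs = compute_cutoff(vals, pct, biomarker=biomarker, sex=sex,
                                    method=method)
                rows.append({"biomarker": biomarker, "unit": cs.unit, "sex": sex,
                             "percentile": pct, "cutoff": cs.value})
    return pd.DataFrame(rows)
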