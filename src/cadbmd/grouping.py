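"""Dose stratification of urinary-cadmium records into quantal group tables.

Subjects are stratified on creatinine-adjusted urinary cadmium (UCd, µg/g Cr)
into fixed concentration bands; each band is summarized by its geometric-mean
dose, its size, and the count of subjects whose biomarker exceeds the
abnormality cut-off.  The resulting quantal table is the input to trend
testing and benchmark-dose fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BOUNDARIES",
    "DoseGroupTable",
    "assign_dose_group",
    "geometric_mean",
    "group_labels",
    "build_prevalence_table",
]

#: Band edges on the 2-dp-rounded UCd scale (µg/g Cr): <=0.49, 0.50-0.99,
#: 1.00-1.49, 1.50-1.99, >=2.00.
DEFAULT_BOUNDARIES = (0.50, 1.00, 1.50, 2.00)


def group_labels(boundaries=DEFAULT_BOUNDARIES) -> tuple[str, ...]:
    """Display labels for the bands implied by the boundaries (2-dp style)."""
    bnd = list(boundaries)
    labels = [f"<={bnd[0] - 0.01:.2f}"]
    labels += [f"{lo:.2f}-{hi - 0.01:.2f}" for lo, hi in zip(bnd[:-1], bnd[1:])]
    labels.append(f">={bnd[-1]:.2f}")
    return tuple(labels)


def assign_dose_group(ucd, boundaries=DEFAULT_BOUNDARIES):
    """Dose-group index (1..k+1) for UCd value(s).

    Values are rounded to 2 decimals first, so the printed band labels
    (e.g. "<=0.49" next to "0.50-0.99") partition the line without a gap;
    bands are half-open at the boundaries.
    """
    arr = np.asarray(ucd, dtype=float)
    if np.any(arr < 0):
        raise ValueError("urinary Cd must be nonnegative")
    bnd = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(bnd) <= 0):
        raise ValueError("boundaries must be strictly increasing")
    idx = np.searchsorted(bnd, np.round(arr, 2), side="right") + 1
    return idx if idx.ndim else int(idx)


def geometric_mean(values, min_positive_fraction: float = 0.5) -> float:
    """Geometric mean exp(mean(ln v)) over the strictly positive values.

    Groups dominated by non-detects (recorded as 0) have no meaningful GM;
    if the positive fraction falls below ``min_positive_fraction`` the
    conventional summary 0 is returned, matching the reporting of an
    all-non-detect lowest band.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("geometric mean of an empty collection is undefined")
    pos = arr > 0
    if pos.mean() < min_positive_fraction:
        return 0.0
    return float(np.exp(np.mean(np.log(arr[pos]))))


@dataclass(frozen=True)
class DoseGroupTable:
    """Quantal summary of one biomarker/sex/cut-off stratification."""

    biomarker: str
    sex: str
    cutoff_percentile: int
    labels: tuple
    doses: tuple
    n: tuple
    positives: tuple

    def __post_init__(self):
        k = len(self.doses)
        if not (len(self.labels) == len(self.n) == len(self.positives) == k):
            raise ValueError("labels, doses, n and positives must have equal length")
        n = np.asarray(self.n)
        y = np.asarray(self.positives)
        if np.any(y > n) or np.any(y < 0) or np.any(n < 0):
            raise ValueError("need 0 <= positives <= n in every group")
        d = np.asarray(self.doses, float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("group doses must be strictly increasing")

    @property
    def total_n(self) -> int:
        return int(sum(self.n))

    @property
    def total_positives(self) -> int:
        return int(sum(self.positives))

    @property
    def prevalence(self) -> np.ndarray:
        """Per-group positive fraction (NaN for empty groups)."""
        n = np.asarray(self.n, float)
        y = np.asarray(self.positives, float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, y / n, np.nan)

    def to_frame(self, totals: bool = True) -> pd.DataFrame:
        df = pd.DataFrame({
            "range": list(self.labels),
            "gm_dose": list(self.doses),
            "n": list(self.n),
            "positives": list(self.positives),
            "prevalence_pct": np.round(100 * self.prevalence, 1),
        })
        if totals:
            tot_prev = round(100 * self.total_positives / self.total_n, 1) \
                if self.total_n else float("nan")
            df.loc[len(df)] = ["Total", np.nan, self.total_n,
                               self.total_positives, tot_prev]
        return df


def build_prevalence_table(records: pd.DataFrame, cutoff: float, biomarker: str,
                           sex: str, percentile: int,
                           boundaries=DEFAULT_BOUNDARIES,
                           ucd_col: str = "ucd") -> DoseGroupTable:
    """Assemble the quantal dose-group table for one biomarker and sex.

    Only subjects of the given sex with a non-missing biomarker enter the
    denominators; positives are counts strictly above the cut-off.  The
    per-group dose is the geometric mean of that group's UCd values.
    """
    sub = records[records["sex"] == sex]
    if sub.empty:
        raise ValueError(f"no records for sex={sex!r}")
    sub = sub[sub[biomarker].notna()]
    groups = assign_dose_group(sub[ucd_col].to_numpy(), boundaries)
    k = len(boundaries) + 1
    n, y, dose = [], [], []
    for i in range(1, k + 1):
        in_g = groups == i
        vals = sub.loc[in_g, biomarker].to_numpy()
        n.append(int(in_g.sum()))
        y.append(int(np.sum(vals > cutoff)))
        dose.append(geometric_mean(sub.loc[in_g, ucd_col].to_numpy())
                    if in_g.any() else np.nan)
    # empty groups are allowed (n=0) but break the strictly-increasing dose
    # check only if interior; give them a placeholder between neighbours
    dose = _fill_empty_doses(dose, boundaries)
    return DoseGroupTable(biomarker=biomarker, sex=sex,
                          cutoff_percentile=int(percentile),
                          labels=group_labels(boundaries),
                          doses=tuple(dose), n=tuple(n), positives=tuple(y))


def _fill_empty_doses(dose, boundaries):
    bnd = list(boundaries)
    mids = [bnd[0] / 2] + [(lo + hi) / 2 for lo, hi in zip(bnd[:-1], bnd[1:])] \
        + [1.5 * bnd[-1]]
    out = [m if (d is None or np.isnan(d)) else d for d, m in zip(dose, mids)]
    # the lowest band may legitimately summarize to 0 (all non-detects)
    for i in range(1, len(out)):
        if out[i] <= out[i - 1]:
            out[i] = mids[i]
    return out
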