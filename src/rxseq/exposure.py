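"""Exposure construction: dispensation records to the 88x18 model input.

The exposure of a patient to each drug is reconstructed from purchase
records under the assumption that a patient who buys a drug again has fully
consumed the previous supply: the amount of each purchase is spread as a
constant daily dose over the interval to the next purchase of the same drug.
The mean daily dose is then averaged within eighteen 30-day windows counted
back from the patient's index date (month 18 being the 30 days immediately
before the index date), smoothed with the weighted sliding average

    D'_m = (D_{m-1} + 4 D_m + D_{m+1}) / 6

to remove artefactual zero months caused by stockpiling, and max-scaled per
drug using scales fitted on training patients only. The 88th row codes
hospitalization (any ward) during the month.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_MONTHS = 18
DAYS_PER_MONTH = 30
DEFAULT_SUPPLY_DAYS = 30
COVERAGE_CAP_DAYS = 90
AGE_LO, AGE_HI = 18.0, 65.0


def coverage_intervals(
    dispensations: pd.DataFrame,
    window_end: pd.Timestamp,
    default_supply_days: int = DEFAULT_SUPPLY_DAYS,
    cap_days: int = COVERAGE_CAP_DAYS,
) -> list[tuple[pd.Timestamp, pd.Timestamp, float]]:
    """Daily-dose coverage intervals for one patient-drug purchase history.

    Each purchase of ``A`` mg followed ``gap`` days later by the next
    purchase of the same drug contributes ``A / gap`` mg/day over
    ``[date, date + min(gap, cap_days))``. The final purchase, which has no
    successor, is spread over ``default_supply_days``. Same-day purchases
    are merged (amounts summed) before the gaps are computed, and intervals
    are truncated at ``window_end``.
    """
    if dispensations.empty:
        return []
    window_end = pd.Timestamp(window_end)
    df = (
        dispensations.assign(date=pd.to_datetime(dispensations["date"]))
        .groupby("date", as_index=False)["total_mg"]
        .sum()
        .sort_values("date")
    )
    df = df[df["date"] < window_end]
    if df.empty:
        return []
    dates = df["date"].to_list()
    amounts = df["total_mg"].to_list()
    intervals = []
    for k, (t, a) in enumerate(zip(dates, amounts)):
        if k + 1 < len(dates):
            gap = (dates[k + 1] - t).days
            dose = a / gap
            span = min(gap, cap_days)
        else:
            dose = a / default_supply_days
            span = default_supply_days
        end = min(t + pd.Timedelta(days=span), window_end)
        if end > t:
            intervals.append((t, end, float(dose)))
    return intervals


def _month_windows(index_date: pd.Timestamp):
    """Half-open 30-day windows; month m (1..18) ends (19-m-1)*30 days back."""
    index_date = pd.Timestamp(index_date)
    out = []
    for m in range(1, N_MONTHS + 1):
        start = index_date - pd.Timedelta(days=(19 - m) * DAYS_PER_MONTH)
        end = index_date - pd.Timedelta(days=(18 - m) * DAYS_PER_MONTH)
        out.append((start, end))
    return out


def monthly_mean_dose(intervals, index_date) -> np.ndarray:
    """Mean daily dose (mg attributed to the window / 30) per month 1..18."""
    doses = np.zeros(N_MONTHS)
    for m, (w_start, w_end) in enumerate(_month_windows(index_date)):
        total_mg = 0.0
        for start, end, dose in intervals:
            lo = max(start, w_start)
            hi = min(end, w_end)
            days = (hi - lo).days
            if days > 0:
                total_mg += dose * days
        doses[m] = total_mg / DAYS_PER_MONTH
    return doses


def smooth_doses(raw: np.ndarray) -> np.ndarray:
    """Sliding weighted average (1, 4, 1)/6 with replicate boundary padding."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("doses must be non-negative")
    padded = np.concatenate([raw[..., :1], raw, raw[..., -1:]], axis=-1)
    return (padded[..., :-2] + 4.0 * padded[..., 1:-1] + padded[..., 2:]) / 6.0


def hospitalization_row(stays: pd.DataFrame, index_date) -> np.ndarray:
    """1 per month iff any hospital stay (either ward) overlaps the window.

    Stays are day-inclusive on both ends; month windows are half-open, so a
    one-day stay on the boundary day belongs to the later month only.
    """
    row = np.zeros(N_MONTHS)
    if stays.empty:
        return row
    starts = pd.to_datetime(stays["start"])
    ends = pd.to_datetime(stays["end"])
    for m, (w_start, w_end) in enumerate(_month_windows(index_date)):
        overlap = (starts < w_end) & (ends >= w_start)
        if bool(overlap.any()):
            row[m] = 1.0
    return row


@dataclass
class ExposureMatrix:
    """One patient's model input before/after normalization.

    ``raw_doses`` and ``smoothed_doses`` are (n_drugs, 18) in mg/day;
    ``static`` is (sex, age_at_inclusion_years, bd, szd) with sex coded
    0 = male, 1 = female.
    """

    patient_id: int
    raw_doses: np.ndarray
    smoothed_doses: np.ndarray
    hospitalized: np.ndarray
    static: np.ndarray

    @property
    def n_drugs(self) -> int:
        return self.raw_doses.shape[0]


def build_exposure_matrix(
    patient_row: pd.Series,
    dispensations: pd.DataFrame,
    stays: pd.DataFrame,
    index_date,
    n_drugs: int,
) -> ExposureMatrix:
    """Assemble one patient's exposure matrix for a given index date.

    Only purchases strictly before ``index_date`` contribute; the age static
    covariate is the age at inclusion, i.e. 18 months before the index date.
    """
    index_date = pd.Timestamp(index_date)
    raw = np.zeros((n_drugs, N_MONTHS))
    if not dispensations.empty:
        for drug_id, grp in dispensations.groupby("drug_id"):
            d = int(drug_id)
            if d >= n_drugs:
                raise ValueError(f"drug_id {d} outside formulary of size {n_drugs}")
            intervals = coverage_intervals(grp, index_date)
            raw[d] = monthly_mean_dose(intervals, index_date)
    smoothed = smooth_doses(raw)
    hosp = hospitalization_row(stays, index_date)
    inclusion = index_date - pd.Timedelta(days=N_MONTHS * DAYS_PER_MONTH)
    age = (inclusion - pd.Timestamp(patient_row["birth_date"])).days / 365.25
    static = np.array(
        [
            float(patient_row["sex"]),
            float(age),
            float(patient_row["bd"]),
            float(patient_row["szd"]),
        ]
    )
    return ExposureMatrix(
        patient_id=int(patient_row["patient_id"]),
        raw_doses=raw,
        smoothed_doses=smoothed,
        hospitalized=hosp,
        static=static,
    )


@dataclass
class NormalizationParams:
    """Per-drug max scales (mg/day, fitted on training patients) + age bounds."""

    drug_scale: np.ndarray
    age_bounds: tuple = (AGE_LO, AGE_HI)

    def to_json(self) -> str:
        return json.dumps(
            {"drug_scale": self.drug_scale.tolist(), "age_bounds": list(self.age_bounds)}
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationParams":
        d = json.loads(text)
        return cls(np.asarray(d["drug_scale"], dtype=float), tuple(d["age_bounds"]))


def fit_normalization(training: list[ExposureMatrix]) -> NormalizationParams:
    """Per-drug max of the smoothed dose over training patients and months.

    Fit on training patients only — test exposures are scaled with these
    parameters, never refit, to avoid leakage.
    """
    if not training:
        raise ValueError("cannot fit normalization on an empty training set")
    stacked = np.stack([m.smoothed_doses for m in training])
    scale = stacked.max(axis=(0, 2))
    return NormalizationParams(drug_scale=scale)


def apply_normalization(matrix: ExposureMatrix, params: NormalizationParams):
    """Scaled (n_drugs+1, 18) input and 4-vector of static covariates.

    Drug rows are divided by the training max (rows whose training max is 0
    stay 0); the hospitalization row passes through; age is mapped by
    (age - 18) / 47.
    """
    if params.drug_scale.shape[0] != matrix.n_drugs:
        raise ValueError("normalization params cover a different formulary")
    scale = np.where(params.drug_scale > 0, params.drug_scale, 1.0)
    drugs = matrix.smoothed_doses / scale[:, None]
    # a drug absent from training carries no usable scale: its row is zeroed
    drugs[params.drug_scale <= 0, :] = 0.0
    grid = np.vstack([drugs, matrix.hospitalized[None, :]])
    lo, hi = params.age_bounds
    static = matrix.static.copy()
    static[1] = (static[1] - lo) / (hi - lo)
    return grid, static


def exposures_to_long(matrices: list[ExposureMatrix]) -> pd.DataFrame:
    """Long-format table (patient_id, feature, month, value) of smoothed doses."""
    records = []
    for m in matrices:
        for d in range(m.n_drugs):
            for month in range(N_MONTHS):
                v = m.smoothed_doses[d, month]
                if v != 0.0:
                    records.append((m.patient_id, f"drug_{d}", month + 1, v))
        for month in range(N_MONTHS):
            if m.hospitalized[month]:
                records.append((m.patient_id, "hospitalized", month + 1, 1.0))
    return pd.DataFrame(records, columns=["patient_id", "feature", "month", "value"])
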