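"""Matched case-control cohort construction and sample bookkeeping.

Cases are patients whose first adverse-event hospitalization occurred at
least 18 months after the initial BD/SZD diagnosis. Each case is matched 1:1
without replacement to a control hospitalized in the same ward type during
the index month who never experienced an adverse event, with exact agreement
on sex, BD/SZD flags, neurological comorbidity flags, Charlson integer, and
age in completed years at inclusion (18 months before the index date), with
fallback to +/-1 then +/-2 years when no exact-age candidate remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import DAYS_PER_MONTH, N_MONTHS
from .synthetic import EVENT_NAMES, NEURO_FLAGS

MATCH_MONTHS_BEFORE = 18


@dataclass
class CaseRecord:
    patient_id: int
    index_date: pd.Timestamp
    labels: np.ndarray  # binary[9], at least one set
    ward: str


@dataclass
class MatchedPair:
    case: CaseRecord
    control: int


@dataclass
class SelectionCounts:
    screened: int
    with_event: int
    eligible: int


def select_cases(
    events: pd.DataFrame, patients: pd.DataFrame
) -> tuple[list[CaseRecord], SelectionCounts]:
    """First qualifying adverse-event hospitalization per patient.

    An event qualifies if it falls at least 18 months (540 days) after the
    patient's initial diagnosis date. Returns screening counts for the
    flowchart-style report.
    """
    screened = len(patients)
    if events.empty:
        return [], SelectionCounts(screened, 0, 0)
    ev = events.assign(date=pd.to_datetime(events["date"]))
    diag = pd.to_datetime(
        patients.set_index("patient_id")["diagnosis_date"]
    )
    with_event = ev["patient_id"].nunique()
    cases: list[CaseRecord] = []
    for pid, grp in ev.sort_values("date", kind="stable").groupby("patient_id"):
        cutoff = diag.loc[int(pid)] + pd.Timedelta(days=MATCH_MONTHS_BEFORE * DAYS_PER_MONTH)
        ok = grp[grp["date"] >= cutoff]
        if ok.empty:
            continue
        first = ok.iloc[0]
        labels = first[EVENT_NAMES].to_numpy(dtype=int)
        if labels.sum() == 0:
            continue
        cases.append(
            CaseRecord(
                patient_id=int(pid),
                index_date=first["date"],
                labels=labels,
                ward=str(first["ward"]),
            )
        )
    return cases, SelectionCounts(screened, int(with_event), len(cases))


def _match_key(row: pd.Series) -> tuple:
    return (
        int(row["sex"]),
        int(row["bd"]),
        int(row["szd"]),
        *(int(row[f]) for f in NEURO_FLAGS),
        int(row["charlson"]),
    )


def _age_years(birth: pd.Timestamp, at: pd.Timestamp) -> int:
    return int((pd.Timestamp(at) - pd.Timestamp(birth)).days // 365.25)


def match_controls(
    cases: list[CaseRecord],
    patients: pd.DataFrame,
    stays: pd.DataFrame,
    events: pd.DataFrame,
    seed: int,
) -> tuple[list[MatchedPair], list[int]]:
    """1:1 matching without replacement; returns (pairs, unmatched case ids).

    Candidates are patients with no adverse-event record at any time who
    were hospitalized in the case's ward type during the case's index month
    (the 30 days ending at the index date). Exact keys: sex, BD, SZD, the
    six neurological flags, Charlson. Age at inclusion is matched exactly in
    completed years, then +/-1, then +/-2. Ties among equally good
    candidates are broken by a seeded uniform draw.
    """
    rng = np.random.default_rng(seed)
    event_ids = set(events["patient_id"].tolist()) if len(events) else set()
    pat = patients.set_index("patient_id", drop=False)
    birth = pd.to_datetime(pat["birth_date"])

    stay_start = pd.to_datetime(stays["start"]) if len(stays) else pd.Series(dtype="datetime64[ns]")
    stay_end = pd.to_datetime(stays["end"]) if len(stays) else pd.Series(dtype="datetime64[ns]")
    stay_pid = stays["patient_id"] if len(stays) else pd.Series(dtype=np.int64)
    stay_ward = stays["ward"] if len(stays) else pd.Series(dtype=str)

    case_ids = {c.patient_id for c in cases}
    used: set[int] = set()
    pairs: list[MatchedPair] = []
    unmatched: list[int] = []

    order = rng.permutation(len(cases))
    for ci in order:
        case = cases[ci]
        # the index month runs from the event admission forward: the case's
        # own event stay overlaps it, and a control stay here never leaks
        # into the 18-month pre-index exposure window
        index_date = pd.Timestamp(case.index_date)
        w_end = index_date + pd.Timedelta(days=DAYS_PER_MONTH)
        in_window = (
            (stay_start < w_end)
            & (stay_end >= index_date)
            & (stay_ward == case.ward)
        )
        pool_ids = set(stay_pid[in_window].tolist())
        pool_ids -= event_ids
        pool_ids -= case_ids
        pool_ids -= used
        pool_ids.discard(case.patient_id)
        if not pool_ids:
            unmatched.append(case.patient_id)
            continue

        key = _match_key(pat.loc[case.patient_id])
        inclusion = index_date - pd.Timedelta(days=MATCH_MONTHS_BEFORE * DAYS_PER_MONTH)
        case_age = _age_years(birth.loc[case.patient_id], inclusion)

        candidates = sorted(pool_ids)
        keyed = [
            (pid, abs(_age_years(birth.loc[pid], inclusion) - case_age))
            for pid in candidates
            if _match_key(pat.loc[pid]) == key
        ]
        chosen = None
        for band in (0, 1, 2):
            in_band = [pid for pid, d in keyed if d == band]
            if in_band:
                chosen = in_band[int(rng.integers(len(in_band)))]
                break
        if chosen is None:
            unmatched.append(case.patient_id)
            continue
        used.add(chosen)
        pairs.append(MatchedPair(case=case, control=chosen))
    # restore input order of the cases for downstream determinism
    pairs.sort(key=lambda p: p.case.patient_id)
    unmatched.sort()
    return pairs, unmatched


def split_train_test(
    pairs: list[MatchedPair], seed: int, test_fraction: float = 0.2
) -> tuple[list[MatchedPair], list[MatchedPair]]:
    """80/20 split at the pair level — a case and its control never straddle."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_test = int(round(len(pairs) * test_fraction))
    test_idx = set(order[:n_test].tolist())
    train = [p for i, p in enumerate(pairs) if i not in test_idx]
    test = [p for i, p in enumerate(pairs) if i in test_idx]
    return train, test


def kfold(pairs: list[MatchedPair], k: int = 5, seed: int = 0):
    """k disjoint (train-subset, validation-subset) partitions of the pairs."""
    if len(pairs) < k:
        raise ValueError(f"need at least {k} pairs for {k}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    folds = np.array_split(order, k)
    out = []
    for i in range(k):
        val_idx = set(folds[i].tolist())
        train = [p for j, p in enumerate(pairs) if j not in val_idx]
        val = [p for j, p in enumerate(pairs) if j in val_idx]
        out.append((train, val))
    return out


@dataclass
class EventWeights:
    """Loss weights w_e = 1 - training frequency of event e."""

    w: np.ndarray = field(default_factory=lambda: np.ones(len(EVENT_NAMES)))


def compute_loss_weights(labels: np.ndarray) -> EventWeights:
    """w_e = 1 - (positives of event e) / (individuals), controls included.

    Events absent from the training sample get weight 1.0 with a warning —
    the loss then never down-weights their (nonexistent) positives.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[1] != len(EVENT_NAMES):
        raise ValueError(f"labels must be (n, {len(EVENT_NAMES)})")
    n = labels.shape[0]
    counts = labels.sum(axis=0)
    w = 1.0 - counts / n
    for e in np.nonzero(counts == 0)[0]:
        warnings.warn(f"event '{EVENT_NAMES[e]}' absent from training data; weight 1.0")
    return EventWeights(w=w.astype(float))


def percentage(count: int, total: int, digits: int = 1) -> float:
    """Cohort-report percentage, rounded for display."""
    if total == 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, digits)


def cohort_summary(
    pairs: list[MatchedPair], patients: pd.DataFrame, labels: np.ndarray
) -> dict:
    """Table-1-style report: counts/percentages by arm plus event frequencies."""
    if not pairs:
        return {}
    pat = patients.set_index("patient_id")
    out: dict = {"n_pairs": len(pairs)}
    for arm, ids in (
        ("cases", [p.case.patient_id for p in pairs]),
        ("controls", [p.control for p in pairs]),
    ):
        sub = pat.loc[ids]
        n = len(sub)
        arm_report = {
            "n": n,
            "female_pct": percentage(int(sub["sex"].sum()), n),
            "bd_pct": percentage(int(sub["bd"].sum()), n),
            "szd_pct": percentage(int(sub["szd"].sum()), n),
            "charlson_nonzero_pct": percentage(int((sub["charlson"] > 0).sum()), n),
            "mean_age": float(
                np.round(
                    (
                        (pd.Timestamp("2020-01-01") - pd.to_datetime(sub["birth_date"]))
                        .dt.days
                        / 365.25
                    ).mean(),
                    1,
                )
            ),
        }
        for f in NEURO_FLAGS:
            arm_report[f"{f}_pct"] = percentage(int(sub[f].sum()), n)
        out[arm] = arm_report
    out["psychiatric_ward_pct"] = percentage(
        sum(1 for p in pairs if p.case.ward == "psychiatric"), len(pairs)
    )
    labels = np.asarray(labels)
    out["events_among_cases"] = {
        EVENT_NAMES[e]: percentage(int(labels[:, e].sum()), len(pairs))
        for e in range(len(EVENT_NAMES))
    }
    return out
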