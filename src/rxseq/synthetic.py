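"""Seeded synthetic claims-style cohorts with planted iatrogenic effects.

Emulates the data structure of a national claims extract for adults with
bipolar (BD) or schizophrenia-spectrum (SZD) disorders: outpatient drug
dispensations (date, drug, total mg) at irregular intervals, hospital stays
in psychiatric or non-psychiatric wards, demographics/diagnoses, and nine
non-mutually-exclusive in-hospital adverse events whose monthly hazard
depends on current dose, recent dose change, age, and sex.

Prescription dynamics are a per-drug monthly Markov process: a drug switches
on with ``initiation_rate`` per month and off with ``discontinuation_rate``;
while on, the daily dose is lognormal around the drug's typical dose
(titration noise resampled monthly). Purchases happen when the previous pack
is exhausted at the current daily dose, jittered by up to +/-7 days, so
inter-purchase gaps are irregular as in real reimbursement data.

Adverse events are generated from the *true* (unsmoothed) monthly doses;
smoothing is part of the downstream analysis, not of the simulated world.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30
N_EVENTS = 9

EVENT_NAMES = [
    "urinary_retention",
    "constipation",
    "electrolyte_imbalance",
    "motor_disorder",
    "delirium",
    "seizure",
    "pneumonia",
    "cardiac_disorder",
    "thyroid_disorder",
]

NEURO_FLAGS = [
    "traumatic_brain_injury",
    "parkinson",
    "dementia",
    "multiple_sclerosis",
    "epilepsy",
    "cerebrovascular",
]

#: marginal prevalence of each neurological comorbidity (per the matched
#: cohort: 1%, 0.1%, 0.1%, <0.1%, 0.8%, 0.8%)
NEURO_PREVALENCE = [0.010, 0.001, 0.001, 0.0004, 0.008, 0.008]

#: probability that the index hospitalization is in a psychiatric ward
PSY_WARD_PROB = 0.336

ORIGIN = pd.Timestamp("2015-01-01")


@dataclass(frozen=True)
class DrugProfile:
    drug_id: int
    typical_daily_dose_mg: float
    pack_size_mg: float
    initiation_rate: float
    discontinuation_rate: float
    titration_sd: float

    def __post_init__(self) -> None:
        if self.typical_daily_dose_mg <= 0 or self.pack_size_mg <= 0:
            raise ValueError("doses must be positive")
        for r in (self.initiation_rate, self.discontinuation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class EventHazardSpec:
    """Planted ground-truth hazard for the nine adverse events.

    Monthly probability of event ``e`` for patient ``i`` at month ``m``:

        logistic( baseline[e] + age_coef[e] * (age - 45)
                  + sex_coef[e] * female
                  + sum_d dose_coefs[e][d] * dose_{i,d,m}
                  + sum_d recency_coefs[e][d] * (dose_{i,d,m} - dose_{i,d,m-k}) )

    ``dose_coefs``/``recency_coefs`` map event index -> {drug_id: per-mg/day
    coefficient}; absent entries are zero.
    """

    #: default gives ~27% of patients an event over a 24-month record
    baseline: tuple = tuple([-5.2] * N_EVENTS)
    age_coef: tuple = tuple([0.01] * N_EVENTS)
    sex_coef: tuple = tuple([0.0] * N_EVENTS)
    dose_coefs: dict = field(default_factory=dict)
    recency_coefs: dict = field(default_factory=dict)
    recency_window_k: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.recency_window_k <= 6:
            raise ValueError("recency_window_k must be in [1, 6]")
        for name in ("baseline", "age_coef", "sex_coef"):
            if len(getattr(self, name)) != N_EVENTS:
                raise ValueError(f"{name} must have {N_EVENTS} entries")


def default_formulary(n_drugs: int = 87, seed: int = 87) -> list[DrugProfile]:
    """A deterministic formulary of ``n_drugs`` psychotropic-like profiles.

    Typical daily doses span the psychotropic range (2 mg anticholinergics to
    ~800 mg quetiapine-like), packs hold roughly a 30-day supply, and
    initiation/discontinuation rates reproduce sparse, intermittent use.
    """
    rng = np.random.default_rng(seed)
    doses = np.exp(rng.uniform(np.log(2.0), np.log(800.0), size=n_drugs))
    profiles = []
    for d in range(n_drugs):
        typical = float(np.round(doses[d], 1))
        profiles.append(
            DrugProfile(
                drug_id=d,
                typical_daily_dose_mg=typical,
                pack_size_mg=float(np.round(typical * DAYS_PER_MONTH, 1)),
                initiation_rate=float(rng.uniform(0.005, 0.03)),
                discontinuation_rate=float(rng.uniform(0.05, 0.20)),
                titration_sd=0.3,
            )
        )
    return profiles


@dataclass(frozen=True)
class SyntheticSpec:
    n_patients: int
    seed: int
    n_drugs: int = 87
    female_fraction: float = 0.537
    age_range: tuple = (18, 65)
    #: probabilities of (BD only, SZD only, both); per the cohort: 30.4% /
    #: 49.8% / 19.8%
    dx_prevalence: tuple = (0.304, 0.498, 0.198)
    #: categorical over Charlson {0, 1, 2, 3+}; 44.9% nonzero overall
    charlson_distribution: tuple = (0.551, 0.214, 0.135, 0.100)
    formulary: tuple = None
    hazard_model: EventHazardSpec = field(default_factory=EventHazardSpec)
    months_simulated: int = 24

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.n_drugs < 1:
            raise ValueError("n_drugs must be >= 1")
        if self.months_simulated < 19:
            raise ValueError("months_simulated must be >= 19")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be a probability")
        for name, probs, partition in (
            ("dx_prevalence", self.dx_prevalence, False),
            ("charlson_distribution", self.charlson_distribution, True),
        ):
            arr = np.asarray(probs, dtype=float)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            total = float(arr.sum())
            if partition and abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if not partition and total > 1.0 + 1e-9:
                raise ValueError(f"{name} must sum to at most 1 (got {total})")
        if self.formulary is not None and len(self.formulary) != self.n_drugs:
            raise ValueError("formulary length must equal n_drugs")

    def resolved_formulary(self) -> list[DrugProfile]:
        if self.formulary is not None:
            return list(self.formulary)
        return default_formulary(self.n_drugs)


# ---------------------------------------------------------------------------
# cohort table


def generate_cohort(spec: SyntheticSpec) -> pd.DataFrame:
    """Patient-level table: demographics, diagnoses, Charlson index.

    Deterministic under a fixed ``spec.seed``: two calls with the same spec
    return byte-identical tables.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    n = spec.n_patients
    sex = (rng.random(n) < spec.female_fraction).astype(np.int64)  # 1 = female
    lo, hi = spec.age_range
    age = rng.uniform(lo, hi, size=n)

    p_bd, p_szd, p_both = spec.dx_prevalence
    u = rng.random(n)
    bd = ((u < p_bd) | (u >= p_bd + p_szd)).astype(np.int64)
    szd = (u >= p_bd).astype(np.int64)
    # residual mass (1 - sum) would leave neither flag set; clamp to BD so the
    # inclusion criterion (BD or SZD) always holds
    neither = (bd == 0) & (szd == 0)
    bd[neither] = 1

    charlson = rng.choice(
        np.arange(len(spec.charlson_distribution)),
        size=n,
        p=np.asarray(spec.charlson_distribution, dtype=float),
    ).astype(np.int64)

    neuro = {
        flag: (rng.random(n) < p).astype(np.int64)
        for flag, p in zip(NEURO_FLAGS, NEURO_PREVALENCE)
    }

    # diagnosis at the simulation origin; the dispensation record then spans
    # months_simulated months, so events after month 18 satisfy the
    # ">= 18 months after initial diagnosis" criterion
    diagnosis_date = ORIGIN
    birth = diagnosis_date - pd.to_timedelta(np.round(age * 365.25), unit="D")

    table = pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=np.int64),
            "sex": sex,
            "birth_date": birth.strftime("%Y-%m-%d") if n else pd.Series([], dtype=str),
            "bd": bd,
            "szd": szd,
            "charlson": charlson,
            "diagnosis_date": diagnosis_date.strftime("%Y-%m-%d"),
        }
    )
    for flag in NEURO_FLAGS:
        table[flag] = neuro[flag]
    if n == 0:
        table = table.astype(
            {"birth_date": str, "diagnosis_date": str}, errors="ignore"
        )
    return table


# ---------------------------------------------------------------------------
# dispensations, true doses, hospital stays


def _simulate_doses(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """True daily dose per (patient, drug, month): the Markov on/off process."""
    n, d, m = spec.n_patients, spec.n_drugs, spec.months_simulated
    profiles = spec.resolved_formulary()
    init = np.array([p.initiation_rate for p in profiles])
    disc = np.array([p.discontinuation_rate for p in profiles])
    typical = np.array([p.typical_daily_dose_mg for p in profiles])
    sd = np.array([p.titration_sd for p in profiles])

    doses = np.zeros((n, d, m))
    on = rng.random((n, d)) < init  # stationary-ish start: one step from off
    for month in range(m):
        if month > 0:
            u = rng.random((n, d))
            on = np.where(on, u >= disc, u < init)
        z = rng.normal(0.0, 1.0, size=(n, d))
        dose = typical * np.exp(sd * z)
        doses[:, :, month] = np.where(on, dose, 0.0)
    return doses


def _purchases_from_doses(
    spec: SyntheticSpec, doses: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Supply-exhaustion purchase dates from the true dose trajectory.

    While a drug is on, a pack of ``pack_size_mg`` is bought whenever the
    previous supply runs out at the prevailing daily dose, with uniform
    jitter of +/-7 days — gaps between purchases therefore vary even under a
    constant dose.
    """
    profiles = spec.resolved_formulary()
    rows_pid, rows_day, rows_drug, rows_mg = [], [], [], []
    n, n_drugs, m = doses.shape
    jitter = rng.integers(-7, 8, size=n * n_drugs * (m + 2) or 1)
    j = 0
    for i in range(n):
        for d in range(n_drugs):
            traj = doses[i, d]
            active = np.nonzero(traj > 0)[0]
            if active.size == 0:
                continue
            pack = profiles[d].pack_size_mg
            next_day = None
            for month in active:
                start, end = month * DAYS_PER_MONTH, (month + 1) * DAYS_PER_MONTH
                if next_day is None or next_day < start:
                    next_day = start  # (re)initiation: buy at month start
                while next_day < end:
                    rows_pid.append(i)
                    rows_day.append(next_day)
                    rows_drug.append(d)
                    rows_mg.append(pack)
                    supply_days = pack / traj[month]
                    step = max(1, int(round(supply_days)) + int(jitter[j % jitter.size]))
                    j += 1
                    next_day += step
    dates = ORIGIN + pd.to_timedelta(rows_day, unit="D")
    return pd.DataFrame(
        {
            "patient_id": np.asarray(rows_pid, dtype=np.int64),
            "date": dates.strftime("%Y-%m-%d"),
            "drug_id": np.asarray(rows_drug, dtype=np.int64),
            "total_mg": np.asarray(rows_mg, dtype=float),
        }
    )


def _background_stays(
    spec: SyntheticSpec, rng: np.random.Generator, p_month: float = 0.12
) -> pd.DataFrame:
    """Hospital stays unrelated to the adverse events (any ward).

    The monthly stay probability reflects a heavily hospitalized severe
    mental illness population (roughly one stay per 8 months); it also sets
    the density of ward-matched control candidates in the index month.
    """
    n, m = spec.n_patients, spec.months_simulated
    hit = rng.random((n, m)) < p_month
    pid, month = np.nonzero(hit)
    offset = rng.integers(0, DAYS_PER_MONTH - 1, size=pid.size)
    length = rng.integers(1, 15, size=pid.size)
    psy = rng.random(pid.size) < PSY_WARD_PROB
    start_day = month * DAYS_PER_MONTH + offset
    starts = ORIGIN + pd.to_timedelta(start_day, unit="D")
    ends = ORIGIN + pd.to_timedelta(start_day + length, unit="D")
    return pd.DataFrame(
        {
            "patient_id": pid.astype(np.int64),
            "start": starts.strftime("%Y-%m-%d"),
            "end": ends.strftime("%Y-%m-%d"),
            "ward": np.where(psy, "psychiatric", "non-psychiatric"),
        }
    )


def generate_dispensations(
    patients: pd.DataFrame, spec: SyntheticSpec
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Dispensation and hospital-stay tables plus the true dose array.

    Returns ``(dispensations, hospital_stays, true_doses)`` where
    ``true_doses`` has shape (n_patients, n_drugs, months_simulated) in
    mg/day — the latent exposure the event hazard acts on.
    """
    if len(patients) != spec.n_patients:
        raise ValueError("patients table does not match spec.n_patients")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    doses = _simulate_doses(spec, rng)
    dispensations = _purchases_from_doses(spec, doses, rng)
    stays = _background_stays(spec, rng)
    return dispensations, stays, doses


# ---------------------------------------------------------------------------
# adverse events


def _monthly_event_probs(
    patients: pd.DataFrame, doses: np.ndarray, spec: SyntheticSpec
) -> np.ndarray:
    """P(event e in month m | no prior event) of shape (n, 9, months)."""
    from scipy.special import expit

    hz = spec.hazard_model
    n, n_drugs, m = doses.shape
    age = (
        pd.Timestamp(ORIGIN) - pd.to_datetime(patients["birth_date"])
    ).dt.days.to_numpy() / 365.25
    female = patients["sex"].to_numpy()

    eta = np.empty((n, N_EVENTS, m))
    base = np.asarray(hz.baseline)
    eta[:] = base[None, :, None]
    eta += np.asarray(hz.age_coef)[None, :, None] * (age - 45.0)[:, None, None]
    eta += np.asarray(hz.sex_coef)[None, :, None] * female[:, None, None]

    k = hz.recency_window_k
    lagged = np.zeros_like(doses)
    lagged[:, :, k:] = doses[:, :, :-k]
    delta = doses - lagged
    for e in range(N_EVENTS):
        for drug_id, coef in hz.dose_coefs.get(e, {}).items():
            eta[:, e, :] += coef * doses[:, drug_id, :]
        for drug_id, coef in hz.recency_coefs.get(e, {}).items():
            eta[:, e, :] += coef * delta[:, drug_id, :]
    return expit(eta)


def generate_events(
    patients: pd.DataFrame, true_doses: np.ndarray, spec: SyntheticSpec
) -> pd.DataFrame:
    """Adverse-event hospitalizations: at most one (the first) per patient.

    Each of the nine events fires independently each month with its hazard
    probability; the first month in which at least one fires becomes the
    event hospitalization, labelled with the 9-bit vector of everything that
    fired that month. Only months >= 19 are eligible so every case has a full
    18-month pre-event record.
    """
    if true_doses.shape[0] != len(patients):
        raise ValueError("exposure array does not match patients table")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    probs = _monthly_event_probs(patients, true_doses, spec)
    n, _, m = probs.shape
    fires = rng.random((n, N_EVENTS, m)) < probs  # (n, 9, months)
    eligible = np.zeros(m, dtype=bool)
    eligible[18:] = True
    any_fire = fires.any(axis=1) & eligible[None, :]

    rows = []
    day_offsets = rng.integers(0, DAYS_PER_MONTH, size=n)
    psy = rng.random(n) < PSY_WARD_PROB
    for i in range(n):
        months = np.nonzero(any_fire[i])[0]
        if months.size == 0:
            continue
        month = int(months[0])
        labels = fires[i, :, month].astype(int)
        date = ORIGIN + pd.Timedelta(days=month * DAYS_PER_MONTH + int(day_offsets[i]))
        rows.append(
            {
                "patient_id": int(patients["patient_id"].iloc[i]),
                "date": date.strftime("%Y-%m-%d"),
                "ward": "psychiatric" if psy[i] else "non-psychiatric",
                **{EVENT_NAMES[e]: int(labels[e]) for e in range(N_EVENTS)},
            }
        )
    cols = ["patient_id", "date", "ward", *EVENT_NAMES]
    if not rows:
        return pd.DataFrame(columns=cols).astype({"patient_id": np.int64})
    return pd.DataFrame(rows, columns=cols)


def generate_dataset(spec: SyntheticSpec) -> dict:
    """Full synthetic dataset: patients, dispensations, stays, events.

    Event hospitalizations are appended to the stay table (the index
    admission is itself a stay, in the ward recorded on the event row).
    """
    patients = generate_cohort(spec)
    dispensations, stays, doses = generate_dispensations(patients, spec)
    events = generate_events(patients, doses, spec)
    if len(events):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
        lengths = rng.integers(2, 12, size=len(events))
        ev_stays = pd.DataFrame(
            {
                "patient_id": events["patient_id"].to_numpy(),
                "start": events["date"].to_numpy(),
                "end": (
                    pd.to_datetime(events["date"]) + pd.to_timedelta(lengths, unit="D")
                ).dt.strftime("%Y-%m-%d"),
                "ward": events["ward"].to_numpy(),
            }
        )
        stays = pd.concat([stays, ev_stays], ignore_index=True)
        stays = stays.sort_values(["patient_id", "start"], kind="stable").reset_index(
            drop=True
        )
    return {
        "patients": patients,
        "dispensations": dispensations,
        "hospital_stays": stays,
        "events": events,
        "true_doses": doses,
    }


def write_dataset(dataset: dict, outdir) -> None:
    """Write the four CSV tables with ISO-8601 dates."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("patients", "dispensations", "hospital_stays", "events"):
        dataset[name].to_csv(out / f"{name}.csv", index=False)


def spec_to_dict(spec: SyntheticSpec) -> dict:
    """JSON/YAML-serializable description that fully determines a dataset."""
    d = dataclasses.asdict(spec)
    d["hazard_model"]["dose_coefs"] = {
        str(e): {str(k): v for k, v in m.items()}
        for e, m in spec.hazard_model.dose_coefs.items()
    }
    d["hazard_model"]["recency_coefs"] = {
        str(e): {str(k): v for k, v in m.items()}
        for e, m in spec.hazard_model.recency_coefs.items()
    }
    if spec.formulary is not None:
        d["formulary"] = [dataclasses.asdict(p) for p in spec.formulary]
    return d


def spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d)
    hz = d.get("hazard_model")
    if isinstance(hz, dict):
        hz = dict(hz)
        for key in ("dose_coefs", "recency_coefs"):
            hz[key] = {
                int(e): {int(k): float(v) for k, v in m.items()}
                for e, m in hz.get(key, {}).items()
            }
        for key in ("baseline", "age_coef", "sex_coef"):
            if key in hz:
                hz[key] = tuple(hz[key])
        d["hazard_model"] = EventHazardSpec(**hz)
    if d.get("formulary") is not None:
        d["formulary"] = tuple(DrugProfile(**p) for p in d["formulary"])
    for key in ("age_range", "dx_prevalence", "charlson_distribution"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SyntheticSpec(**d)
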