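"""Shared fixtures: planted-signal cohorts and trained models.

Everything is generated programmatically and seeded; the heavier trained
models are session-scoped so several tests can share one fit.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

from rxseq import cohort as C
from rxseq import model as M
from rxseq import pipeline as P
from rxseq import synthetic as S


def make_planted_formulary(n_drugs: int = 8):
    """Default formulary but with drug 0 widely used (clear planted signal)."""
    form = list(S.default_formulary(n_drugs))
    form[0] = dataclasses.replace(
        form[0], initiation_rate=0.15, discontinuation_rate=0.08
    )
    return form


def single_drug_hazard(form, event: int = 0, strength: float = 2.5):
    """Hazard where only drug 0 carries risk, and only for one event."""
    base = [-30.0] * S.N_EVENTS
    base[event] = -4.5
    return S.EventHazardSpec(
        baseline=tuple(base),
        age_coef=tuple([0.0] * S.N_EVENTS),
        sex_coef=tuple([0.0] * S.N_EVENTS),
        dose_coefs={event: {0: strength / form[0].typical_daily_dose_mg}},
    )


def strong_hazard(form):
    """Several strong dose and dose-change effects across events.

    Per-typical-dose log-odds around 1.5-2 ("strong" in the sense that a
    typical user's dose roughly quadruples the monthly event odds).
    """
    typ = [p.typical_daily_dose_mg for p in form]
    return S.EventHazardSpec(
        dose_coefs={
            0: {0: 2.0 / typ[0]},
            2: {1: 2.0 / typ[1]},
            6: {2: 1.5 / typ[2]},
            8: {3: 1.5 / typ[3]},
        },
        recency_coefs={5: {0: 1.5 / typ[0]}, 6: {2: 1.0 / typ[2]}},
    )


def null_hazard():
    """No dose, age or sex effects: outcomes carry no learnable signal."""
    return S.EventHazardSpec(
        age_coef=tuple([0.0] * S.N_EVENTS), sex_coef=tuple([0.0] * S.N_EVENTS)
    )


def fit_planted_cohort(seed, hazard, formulary, n_patients=2000, max_epochs=60,
                       patience=15):
    """Generate, match, normalize and train; returns model + arrays dict."""
    spec = S.SyntheticSpec(
        n_patients=n_patients, seed=seed, n_drugs=len(formulary),
        months_simulated=24, formulary=tuple(formulary), hazard_model=hazard,
    )
    dataset = S.generate_dataset(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        asm = P.assemble_cohort(dataset, match_seed=seed + 1, split_seed=seed + 2)
        sub_tr, sub_val = C.split_train_test(asm["train_pairs"], seed + 3)
        net = M.build_model(M.ModelConfig(), seed=seed + 4)
        fit = M.train_with_early_stopping(
            net,
            P.subset_arrays(sub_tr, asm["train_pairs"], asm["X_train"],
                            asm["S_train"], asm["y_train"]),
            P.subset_arrays(sub_val, asm["train_pairs"], asm["X_train"],
                            asm["S_train"], asm["y_train"]),
            M.TrainConfig(max_epochs=max_epochs, patience=patience, seed=seed + 4),
            asm["weights"],
        )
    asm["net"] = net
    asm["fit"] = fit
    asm["dataset"] = dataset
    asm["spec"] = spec
    return asm


FEATURE_NAMES = [f"drug_{d}" for d in range(P.N_DRUGS_MODEL)] + ["hospitalized"]


@pytest.fixture(scope="session")
def planted_run():
    """One trained planted-signal cohort shared by the slower tests."""
    form = make_planted_formulary()
    return fit_planted_cohort(
        seed=200, hazard=single_drug_hazard(form), formulary=form
    )


def simulate_matched_pairs(n_pairs, gamma, seed, baseline=-2.0,
                           exposure_prob=0.3, dose_mu=np.log(50.0), dose_sd=0.5):
    """Matched pairs from a planted logistic dose hazard.

    Subjects carry a zero-inflated lognormal daily dose; events follow
    logistic(baseline + gamma * dose). Each case is paired with a random
    non-event control, so the paired conditional likelihood is exactly the
    within-pair logistic model with coefficient gamma.
    """
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    x_case, x_control = [], []
    while len(x_case) < n_pairs:
        m = 8 * n_pairs
        dose = np.where(
            rng.random(m) < exposure_prob,
            np.exp(rng.normal(dose_mu, dose_sd, size=m)),
            0.0,
        )
        y = rng.random(m) < expit(baseline + gamma * dose)
        cases = dose[y]
        controls = dose[~y]
        k = min(len(cases), len(controls), n_pairs - len(x_case))
        x_case.extend(cases[:k])
        x_control.extend(controls[:k])
    return np.asarray(x_case)[:, None], np.asarray(x_control)[:, None]
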