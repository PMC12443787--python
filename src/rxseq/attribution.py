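"""Expected-gradients (SHAP-style) attributions and their aggregations.

For each patient and each of the nine outputs, the attribution of feature j
is the Monte-Carlo estimate

    phi_j = E_{x' ~ background, a ~ U(0,1)} [ (x_j - x'_j) *
             df(x' + a (x - x')) / dx_j ]

which converges to the Aumann-Shapley value and satisfies completeness:
sum_j phi_j ~= f(x) - E_background f. Attributions are converted to relative
percentages of the patient's total absolute attribution so they can be
compared across patients, then averaged across months (temporal importance,
with a cumulative tail used to read off how many recent months carry half
the decision) or across features (feature ranking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AttributionTensor:
    """phi per (patient, outcome) over the time grid and static features.

    ``grid`` has shape (n, n_outputs, months, features); ``static`` has
    shape (n, n_outputs, 4).
    """

    grid: np.ndarray
    static: np.ndarray
    n_samples: int
    background_size: int
    #: Monte-Carlo standard error of the per-(patient, outcome) total
    #: attribution — the natural yardstick for the completeness check
    total_se: np.ndarray = None


def expected_gradients(
    model, X, static, background: tuple, n_samples: int = 200, seed: int = 0
) -> AttributionTensor:
    """Monte-Carlo expected gradients for every patient and outcome.

    ``model`` is anything with an ``input_gradients``-compatible callable:
    here either a fitted :class:`rxseq.model.Model` (routed through
    :func:`rxseq.model.input_gradients`) or any object exposing
    ``input_gradients(X, static) -> (probs, dX, dstatic)``. ``background``
    is ``(X_bg, static_bg)`` drawn from training patients. Deterministic
    per seed.
    """
    from . import model as model_mod

    X_bg, S_bg = background
    if X_bg.shape[0] == 0:
        raise ValueError("background set is empty")
    if hasattr(model, "input_gradients"):
        grad_fn = model.input_gradients
    else:
        grad_fn = lambda Xb, Sb: model_mod.input_gradients(model, Xb, Sb)

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    # output dims probed on one evaluation
    probe, _, _ = grad_fn(X[:1], static[:1])
    k = probe.shape[1]
    grid = np.zeros((n, k) + X.shape[1:])
    stat = np.zeros((n, k, static.shape[1]))
    total_se = np.zeros((n, k))
    for i in range(n):
        bidx = rng.integers(0, X_bg.shape[0], size=n_samples)
        alpha = rng.random(n_samples)
        dX_full = X[i][None] - X_bg[bidx]  # (s, T, F)
        dS_full = static[i][None] - S_bg[bidx]
        Xi = X_bg[bidx] + alpha[:, None, None] * dX_full
        Si = S_bg[bidx] + alpha[:, None] * dS_full
        _, gX, gS = grad_fn(Xi, Si)  # (s, k, T, F), (s, k, 4)
        contrib_grid = dX_full[:, None] * gX
        contrib_stat = dS_full[:, None] * gS
        grid[i] = contrib_grid.mean(axis=0)
        stat[i] = contrib_stat.mean(axis=0)
        per_draw_total = contrib_grid.sum(axis=(2, 3)) + contrib_stat.sum(axis=2)
        total_se[i] = per_draw_total.std(axis=0, ddof=1) / np.sqrt(n_samples)
    return AttributionTensor(
        grid=grid, static=stat, n_samples=n_samples,
        background_size=X_bg.shape[0], total_se=total_se,
    )


@dataclass
class RelativeAttribution:
    """phi as signed percentages of the per-(patient, outcome) total |phi|."""

    grid: np.ndarray  # (n, k, months, features), percent
    static: np.ndarray  # (n, k, 4), percent
    denominator: np.ndarray  # (n, k) total absolute attribution


def to_relative(att: AttributionTensor) -> RelativeAttribution:
    """pct_j = 100 phi_j / sum_k |phi_k| per patient-outcome.

    The denominator includes the static features; a zero denominator yields
    all-zero percentages. Scale-invariant: multiplying phi by c > 0 leaves
    pct unchanged, and sum |pct| = 100 wherever the denominator is positive.
    """
    if not (np.all(np.isfinite(att.grid)) and np.all(np.isfinite(att.static))):
        raise ValueError("attributions must be finite")
    denom = np.abs(att.grid).sum(axis=(2, 3)) + np.abs(att.static).sum(axis=2)
    safe = np.where(denom > 0, denom, 1.0)
    return RelativeAttribution(
        grid=100.0 * att.grid / safe[:, :, None, None],
        static=100.0 * att.static / safe[:, :, None],
        denominator=denom,
    )


def monthly_importance(rel: RelativeAttribution, outcome: int):
    """(month_scores[18], cumulative tail) for one outcome, in percent.

    The month score is the mean over patients of the summed percentage
    attribution of all time-dependent features at that month (static
    features have no month and are excluded). ``cumulative[m]`` sums the
    scores from month m+1 (1-based m) through the final pre-event month.
    """
    per_patient = rel.grid[:, outcome].sum(axis=2)  # (n, months)
    month_scores = per_patient.mean(axis=0)
    cumulative = np.cumsum(month_scores[::-1])[::-1]
    return month_scores, cumulative


def months_to_half(month_scores: np.ndarray):
    """Smallest k such that the last k months strictly exceed half the total.

    Counted back from the event: k = 1 is the final pre-event month. Returns
    None when the total monthly score is not positive (the threshold is then
    undefined).
    """
    total = float(np.sum(month_scores))
    if total <= 0:
        return None
    tail = np.cumsum(month_scores[::-1])
    # strictly exceed: a tail reaching exactly half (up to fp noise) does not count
    threshold = 0.5 * total * (1.0 + 1e-9)
    for k, c in enumerate(tail, start=1):
        if c > threshold:
            return k
    return len(month_scores)


def feature_importance(
    rel: RelativeAttribution,
    outcome: int,
    feature_names: list,
    static_names: tuple = ("sex", "age", "bd", "szd"),
):
    """Features ranked by mean |per-patient total pct| for one outcome.

    Time-dependent features are first summed over months per patient; static
    features enter with their own percentages. Ties in the mean absolute
    score break deterministically by feature name. Returns a list of dicts
    (feature, mean_abs_pct, mean_pct, per_patient).
    """
    per_patient_grid = rel.grid[:, outcome].sum(axis=1)  # (n, features)
    per_patient_static = rel.static[:, outcome]  # (n, 4)
    values = np.concatenate([per_patient_grid, per_patient_static], axis=1)
    names = list(feature_names) + list(static_names)
    rows = []
    for j, name in enumerate(names):
        v = values[:, j]
        rows.append(
            {
                "feature": name,
                "mean_abs_pct": float(np.mean(np.abs(v))),
                "mean_pct": float(np.mean(v)),
                "per_patient": v,
            }
        )
    rows.sort(key=lambda r: (-r["mean_abs_pct"], r["feature"]))
    return rows


def top_k(
    ranked: list,
    k: int,
    exclude: tuple = ("hospitalized", "sex", "age", "bd", "szd"),
) -> list:
    """Top-k *medication* features from a ranked list.

    Hospitalization and the static demographics are excluded when selecting
    predictors for the conditional-logit stage. k larger than the number of
    medication features returns them all.
    """
    meds = [r["feature"] for r in ranked if r["feature"] not in exclude]
    return meds[: max(k, 0)]
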