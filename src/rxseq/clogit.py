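"""Conditional logistic regression for 1:1 matched case-control pairs.

With one case and one control per matched set, the conditional likelihood
of the pair contributes

    l_pair(beta) = x_case . beta - log(exp(x_case . beta) + exp(x_control . beta))
                 = -log(1 + exp(-(x_case - x_control) . beta))

so the fit reduces to an intercept-free logistic likelihood on within-pair
predictor differences; matching variables cancel out exactly. Maximized by
Newton-Raphson. For a single binary predictor the estimate has the closed
form OR = n10 / n01 (case-exposed over control-exposed discordant pairs),
which the test suite checks exactly; concordant pairs contribute zero
gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

MAX_ITER = 100
GRAD_TOL = 1e-8
SEPARATION_NORM = 20.0


@dataclass
class ClogitDesign:
    """Within-pair predictor differences, already divided by unit scales.

    ``x_case`` and ``x_control`` hold the event-month raw doses (mg/day)
    divided by ``unit_scales`` (1, 10, or 100 mg/day per predictor).
    """

    x_case: np.ndarray  # (n_pairs, p)
    x_control: np.ndarray
    predictors: list
    unit_scales: np.ndarray

    @property
    def diffs(self) -> np.ndarray:
        return self.x_case - self.x_control


def build_design(
    doses_case: np.ndarray,
    doses_control: np.ndarray,
    predictors: list,
    feature_names: list,
    unit_scales=None,
) -> ClogitDesign:
    """Select predictor columns (by name) and apply per-predictor unit scales.

    ``doses_case``/``doses_control`` are (n_pairs, n_features) raw
    event-month doses in mg/day. Unit scales default to 1 mg/day.
    """
    index = {name: j for j, name in enumerate(feature_names)}
    missing = [p for p in predictors if p not in index]
    if missing:
        raise KeyError(f"predictors absent from exposure data: {missing}")
    cols = [index[p] for p in predictors]
    if unit_scales is None:
        unit_scales = np.ones(len(predictors))
    unit_scales = np.asarray(unit_scales, dtype=float)
    xc = doses_case[:, cols] / unit_scales[None, :]
    xk = doses_control[:, cols] / unit_scales[None, :]
    if not (np.all(np.isfinite(xc)) and np.all(np.isfinite(xk))):
        raise ValueError("predictors must be finite")
    return ClogitDesign(
        x_case=xc, x_control=xk, predictors=list(predictors), unit_scales=unit_scales
    )


@dataclass
class ClogitFit:
    beta: np.ndarray
    cov: np.ndarray
    predictors: list
    unit_scales: np.ndarray
    converged: bool
    n_iter: int
    separated: bool
    loglik: float
    undefined: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def _loglik(beta, d):
    eta = d @ beta
    return float(-np.sum(np.logaddexp(0.0, -eta)))


def fit_clogit(design: ClogitDesign) -> ClogitFit:
    """Newton-Raphson maximization of the paired conditional likelihood.

    Converges when the gradient norm drops below 1e-8 (or 100 iterations).
    Predictors concordant in every pair (all differences zero) have no
    information; their coefficients are reported as undefined (NaN).
    Separation — likelihood unbounded, ||beta|| diverging with a
    non-vanishing gradient — is flagged and the coefficient reported
    infinite with a warning.
    """
    d = design.diffs
    n, p = d.shape
    if n == 0:
        raise ValueError("no pairs in design")
    informative = np.any(d != 0.0, axis=0)
    for j in np.nonzero(~informative)[0]:
        warnings.warn(
            f"predictor '{design.predictors[j]}' concordant in every pair; "
            "coefficient undefined"
        )
    di = d[:, informative]
    beta_i = np.zeros(int(informative.sum()))
    separated = False
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        p_pair = expit(di @ beta_i)  # P(observed case is the case | pair)
        grad = di.T @ (1.0 - p_pair)
        if np.linalg.norm(grad) < GRAD_TOL:
            converged = True
            break
        w = p_pair * (1.0 - p_pair)
        hess = -(di * w[:, None]).T @ di
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        # damped Newton: halve until the log-likelihood does not decrease
        ll0 = _loglik(beta_i, di)
        scale = 1.0
        for _ in range(30):
            cand = beta_i + scale * step
            if _loglik(cand, di) >= ll0 - 1e-12:
                break
            scale *= 0.5
        beta_i = beta_i + scale * step
        if np.linalg.norm(beta_i) > SEPARATION_NORM and np.linalg.norm(grad) > GRAD_TOL:
            separated = True
            break
    if separated:
        warnings.warn("separation detected: conditional likelihood unbounded")

    # predictors concordant in every pair carry no information: beta pinned
    # at 0 (OR = 1) but flagged undefined, with NaN variance
    beta = np.zeros(p)
    cov = np.full((p, p), np.nan)
    if informative.any():
        if separated:
            beta[informative] = np.sign(beta_i) * np.inf
        else:
            beta[informative] = beta_i
            p_pair = expit(di @ beta_i)
            w = p_pair * (1.0 - p_pair)
            info = (di * w[:, None]).T @ di
            cov_i = np.linalg.inv(info)
            ix = np.ix_(informative, informative)
            cov[ix] = cov_i
    return ClogitFit(
        beta=beta,
        cov=cov,
        predictors=design.predictors,
        unit_scales=design.unit_scales,
        converged=converged,
        n_iter=it,
        separated=separated,
        loglik=_loglik(beta_i, di) if informative.any() and not separated else float("nan"),
        undefined=~informative,
    )


def summarize_fit(fit: ClogitFit, alpha: float = 0.05) -> list:
    """Per-predictor OR at its stated unit, Wald 95% CI and p-value.

    The predictors were already divided by their unit scales in the design,
    so OR = exp(beta) is directly "per unit_scale mg/day". No
    multiple-testing correction is applied across predictors or outcomes.
    """
    z = norm.ppf(1.0 - alpha / 2.0)
    rows = []
    for j, name in enumerate(fit.predictors):
        b = fit.beta[j]
        se = float(np.sqrt(fit.cov[j, j])) if np.isfinite(fit.cov[j, j]) else float("nan")
        if fit.undefined.size and fit.undefined[j]:
            rows.append(
                {"predictor": name, "unit_scale": float(fit.unit_scales[j]),
                 "or": 1.0, "ci_low": float("nan"), "ci_high": float("nan"),
                 "p": float("nan"), "note": "undefined (all pairs concordant)"}
            )
            continue
        if np.isinf(b):
            rows.append(
                {"predictor": name, "unit_scale": float(fit.unit_scales[j]),
                 "or": float(np.exp(b)), "ci_low": float("nan"),
                 "ci_high": float("nan"), "p": float("nan"),
                 "note": "separation"}
            )
            continue
        wald = b / se if se > 0 else float("inf")
        with np.errstate(over="ignore"):  # huge SEs overflow to inf cleanly
            rows.append(
                {
                    "predictor": name,
                    "unit_scale": float(fit.unit_scales[j]),
                    "or": float(np.exp(b)),
                    "ci_low": float(np.exp(b - z * se)),
                    "ci_high": float(np.exp(b + z * se)),
                    "p": float(2.0 * norm.sf(abs(wald))),
                    "note": "",
                }
            )
    return rows
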