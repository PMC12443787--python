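# Methods

`rxseq` reimplements, as a tested pipeline on synthetic claims data, an
analysis of how psychotropic prescription sequences contribute to the risk
of in-hospital non-psychiatric adverse events in adults with bipolar (BD)
or schizophrenia-spectrum (SZD) disorders. The pipeline has six scientific
stages — synthetic claims simulation, exposure construction, matched
case-control cohort assembly, a bidirectional-GRU multi-label classifier,
expected-gradients attribution, and conditional logistic risk estimation —
driven end-to-end from one YAML configuration.

## The synthetic world

Real claims extracts of this kind are access-restricted, so the package
ships a generator that emulates their statistical structure with planted
ground truth, which the rest of the pipeline must then recover.

**Patients.** Demographics and diagnoses follow the matched cohort's
marginals: 53.7% female, age uniform on [18, 65], diagnosis partition
30.4% BD-only / 49.8% SZD-only / 19.8% both, Charlson comorbidity index
categorical over {0, 1, 2, 3} with 44.9% nonzero, and six rare neurological
comorbidity flags (prevalences 0.04%–1%).

**Prescriptions.** Each of up to 87 drugs follows an independent per-drug
monthly Markov process: off→on with `initiation_rate`, on→off with
`discontinuation_rate`; while on, the daily dose is lognormal around the
drug's typical dose with monthly titration noise (sd 0.3 on the log scale).
Purchases are generated by supply exhaustion — a pack (≈30-day supply) is
bought when the previous one runs out at the prevailing dose, jittered by
±7 days — so inter-purchase gaps are irregular, as in reimbursement data.
Independence across drugs is a modelling choice; real polypharmacy is
correlated.

**Hospitalizations.** Background stays occur with probability 0.12 per
patient-month (roughly one stay per 8 months — a heavily hospitalized
severe-mental-illness population), psychiatric with probability 0.336
(matching the cohort's index-month ward marginal), lasting 1–14 days.

**Adverse events.** Nine non-mutually-exclusive events fire monthly with
probability

    logistic( baseline_e + age_coef_e·(age−45) + sex_coef_e·female
              + Σ_d dose_coef_{e,d}·dose_{d,m}
              + Σ_d recency_coef_{e,d}·(dose_{d,m} − dose_{d,m−k}) )

acting on the *true* (unsmoothed) doses; smoothing belongs to the analysis,
not the world. The default baseline of −5.2 per event yields ≈27% of
patients with an event over a 24-month record, matching the source cohort's
10-year prevalence of 27.3%. The recency window k defaults to 3 months.
Only the first event hospitalization is retained per patient, labelled with
every event that fired that month, and only from month 19 onward so every
case has a full 18-month history.

What the generator does **not** emulate: ATC-coded formularies and
pharmacokinetics, adherence (doses are reimbursement-based, as in the real
data), death/censoring, correlated polypharmacy, and event-on-event
causation. Passing tests therefore demonstrate that the pipeline recovers
signals of the planted form, not that the real-data findings replicate.

## Exposure construction

Purchases of a drug are converted to daily-dose coverage under the
assumption that a repeat purchaser has consumed the previous supply: each
purchase of A mg followed `gap` days later by the next contributes A/gap
mg/day over that interval (same-day purchases merged; gap capped at 90
days; final purchase spread over a default 30-day supply). Months are
30-day bins counted back from the patient's index date — the event
admission for cases, the matched case's index date for controls — with
month 18 the 30 days immediately before the index date; windows are
half-open and only purchases strictly before the index date count. The
monthly mean daily dose is smoothed with the sliding kernel
D′_m = (D_{m−1} + 4·D_m + D_{m+1})/6, with replicate padding at the two
boundary months where the kernel is otherwise undefined. An 88th row codes
any hospital stay overlapping each month. Drug rows are max-scaled per drug
with scales fitted on training patients only (test rows for drugs unseen in
training are zeroed — they carry no usable scale); age maps to
(age−18)/47.

## Cohort assembly

Cases are patients whose first adverse-event hospitalization fell ≥18
months after the initial diagnosis. Matching is 1:1 without replacement,
exact on sex, BD, SZD, the six neurological flags and the Charlson integer;
age at inclusion (18 months before the index date) is matched exactly in
completed years with fallback bands ±1 then ±2 years (exact-only matching
would discard most synthetic cases at desk scale); ties break by a seeded
draw. Controls must never have an adverse-event record and must be
hospitalized in the case's ward type during the index month, taken as
[index date, index date + 30 d): the month *of* the event. This convention
matters — a control stay in that window, like the case's own event
admission, lies outside the 18-month exposure window. Defining the index
month as the 30 days *before* the index date instead makes the
hospitalization input anti-informative by construction (every control, but
few cases, shows a stay in month 18), an artifact the classifier will
happily exploit.

Pairs, not individuals, are the split unit: 80/20 train/test, then 5-fold
partitions of the train pairs for hyperparameter selection, so a case and
its control never straddle a split and no test information reaches
normalization, loss weights or model selection.

Loss weights are w_e = 1 − frequency of event e among training individuals
(controls included). Fed the source cohort's printed counts — 9,822
electrolyte-imbalance positives among 87,182 individuals — this reproduces
the published weight 0.8873 at four decimals.

## Classifier

The model takes the 88×18 normalized grid plus 4 static covariates and
returns 9 event probabilities: affine 88→32 + ReLU + 10% dropout applied at
each month; a bidirectional GRU (hidden size h, default 8; single bias per
gate per direction) over the 18 months; the two final hidden states
concatenated with the static covariates; then affine (2h+4)→24 + ReLU +
dropout, 24→8 + ReLU, 8→9 + sigmoid. With defaults this has exactly 5,601
trainable parameters (encoder 2,848 + biGRU 1,968 + head 785); the inner
head widths (24, 8) and the single-bias convention are the configuration
consistent with that total. Dropout placement (after the encoder and the
first head layer) and the 500-epoch cap are our choices. The loss is a
weighted binary cross entropy averaged over the nine events,
−(1/9)Σ_e[w_e·y_e·log p_e + (1−w_e)(1−y_e)·log(1−p_e)], with logs clamped
at 10⁻⁷; since every w_e > ½, a false negative always costs more than the
symmetric false positive. Optimization is Adam (lr 5·10⁻⁴, batch 128),
with early stopping after 15 consecutive epochs without validation-loss
improvement and restoration of the best-epoch parameters. The hidden size
is selected by five-fold cross-validated mean AUC over {4, 8, 16, 32}.

The network, its backward pass and its input gradients are implemented
directly in NumPy; correctness is enforced by finite-difference gradient
checks and a time-reversal symmetry test (reversing the month axis while
swapping the two directions' parameter blocks leaves outputs unchanged).

**Early stopping at reduced problem sizes.** The patience of 15 epochs is
calibrated to full-cohort training, where one epoch is ~550 gradient steps.
At the problem sizes used in this package's statistical checks (~1,000
pairs, ~11 steps per epoch) the same window covers 50× fewer steps and
fires before the dose signal moves the validation loss. Those checks
therefore hold the no-improvement window constant in *gradient steps*,
which at desk scale exceeds the epoch cap: training runs to the cap
(100–250 epochs) and keeps the best-validation-epoch parameters. The
early-stopping rule itself, and its epoch-denominated default, are
unchanged.

## Attribution

Expected gradients: φ_j = E[(x_j − x′_j)·∂f(x′ + α(x − x′))/∂x_j] over
background draws x′ (default 100 training patients) and α ~ U(0, 1),
per patient and outcome, with the Monte-Carlo standard error of the total
tracked so the Aumann–Shapley completeness identity Σφ ≈ f(x) − E_bg f can
be checked in SE units. Attributions are converted to percentages of the
patient's total *absolute* attribution (a signed total can pass through
zero and explode; the cumulative-half-threshold reading below only makes
sense with a positive denominator), so Σ|pct| = 100 per patient-outcome.

Temporal importance averages, over patients, the summed percentage of all
88 time-dependent rows at each month; the months-to-half statistic is the
smallest k such that the last k months' cumulative score *strictly* exceeds
half the total (ties, up to floating-point noise, do not count — a uniform
profile gives k = 10). Feature importance sums each feature's percentage
over months per patient and ranks by mean absolute value, ties broken by
feature name; static covariates are ranked but excluded, along with the
hospitalization row, when selecting the top-k medication predictors for
the regression stage.

## Conditional logistic regression

For 1:1 matched pairs the conditional likelihood reduces to an
intercept-free logistic model on within-pair differences of the
event-month (month-18) *raw* doses — odds ratios are reported per 1, 10 or
100 mg/day depending on the drug's dose range, which requires unscaled
inputs; smoothing and normalization are model-input transforms only.
Newton–Raphson with step-halving, convergence at gradient norm < 10⁻⁸ or
100 iterations; Wald covariance from the observed information. For a single
binary predictor the estimate equals the discordant-pair ratio n10/n01
exactly. Fully concordant predictors are pinned at β = 0 (OR 1) and flagged
undefined with NaN variance; separation (‖β‖ > 20 with a non-vanishing
gradient) is flagged and reported as an infinite coefficient. One
regression per outcome enters the top-10 medications jointly; no
multiple-testing correction is applied, and the output notes as much.

## Problem sizes and numerical choices

The statistical test-suite checks run at sizes a workstation handles in
minutes, chosen once: 6–10-drug formularies (the model input stays the full
88×18 grid; unused rows are zero), cohorts of 300–5,000 patients,
attribution with 80–600 samples per patient over 25–100 background
patients, 50 replications of 2,000 pairs for conditional-logit coverage.
Planted "strong" effects are ~1.5–2 log-odds per typical daily dose, with
recency effects of similar size. Under those conditions the classifier
reaches a test mean AUC of roughly 0.55–0.60 at n = 5,000 — a modest
separability comparable in magnitude to what such models achieve on real
claims sequences — while a null cohort with all hazard coefficients zeroed
stays statistically indistinguishable from 0.5.

Degenerate inputs are handled explicitly: empty cohorts produce full-schema
empty tables; AUC is undefined (NaN, excluded from means) when a class is
absent; events absent from training get loss weight 1 with a warning;
months-to-half is undefined (None) for non-positive totals; duplicate
same-day purchases merge before gap computation.

## Known limitations

* The generator's drug-independence and single-index-date design understate
  real confounding by indication and polypharmacy; recovered odds ratios are
  cleaner than anything real claims would yield.
* Matching at small n drops 30–60% of synthetic cases (the candidate pool is
  thin when exact keys include a 4-level Charlson index); the real analysis,
  drawing controls from hundreds of thousands, matches nearly all.
* Attribution noise scales with model quality; with weak fits, static
  covariates can outrank genuinely causal drugs, which is why the planted
  recovery checks are majority-over-seeds statements rather than per-seed
  guarantees.
* Expected-gradient SHAP values are stochastic; everything downstream of
  them (rankings, months-to-half) inherits Monte-Carlo noise controlled by
  the sample count, not eliminated.
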