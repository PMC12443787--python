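"""End-to-end orchestration: one YAML config drives every stage.

Stage order: simulate -> select/match -> split -> exposure+normalization ->
loss weights -> (optional) hidden-size CV -> train -> evaluate -> attribute
-> conditional logit. Every stochastic stage takes its own seed from the
config, outputs are plain CSV/JSON under the run directory, and a manifest
records the config hash, seeds, row counts and a digest of every artifact;
two runs of the same config produce bit-identical outputs.

The model input is always the fixed (87 drugs + hospitalization) x 18
grid — synthetic formularies smaller than 87 drugs simply leave the unused
rows at zero.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr_mod
from . import clogit as clogit_mod
from . import cohort as cohort_mod
from . import evaluation as eval_mod
from . import exposure as exposure_mod
from . import model as model_mod
from . import synthetic as syn_mod

log = logging.getLogger("rxseq")

N_DRUGS_MODEL = 87

DEFAULT_CONFIG = {
    "output_dir": "runs/run",
    "seeds": {"data": 1, "match": 2, "split": 3, "model": 4, "attribution": 5},
    "synthetic": {"n_patients": 300, "n_drugs": 6, "months_simulated": 24},
    "model": {"hidden_size": 8},
    "train": {
        "learning_rate": 5e-4,
        "batch_size": 128,
        "patience": 15,
        "max_epochs": 60,
    },
    "cv": {"enabled": False, "grid": [4, 8]},
    "attribution": {"n_samples": 100, "background_size": 100, "max_patients": 100},
    "clogit": {"top_k": 10},
    "stages": {
        "simulate": True,
        "match": True,
        "train": True,
        "evaluate": True,
        "attribute": True,
        "clogit": True,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    """Digest of the scientific configuration (output location excluded)."""
    hashed = {k: v for k, v in config.items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_json(path: pathlib.Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage


def _unit_scale_for(typical_dose: float) -> float:
    """Reporting unit for a drug's OR: 1, 10 or 100 mg/day by dose range."""
    if typical_dose < 20:
        return 1.0
    if typical_dose < 150:
        return 10.0
    return 100.0


def pair_exposure_matrices(dataset: dict, pairs: list):
    """(ExposureMatrix list, labels) for the individuals of the pairs.

    Case and control alternate (case first); controls carry all-zero labels
    and use their matched case's index date.
    """
    disp = dataset["dispensations"]
    stays = dataset["hospital_stays"]
    pat = dataset["patients"].set_index("patient_id", drop=False)
    disp_by = dict(tuple(disp.groupby("patient_id"))) if len(disp) else {}
    stays_by = dict(tuple(stays.groupby("patient_id"))) if len(stays) else {}
    empty_disp, empty_stays = disp.iloc[0:0], stays.iloc[0:0]
    mats, labels = [], []
    for p in pairs:
        for pid, lab in (
            (p.case.patient_id, p.case.labels),
            (p.control, np.zeros(syn_mod.N_EVENTS, dtype=int)),
        ):
            mats.append(
                exposure_mod.build_exposure_matrix(
                    pat.loc[pid],
                    disp_by.get(pid, empty_disp),
                    stays_by.get(pid, empty_stays),
                    p.case.index_date,
                    n_drugs=N_DRUGS_MODEL,
                )
            )
            labels.append(lab)
    return mats, np.asarray(labels)


def normalized_arrays(mats: list, norm) -> tuple:
    """Stack normalized matrices into model inputs (n, months, features), (n, 4)."""
    grids, stats = [], []
    for m in mats:
        grid, static = exposure_mod.apply_normalization(m, norm)
        grids.append(grid.T)
        stats.append(static)
    return np.stack(grids), np.stack(stats)


def assemble_cohort(dataset: dict, match_seed: int, split_seed: int) -> dict:
    """Select cases, match, split, build normalized model inputs.

    Returns a dict with pairs, exposure matrices, normalization params,
    train/test arrays and labels, and the loss weights — everything the
    modelling stages consume. Normalization and weights use training
    individuals only.
    """
    cases, counts = cohort_mod.select_cases(dataset["events"], dataset["patients"])
    pairs, unmatched = cohort_mod.match_controls(
        cases, dataset["patients"], dataset["hospital_stays"], dataset["events"],
        seed=match_seed,
    )
    if not pairs:
        raise RuntimeError("no matched pairs; cohort too small")
    train_pairs, test_pairs = cohort_mod.split_train_test(pairs, split_seed)
    train_mats, y_train = pair_exposure_matrices(dataset, train_pairs)
    test_mats, y_test = pair_exposure_matrices(dataset, test_pairs)
    norm = exposure_mod.fit_normalization(train_mats)
    X_train, S_train = normalized_arrays(train_mats, norm)
    X_test, S_test = (
        normalized_arrays(test_mats, norm) if test_mats else (
            np.zeros((0,) + X_train.shape[1:]), np.zeros((0, 4)))
    )
    return {
        "counts": counts,
        "pairs": pairs,
        "unmatched": unmatched,
        "train_pairs": train_pairs,
        "test_pairs": test_pairs,
        "train_mats": train_mats,
        "test_mats": test_mats,
        "norm": norm,
        "X_train": X_train,
        "S_train": S_train,
        "y_train": y_train,
        "X_test": X_test,
        "S_test": S_test,
        "y_test": y_test,
        "weights": cohort_mod.compute_loss_weights(y_train).w,
    }


def subset_arrays(pair_subset: list, all_pairs: list, X, S, y) -> tuple:
    """Rows (case+control) of a pair subset from interleaved arrays."""
    pos = {id(p): i for i, p in enumerate(all_pairs)}
    idx = np.asarray(
        [j for p in pair_subset for j in (2 * pos[id(p)], 2 * pos[id(p)] + 1)],
        dtype=int,
    )
    return X[idx], S[idx], y[idx]


def run(config: dict, force: bool = False) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    config = _merge(DEFAULT_CONFIG, config)
    outdir = pathlib.Path(config["output_dir"])
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {outdir} is not empty; pass force=True (--force)"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config["seeds"]
    stages = config["stages"]
    manifest = {
        "config_hash": config_hash(config),
        "seeds": seeds,
        "stages_run": [],
        "counts": {},
        "artifacts": {},
    }

    def finish(stage):
        manifest["stages_run"].append(stage)

    def record(name, path):
        manifest["artifacts"][name] = _sha256(path)

    t_total = time.time()

    # ---- simulate -------------------------------------------------------
    stage = "simulate"
    t0 = time.time()
    try:
        syn_cfg = dict(config["synthetic"])
        syn_cfg["seed"] = int(seeds["data"])
        spec = syn_mod.spec_from_dict(syn_cfg)
        if spec.n_drugs > N_DRUGS_MODEL:
            raise ValueError(f"n_drugs must be <= {N_DRUGS_MODEL}")
        dataset = syn_mod.generate_dataset(spec)
        if stages.get("simulate", True):
            syn_mod.write_dataset(dataset, outdir)
            for name in ("patients", "dispensations", "hospital_stays", "events"):
                record(f"{name}.csv", outdir / f"{name}.csv")
        manifest["counts"]["patients"] = len(dataset["patients"])
        manifest["counts"]["dispensations"] = len(dataset["dispensations"])
        manifest["counts"]["events"] = len(dataset["events"])
    except Exception as exc:
        raise StageError(stage, exc) from exc
    log.info("stage %s: %.1fs (%d patients)", stage, time.time() - t0,
             manifest["counts"]["patients"])
    finish(stage)
    if not stages.get("match", True):
        _write_json(outdir / "manifest.json", manifest)
        return manifest

    # ---- select + match + split + exposure ------------------------------
    stage = "match"
    t0 = time.time()
    try:
        asm = assemble_cohort(dataset, int(seeds["match"]), int(seeds["split"]))
        counts, pairs, unmatched = asm["counts"], asm["pairs"], asm["unmatched"]
        pairs_df = pd.DataFrame(
            {
                "case_id": [p.case.patient_id for p in pairs],
                "control_id": [p.control for p in pairs],
                "index_date": [
                    pd.Timestamp(p.case.index_date).strftime("%Y-%m-%d") for p in pairs
                ],
                "ward": [p.case.ward for p in pairs],
                **{
                    name: [int(p.case.labels[e]) for p in pairs]
                    for e, name in enumerate(syn_mod.EVENT_NAMES)
                },
            }
        )
        pairs_df.to_csv(outdir / "pairs.csv", index=False)
        record("pairs.csv", outdir / "pairs.csv")
        manifest["counts"].update(
            screened=counts.screened,
            with_event=counts.with_event,
            eligible_cases=counts.eligible,
            matched_pairs=len(pairs),
            unmatched_cases=len(unmatched),
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    log.info("stage %s: %.1fs (%d pairs, %d unmatched)", stage, time.time() - t0,
             len(pairs), len(unmatched))
    finish(stage)

    train_pairs, test_pairs = asm["train_pairs"], asm["test_pairs"]
    train_mats, test_mats = asm["train_mats"], asm["test_mats"]
    X_train, S_train, y_train = asm["X_train"], asm["S_train"], asm["y_train"]
    X_test, S_test, y_test = asm["X_test"], asm["S_test"], asm["y_test"]
    manifest["counts"]["train_pairs"] = len(train_pairs)
    manifest["counts"]["test_pairs"] = len(test_pairs)

    stage = "exposure"
    t0 = time.time()
    try:
        (outdir / "normalization.json").write_text(asm["norm"].to_json())
        record("normalization.json", outdir / "normalization.json")
        long = exposure_mod.exposures_to_long(train_mats + test_mats)
        long.to_csv(outdir / "exposures_long.csv", index=False)
        record("exposures_long.csv", outdir / "exposures_long.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    log.info("stage %s: %.1fs (%d matrices)", stage, time.time() - t0,
             len(train_mats) + len(test_mats))
    finish(stage)

    # ---- loss weights (train individuals only) --------------------------
    weights = asm["weights"]
    _write_json(outdir / "loss_weights.json",
                {n: round(float(w), 4) for n, w in zip(syn_mod.EVENT_NAMES, weights)})
    record("loss_weights.json", outdir / "loss_weights.json")

    summary = cohort_mod.cohort_summary(
        pairs, dataset["patients"], np.stack([p.case.labels for p in pairs])
    )
    _write_json(outdir / "cohort_summary.json", summary)
    record("cohort_summary.json", outdir / "cohort_summary.json")

    if not stages.get("train", True):
        _write_json(outdir / "manifest.json", manifest)
        return manifest

    # ---- CV (optional) + train ------------------------------------------
    stage = "train"
    t0 = time.time()
    try:
        feature_names = [f"drug_{d}" for d in range(N_DRUGS_MODEL)] + ["hospitalized"]
        tr_cfg = config["train"]
        train_config = model_mod.TrainConfig(
            learning_rate=float(tr_cfg["learning_rate"]),
            batch_size=int(tr_cfg["batch_size"]),
            patience=int(tr_cfg["patience"]),
            max_epochs=int(tr_cfg["max_epochs"]),
            seed=int(seeds["model"]),
        )
        hidden = int(config["model"]["hidden_size"])
        if config["cv"].get("enabled", False):
            folds_idx = cohort_mod.kfold(train_pairs, k=5, seed=int(seeds["split"]) + 1)
            folds = [
                (
                    subset_arrays(tr, train_pairs, X_train, S_train, y_train),
                    subset_arrays(va, train_pairs, X_train, S_train, y_train),
                )
                for tr, va in folds_idx
            ]
            hidden, cv_table = model_mod.cross_validate_hidden_size(
                folds, grid=tuple(config["cv"]["grid"]), seed=int(seeds["model"]),
                train_config=train_config,
            )
            _write_json(outdir / "cv_scores.json",
                        {"selected_hidden_size": hidden, "mean": cv_table["mean"],
                         "per_fold": cv_table["per_fold"]})
            record("cv_scores.json", outdir / "cv_scores.json")

        # inner 80/20 split of the train pairs for early stopping
        sub_train, sub_val = cohort_mod.split_train_test(
            train_pairs, int(seeds["split"]) + 2
        )
        cfg = model_mod.ModelConfig(hidden_size=hidden)
        net = model_mod.build_model(cfg, seed=int(seeds["model"]))
        fit = model_mod.train_with_early_stopping(
            net,
            subset_arrays(sub_train, train_pairs, X_train, S_train, y_train),
            subset_arrays(sub_val, train_pairs, X_train, S_train, y_train),
            train_config,
            weights,
        )
        curves = pd.DataFrame(
            {"epoch": np.arange(1, len(fit.train_losses) + 1),
             "train_loss": fit.train_losses, "val_loss": fit.val_losses}
        )
        curves.to_csv(outdir / "training_curves.csv", index=False)
        record("training_curves.csv", outdir / "training_curves.csv")
        manifest["counts"]["epochs_trained"] = len(fit.train_losses)
        manifest["counts"]["best_epoch"] = fit.best_epoch
        np.savez(outdir / "model_params.npz", **net.params)
        _write_json(outdir / "model_config.json",
                    {"hidden_size": hidden, "n_parameters": model_mod.n_params(net.params)})
        record("model_config.json", outdir / "model_config.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    log.info("stage %s: %.1fs (best epoch %d)", stage, time.time() - t0, fit.best_epoch)
    finish(stage)

    # ---- evaluate --------------------------------------------------------
    if stages.get("evaluate", True):
        stage = "evaluate"
        t0 = time.time()
        try:
            probs = model_mod.predict(net, X_test, S_test)
            report = eval_mod.evaluation_report(probs, y_test)
            _write_json(outdir / "evaluation.json", report)
            record("evaluation.json", outdir / "evaluation.json")
            manifest["counts"]["test_individuals"] = int(X_test.shape[0])
        except Exception as exc:
            raise StageError(stage, exc) from exc
        log.info("stage %s: %.1fs (mean AUC %.3f)", stage, time.time() - t0,
                 report["mean_auc"])
        finish(stage)

    # ---- attribute -------------------------------------------------------
    ranked_by_outcome = None
    if stages.get("attribute", True):
        stage = "attribute"
        t0 = time.time()
        try:
            at_cfg = config["attribution"]
            rng = np.random.default_rng(int(seeds["attribution"]))
            bg_n = min(int(at_cfg["background_size"]), X_train.shape[0])
            bg_idx = rng.choice(X_train.shape[0], size=bg_n, replace=False)
            n_at = min(int(at_cfg["max_patients"]), X_test.shape[0])
            at_idx = np.arange(n_at)
            att = attr_mod.expected_gradients(
                net, X_test[at_idx], S_test[at_idx],
                (X_train[bg_idx], S_train[bg_idx]),
                n_samples=int(at_cfg["n_samples"]),
                seed=int(seeds["attribution"]) + 1,
            )
            rel = attr_mod.to_relative(att)
            temporal = {}
            ranked_by_outcome = {}
            rows = []
            for e, name in enumerate(syn_mod.EVENT_NAMES):
                scores, cum = attr_mod.monthly_importance(rel, e)
                temporal[name] = {
                    "month_scores": [round(float(v), 4) for v in scores],
                    "cumulative": [round(float(v), 4) for v in cum],
                    "months_to_half": attr_mod.months_to_half(scores),
                }
                ranked = attr_mod.feature_importance(rel, e, feature_names)
                ranked_by_outcome[name] = ranked
                for r in ranked:
                    rows.append(
                        {"outcome": name, "feature": r["feature"],
                         "mean_pct": round(r["mean_pct"], 4),
                         "mean_abs_pct": round(r["mean_abs_pct"], 4)}
                    )
            pd.DataFrame(rows).to_csv(outdir / "feature_importance.csv", index=False)
            record("feature_importance.csv", outdir / "feature_importance.csv")
            _write_json(outdir / "temporal_importance.json", temporal)
            record("temporal_importance.json", outdir / "temporal_importance.json")
        except Exception as exc:
            raise StageError(stage, exc) from exc
        log.info("stage %s: %.1fs (%d patients attributed)", stage,
                 time.time() - t0, n_at)
        finish(stage)

    # ---- conditional logit ----------------------------------------------
    if stages.get("clogit", True) and ranked_by_outcome is not None:
        stage = "clogit"
        t0 = time.time()
        try:
            formulary = spec.resolved_formulary()
            scale_of = {
                f"drug_{p.drug_id}": _unit_scale_for(p.typical_daily_dose_mg)
                for p in formulary
            }
            all_mats = train_mats + test_mats
            raw_last = np.stack(
                [np.append(m.raw_doses[:, -1], m.hospitalized[-1]) for m in all_mats]
            )
            case_rows = raw_last[0::2]
            control_rows = raw_last[1::2]
            all_pairs = train_pairs + test_pairs
            case_labels = np.stack([p.case.labels for p in all_pairs])
            out_rows = []
            for e, name in enumerate(syn_mod.EVENT_NAMES):
                mask = case_labels[:, e] == 1
                if mask.sum() < 2:
                    continue
                predictors = attr_mod.top_k(
                    ranked_by_outcome[name], int(config["clogit"]["top_k"])
                )
                predictors = [p for p in predictors if p in scale_of]
                if not predictors:
                    continue
                scales = [scale_of[p] for p in predictors]
                design = clogit_mod.build_design(
                    case_rows[mask], control_rows[mask], predictors,
                    feature_names, scales,
                )
                informative = np.any(design.diffs != 0.0, axis=0)
                if not informative.any():
                    continue
                fit_c = clogit_mod.fit_clogit(design)
                for row in clogit_mod.summarize_fit(fit_c):
                    row["outcome"] = name
                    row["n_pairs"] = int(mask.sum())
                    out_rows.append(row)
            pd.DataFrame(out_rows).to_csv(outdir / "odds_ratios.csv", index=False)
            record("odds_ratios.csv", outdir / "odds_ratios.csv")
        except Exception as exc:
            raise StageError(stage, exc) from exc
        log.info("stage %s: %.1fs", stage, time.time() - t0)
        finish(stage)

    log.info("run complete in %.1fs", time.time() - t_total)
    _write_json(outdir / "manifest.json", manifest)
    return manifest
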