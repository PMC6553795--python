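"""End-to-end orchestration: features → split → select → tune → evaluate.

`run_study` is the in-memory path used by the library, the examples and the
acceptance script: given a feature table and a labeled pair set it performs
the drug-based train/test split, group-MCP feature selection on the
training pairs, hold-out-driven hyperparameter tuning, repeated hold-out
evaluation on the training drugs (averaged curves, mean AUROC/AUPR, and the
maximum-averaged-F1 probability cutoff), and a final leakage-free test-set
evaluation.

`run_pipeline` is the file-based counterpart behind the command-line
interface: each stage reads declared inputs, writes artifacts into the
output directory, and records every artifact with a content hash in a
manifest, so reruns with the same config and inputs are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .align import ScoringScheme
from .features import FEATURE_GROUPS, FEATURE_NAMES, build_feature_table
from .gi import collapse_allele_scores
from .metrics import (
    auroc,
    aupr,
    average_curves,
    max_f1_threshold,
    pr_points,
    precision_at_k,
    predict_novel,
    rank_predictions,
    roc_points,
)
from .model import HyperparamSpace, TrialRecord, train_classifier, tune_hyperparameters
from .pairs import (
    LabeledPairSet,
    SplitPlan,
    assemble_pairs,
    drug_split,
    filter_complete,
    holdout_splits,
)
from .select import SelectionConfig, SelectionResult, group_mcp_select


@dataclass
class StudyResult:
    """Everything one full study run produces."""

    split: SplitPlan
    selection: SelectionResult
    selected_features: tuple[str, ...]
    best_params: dict
    tuning_history: list[TrialRecord]
    holdout_aurocs: list[float]
    holdout_auprs: list[float]
    roc_curve: object
    pr_curve: object
    threshold: float
    test_auroc: float
    test_aupr: float
    ranked_test: pd.DataFrame
    model: object

    @property
    def mean_holdout_auroc(self) -> float:
        return float(np.mean(self.holdout_aurocs))

    @property
    def mean_holdout_aupr(self) -> float:
        return float(np.mean(self.holdout_auprs))

    def metrics_dict(self) -> dict:
        return {
            "train_mean_auroc": self.mean_holdout_auroc,
            "train_mean_aupr": self.mean_holdout_aupr,
            "test_auroc": self.test_auroc,
            "test_aupr": self.test_aupr,
            "threshold": self.threshold,
            "selected_features": list(self.selected_features),
            "holdout_aurocs": self.holdout_aurocs,
            "holdout_auprs": self.holdout_auprs,
            "n_train_pairs": len(self.split.train_pairs),
            "n_test_pairs": len(self.split.test_pairs),
        }


def _pair_rows(features: pd.DataFrame, pairs, names):
    idx = [(a, b) for a, b, _ in pairs]
    X = features.loc[idx, list(names)].to_numpy(dtype=float)
    y = np.array([lab for *_, lab in pairs], dtype=int)
    return X, y


def run_study(
    features: pd.DataFrame,
    pair_set: LabeledPairSet,
    seed: int = 0,
    *,
    ratio: tuple[int, int] = (2, 1),
    balance_tol: float = 0.25,
    selection_cfg: SelectionConfig | None = None,
    space: HyperparamSpace | None = None,
    n_tune_iter: int = 50,
    n_tune_holdout: int = 10,
    n_eval_runs: int = 50,
    skip_selection: bool = False,
    skip_tuning: bool = False,
) -> StudyResult:
    """Run the complete modeling study on a feature table and labeled pairs.

    Defaults are desk scale (50 TPE iterations x 10 tuning hold-outs,
    50 evaluation hold-outs); the study-scale protocol (2,000 x 50 and
    1,000 evaluation runs) is reached by raising the corresponding
    arguments.  ``skip_selection`` keeps all 16 features; ``skip_tuning``
    uses library-default boosting parameters.
    """
    complete = filter_complete(pair_set, features)
    plan = drug_split(complete, ratio=ratio, balance_tol=balance_tol, seed=seed)
    train_set = LabeledPairSet(plan.train_pairs, plan.train_drugs)

    X_tr, y_tr = _pair_rows(features, plan.train_pairs, FEATURE_NAMES)
    if skip_selection:
        selection = None
        selected = FEATURE_NAMES
    else:
        cfg = selection_cfg or SelectionConfig(groups=FEATURE_GROUPS, seed=seed)
        selection = group_mcp_select(
            X_tr,
            y_tr,
            cfg,
            feature_names=FEATURE_NAMES,
            pair_drugs=[(a, b) for a, b, _ in plan.train_pairs],
        )
        selected = selection.selected or FEATURE_NAMES  # never model on nothing

    if skip_tuning:
        best_params, history = {}, []
    else:
        best_params, history = tune_hyperparameters(
            train_set,
            features,
            selected,
            space=space,
            n_iter=n_tune_iter,
            n_holdout=n_tune_holdout,
            seed=seed,
            ratio=ratio,
            balance_tol=balance_tol,
        )

    # evaluation hold-outs on the training drugs with the tuned parameters
    outer = SplitPlan(
        train_drugs=plan.train_drugs,
        test_drugs=frozenset(),
        train_pairs=plan.train_pairs,
        test_pairs=(),
        dropped_pairs=(),
        seed=seed,
        ratio=ratio,
    )
    eval_plans = holdout_splits(
        outer, n_eval_runs, ratio=ratio, balance_tol=balance_tol, seed=seed + 1
    )
    aurocs, auprs, runs, roc_runs, pr_runs = [], [], [], [], []
    for p in eval_plans:
        Xf, yf = _pair_rows(features, p.train_pairs, selected)
        Xv, yv = _pair_rows(features, p.test_pairs, selected)
        m = train_classifier(Xf, yf, best_params, seed=seed)
        probs = m.predict_proba(Xv)[:, 1]
        aurocs.append(auroc(probs, yv))
        auprs.append(aupr(probs, yv))
        runs.append((probs, yv))
        roc_runs.append(roc_points(probs, yv))
        pr_runs.append(pr_points(probs, yv))
    roc_curve = average_curves(roc_runs, "ROC")
    pr_curve = average_curves(pr_runs, "PR")
    threshold = max_f1_threshold(runs)

    # final fit on all training pairs, scored once on the held-out test drugs
    model = train_classifier(X_tr[:, [FEATURE_NAMES.index(f) for f in selected]], y_tr,
                             best_params, seed=seed)
    X_te, y_te = _pair_rows(features, plan.test_pairs, selected)
    test_probs = model.predict_proba(X_te)[:, 1]
    ranked = rank_predictions(
        [(a, b) for a, b, _ in plan.test_pairs], test_probs, y_te
    )
    return StudyResult(
        split=plan,
        selection=selection,
        selected_features=tuple(selected),
        best_params=best_params,
        tuning_history=history,
        holdout_aurocs=aurocs,
        holdout_auprs=auprs,
        roc_curve=roc_curve,
        pr_curve=pr_curve,
        threshold=threshold,
        test_auroc=auroc(test_probs, y_te),
        test_aupr=aupr(test_probs, y_te),
        ranked_test=ranked,
        model=model,
    )


# ---------------------------------------------------------------------------
# file-based pipeline (CLI backend)
# ---------------------------------------------------------------------------

STAGES = ("features", "split", "select", "tune", "train", "evaluate", "predict")


@dataclass
class PipelineConfig:
    """Paths and parameters for the file-based pipeline."""

    inputs: dict = field(default_factory=dict)  # meddra, indications, ...
    out_dir: str = "out"
    seed: int = 0
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    p_cutoff: float = 0.05
    ratio: tuple[int, int] = (2, 1)
    balance_tol: float = 0.25
    selection: dict = field(default_factory=dict)  # gamma, cv_trials, ...
    tune: dict = field(default_factory=dict)  # n_iter, n_holdout
    n_eval_runs: int = 50

    REQUIRED_INPUTS = (
        "meddra",
        "indications",
        "side_effects",
        "drugs",
        "fasta",
        "gi",
        "homologs",
        "labels",
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        scheme_raw = raw.get("scheme", {})
        sub = scheme_raw.get("substitution", "blosum62")
        if isinstance(sub, list):
            sub = tuple(sub)
        scheme = ScoringScheme(
            substitution=sub,
            gap_open=float(scheme_raw.get("gap_open", 11.0)),
            gap_extend=float(scheme_raw.get("gap_extend", 1.0)),
        )
        ratio = tuple(raw.get("ratio", (2, 1)))
        return cls(
            inputs=dict(raw.get("inputs", {})),
            out_dir=str(raw.get("out_dir", "out")),
            seed=int(raw.get("seed", 0)),
            scheme=scheme,
            p_cutoff=float(raw.get("p_cutoff", 0.05)),
            ratio=(int(ratio[0]), int(ratio[1])),
            balance_tol=float(raw.get("balance_tol", 0.25)),
            selection=dict(raw.get("selection", {})),
            tune=dict(raw.get("tune", {})),
            n_eval_runs=int(raw.get("n_eval_runs", 50)),
        )

    def validate(self, stages: Sequence[str]) -> None:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        missing = [
            k
            for k in self.REQUIRED_INPUTS
            if k not in self.inputs or not Path(self.inputs[k]).exists()
        ]
        if "features" in stages and missing:
            raise ValueError(f"missing input files: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages in dependency order; return the manifest."""
    stages = list(stages or STAGES)
    cfg.validate(stages)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "artifacts": {}}
    ordered = [s for s in STAGES if s in stages]

    def _log(stage: str, started: float, wrote: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seed": cfg.seed,
            "wall_time_s": round(time.time() - started, 3),
        }
        for p in wrote:
            manifest["artifacts"][p.name] = _sha256(p)

    for stage in ordered:
        t0 = time.time()
        if stage == "features":
            hierarchy = gio.read_hierarchy(cfg.inputs["meddra"])
            profiles = gio.read_annotations(
                cfg.inputs["indications"], cfg.inputs["side_effects"]
            )
            targets = gio.read_targets(cfg.inputs["drugs"], cfg.inputs["fasta"])
            gmap = collapse_allele_scores(
                gio.read_gi_table(cfg.inputs["gi"]), cfg.p_cutoff
            )
            hmap = gio.read_homologs(cfg.inputs["homologs"])
            positives, exclusions = gio.read_label_pairs(cfg.inputs["labels"])
            universe = sorted(targets)
            pair_set = assemble_pairs(positives, universe, exclusions)
            table = build_feature_table(
                [(a, b) for a, b, _ in pair_set.pairs],
                profiles,
                hierarchy,
                targets,
                hmap,
                gmap,
                cfg.scheme,
            )
            fpath = out / "features.tsv"
            gio.write_features(
                table, fpath, {"scheme": cfg.scheme.describe(), "p_cutoff": cfg.p_cutoff}
            )
            pair_set.to_frame().to_csv(out / "pairs.tsv", sep="\t", index=False)
            _log(stage, t0, [fpath, out / "pairs.tsv"])
        else:
            features = gio.read_features(out / "features.tsv")
            pairs_frame = pd.read_csv(out / "pairs.tsv", sep="\t", dtype={"label": int})
            pair_set = LabeledPairSet(
                tuple(
                    (str(a), str(b), int(y))
                    for a, b, y in pairs_frame.itertuples(index=False)
                ),
                frozenset(pairs_frame["drug_a"]).union(pairs_frame["drug_b"]),
            )
            complete = filter_complete(pair_set, features)
            if stage == "split":
                plan = drug_split(
                    complete, ratio=cfg.ratio, balance_tol=cfg.balance_tol, seed=cfg.seed
                )
                gio.write_split(plan, out / "split.json")
                _log(stage, t0, [out / "split.json"])
                continue

            split_info = json.loads((out / "split.json").read_text())
            plan = _rebuild_plan(split_info, complete)
            train_set = LabeledPairSet(plan.train_pairs, plan.train_drugs)
            X_tr, y_tr = _pair_rows(features, plan.train_pairs, FEATURE_NAMES)

            if stage == "select":
                cfg_sel = SelectionConfig(
                    groups=FEATURE_GROUPS, seed=cfg.seed, **cfg.selection
                )
                selection = group_mcp_select(
                    X_tr,
                    y_tr,
                    cfg_sel,
                    feature_names=FEATURE_NAMES,
                    pair_drugs=[(a, b) for a, b, _ in plan.train_pairs],
                )
                payload = {
                    "selected": list(selection.selected),
                    "lambda": float(selection.lambda_path[selection.lambda_index]),
                    "selected_groups": list(selection.selected_groups),
                }
                (out / "selection.json").write_text(json.dumps(payload, indent=2))
                _log(stage, t0, [out / "selection.json"])
                continue

            selected = tuple(
                json.loads((out / "selection.json").read_text())["selected"]
                if (out / "selection.json").exists()
                else FEATURE_NAMES
            ) or FEATURE_NAMES

            if stage == "tune":
                best, history = tune_hyperparameters(
                    train_set,
                    features,
                    selected,
                    n_iter=int(cfg.tune.get("n_iter", 50)),
                    n_holdout=int(cfg.tune.get("n_holdout", 10)),
                    seed=cfg.seed,
                    ratio=cfg.ratio,
                    balance_tol=cfg.balance_tol,
                )
                payload = {
                    "best": best,
                    "history": [
                        {"hyperparams": t.hyperparams, "loss": t.loss} for t in history
                    ],
                }
                (out / "tuning.json").write_text(json.dumps(payload, indent=2))
                _log(stage, t0, [out / "tuning.json"])
                continue

            best = (
                json.loads((out / "tuning.json").read_text())["best"]
                if (out / "tuning.json").exists()
                else {}
            )

            if stage == "train":
                Xsel = features.loc[
                    [(a, b) for a, b, _ in plan.train_pairs], list(selected)
                ].to_numpy(dtype=float)
                model = train_classifier(Xsel, y_tr, best, seed=cfg.seed)
                # persist the booster itself; the sklearn wrapper's
                # save_model is brittle across sklearn versions
                model.get_booster().save_model(str(out / "model.ubj"))
                meta = {
                    "selected_features": list(selected),
                    "scheme": cfg.scheme.describe(),
                    "hyperparams": best,
                    "train_drugs": sorted(plan.train_drugs),
                }
                (out / "model.meta.json").write_text(json.dumps(meta, indent=2))
                _log(stage, t0, [out / "model.ubj", out / "model.meta.json"])
                continue

            if stage == "evaluate":
                meta = json.loads((out / "model.meta.json").read_text())
                overlap = set(meta["train_drugs"]) & plan.test_drugs
                if overlap:
                    raise RuntimeError(
                        f"leakage guard: test pairs share drugs with the "
                        f"model's training drugs: {sorted(overlap)[:5]}"
                    )
                outer = SplitPlan(
                    train_drugs=plan.train_drugs,
                    test_drugs=frozenset(),
                    train_pairs=plan.train_pairs,
                    test_pairs=(),
                    dropped_pairs=(),
                    seed=cfg.seed,
                    ratio=cfg.ratio,
                )
                eval_plans = holdout_splits(
                    outer,
                    cfg.n_eval_runs,
                    ratio=cfg.ratio,
                    balance_tol=cfg.balance_tol,
                    seed=cfg.seed + 1,
                )
                aurocs, auprs, runs, roc_runs, pr_runs = [], [], [], [], []
                for p in eval_plans:
                    Xf, yf = _pair_rows(features, p.train_pairs, selected)
                    Xv, yv = _pair_rows(features, p.test_pairs, selected)
                    m = train_classifier(Xf, yf, best, seed=cfg.seed)
                    probs = m.predict_proba(Xv)[:, 1]
                    aurocs.append(auroc(probs, yv))
                    auprs.append(aupr(probs, yv))
                    runs.append((probs, yv))
                    roc_runs.append(roc_points(probs, yv))
                    pr_runs.append(pr_points(probs, yv))
                threshold = max_f1_threshold(runs)
                final = train_classifier(
                    features.loc[
                        [(a, b) for a, b, _ in plan.train_pairs], list(selected)
                    ].to_numpy(dtype=float),
                    y_tr,
                    best,
                    seed=cfg.seed,
                )
                X_te, y_te = _pair_rows(features, plan.test_pairs, selected)
                test_probs = final.predict_proba(X_te)[:, 1]
                ranked = rank_predictions(
                    [(a, b) for a, b, _ in plan.test_pairs], test_probs, y_te
                )
                payload = {
                    "train_mean_auroc": float(np.mean(aurocs)),
                    "train_mean_aupr": float(np.mean(auprs)),
                    "test_auroc": auroc(test_probs, y_te),
                    "test_aupr": aupr(test_probs, y_te),
                    "threshold": threshold,
                    "selected_features": list(selected),
                    "n_train_pairs": len(plan.train_pairs),
                    "n_test_pairs": len(plan.test_pairs),
                }
                (out / "metrics.json").write_text(json.dumps(payload, indent=2))
                average_curves(roc_runs, "ROC").to_frame().to_csv(
                    out / "roc_curve.tsv", sep="\t", index=False
                )
                average_curves(pr_runs, "PR").to_frame().to_csv(
                    out / "pr_curve.tsv", sep="\t", index=False
                )
                gio.write_predictions(ranked, out / "test_predictions.tsv")
                _log(
                    stage,
                    t0,
                    [
                        out / "metrics.json",
                        out / "roc_curve.tsv",
                        out / "pr_curve.tsv",
                        out / "test_predictions.tsv",
                    ],
                )
                continue

            if stage == "predict":
                metrics_info = json.loads((out / "metrics.json").read_text())
                Xall, yall = _pair_rows(features, complete.pairs, selected)
                full_model = train_classifier(Xall, yall, best, seed=cfg.seed)
                used = {(a, b) for a, b, _ in complete.pairs}
                candidates = [
                    p
                    for p in (
                        (a, b)
                        for i, a in enumerate(sorted(pair_set.drugs))
                        for b in sorted(pair_set.drugs)[i + 1 :]
                    )
                    if p not in used
                ]
                ranked, missing = predict_novel(
                    full_model,
                    candidates,
                    features,
                    metrics_info["threshold"],
                    selected,
                )
                gio.write_predictions(ranked, out / "predictions.tsv")
                (out / "predictions.meta.json").write_text(
                    json.dumps(
                        {
                            "cutoff": metrics_info["threshold"],
                            "n_candidates": len(candidates),
                            "n_scored": len(ranked),
                            "n_flagged": int(ranked["flagged"].sum()),
                            "n_missing_features": len(missing),
                        },
                        indent=2,
                    )
                )
                _log(stage, t0, [out / "predictions.tsv", out / "predictions.meta.json"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _rebuild_plan(split_info: Mapping, complete: LabeledPairSet) -> SplitPlan:
    train_drugs = frozenset(split_info["train_drugs"])
    test_drugs = frozenset(split_info["test_drugs"])
    train, test, dropped = [], [], []
    for p in complete.pairs:
        a, b, _ = p
        if a in train_drugs and b in train_drugs:
            train.append(p)
        elif a in test_drugs and b in test_drugs:
            test.append(p)
        else:
            dropped.append(p)
    return SplitPlan(
        train_drugs=train_drugs,
        test_drugs=test_drugs,
        train_pairs=tuple(train),
        test_pairs=tuple(test),
        dropped_pairs=tuple(dropped),
        seed=int(split_info["seed"]),
        ratio=tuple(split_info["ratio"]),
    )
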