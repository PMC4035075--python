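"""End-to-end study orchestration.

``run_study`` chains the whole analysis: generate (or load) a study, scan
with one or more reference-predictor configurations, evaluate each against
the validated interactions (confusion counts, precision/recall threshold
sweep, optimal score, ROC/AUC), combine predictors by union and
intersection, characterize the TP-like vs FN-like duplex features (four
features with rank-test p-values, entropy profiles, alignment-vector
clustering), and fit the free-energy-vs-length trend.  The result is one
JSON-serializable report, deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
import tomllib
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from mirduplex.evaluation import (
    combine_predictions,
    confusion_from_predictions,
    energy_length_trend,
    optimal_score,
    precision_recall,
    roc_auc,
    specificity_sensitivity,
    threshold_sweep,
)
from mirduplex.interaction_features import (
    alignment_vector,
    cluster_alignment_vectors,
    compare_feature_distributions,
    entropy_profile,
    feature_vector,
)
from mirduplex.io_formats import Prediction
from mirduplex.reference_predictor import ScanConfig, predict_transcriptome
from mirduplex.synth_data import StudyConfig, SynthStudy, generate_study

_SCHEMA_PATH = Path(__file__).with_name("report_schema.json")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 42,
    "study": {"n_tp": 60, "n_fn": 60, "n_decoys": 10},
    "evaluation": {"n_tp": 25, "n_fn": 25, "n_decoys": 8},
    "predictors": {
        "strict": {"cutoff": 3.0},
        "lenient": {"cutoff": 6.0, "anchor_max_mismatches": 2},
    },
    "combination": {"pair": ["strict", "lenient"]},
    "trend": {"frac": 0.5},
}


def load_config(path) -> dict:
    """Read a flat TOML run configuration, merged over the defaults."""
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, Mapping) and isinstance(cfg.get(key), dict):
            if key == "predictors":
                cfg[key] = {k: dict(v) for k, v in value.items()}
            else:
                cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _scan_config(pred_cfg: Mapping[str, Any]) -> ScanConfig:
    kwargs = {
        k: pred_cfg[k]
        for k in ("seed_anchor", "anchor_max_mismatches", "gap_rescue_margin")
        if k in pred_cfg
    }
    if "anchor_window" in pred_cfg:
        kwargs["anchor_window"] = tuple(pred_cfg["anchor_window"])
    return ScanConfig(**kwargs)


def _pair_scores(
    predictions: Sequence[Prediction], pairs: Sequence[tuple[str, str]], sentinel: float
) -> list[float]:
    """Best (lowest) score per pair; ``sentinel`` for pairs never called."""
    best: dict[tuple[str, str], float] = {}
    for p in predictions:
        if p.pair not in best or p.score < best[p.pair]:
            best[p.pair] = p.score
    return [best.get(pair, sentinel) for pair in pairs]


def _evaluate_predictor(
    name: str,
    pred_cfg: Mapping[str, Any],
    mirnas,
    transcripts,
    validated_pairs,
    negative_pairs,
) -> tuple[dict, list[Prediction]]:
    cutoff = float(pred_cfg.get("cutoff", 4.0))
    scan = predict_transcriptome(
        mirnas, transcripts, cutoff, _scan_config(pred_cfg), tool=name
    )
    predictions = list(scan.predictions)
    counts = confusion_from_predictions(predictions, validated_pairs, negative_pairs)
    prec, rec = precision_recall(counts)
    spec, sens = specificity_sensitivity(counts)

    section: dict[str, Any] = {
        "cutoff": cutoff,
        "n_predictions": len(predictions),
        "mean_predictions_per_mirna": scan.mean_predictions_per_mirna,
        "confusion_default": _counts_dict(counts),
        "precision": prec,
        "recall": rec,
        "specificity": spec,
        "sensitivity": sens,
    }

    if predictions:
        curve = threshold_sweep(predictions, validated_pairs, negative_pairs)
        opt = optimal_score(curve)
        called = [p for p in predictions if p.score <= opt]
        counts_opt = confusion_from_predictions(called, validated_pairs, negative_pairs)
        p_opt, r_opt = precision_recall(counts_opt)
        section["threshold_curve"] = {
            "thresholds": list(curve.thresholds),
            "precision": list(curve.precision),
            "recall": list(curve.recall),
        }
        section["optimal_score"] = opt
        section["confusion_at_optimal"] = _counts_dict(counts_opt)
        section["precision_at_optimal"] = p_opt
        section["recall_at_optimal"] = r_opt

        sentinel = max(p.score for p in predictions) + 1.0
        pos = _pair_scores(predictions, list(validated_pairs), sentinel)
        neg = _pair_scores(predictions, list(negative_pairs), sentinel)
        _, auc = roc_auc(pos, neg, "lower_better")
        section["auc"] = auc
    else:
        section["threshold_curve"] = {"thresholds": [], "precision": [], "recall": []}
        section["optimal_score"] = None
        section["confusion_at_optimal"] = _counts_dict(counts)
        section["precision_at_optimal"] = prec
        section["recall_at_optimal"] = rec
        section["auc"] = None
    return section, predictions


def _counts_dict(c) -> dict:
    return {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn}


def _feature_frame(study: SynthStudy) -> pd.DataFrame:
    mirna_seq = {m.identifier: m.residues for m in study.mirnas}
    rows = []
    for group, records in (("tp", study.validated), ("fn", study.divergent)):
        for rec in records:
            aln = study.alignments[rec.pair]
            fv = feature_vector(aln, mirna_seq[rec.mirna_id])
            rows.append(
                {
                    "mirna_id": rec.mirna_id,
                    "target_id": rec.target_id,
                    "dataset": rec.dataset,
                    "group": group,
                    "gc_fraction": fv.gc_fraction,
                    "max_match_stretch": fv.max_match_stretch,
                    "first_stretch": fv.first_stretch,
                    "match_mismatch_ratio": fv.match_mismatch_ratio,
                }
            )
    return pd.DataFrame(rows)


def characterize_features(study: SynthStudy) -> tuple[dict, pd.DataFrame]:
    """TP-like vs FN-like feature comparison, entropy profiles, clustering."""
    frame = _feature_frame(study)
    tp = frame[frame["group"] == "tp"]
    fn = frame[frame["group"] == "fn"]
    tests = {}
    for feat in ("gc_fraction", "max_match_stretch", "first_stretch", "match_mismatch_ratio"):
        res = compare_feature_distributions(tp[feat], fn[feat])
        tests[feat] = {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}

    tp_alns = [study.alignments[r.pair] for r in study.validated]
    fn_alns = [study.alignments[r.pair] for r in study.divergent]
    profiles = {
        "tp": list(entropy_profile(tp_alns).values),
        "fn": list(entropy_profile(fn_alns).values),
    }
    vectors = np.array([alignment_vector(a) for a in tp_alns + fn_alns])
    _, leaves = cluster_alignment_vectors(vectors)
    section = {
        "n_tp": int(len(tp)),
        "n_fn": int(len(fn)),
        "rank_tests": tests,
        "entropy_profiles": profiles,
        "cluster_leaf_order": leaves,
    }
    return section, frame


def run_study(config: Mapping[str, Any] | str | Path | None = None, seed: int | None = None) -> dict:
    """Run the full simulate-scan-evaluate-characterize pipeline.

    ``config`` may be a mapping, a path to a TOML file, or ``None`` for the
    packaged demo configuration.  ``seed`` overrides the configured seed.
    The returned report validates against the packaged report schema.
    """
    if config is None:
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    elif isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))
        for key, value in config.items():
            if isinstance(value, Mapping) and isinstance(cfg.get(key), dict) and key != "predictors":
                cfg[key].update(value)
            elif key == "predictors":
                cfg[key] = {k: dict(v) for k, v in value.items()}
            else:
                cfg[key] = value
    if seed is not None:
        cfg["seed"] = int(seed)

    study_cfg = StudyConfig(**cfg.get("study", {}), seed=int(cfg["seed"]))
    study = generate_study(study_cfg)

    # evaluation runs on a subset of the study so scanning stays cheap;
    # feature characterization uses every interaction
    ev = cfg.get("evaluation", {})
    n_tp = min(int(ev.get("n_tp", 25)), len(study.validated))
    n_fn = min(int(ev.get("n_fn", 25)), len(study.divergent))
    n_dec = min(int(ev.get("n_decoys", 8)), len(study.decoys))
    eval_records = list(study.validated[:n_tp]) + list(study.divergent[:n_fn])
    eval_pairs = [r.pair for r in eval_records]
    mirna_by_id = {m.identifier: m for m in study.mirnas}
    tx_by_id = {t.identifier: t for t in study.transcripts}
    eval_mirnas = [mirna_by_id[r.mirna_id] for r in eval_records]
    eval_transcripts = [tx_by_id[r.target_id] for r in eval_records]
    eval_decoys = list(study.decoys[:n_dec])
    negative_pairs = [
        (m.identifier, d.identifier) for m in eval_mirnas for d in eval_decoys
    ]

    predictors: dict[str, dict] = {}
    predictions_by_tool: dict[str, list[Prediction]] = {}
    for name, pred_cfg in cfg["predictors"].items():
        section, preds = _evaluate_predictor(
            name,
            pred_cfg,
            eval_mirnas,
            eval_transcripts + eval_decoys,
            eval_pairs,
            negative_pairs,
        )
        predictors[name] = section
        predictions_by_tool[name] = preds

    combo_pair = cfg.get("combination", {}).get("pair") or list(predictors)[:2]
    combinations: dict[str, dict] = {}
    if len(combo_pair) == 2 and all(t in predictions_by_tool for t in combo_pair):
        a, b = (predictions_by_tool[t] for t in combo_pair)
        for mode in ("union", "intersection"):
            combined = combine_predictions(a, b, mode)
            counts = confusion_from_predictions(combined, eval_pairs, negative_pairs)
            prec, rec = precision_recall(counts)
            combinations[f"{combo_pair[0]}|{combo_pair[1]}|{mode}"] = {
                "mode": mode,
                "confusion": _counts_dict(counts),
                "precision": prec,
                "recall": rec,
            }

    features_section, feature_frame = characterize_features(study)

    trend = energy_length_trend(
        study.energy_records, frac=float(cfg.get("trend", {}).get("frac", 0.5))
    )
    trend_section = {
        "spearman_rho": trend.rho,
        "spearman_pvalue": trend.pvalue,
        "smoothed_first": trend.smoothed[0],
        "smoothed_last": trend.smoothed[-1],
        "n_records": len(study.energy_records),
    }

    report = {
        "seed": int(cfg["seed"]),
        "study": {
            "n_tp": len(study.validated),
            "n_fn": len(study.divergent),
            "n_decoys": len(study.decoys),
            "n_negative_pairs": len(study.negatives),
        },
        "predictors": predictors,
        "combinations": combinations,
        "features": features_section,
        "energy_trend": trend_section,
    }
    validate_report(report)
    report["_feature_table"] = feature_frame.to_dict(orient="list")
    return report


# ---------------------------------------------------------------------------
# Minimal schema validation
# ---------------------------------------------------------------------------

def load_report_schema() -> dict:
    return json.loads(_SCHEMA_PATH.read_text())


def validate_report(report: Mapping[str, Any], schema: Mapping[str, Any] | None = None) -> None:
    """Validate a report against the packaged schema.

    Supports the subset of JSON-schema keywords the schema uses: ``type``,
    ``properties``, ``required``, ``items``, ``additionalProperties`` (as a
    schema applied to extra keys).  Raises ``ValueError`` on mismatch.
    """
    if schema is None:
        schema = load_report_schema()
    _validate(report, schema, path="$")


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "boolean": bool,
}


def _validate(value, schema: Mapping[str, Any], path: str) -> None:
    typ = schema.get("type")
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        ok = False
        for t in allowed:
            if t == "number":
                ok = ok or (isinstance(value, (int, float)) and not isinstance(value, bool))
            elif t == "null":
                ok = ok or value is None
            else:
                ok = ok or (
                    isinstance(value, _TYPES[t])
                    and not (t != "boolean" and isinstance(value, bool))
                )
        if not ok:
            raise ValueError(f"{path}: expected type {typ}, got {type(value).__name__}")
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                raise ValueError(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        extra_schema = schema.get("additionalProperties")
        for key, sub in value.items():
            if key in props:
                _validate(sub, props[key], f"{path}.{key}")
            elif isinstance(extra_schema, dict):
                _validate(sub, extra_schema, f"{path}.{key}")
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _validate(item, schema["items"], f"{path}[{i}]")
    if _nonfinite_float(value):
        raise ValueError(f"{path}: non-finite number")


def _nonfinite_float(value) -> bool:
    return isinstance(value, float) and not math.isfinite(value)
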