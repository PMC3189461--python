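"""End-to-end orchestration: signals -> features -> rules -> classification.

A run is described by a single YAML config (see ``PipelineConfig``); every
source of randomness is derived from one master seed, per-patient child
seeds keep patients independent yet reproducible, and each run writes a
manifest recording the resolved configuration and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import load_laryngopathy_dataset
from .deformation import _spawn_seeds, two_path_results
from .rnn import NetworkConfig, TrainingDivergenceError
from .rough import (
    DecisionSystem,
    c45_tree,
    lem2,
    md_discretize,
    training_report,
    tree_to_rules,
    classify,
)
from .signals import COHORT_PRESETS, SynthesisSpec, read_wav, synth_phoneme

logger = logging.getLogger("phonodeform")

__all__ = [
    "PipelineConfig",
    "run_features",
    "run_classify",
    "reference_rules",
]


@dataclass
class PipelineConfig:
    """Resolved configuration of a feature-extraction run.

    ``inputs`` lists WAV recordings with labels; ``synthetic`` lists cohorts
    generated in-package instead. Exactly one of the two must be non-empty.
    """

    inputs: list[dict] = field(default_factory=list)  # {path, label, id?}
    synthetic: list[dict] = field(default_factory=list)  # cohort dicts
    network: dict = field(default_factory=dict)  # NetworkConfig overrides
    windowing: dict = field(default_factory=dict)  # mode/window_length/k
    seed: int = 0
    classifier: str = "both"  # lem2 | tree | both
    output_dir: str = "phonodeform_out"

    def __post_init__(self) -> None:
        if self.classifier not in ("lem2", "tree", "both"):
            raise ValueError(f"invalid classifier choice: {self.classifier!r}")
        if bool(self.inputs) == bool(self.synthetic):
            raise ValueError("provide exactly one of 'inputs' or 'synthetic'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(**{"max_epochs": 400, **self.network})

    def windowing_params(self) -> dict:
        return {
            "mode": self.windowing.get("mode", "fixed"),
            "window_length": int(self.windowing.get("window_length", 256)),
            "k_windows": int(self.windowing.get("k_windows", 4)),
            "min_distance": int(self.windowing.get("min_distance", 32)),
        }


def _synthetic_patients(config: PipelineConfig):
    """Yield (patient_id, label, Signal) for the synthetic cohorts."""
    seeds = _spawn_seeds(config.seed, 1 + sum(
        int(c.get("n_signals", 10)) for c in config.synthetic
    ))
    pos = 1
    for cohort in config.synthetic:
        name = cohort.get("name", "cohort")
        label = cohort.get("label", "yes")
        n_signals = int(cohort.get("n_signals", 10))
        preset = dict(COHORT_PRESETS.get(cohort.get("preset", ""), {}))
        for key in ("jitter", "shimmer", "noise_level", "n_cycles", "base_period"):
            if key in cohort:
                preset[key] = cohort[key]
        preset.setdefault("n_cycles", 40)
        preset.setdefault("base_period", 64)
        for i in range(n_signals):
            spec = SynthesisSpec(seed=seeds[pos], **preset)
            pos += 1
            yield f"{name}_{i + 1}", label, synth_phoneme(spec)


def _wav_patients(config: PipelineConfig):
    for i, item in enumerate(config.inputs):
        patient_id = item.get("id", Path(item["path"]).stem)
        yield patient_id, item.get("label"), read_wav(item["path"])


def run_features(config: PipelineConfig) -> pd.DataFrame:
    """Compute the (a1, a2) feature table for every input signal.

    Writes ``features.csv``, a ``features.json`` sidecar with the full
    per-repeat arrays, and ``manifest.json`` with the resolved configuration
    into ``config.output_dir``. A patient whose training diverges is flagged
    in a ``status`` column; the run continues.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    net_config = config.network_config()
    win = config.windowing_params()
    patients = (
        _synthetic_patients(config) if config.synthetic else _wav_patients(config)
    )
    patient_list = list(patients)
    seeds = _spawn_seeds(config.seed ^ 0x5EED, len(patient_list) or 1)
    rows = []
    sidecar = []
    for i, (patient_id, label, signal) in enumerate(patient_list):
        try:
            res1, res2 = two_path_results(
                signal,
                net_config,
                k_windows=win["k_windows"],
                window_length=win["window_length"],
                seed=seeds[i],
                mode=win["mode"],
                min_distance=win["min_distance"],
            )
        except TrainingDivergenceError as exc:
            logger.error("patient %s: training diverged (%s)", patient_id, exc)
            rows.append(
                {
                    "patient_id": patient_id,
                    "a1": np.nan,
                    "a2": np.nan,
                    "n_bar_original": np.nan,
                    "n_bar_derivative": np.nan,
                    "label": label,
                    "status": "diverged",
                }
            )
            continue
        rows.append(
            {
                "patient_id": patient_id,
                "a1": res1.E_bar,
                "a2": res2.E_bar,
                "n_bar_original": res1.n_bar,
                "n_bar_derivative": res2.n_bar,
                "label": label,
                "status": "ok",
            }
        )
        sidecar.append(
            {
                "patient_id": patient_id,
                "original": {
                    "per_repeat_mse": list(res1.per_repeat_mse),
                    "per_repeat_epochs": list(res1.per_repeat_epochs),
                },
                "derivative": {
                    "per_repeat_mse": list(res2.per_repeat_mse),
                    "per_repeat_epochs": list(res2.per_repeat_epochs),
                },
            }
        )
        logger.info(
            "patient %s: a1=%.5f a2=%.5f", patient_id, res1.E_bar, res2.E_bar
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "features.csv", index=False, float_format="%.8f")
    (out / "features.json").write_text(json.dumps(sidecar, indent=2))
    manifest = {
        "package": "phonodeform",
        "version": __version__,
        "config": config.to_dict(),
        "n_patients": len(patient_list),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return df


def _induce(ds: DecisionSystem, method: str):
    if method == "lem2":
        cuts = md_discretize(ds)
        rules = lem2(ds, cuts)
        return rules, {"cuts": [(c.attribute, c.threshold) for c in cuts]}
    if method == "tree":
        tree = c45_tree(ds)
        return tree, {"tree": json.loads(tree.to_json())}
    raise ValueError(f"unknown method: {method!r}")


def _rules_of(classifier) -> list:
    from .rough import DecisionTree

    if isinstance(classifier, DecisionTree):
        return tree_to_rules(classifier)
    return classifier


def run_classify(
    features_csv: str | Path,
    method: str = "lem2",
    labeled: bool | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Classify a features table, inducing rules when labels are present.

    With a ``label``/``decision`` column (or ``labeled=True``), a classifier
    is induced from the table itself and a training report computed;
    otherwise the rules induced from the packaged 30-patient reference data
    are applied. Returns a JSON-serializable report; when ``output_dir`` is
    given, writes ``report.json`` and the rules in IF/THEN style.
    """
    df = pd.read_csv(features_csv)
    label_col = next(
        (c for c in ("label", "decision", "d") if c in df.columns), None
    )
    if labeled is None:
        labeled = label_col is not None and df[label_col].notna().all()
    usable = df[df.get("status", "ok") == "ok"] if "status" in df.columns else df
    report: dict = {"method": method, "trained_on": None}
    if labeled:
        if label_col is None:
            raise ValueError("labeled classification requires a label column")
        ds = DecisionSystem(
            tuple(str(v) for v in usable["patient_id"]),
            ("a1", "a2"),
            tuple(
                (float(r.a1), float(r.a2)) for r in usable.itertuples()
            ),
            tuple(str(v) for v in usable[label_col]),
        )
        classifier, extra = _induce(ds, method)
        report["trained_on"] = "input features"
        report.update(extra)
    else:
        ref = load_laryngopathy_dataset()
        classifier, extra = _induce(ref, method)
        report["trained_on"] = "packaged reference data"
        report.update(extra)
        ds = None
    rules = _rules_of(classifier)
    report["rules"] = [str(r) for r in rules]
    predictions = [
        classify(classifier, {"a1": float(r.a1), "a2": float(r.a2)})
        for r in usable.itertuples()
    ]
    report["predictions"] = dict(zip(usable["patient_id"].astype(str), predictions))
    if ds is not None:
        train = training_report(classifier, ds)
        report["training_error_percent"] = train.error_rate
        report["uncovered_count"] = train.uncovered_count
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        (out / "rules.txt").write_text("\n".join(report["rules"]) + "\n")
    return report


def reference_rules() -> dict:
    """Induce both classifiers on the packaged 30-patient reference data.

    Returns the discretization cuts, the LEM2 rules, the decision tree and
    its rules, and both training reports.
    """
    ds = load_laryngopathy_dataset()
    cuts = md_discretize(ds)
    rules = lem2(ds, cuts)
    tree = c45_tree(ds)
    lem2_report = training_report(rules, ds)
    tree_report = training_report(tree, ds)
    uncovered_ids = [
        case_id
        for case_id, pred in zip(ds.case_ids, lem2_report.predictions)
        if pred == "uncovered"
    ]
    return {
        "cuts": [(c.attribute, c.threshold) for c in cuts],
        "lem2_rules": [str(r) for r in rules],
        "lem2_error_percent": lem2_report.error_rate,
        "lem2_uncovered": uncovered_ids,
        "tree": json.loads(tree.to_json()),
        "tree_rules": [str(r) for r in tree_to_rules(tree)],
        "tree_error_percent": tree_report.error_rate,
    }
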