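"""End-to-end orchestration: simulate -> standardize -> train -> screen ->
predict -> evaluate, as one reproducible seeded run.

A single global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence([seed, stage_index])`` so that changing one
stage's consumption of randomness cannot perturb another stage.  Each stage
writes its outputs to the run directory and subsequent stages re-read them
from disk: there is no hidden in-process state between stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from .cutoff_screen import derive_cutoff_rules, recall_protocol, screen_cohort, write_rules
from .errors import PipelineStageError
from .risk_model import (
    MODEL_FAMILIES,
    compute_feature_ranking,
    predict,
    save_model,
    select_features,
    select_model,
    split_data,
    train_candidates,
)
from .standardize import (
    DEFAULT_RATIOS,
    compute_median_reference,
    feature_frame,
    write_median_reference,
)
from .synth_cohort import (
    DEFAULT_DEMO_GROUPS,
    SimulationConfig,
    default_disease_groups,
    default_panel,
    read_cohort,
    simulate_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "stage_seed", "run_pipeline", "default_run_config"]

#: fixed stage indices for seed fan-out
STAGES = ("simulate", "split", "train", "screen", "inject")


def stage_seed(seed: int, *indices: int) -> int:
    """Deterministic child seed below 2**31 for a pipeline stage."""
    return int(np.random.SeedSequence([int(seed), *map(int, indices)]).generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible run needs; the seed is mandatory."""

    seed: int
    n_newborns: int = 20000
    group_ids: tuple = DEFAULT_DEMO_GROUPS
    n_batches: int = 8
    batch_effect_sd: float = 0.06
    measurement_cv: float = 0.10
    families: tuple = MODEL_FAMILIES
    hyperparams: dict = field(default_factory=dict)
    top_k: int = 12
    redundancy_r: float = 0.95
    flag_rate_multiplier: float = 10.0
    cutoff_lower_pct: float = 0.5
    cutoff_upper_pct: float = 99.5
    split_ratio: tuple = (8, 2)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_newborns=self.n_newborns,
            seed=stage_seed(self.seed, 0),
            analytes=default_panel(),
            disease_groups=default_disease_groups(self.group_ids),
            n_batches=self.n_batches,
            batch_effect_sd=self.batch_effect_sd,
            measurement_cv=self.measurement_cv,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_ids"] = list(self.group_ids)
        d["families"] = list(self.families)
        d["split_ratio"] = list(self.split_ratio)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise ValueError("run config must specify a seed")
        for key in ("group_ids", "families", "split_ratio"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def default_run_config(seed: int, **overrides) -> RunConfig:
    return RunConfig(seed=seed, **overrides)


@dataclass
class RunManifest:
    config: dict
    stage_seeds: dict
    versions: dict
    checksums: dict
    metrics: dict

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _versions() -> dict:
    import sklearn

    from . import __version__

    return {
        "neoscreen": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def run_pipeline(config: RunConfig, outdir) -> RunManifest:
    """Execute all stages, writing the cohort, median reference, model,
    cutoff rules, calls and report under ``outdir``.  Any stage error
    aborts with the stage name; partial outputs are retained next to a
    FAILED marker."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        sim_config = config.simulation_config()
        groups = list(sim_config.disease_groups)
        cohort = simulate_cohort(sim_config)
        write_cohort(cohort, out / "cohort.tsv")

        stage = "standardize"
        analyte_names = [a.name for a in sim_config.analytes]
        cohort = read_cohort(out / "cohort.tsv", required_analytes=analyte_names)
        # the laboratory default of 50 per stratum, relaxed for small demo
        # runs where random batch assignment leaves fewer per batch
        ref = compute_median_reference(
            cohort, min_count=min(50, max(1, config.n_newborns // (2 * config.n_batches))))
        write_median_reference(ref, out / "median_reference.tsv")
        X = feature_frame(cohort, ref, DEFAULT_RATIOS)
        labels = pd.Series([r.true_group for r in cohort],
                           index=[r.sample_id for r in cohort])

        stage = "train"
        model = None
        split = None
        if groups:
            split = split_data(list(labels.index), list(labels), ratio=config.split_ratio,
                               seed=stage_seed(config.seed, 1))
            X_train = X.loc[list(split.train_ids)]
            y_train = labels.loc[list(split.train_ids)]
            any_case = (~y_train.isna()).astype(int)
            ranking = compute_feature_ranking(X_train, any_case)
            features = select_features(ranking, X_train, top_k=config.top_k,
                                       redundancy_r=config.redundancy_r)
            candidates = train_candidates(
                X_train[features], list(y_train), [g.group_id for g in groups],
                families=config.families, seed=stage_seed(config.seed, 2),
                hyperparams=config.hyperparams,
            )
            prevalences = {g.group_id: g.prevalence for g in groups}
            X_test = X.loc[list(split.test_ids)]
            y_test = labels.loc[list(split.test_ids)]
            model = select_model(candidates, X_train[features], list(y_train),
                                 prevalences, config.flag_rate_multiplier,
                                 X_test=X_test[features], labels_test=list(y_test))
            save_model(model, out / "model")

        stage = "screen"
        protocol = derive_cutoff_rules(cohort, groups, config.cutoff_lower_pct,
                                       config.cutoff_upper_pct) if groups else None
        if protocol is not None:
            write_rules(protocol, out / "cutoff_rules.tsv")
            initial = screen_cohort(cohort, protocol)
            suspected = recall_protocol(cohort, protocol, seed=stage_seed(config.seed, 3))
        else:
            index = [r.sample_id for r in cohort]
            initial = pd.DataFrame(index=index)
            suspected = pd.DataFrame(index=index)
        suspected.to_csv(out / "suspected.tsv", sep="\t")

        stage = "predict"
        if model is not None:
            result = predict(model, X[list(model.feature_names)])
            calls = pd.concat(
                [result.scores.add_prefix("score_"), result.flags.add_prefix("flag_")], axis=1
            )
        else:
            result = None
            calls = pd.DataFrame(index=X.index)
        calls.to_csv(out / "calls.tsv", sep="\t")

        stage = "evaluate"
        metrics = _evaluate_run(config, cohort, labels, split, model, result,
                                initial, suspected, out)
    except Exception as exc:  # noqa: BLE001 - stage tagging is the contract
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineStageError(stage, exc) from exc

    checksums = {
        p.name: _sha256(p)
        for p in sorted(out.glob("*.tsv")) + sorted(out.glob("report.json"))
    }
    manifest = RunManifest(
        config=config.to_dict(),
        stage_seeds={name: stage_seed(config.seed, i) for i, name in enumerate(STAGES)},
        versions=_versions(),
        checksums=checksums,
        metrics=metrics,
    )
    manifest.write(out / "manifest.json")
    return manifest


def _evaluate_run(config, cohort, labels, split, model, result, initial, suspected, out):
    n = len(cohort)
    truth = {r.sample_id: r.true_group for r in cohort}
    group_ids = list(initial.columns)

    ai_flags = {
        g: set(result.flags.index[result.flags[g]]) for g in result.flags.columns
    } if result is not None else {}
    phys_flags = {g: set(suspected.index[suspected[g]]) for g in group_ids}
    summary = ev.build_comparison_table(ai_flags, phys_flags, truth, n) if n else None

    initial_any = int(initial.any(axis=1).sum()) if len(initial.columns) else 0
    suspected_any = int(suspected.any(axis=1).sum()) if len(suspected.columns) else 0
    ai_any_ids = set().union(*ai_flags.values()) if ai_flags else set()

    unaffected = [sid for sid, g in truth.items() if g is None]
    unaffected_flagged = len(ai_any_ids & set(unaffected))

    metrics: dict = {
        "n_screened": n,
        "n_cases": int(sum(1 for g in truth.values() if g is not None)),
        "initial_positive": initial_any,
        "suspected_positive": suspected_any,
        "ai_positive": len(ai_any_ids),
        "recall_rate_percent": ev.recall_rate(initial_any, n) if n else None,
        "ai_positive_rate_percent": ev.positive_rate(len(ai_any_ids), n) if n else None,
        "unaffected_flag_rate_percent": (
            ev.positive_rate(unaffected_flagged, len(unaffected)) if unaffected else None
        ),
        "overall_fp_reduction_percent": (
            ev.fp_reduction(suspected_any, len(ai_any_ids)) if suspected_any else None
        ),
        "selected_family": model.family if model is not None else None,
    }

    if model is not None and split is not None:
        train_labels = labels.loc[list(split.train_ids)]
        test_labels = labels.loc[list(split.test_ids)]
        per_group_train_sens = {}
        test_hits = 0
        test_cases = 0
        for g in model.groups:
            train_pos = train_labels.index[train_labels == g]
            flagged = result.flags.loc[train_pos, g]
            per_group_train_sens[g] = float(flagged.mean()) if len(train_pos) else None
            test_pos = test_labels.index[test_labels == g]
            test_cases += len(test_pos)
            test_hits += int(result.flags.loc[test_pos, g].sum())
        metrics["train_sensitivity_per_group"] = per_group_train_sens
        metrics["test_cases"] = test_cases
        metrics["test_cases_flagged"] = test_hits
        metrics["test_sensitivity_percent"] = (
            ev.positive_rate(test_hits, test_cases) if test_cases else None
        )

    report = {"metrics": metrics}
    if summary is not None:
        report["comparison"] = [dataclasses.asdict(r) for r in summary.rows]
        report["totals"] = {
            "ai_total": summary.ai_total,
            "phys_total": summary.phys_total,
            "both": summary.both,
            "ai_only": summary.ai_only,
        }
        summary.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return metrics
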