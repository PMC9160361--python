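"""Desk-scale recovery experiments.

These run the whole method in memory on synthetic cohorts and measure how
well it recovers the planted truth: sensitivity on held-out cases, the
unaffected flag rate, the flag volume relative to the cutoff-screen
baseline, and the borderline-case scenario in which the primary marker
stays inside its normal range while secondary markers carry the signal.
Shared by the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cutoff_screen import apply_cutoffs, derive_cutoff_rules, recall_protocol
from .pipeline import RunConfig, stage_seed
from .risk_model import (
    compute_feature_ranking,
    predict,
    select_features,
    select_model,
    split_data,
    train_candidates,
)
from .standardize import DEFAULT_RATIOS, compute_median_reference, feature_frame
from .synth_cohort import inject_borderline_case, simulate_cohort

__all__ = ["SeedResult", "run_recovery_seed", "run_recovery_experiment"]


@dataclass
class SeedResult:
    seed: int
    selected_family: str
    train_sensitivity: float          # fraction of training cases flagged for their group
    test_cases: int
    test_cases_flagged: int
    unaffected: int
    unaffected_flagged: int
    ai_positive: int                  # distinct samples flagged by the model
    suspected_positive: int           # distinct cutoff-screen suspected positives
    borderline_missed_by_cutoffs: bool
    borderline_flagged_by_model: bool

    @property
    def test_sensitivity(self) -> float | None:
        return self.test_cases_flagged / self.test_cases if self.test_cases else None

    @property
    def unaffected_flag_rate(self) -> float:
        return self.unaffected_flagged / self.unaffected if self.unaffected else 0.0

    @property
    def fp_reduction_vs_cutoffs(self) -> float | None:
        if self.suspected_positive == 0:
            return None
        return 100.0 * (self.suspected_positive - self.ai_positive) / self.suspected_positive


def run_recovery_seed(config: RunConfig, borderline_group: str = "NICCD") -> SeedResult:
    """One seeded end-to-end run on a fresh synthetic cohort."""
    sim_config = config.simulation_config()
    groups = list(sim_config.disease_groups)
    group_ids = [g.group_id for g in groups]
    cohort = simulate_cohort(sim_config)

    ref = compute_median_reference(cohort)
    X = feature_frame(cohort, ref, DEFAULT_RATIOS)
    labels = pd.Series([r.true_group for r in cohort], index=[r.sample_id for r in cohort])

    split = split_data(list(labels.index), list(labels), ratio=config.split_ratio,
                       seed=stage_seed(config.seed, 1))
    X_train = X.loc[list(split.train_ids)]
    y_train = labels.loc[list(split.train_ids)]
    ranking = compute_feature_ranking(X_train, (~y_train.isna()).astype(int))
    features = select_features(ranking, X_train, top_k=config.top_k,
                               redundancy_r=config.redundancy_r)
    candidates = train_candidates(X_train[features], list(y_train), group_ids,
                                  families=config.families, seed=stage_seed(config.seed, 2),
                                  hyperparams=config.hyperparams)
    prevalences = {g.group_id: g.prevalence for g in groups}
    X_test = X.loc[list(split.test_ids)]
    y_test = labels.loc[list(split.test_ids)]
    model = select_model(candidates, X_train[features], list(y_train), prevalences,
                         config.flag_rate_multiplier,
                         X_test=X_test[features], labels_test=list(y_test))

    result = predict(model, X[list(model.feature_names)])
    flags = result.flags

    protocol = derive_cutoff_rules(cohort, groups, config.cutoff_lower_pct,
                                   config.cutoff_upper_pct)
    suspected = recall_protocol(cohort, protocol, seed=stage_seed(config.seed, 3))

    # recovery metrics
    train_pos_flagged = 0
    train_pos = 0
    test_cases = 0
    test_hits = 0
    for g in model.groups:
        tr = [s for s in split.train_ids if labels[s] == g]
        te = [s for s in split.test_ids if labels[s] == g]
        train_pos += len(tr)
        train_pos_flagged += int(flags.loc[tr, g].sum())
        test_cases += len(te)
        test_hits += int(flags.loc[te, g].sum())

    unaffected_ids = labels.index[labels.isna()]
    ai_any = flags.any(axis=1)
    suspected_any = suspected.any(axis=1)

    # borderline scenario: primary marker inside the screening protocol's
    # own normal range, secondary markers fully shifted
    group = next(g for g in groups if g.group_id == borderline_group)
    rule = protocol.rules[borderline_group][0]
    injected_cohort = inject_borderline_case(
        cohort, sim_config, group, (rule.low, rule.high),
        seed=stage_seed(config.seed, 4),
    )
    injected = injected_cohort[-1]
    all_rules = [r for rs in protocol.rules.values() for r in rs]
    missed = not apply_cutoffs(injected, all_rules)
    inj_X = feature_frame([injected], ref, DEFAULT_RATIOS)
    inj_flags = predict(model, inj_X[list(model.feature_names)]).flags
    flagged = bool(inj_flags.iloc[0][borderline_group])

    return SeedResult(
        seed=config.seed,
        selected_family=model.family,
        train_sensitivity=train_pos_flagged / train_pos if train_pos else 1.0,
        test_cases=test_cases,
        test_cases_flagged=test_hits,
        unaffected=len(unaffected_ids),
        unaffected_flagged=int(ai_any.loc[unaffected_ids].sum()),
        ai_positive=int(ai_any.sum()),
        suspected_positive=int(suspected_any.sum()),
        borderline_missed_by_cutoffs=missed,
        borderline_flagged_by_model=flagged,
    )


def run_recovery_experiment(base_seed: int, n_seeds: int = 5, **config_overrides) -> list:
    """Repeat the recovery run over ``n_seeds`` independent child seeds."""
    results = []
    for i in range(n_seeds):
        config = RunConfig(seed=stage_seed(base_seed, 100 + i), **config_overrides)
        results.append(run_recovery_seed(config))
    return results
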