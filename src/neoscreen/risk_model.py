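"""Multi-disease risk model: feature selection, candidate training,
sensitivity-constrained model selection, quantile risk-score mapping and
prevalence-tied cutoff calibration.

The model is one-vs-rest per disease group: groups share markers, so one
newborn may legitimately flag for several.  Candidate families are a bagged
tree ensemble (random forest), a boosted tree ensemble, and a small
feedforward network.  The winner is the candidate that flags every training
case at the calibrated per-group cutoffs with the fewest false positives —
a deliberately asymmetric criterion: in screening, a missed case is worth
far more than a recalled healthy newborn.

Risk scores are population quantiles: score = 100 x (fraction of a sorted
reference of training probabilities <= p), so a score of 99 means the
sample is riskier than 99% of the screened population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import json
import numpy as np
import pandas as pd
import joblib
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import CalibrationError, ConfigurationError, FeatureError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureScore",
    "TrainTestSplit",
    "CandidateModel",
    "TrainedRiskModel",
    "RiskCall",
    "PredictionResult",
    "MODEL_FAMILIES",
    "information_gain",
    "compute_feature_ranking",
    "select_features",
    "split_data",
    "train_candidates",
    "select_model",
    "map_risk_score",
    "calibrate_cutoffs",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FAMILIES = ("tree_ensemble_bagged", "tree_ensemble_boosted", "feedforward_network")


# ---------------------------------------------------------------------------
# feature screening

def _entropy(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(values, labels, n_bins: int = 10) -> float:
    """Information gain H(Y) - H(Y | X_binned), in bits.

    Continuous features are discretized into ``n_bins`` quantile bins; a
    feature with at most ``n_bins`` distinct values is treated as already
    discrete.  Constant labels give 0 by convention.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ConfigurationError("values and labels must have equal length")
    if x.shape[0] < 2:
        raise ConfigurationError("information gain needs at least 2 samples")
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) == 1:
        return 0.0

    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        bins = np.searchsorted(uniq, x)
    else:
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
        bins = np.digitize(x, edges)

    h_y = _entropy(np.bincount(y_codes))
    n = len(x)
    h_y_given_x = 0.0
    for b in np.unique(bins):
        mask = bins == b
        h_y_given_x += mask.sum() / n * _entropy(np.bincount(y_codes[mask]))
    return max(0.0, h_y - h_y_given_x)


class FeatureScore(NamedTuple):
    information_gain: float
    abs_correlation: float


def compute_feature_ranking(X: pd.DataFrame, labels, n_bins: int = 10) -> dict:
    """Per-feature information gain and |point-biserial correlation| with
    the binary label."""
    y = np.asarray(labels).astype(float)
    ranking = {}
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        ig = information_gain(x, y, n_bins=n_bins)
        if np.std(x) == 0 or np.std(y) == 0:
            corr = 0.0
        else:
            corr = abs(float(np.corrcoef(x, y)[0, 1]))
        ranking[name] = FeatureScore(ig, corr)
    return ranking


def select_features(
    ranking: Mapping[str, FeatureScore],
    X: pd.DataFrame,
    top_k: int,
    redundancy_r: float = 0.95,
) -> list:
    """Greedy redundancy-pruned top-k by information gain.

    Features are visited in decreasing information gain (name as a
    deterministic tie-break); a feature is dropped when its |Pearson
    correlation| with an already-kept feature exceeds ``redundancy_r``.
    If fewer than ``top_k`` features survive, all survivors are returned
    with a logged notice.
    """
    if top_k < 1:
        raise ConfigurationError("top_k must be >= 1")
    ordered = sorted(ranking, key=lambda f: (-ranking[f].information_gain, f))
    kept: list = []
    corr = X[ordered].corr().abs()
    for f in ordered:
        if any(corr.loc[f, k] > redundancy_r for k in kept):
            continue
        kept.append(f)
        if len(kept) == top_k:
            return kept
    if len(kept) < top_k:
        logger.info("only %d of requested %d features survive redundancy pruning", len(kept), top_k)
    return kept


# ---------------------------------------------------------------------------
# splitting and training

@dataclass(frozen=True)
class TrainTestSplit:
    train_ids: tuple
    test_ids: tuple
    seed: int


def split_data(sample_ids: Sequence[str], labels: Sequence, ratio=(8, 2), seed: int = 0) -> TrainTestSplit:
    """Stratified train/test split (default 8:2) reproducible by seed.

    Strata are the truth labels (each disease group, plus the unaffected
    pool).  Per stratum, the test count is ``round(n * test_fraction)``,
    capped so at least one member stays in training; a stratum with exactly
    one sample goes to training with a warning.
    """
    ids = list(sample_ids)
    if not ids:
        raise ConfigurationError("cannot split an empty cohort")
    labs = ["__none__" if l is None else str(l) for l in labels]
    if len(labs) != len(ids):
        raise ConfigurationError("sample_ids and labels must align")
    test_frac = ratio[1] / (ratio[0] + ratio[1])
    rng = np.random.default_rng(seed)

    strata: dict = {}
    for sid, lab in zip(ids, labs):
        strata.setdefault(lab, []).append(sid)

    train: list = []
    test: list = []
    for lab in sorted(strata):
        members = sorted(strata[lab])
        if len(members) == 1:
            logger.warning("stratum %r has a single sample; assigned to training", lab)
            train.extend(members)
            continue
        rng.shuffle(members)
        n_test = int(round(len(members) * test_frac))
        n_test = min(n_test, len(members) - 1)
        test.extend(members[:n_test])
        train.extend(members[n_test:])
    return TrainTestSplit(train_ids=tuple(sorted(train)), test_ids=tuple(sorted(test)), seed=seed)


def _default_hyperparams() -> dict:
    # with a handful of positives per group, unregularized trees memorize
    # the cases and generalize poorly; depth/leaf limits keep the
    # probability surface smooth enough to rank unseen presentations
    return {
        "tree_ensemble_bagged": {"n_estimators": 500, "max_depth": 12,
                                 "min_samples_leaf": 2,
                                 "class_weight": "balanced_subsample"},
        "tree_ensemble_boosted": {"max_iter": 100, "max_depth": 3,
                                  "learning_rate": 0.1, "min_samples_leaf": 20,
                                  "class_weight": "balanced", "early_stopping": False},
        "feedforward_network": {"hidden_layer_sizes": (32,), "max_iter": 300},
    }


def _make_estimator(family: str, seed: int, hyperparams: Mapping | None = None):
    hp = dict(_default_hyperparams()[family])
    if hyperparams:
        hp.update(hyperparams)
    if family == "tree_ensemble_bagged":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if family == "tree_ensemble_boosted":
        return HistGradientBoostingClassifier(random_state=seed, **hp)
    if family == "feedforward_network":
        return Pipeline([
            ("scale", StandardScaler()),
            ("net", MLPClassifier(random_state=seed, **hp)),
        ])
    raise ConfigurationError(f"unknown model family {family!r}")


@dataclass
class CandidateModel:
    """One fitted family: a per-group binary classifier exposing case
    probability for each modeled disease group."""

    family: str
    estimators: Mapping[str, object]
    feature_names: tuple
    hyperparams: Mapping = field(default_factory=dict)

    def predict_proba(self, X: pd.DataFrame) -> pd.DataFrame:
        _check_features(X, self.feature_names)
        Xm = X[list(self.feature_names)].to_numpy(dtype=float)
        out = {}
        for group, est in self.estimators.items():
            proba = est.predict_proba(Xm)
            pos_col = list(est.classes_).index(True) if hasattr(est, "classes_") \
                else list(est[-1].classes_).index(True)
            out[group] = proba[:, pos_col]
        return pd.DataFrame(out, index=X.index)


def _check_features(X: pd.DataFrame, feature_names: Iterable[str]) -> None:
    missing = [f for f in feature_names if f not in X.columns]
    if missing:
        raise FeatureError(f"feature matrix is missing features: {missing}")


def _child_seed(seed: int, *ids: int) -> int:
    return int(np.random.SeedSequence([seed, *ids]).generate_state(1)[0] % 2**31)


def train_candidates(
    X_train: pd.DataFrame,
    labels_train: Sequence,
    groups: Sequence[str],
    families: Sequence[str] = MODEL_FAMILIES,
    seed: int = 0,
    hyperparams: Mapping[str, Mapping] | None = None,
) -> list:
    """Fit one candidate per family, each with a one-vs-rest classifier per
    disease group.  A group without training positives is dropped from the
    run with a warning.  Training is fully seeded."""
    labs = pd.Series(["" if l is None else str(l) for l in labels_train], index=X_train.index)
    usable = []
    for g in groups:
        if int((labs == g).sum()) == 0:
            logger.warning("group %r has no training positives; dropped from this run", g)
        else:
            usable.append(g)
    candidates = []
    for fi, family in enumerate(families):
        estimators = {}
        for gi, g in enumerate(usable):
            est = _make_estimator(family, _child_seed(seed, fi, gi),
                                  (hyperparams or {}).get(family))
            est.fit(X_train.to_numpy(dtype=float), (labs == g).to_numpy())
            estimators[g] = est
        candidates.append(CandidateModel(
            family=family,
            estimators=estimators,
            feature_names=tuple(X_train.columns),
            hyperparams=(hyperparams or {}).get(family, {}),
        ))
    return candidates


# ---------------------------------------------------------------------------
# scores and cutoffs

def map_risk_score(probability, population_probabilities) -> np.ndarray | float:
    """Quantile risk score: 100 x (# reference probabilities <= p) / size.

    Monotone (non-decreasing) in p; a higher quantile means a higher risk.
    """
    ref = np.sort(np.asarray(population_probabilities, dtype=float))
    if ref.size == 0:
        raise ConfigurationError("population reference must be non-empty")
    p = np.asarray(probability, dtype=float)
    scores = 100.0 * np.searchsorted(ref, p, side="right") / ref.size
    return float(scores) if np.isscalar(probability) else scores


def calibrate_cutoffs(
    scores: pd.DataFrame,
    labels,
    prevalences: Mapping[str, float],
    flag_rate_multiplier: float = 10.0,
) -> dict:
    """Per-group score cutoff tying flag volume to disease prevalence while
    guaranteeing every training positive is flagged:

    cutoff = min(lowest training-positive score,
                 population score at the (1 - multiplier x prevalence) quantile)

    A cutoff that would flag everyone is floored at 0 with a warning.
    """
    labs = pd.Series(["" if l is None else str(l) for l in labels], index=scores.index)
    cutoffs = {}
    for group in scores.columns:
        pos = scores.loc[labs == group, group]
        if pos.empty:
            raise CalibrationError(f"group {group!r} has no training positives to calibrate against")
        q = 1.0 - flag_rate_multiplier * prevalences[group]
        q = min(max(q, 0.0), 1.0)
        quantile_score = float(np.quantile(scores[group].to_numpy(), q, method="higher"))
        cutoff = min(float(pos.min()), quantile_score)
        if cutoff <= 0:
            logger.warning("group %r cutoff floored at 0 (flags the whole population)", group)
            cutoff = 0.0
        cutoffs[group] = cutoff
    return cutoffs


@dataclass
class TrainedRiskModel:
    """The selected family plus everything needed to score new samples:
    per-group classifiers, the sorted training-probability reference used
    for quantile mapping, per-group cutoffs and prevalences."""

    family: str
    estimators: Mapping[str, object]
    feature_names: tuple
    groups: tuple
    population: Mapping[str, np.ndarray]
    cutoffs: Mapping[str, float]
    prevalences: Mapping[str, float]
    flag_rate_multiplier: float

    def predict_proba(self, X: pd.DataFrame) -> pd.DataFrame:
        return CandidateModel(self.family, self.estimators, self.feature_names).predict_proba(X)

    def scores(self, X: pd.DataFrame) -> pd.DataFrame:
        probs = self.predict_proba(X)
        return pd.DataFrame(
            {g: map_risk_score(probs[g].to_numpy(), self.population[g]) for g in self.groups},
            index=X.index,
        )


@dataclass(frozen=True)
class RiskCall:
    sample_id: str
    scores: Mapping[str, float]
    flags: Mapping[str, bool]


@dataclass
class PredictionResult:
    scores: pd.DataFrame
    flags: pd.DataFrame

    def calls(self) -> list:
        return [
            RiskCall(
                sample_id=str(sid),
                scores={g: float(self.scores.loc[sid, g]) for g in self.scores.columns},
                flags={g: bool(self.flags.loc[sid, g]) for g in self.flags.columns},
            )
            for sid in self.scores.index
        ]


def _evaluate_candidate(candidate, X_train, labels_train, prevalences,
                        flag_rate_multiplier, X_eval=None, labels_eval=None,
                        volume_tolerance=5.0):
    """Calibrate a candidate on the training data and measure it.

    Returns (population, cutoffs, train_sensitivity_ok, volume_ok,
    missed_eval_positives, eval_false_positives).  ``volume_ok`` is False
    when any group's calibrated cutoff flags more than
    ``volume_tolerance x flag_rate_multiplier x prevalence`` of the
    training population — a model that can only reach 100% sensitivity by
    flagging far beyond its incidence-tied budget has failed calibration.
    Evaluation counts use held-out data when given, else the training data.
    """
    probs = candidate.predict_proba(X_train)
    population = {g: np.sort(probs[g].to_numpy()) for g in probs.columns}
    scores = pd.DataFrame(
        {g: map_risk_score(probs[g].to_numpy(), population[g]) for g in probs.columns},
        index=probs.index,
    )
    cutoffs = calibrate_cutoffs(scores, labels_train, prevalences, flag_rate_multiplier)
    labs = pd.Series(["" if l is None else str(l) for l in labels_train], index=scores.index)
    sensitivity_ok = True
    volume_ok = True
    for g in probs.columns:
        pos = labs == g
        if not bool((scores.loc[pos, g] >= cutoffs[g]).all()):
            sensitivity_ok = False
        budget = volume_tolerance * flag_rate_multiplier * prevalences[g]
        if float((scores[g] >= cutoffs[g]).mean()) > budget:
            volume_ok = False

    if X_eval is not None and len(X_eval):
        eval_probs = candidate.predict_proba(X_eval)
        eval_scores = pd.DataFrame(
            {g: map_risk_score(eval_probs[g].to_numpy(), population[g])
             for g in probs.columns},
            index=eval_probs.index,
        )
        eval_labs = pd.Series(["" if l is None else str(l) for l in labels_eval],
                              index=eval_scores.index)
    else:
        eval_scores, eval_labs = scores, labs
    missed = 0
    fp_total = 0
    for g in probs.columns:
        flagged = eval_scores[g] >= cutoffs[g]
        pos = eval_labs == g
        missed += int((~flagged & pos).sum())
        fp_total += int((flagged & ~pos).sum())
    return population, cutoffs, sensitivity_ok, volume_ok, missed, fp_total


def select_model(
    candidates: Sequence[CandidateModel],
    X_train: pd.DataFrame,
    labels_train: Sequence,
    prevalences: Mapping[str, float],
    flag_rate_multiplier: float = 10.0,
    X_test: pd.DataFrame | None = None,
    labels_test: Sequence | None = None,
    volume_tolerance: float = 5.0,
) -> TrainedRiskModel:
    """Select among calibrated candidates: identification first, false
    positives second.

    A candidate qualifies when its calibrated cutoffs flag 100% of
    training positives AND keep each group's flag volume within
    ``volume_tolerance`` times its incidence-tied budget (a model that can
    only reach full sensitivity by flagging a large share of the
    population has failed calibration).  Among qualifiers the winner
    misses the fewest positives on the held-out portion of the split, with
    the false-positive count as tie-break; without a held-out set both are
    counted on the training data.  Raises :class:`CalibrationError` when
    no candidate qualifies."""
    if not candidates:
        raise CalibrationError("no candidate models supplied")
    best = None
    for candidate in candidates:
        population, cutoffs, sens_ok, volume_ok, missed, fp = _evaluate_candidate(
            candidate, X_train, labels_train, prevalences, flag_rate_multiplier,
            X_eval=X_test, labels_eval=labels_test, volume_tolerance=volume_tolerance,
        )
        logger.info(
            "candidate %s: train sensitivity %s, flag volume %s, "
            "held-out misses %d, false positives %d",
            candidate.family, "100%" if sens_ok else "<100%",
            "ok" if volume_ok else "over budget", missed, fp,
        )
        if not (sens_ok and volume_ok):
            continue
        key = (missed, fp)
        if best is None or key < best[0]:
            best = (key, candidate, population, cutoffs)
    if best is None:
        raise CalibrationError(
            "no candidate attains 100% training sensitivity within its "
            "incidence-tied flag budget at the calibrated cutoffs"
        )
    _, candidate, population, cutoffs = best
    model = TrainedRiskModel(
        family=candidate.family,
        estimators=candidate.estimators,
        feature_names=candidate.feature_names,
        groups=tuple(population),
        population=population,
        cutoffs=cutoffs,
        prevalences={g: float(prevalences[g]) for g in population},
        flag_rate_multiplier=float(flag_rate_multiplier),
    )
    # assert, never assume: the winner must flag every training positive
    _assert_train_sensitivity(model, X_train, labels_train)
    return model


def _assert_train_sensitivity(model: TrainedRiskModel, X_train, labels_train) -> None:
    result = predict(model, X_train)
    labs = pd.Series(["" if l is None else str(l) for l in labels_train], index=X_train.index)
    for g in model.groups:
        pos = labs == g
        if not bool(result.flags.loc[pos, g].all()):
            raise CalibrationError(f"selected model misses training positives for group {g!r}")


def predict(model: TrainedRiskModel, X: pd.DataFrame) -> PredictionResult:
    """Score samples and flag each group at its calibrated cutoff.
    A sample may be high-risk for several groups; deterministic for a
    fixed model and inputs."""
    _check_features(X, model.feature_names)
    scores = model.scores(X)
    flags = pd.DataFrame(
        {g: scores[g] >= model.cutoffs[g] for g in model.groups}, index=X.index
    )
    return PredictionResult(scores=scores, flags=flags)


# ---------------------------------------------------------------------------
# persistence

_MANIFEST_VERSION = 1


def save_model(model: TrainedRiskModel, directory) -> None:
    """Serialize to a directory: a JSON manifest (config snapshot, feature
    order, cutoffs, prevalences) plus a joblib payload with the fitted
    estimators and population references."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "manifest_version": _MANIFEST_VERSION,
        "family": model.family,
        "feature_names": list(model.feature_names),
        "groups": list(model.groups),
        "cutoffs": {g: model.cutoffs[g] for g in model.groups},
        "prevalences": {g: model.prevalences[g] for g in model.groups},
        "flag_rate_multiplier": model.flag_rate_multiplier,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    joblib.dump(
        {"estimators": dict(model.estimators),
         "population": {g: np.asarray(model.population[g]) for g in model.groups}},
        d / "payload.joblib",
    )


def load_model(directory) -> TrainedRiskModel:
    from pathlib import Path

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("manifest_version") != _MANIFEST_VERSION:
        raise ConfigurationError("unsupported model manifest version")
    payload = joblib.load(d / "payload.joblib")
    return TrainedRiskModel(
        family=manifest["family"],
        estimators=payload["estimators"],
        feature_names=tuple(manifest["feature_names"]),
        groups=tuple(manifest["groups"]),
        population=payload["population"],
        cutoffs={g: float(v) for g, v in manifest["cutoffs"].items()},
        prevalences={g: float(v) for g, v in manifest["prevalences"].items()},
        flag_rate_multiplier=float(manifest["flag_rate_multiplier"]),
    )
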