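"""Risk model: information gain vs a brute-force contingency oracle,
redundancy-pruned feature selection, stratified splitting, seeded training,
quantile score mapping and sensitivity-constrained calibration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neoscreen.errors import CalibrationError, ConfigurationError, FeatureError
from neoscreen.risk_model import (
    MODEL_FAMILIES,
    calibrate_cutoffs,
    compute_feature_ranking,
    information_gain,
    map_risk_score,
    predict,
    load_model,
    save_model,
    select_features,
    select_model,
    split_data,
    train_candidates,
)


# ---------------------------------------------------------------------------
# information gain

def oracle_ig(table):
    """Brute-force IG from a 2x2 contingency table [[a, b], [c, d]]
    (rows = X levels, columns = Y levels)."""
    table = np.asarray(table, dtype=float)
    n = table.sum()

    def H(counts):
        p = np.asarray(counts, dtype=float)
        p = p[p > 0] / p.sum()
        return -(p * np.log2(p)).sum() if p.size else 0.0

    h_y = H(table.sum(axis=0))
    h_y_x = sum(row.sum() / n * H(row) for row in table if row.sum() > 0)
    return h_y - h_y_x


def _vectors_from_table(table):
    x, y = [], []
    for xi, row in enumerate(table):
        for yi, count in enumerate(row):
            x.extend([xi] * count)
            y.extend([yi] * count)
    return np.array(x), np.array(y)


@pytest.mark.parametrize(
    "table,expected",
    [
        ([[2, 0], [0, 2]], 1.0),            # X perfectly predicts balanced Y
        ([[1, 1], [1, 1]], 0.0),            # independence
        ([[3, 1], [1, 3]], 1 - (-0.75 * math.log2(0.75) - 0.25 * math.log2(0.25))),
    ],
)
def test_information_gain_known_tables(table, expected):
    x, y = _vectors_from_table(table)
    assert information_gain(x, y) == pytest.approx(expected, abs=1e-12)


def test_information_gain_constant_labels_zero():
    assert information_gain([1.0, 2.0, 3.0], [0, 0, 0]) == 0.0


def test_information_gain_matches_oracle_on_all_small_tables():
    """Exhaustive check against the contingency oracle on every 2x2 table
    with 2 <= n <= 8 and both X levels populated."""
    checked = 0
    for n in range(2, 9):
        for a, b, c in itertools.product(range(n + 1), repeat=3):
            d = n - a - b - c
            if d < 0:
                continue
            if a + b == 0 or c + d == 0:  # X must take both levels
                continue
            table = [[a, b], [c, d]]
            x, y = _vectors_from_table(table)
            assert information_gain(x, y) == pytest.approx(
                max(0.0, oracle_ig(table)), abs=1e-12)
            checked += 1
    assert checked > 300


# ---------------------------------------------------------------------------
# feature selection

def _feature_frame_with_labels(seed=0, n=400):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    f1 = y + rng.normal(0, 0.3, n)          # informative
    f2 = f1.copy()                          # perfectly redundant with f1
    f3 = 0.8 * f1 + rng.normal(0, 0.2, n)   # highly correlated with f1
    f4 = rng.normal(0, 1, n)                # noise
    f5 = -y + rng.normal(0, 0.5, n)         # informative, anticorrelated
    X = pd.DataFrame({"f1": f1, "f2": f2, "f3": f3, "f4": f4, "f5": f5})
    return X, y


def test_identical_features_keep_exactly_one():
    X, y = _feature_frame_with_labels()
    ranking = compute_feature_ranking(X[["f1", "f2"]], y)
    kept = select_features(ranking, X[["f1", "f2"]], top_k=2, redundancy_r=0.95)
    assert len(kept) == 1


def test_redundancy_disabled_gives_pure_top_k():
    X, y = _feature_frame_with_labels()
    ranking = compute_feature_ranking(X, y)
    kept = select_features(ranking, X, top_k=3, redundancy_r=1.0)
    by_ig = sorted(ranking, key=lambda f: (-ranking[f].information_gain, f))
    assert kept == by_ig[:3]


def test_greedy_matches_exhaustive_oracle():
    """The greedy redundancy rule must agree with an independently coded
    greedy pass over the same ranking and correlation matrix."""
    X, y = _feature_frame_with_labels(seed=3)
    ranking = compute_feature_ranking(X, y)
    corr = X.corr().abs()
    r = 0.8
    ordered = sorted(ranking, key=lambda f: (-ranking[f].information_gain, f))
    expected = []
    for f in ordered:
        if all(corr.loc[f, k] <= r for k in expected):
            expected.append(f)
    kept = select_features(ranking, X, top_k=len(X.columns), redundancy_r=r)
    assert kept == expected


def test_top_k_exceeding_survivors_returns_all():
    X, y = _feature_frame_with_labels()
    ranking = compute_feature_ranking(X[["f1", "f2"]], y)
    kept = select_features(ranking, X[["f1", "f2"]], top_k=5, redundancy_r=0.95)
    assert len(kept) == 1


# ---------------------------------------------------------------------------
# splitting

def test_split_80_20_no_cases():
    ids = [f"S{i}" for i in range(100)]
    split = split_data(ids, [None] * 100, seed=1)
    assert len(split.train_ids) == 80 and len(split.test_ids) == 20
    assert set(split.train_ids) | set(split.test_ids) == set(ids)
    assert not set(split.train_ids) & set(split.test_ids)


def test_split_deterministic():
    ids = [f"S{i}" for i in range(50)]
    labels = ["G" if i < 10 else None for i in range(50)]
    assert split_data(ids, labels, seed=5) == split_data(ids, labels, seed=5)


def test_split_stratifies_cases_8_2():
    ids = [f"S{i}" for i in range(1000)]
    labels = ["G" if i < 10 else None for i in range(1000)]
    split = split_data(ids, labels, seed=2)
    train_cases = sum(1 for i, l in zip(ids, labels) if l and i in set(split.train_ids))
    assert train_cases == 8


def test_single_case_goes_to_train():
    ids = [f"S{i}" for i in range(20)]
    labels = ["G" if i == 0 else None for i in range(20)]
    split = split_data(ids, labels, seed=0)
    assert "S0" in split.train_ids


# ---------------------------------------------------------------------------
# training and selection

def _separable_toy(seed=0, n=400, n_pos=60):
    rng = np.random.default_rng(seed)
    y = np.array(["G"] * n_pos + [None] * (n - n_pos), dtype=object)
    x1 = np.where(y == "G", rng.normal(8, 0.5, n), rng.normal(0, 0.5, n))
    x2 = rng.normal(0, 1, n)
    X = pd.DataFrame({"x1": x1, "x2": x2}, index=[f"S{i}" for i in range(n)])
    return X, list(y)


def test_every_family_separates_toy_data():
    X, y = _separable_toy()
    candidates = train_candidates(X, y, ["G"], seed=3)
    assert [c.family for c in candidates] == list(MODEL_FAMILIES)
    for c in candidates:
        probs = c.predict_proba(X)["G"]
        pos = probs[[l == "G" for l in y]]
        neg = probs[[l is None for l in y]]
        assert pos.min() > neg.max()  # separable at some threshold


def test_training_is_deterministic():
    X, y = _separable_toy()
    p1 = train_candidates(X, y, ["G"], seed=9)[0].predict_proba(X)
    p2 = train_candidates(X, y, ["G"], seed=9)[0].predict_proba(X)
    assert (p1.to_numpy() == p2.to_numpy()).all()


def test_shuffled_labels_destroy_signal():
    """Permutation null: with labels shuffled, held-out case probabilities
    are statistically indistinguishable from controls."""
    rng = np.random.default_rng(12)
    X, y = _separable_toy(seed=12, n=400, n_pos=40)
    y_shuffled = list(rng.permutation(np.array(y, dtype=object)))
    train_idx = X.index[:300]
    test_idx = X.index[300:]
    cand = train_candidates(X.loc[train_idx], list(np.array(y_shuffled, dtype=object)[:300]),
                            ["G"], families=("tree_ensemble_bagged",), seed=4)[0]
    probs = cand.predict_proba(X.loc[test_idx])["G"]
    is_case = np.array([l == "G" for l in y_shuffled[300:]])
    res = stats.mannwhitneyu(probs[is_case], probs[~is_case])
    assert res.pvalue > 0.01


def test_group_without_positives_dropped():
    X, y = _separable_toy()
    candidates = train_candidates(X, y, ["G", "EMPTY"], seed=0,
                                  families=("tree_ensemble_bagged",))
    assert list(candidates[0].estimators) == ["G"]


# ---------------------------------------------------------------------------
# score mapping and cutoffs

def test_score_at_reference_maximum_is_100():
    assert map_risk_score(0.4, [0.1, 0.2, 0.3, 0.4]) == 100.0


def test_score_rank_count():
    assert map_risk_score(0.1, [0.1, 0.2, 0.3, 0.4]) == 25.0


def test_score_below_reference_is_0():
    assert map_risk_score(0.05, [0.1, 0.2, 0.3, 0.4]) == 0.0


def test_score_empty_reference_error():
    with pytest.raises(ConfigurationError):
        map_risk_score(0.5, [])


def test_score_mapping_monotone_and_uniform_on_reference():
    """Applying the mapping to its own reference yields scores uniform on
    the rank grid {100/n, 200/n, ..., 100}; the mapping is monotone."""
    rng = np.random.default_rng(0)
    ref = rng.random(500)
    scores = map_risk_score(np.sort(ref), ref)
    assert np.allclose(np.sort(scores), 100.0 * np.arange(1, 501) / 500)
    ps = np.linspace(0, 1, 101)
    out = map_risk_score(ps, ref)
    assert (np.diff(out) >= 0).all()


def _scores_frame(pop_scores, pos_scores, group="G"):
    labels = [None] * len(pop_scores) + [group] * len(pos_scores)
    values = list(pop_scores) + list(pos_scores)
    return pd.DataFrame({group: values},
                        index=[f"S{i}" for i in range(len(values))]), labels


def test_cutoff_sensitivity_constraint_binds():
    scores, labels = _scores_frame(np.linspace(0, 96, 200), [87.0, 99.0])
    cutoffs = calibrate_cutoffs(scores, labels, {"G": 0.001}, flag_rate_multiplier=10)
    # min positive score 87 < prevalence-quantile score (~95) -> 87 wins
    assert cutoffs["G"] == 87.0


def test_cutoff_prevalence_bound_binds():
    scores, labels = _scores_frame(np.linspace(0, 96, 200), [99.0, 100.0])
    cutoffs = calibrate_cutoffs(scores, labels, {"G": 0.001}, flag_rate_multiplier=10)
    assert cutoffs["G"] < 99.0  # the 99.8% population quantile, not 99


def test_all_training_positives_above_cutoff():
    rng = np.random.default_rng(7)
    scores, labels = _scores_frame(rng.uniform(0, 100, 300), rng.uniform(50, 100, 10))
    cutoffs = calibrate_cutoffs(scores, labels, {"G": 0.01})
    labs = np.array([l == "G" for l in labels])
    assert (scores["G"].to_numpy()[labs] >= cutoffs["G"]).all()


def test_cutoff_without_positives_raises():
    scores, _ = _scores_frame(np.linspace(0, 96, 50), [])
    with pytest.raises(CalibrationError):
        calibrate_cutoffs(scores, [None] * 50, {"G": 0.01})


# ---------------------------------------------------------------------------
# model selection and prediction

def test_select_model_flags_all_training_positives():
    X, y = _separable_toy()
    candidates = train_candidates(X, y, ["G"], seed=1)
    model = select_model(candidates, X, y, {"G": 0.01})
    result = predict(model, X)
    pos = [i for i, l in zip(X.index, y) if l == "G"]
    assert result.flags.loc[pos, "G"].all()


def test_select_model_prefers_fewer_misses_then_false_positives():
    X, y = _separable_toy()
    candidates = train_candidates(X, y, ["G"], seed=1)
    model = select_model(candidates, X, y, {"G": 0.01})
    # recompute each qualifying candidate's (missed, fp) at its own
    # calibration and check the winner attains the lexicographic minimum
    from neoscreen.risk_model import _evaluate_candidate

    keys = {}
    for c in candidates:
        _, _, sens_ok, vol_ok, missed, fp = _evaluate_candidate(c, X, y, {"G": 0.01}, 10.0)
        if sens_ok and vol_ok:
            keys[c.family] = (missed, fp)
    assert keys[model.family] == min(keys.values())


def test_select_model_no_candidates_raises():
    X, y = _separable_toy()
    with pytest.raises(CalibrationError):
        select_model([], X, y, {"G": 0.01})


def test_predict_feature_mismatch_lists_missing():
    X, y = _separable_toy()
    model = select_model(train_candidates(X, y, ["G"], seed=1,
                                          families=("tree_ensemble_bagged",)),
                         X, y, {"G": 0.01})
    with pytest.raises(FeatureError, match="x2"):
        predict(model, X[["x1"]])


def test_predict_deterministic():
    X, y = _separable_toy()
    model = select_model(train_candidates(X, y, ["G"], seed=1,
                                          families=("tree_ensemble_bagged",)),
                         X, y, {"G": 0.01})
    r1 = predict(model, X)
    r2 = predict(model, X)
    assert (r1.scores.to_numpy() == r2.scores.to_numpy()).all()
    assert (r1.flags.to_numpy() == r2.flags.to_numpy()).all()


def test_model_save_load_round_trip(tmp_path):
    X, y = _separable_toy()
    model = select_model(train_candidates(X, y, ["G"], seed=1,
                                          families=("tree_ensemble_bagged",)),
                         X, y, {"G": 0.01})
    save_model(model, tmp_path / "model")
    back = load_model(tmp_path / "model")
    assert back.family == model.family
    assert back.cutoffs == model.cutoffs
    r1, r2 = predict(model, X), predict(back, X)
    assert (r1.scores.to_numpy() == r2.scores.to_numpy()).all()
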