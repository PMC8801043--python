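"""Metric identities and the cross-validation report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import scarnet as sn
from scarnet.errors import ConfigurationError
from scarnet.metrics import characteristic_block, evaluate, mae


# ----------------------------------------------------------------------
# R^2
# ----------------------------------------------------------------------

def test_r_squared_identities():
    y = np.array([0.2, 0.5, 0.9])
    assert sn.r_squared(y, y) == pytest.approx(1.0)
    assert sn.r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)


def test_r_squared_hand_computed_triple():
    # residuals (0, 0, 2): 1 - 4/2 = -1
    assert sn.r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 5.0]) == pytest.approx(-1.0)


def test_r_squared_rejects_constant_targets():
    with pytest.raises(ConfigurationError):
        sn.r_squared([0.5, 0.5, 0.5], [0.4, 0.5, 0.6])


# ----------------------------------------------------------------------
# aRRMSE
# ----------------------------------------------------------------------

def test_arrmse_identities():
    Y = np.array([[0.1, 0.2], [0.3, 0.4], [0.5, 0.9]])
    assert sn.arrmse(Y, Y) == pytest.approx(0.0)
    col = Y[:, :1]
    mean_pred = np.full_like(col, col.mean())
    assert sn.arrmse(col, mean_pred) == pytest.approx(1.0)


def test_arrmse_against_elementwise_oracle():
    Y = np.array([[0.2, 0.8], [0.4, 0.6], [0.9, 0.5], [0.3, 0.7]])
    P = np.array([[0.25, 0.7], [0.35, 0.65], [0.8, 0.55], [0.4, 0.66]])
    total = 0.0
    for j in range(2):
        num = sum((Y[i, j] - P[i, j]) ** 2 for i in range(4))
        ybar = sum(Y[i, j] for i in range(4)) / 4
        den = sum((Y[i, j] - ybar) ** 2 for i in range(4))
        total += (num / den) ** 0.5
    assert sn.arrmse(Y, P) == pytest.approx(total / 2)


def test_arrmse_names_the_constant_column():
    Y = np.array([[0.1, 0.5], [0.2, 0.5]])
    with pytest.raises(ConfigurationError, match="1"):
        sn.arrmse(Y, Y + 0.01)


# ----------------------------------------------------------------------
# aRelErr and MAE
# ----------------------------------------------------------------------

def test_arelerr_identities():
    assert sn.arelerr([0.5], [0.55]) == pytest.approx(0.1)
    y = np.array([0.3, 0.6])
    assert sn.arelerr(y, y) == 0.0
    with pytest.raises(ConfigurationError):
        sn.arelerr([0.0, 0.5], [0.1, 0.5])


def test_arelerr_against_elementwise_oracle():
    rng = np.random.default_rng(17)
    Y = rng.uniform(0.2, 1.0, size=(10, 10))
    P = Y + rng.normal(scale=0.05, size=(10, 10))
    oracle = np.mean([abs(Y[i, j] - P[i, j]) / abs(Y[i, j])
                      for i in range(10) for j in range(10)])
    assert sn.arelerr(Y, P) == pytest.approx(oracle)


def test_mae_matches_flat_mean():
    assert mae([1.0, 2.0], [1.5, 1.0]) == pytest.approx(0.75)


@given(hnp.arrays(np.float64, (6, 4), elements=st.floats(0.05, 1.0)),
       hnp.arrays(np.float64, (6, 4), elements=st.floats(0.05, 1.0)))
@settings(max_examples=50, deadline=None)
def test_metric_bounds_hold_on_random_fixtures(Y, P):
    if np.any(np.ptp(Y, axis=0) == 0):
        return  # degenerate draws are rejected by the metrics themselves
    assert sn.r_squared(Y, P) <= 1.0
    assert sn.arrmse(Y, P) >= 0.0
    assert sn.arelerr(Y, P) >= 0.0
    assert mae(Y, P) >= 0.0


# ----------------------------------------------------------------------
# min / last RSA
# ----------------------------------------------------------------------

def test_min_last_rsa_extraction():
    assert sn.min_last_rsa(np.ones(365)) == (1.0, 1.0)
    course = np.concatenate([np.linspace(1, 0.4, 60),
                             np.linspace(0.4, 0.9, 305)])
    lo, last = sn.min_last_rsa(course)
    assert lo == pytest.approx(0.4)
    assert last == pytest.approx(0.9)
    with pytest.raises(ConfigurationError):
        sn.min_last_rsa([])


def test_solver_courses_have_min_below_last(tiny_corpus):
    for row in tiny_corpus.Y:
        lo, last = sn.min_last_rsa(row)
        assert lo <= last


# ----------------------------------------------------------------------
# report / evaluate
# ----------------------------------------------------------------------

class _FixedModel:
    """Stand-in model returning predetermined predictions (for scripted
    fold-score tests)."""

    def __init__(self, offset):
        self.offset = offset

    def forward(self, X):
        return self._table[:X.shape[0]] + self.offset


def _mini_split(n=20, n_folds=2, seed=0):
    rng = np.random.default_rng(seed)
    corpus = sn.Corpus(X=rng.uniform(size=(n, 25)),
                       Y=rng.uniform(0.3, 0.9, size=(n, 8)),
                       seeds=np.arange(n),
                       feature_names=sn.VARIED_PARAMETERS)
    return corpus, sn.split_and_scale(corpus, n_folds=n_folds, seed=seed)


def test_perfect_surrogate_scores_perfectly():
    corpus, split = _mini_split()

    class Oracle:
        def forward(self_, X):
            # match rows by lookup in the scaled training/test arrays
            out = np.empty((X.shape[0], split.Y_train.shape[1]))
            for i, row in enumerate(X):
                hit_tr = np.where((split.X_train == row).all(axis=1))[0]
                if hit_tr.size:
                    out[i] = split.Y_train[hit_tr[0]]
                else:
                    hit_te = np.where((split.X_test == row).all(axis=1))[0]
                    out[i] = split.Y_test[hit_te[0]]
            return out

    report = evaluate([Oracle(), Oracle()], Oracle(), split)
    assert report.cv_mean["r2"] == pytest.approx(1.0)
    assert report.test["r2"] == pytest.approx(1.0)
    assert report.test["arrmse"] == pytest.approx(0.0)
    assert report.test["arelerr"] == pytest.approx(0.0)
    for row in report.characteristics.values():
        assert row["range"] == pytest.approx(row["max"] - row["min"])
        assert row["mae"] == pytest.approx(0.0)


def test_cv_sd_uses_sample_standard_deviation():
    corpus, split = _mini_split(n=30, n_folds=3, seed=4)
    models = []
    offsets = (0.0, 0.01, 0.02)
    for off in offsets:
        m = _FixedModel(off)
        m._table = np.zeros((30, split.Y_train.shape[1])) + 0.5
        models.append(m)
    report = evaluate(models, models[0], split)
    scores = report.fold_scores["arelerr"]
    mean = sum(scores) / 3
    sd_oracle = (sum((s - mean) ** 2 for s in scores) / 2) ** 0.5
    assert report.cv_sd["arelerr"] == pytest.approx(sd_oracle)


def test_evaluate_requires_one_model_per_fold():
    corpus, split = _mini_split()
    with pytest.raises(ConfigurationError):
        evaluate([], None, split)


def test_maximizing_r2_is_minimizing_squared_error():
    """Across candidate predictors of a fixed target set, the R^2 ranking is
    exactly the reverse of the MSE ranking."""
    rng = np.random.default_rng(21)
    Y = rng.uniform(0.2, 1.0, size=(40, 6))
    candidates = [Y + rng.normal(scale=s, size=Y.shape)
                  for s in np.linspace(0.01, 0.3, 8)]
    r2s = np.array([sn.r_squared(Y, P) for P in candidates])
    mses = np.array([np.mean((Y - P) ** 2) for P in candidates])
    assert np.array_equal(np.argsort(r2s), np.argsort(-mses))


def test_report_table_renders(tiny_split):
    corpus_like = np.clip(tiny_split.Y_test + 0.01, 0.01, 1.0)
    block = characteristic_block(tiny_split.Y_test, corpus_like)
    assert set(block) == {"min_rsa", "last_rsa"}
    report = sn.MetricsReport(
        cv_mean={"r2": 0.99, "arrmse": 0.06, "arelerr": 0.002},
        cv_sd={"r2": 0.001, "arrmse": 0.008, "arelerr": 0.0003},
        test={"r2": 0.995, "arrmse": 0.05, "arelerr": 0.0019},
        characteristics=block)
    text = report.format_table()
    assert "aRRMSE" in text and "min_rsa" in text
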