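"""Surrogate network: architecture, training protocol, early stopping,
learning-rate range test and prediction contracts."""

import numpy as np
import pytest

import scarnet as sn
from scarnet.errors import ConfigurationError, TrainingError
from scarnet.optimizers import OPTIMIZERS, make_optimizer
from scarnet.surrogate import lr_range_test


def synthetic_problem(n=200, seed=0, n_out=365):
    """Smooth, trivially learnable map from [0,1]^25 into (0,1)."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, 25))
    w = rng.normal(size=(25, n_out)) / 5.0
    Y = 1.0 / (1.0 + np.exp(-(X - 0.5) @ w))
    return X, Y


# ----------------------------------------------------------------------
# architecture
# ----------------------------------------------------------------------

def test_forward_pass_is_sigmoid_bounded():
    model = sn.build_network(seed=0)
    out = model.forward(np.zeros((1, 25)))
    assert out.shape == (1, 365)
    assert np.all((out > 0.0) & (out < 1.0))
    rnd = model.forward(np.random.default_rng(1).normal(size=(7, 25)) * 10)
    assert np.all((rnd > 0.0) & (rnd < 1.0))


def test_build_is_deterministic_per_seed():
    X = np.random.default_rng(2).uniform(size=(4, 25))
    a = sn.build_network(seed=11).forward(X)
    b = sn.build_network(seed=11).forward(X)
    c = sn.build_network(seed=12).forward(X)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_parameter_count_matches_architecture():
    model = sn.build_network(seed=0)
    sizes = model.config.layer_sizes
    expected = sum((fan_in + 1) * fan_out
                   for fan_in, fan_out in zip(sizes[:-1], sizes[1:]))
    assert sizes == (25, 100, 100, 365)
    assert model.n_parameters == expected == model.config.n_parameters


def test_network_config_validation():
    with pytest.raises(ConfigurationError):
        sn.NetworkConfig((25, 100, 365))          # needs two hidden layers
    with pytest.raises(ConfigurationError):
        sn.NetworkConfig((25, 0, 100, 365))
    model = sn.build_network(seed=0)
    with pytest.raises(ConfigurationError):
        model.forward(np.zeros((1, 7)))            # wrong input width


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

def test_training_reduces_the_loss():
    X, Y = synthetic_problem(200)
    model = sn.build_network(seed=0)
    initial = float(np.mean((model.forward(X) - Y) ** 2))
    sn.train(model, X, Y, config=sn.TrainingConfig(max_epochs=40, seed=0))
    assert model.history["train_loss"][-1] < initial


def test_memorization_of_a_tiny_sample():
    X, Y = synthetic_problem(10, seed=3)
    model = sn.build_network(seed=3)
    cfg = sn.TrainingConfig(max_epochs=1500, patience=200, min_delta=0.0,
                            seed=3)
    sn.train(model, X, Y, config=cfg)
    pred = model.forward(X)
    assert sn.r_squared(Y, pred) > 0.999
    assert np.max(np.abs(pred - Y)) < 0.01


def test_early_stopping_bookkeeping_on_scripted_losses():
    stopper = sn.EarlyStopping(patience=30, min_delta=1e-5)
    # 10 improving epochs, then a plateau of sub-threshold fluctuation
    losses = [1.0 / (1 + k) for k in range(10)]
    plateau_start = len(losses)
    losses += [losses[-1] - 4e-6 + (2e-6 if k % 2 else 0.0)
               for k in range(60)]
    stopped_at = None
    for epoch, loss in enumerate(losses):
        if stopper.update(loss):
            stopped_at = epoch
            break
    assert stopped_at is not None
    assert stopped_at <= plateau_start + 30
    assert stopper.best_epoch < plateau_start + 1
    # an improvement of exactly min_delta does not reset the counter
    s2 = sn.EarlyStopping(patience=2, min_delta=1e-5)
    assert not s2.update(1.0)
    assert not s2.update(1.0 - 1e-5)       # change == threshold: no credit
    assert s2.update(1.0 - 1e-5) is True   # second sub-threshold epoch
    assert s2.wait == 2
    assert s2.best == 1.0


def test_early_stopping_halts_training_within_patience_of_plateau():
    X, Y = synthetic_problem(64, seed=5)
    model = sn.build_network(seed=5)
    # huge min_delta: after the baseline epoch no epoch ever 'improves',
    # so training stops after exactly `patience` further epochs
    cfg = sn.TrainingConfig(max_epochs=500, patience=30, min_delta=1e9,
                            seed=5)
    sn.train(model, X, Y, config=cfg)
    assert len(model.history["train_loss"]) == 31


def test_validation_loss_is_monitored_when_given():
    X, Y = synthetic_problem(120, seed=6)
    model = sn.build_network(seed=6)
    sn.train(model, X[:100], Y[:100], X[100:], Y[100:],
             config=sn.TrainingConfig(max_epochs=30, seed=6))
    assert "val_loss" in model.history
    assert len(model.history["val_loss"]) == len(model.history["train_loss"])


def test_divergent_training_raises_with_epoch(monkeypatch):
    X, Y = synthetic_problem(32, seed=7)
    model = sn.build_network(seed=7)
    # poison one weight so the first forward pass is non-finite
    model.weights[0][0, 0] = np.nan
    with pytest.raises(TrainingError) as err:
        sn.train(model, X, Y, config=sn.TrainingConfig(max_epochs=5, seed=7))
    assert err.value.epoch == 0


# ----------------------------------------------------------------------
# optimizers & learning-rate range test
# ----------------------------------------------------------------------

@pytest.mark.parametrize("name", sorted(OPTIMIZERS))
def test_every_optimizer_descends_on_the_synthetic_problem(name):
    X, Y = synthetic_problem(96, seed=8, n_out=20)
    cfg = sn.NetworkConfig((25, 100, 100, 20))
    model = sn.build_network(cfg, seed=8)
    initial = float(np.mean((model.forward(X) - Y) ** 2))
    lr = 0.5 if name in ("adadelta", "ftrl") else 0.01
    sn.train(model, X, Y, config=sn.TrainingConfig(
        optimizer=name, learning_rate=lr, max_epochs=60, seed=8))
    assert model.history["train_loss"][-1] < initial, name


def test_unknown_optimizer_rejected():
    with pytest.raises(ValueError):
        make_optimizer("madgrad", 0.1)
    with pytest.raises(ConfigurationError):
        sn.TrainingConfig(optimizer="madgrad")


def test_lr_range_test_single_cell_and_grid_contract():
    X, Y = synthetic_problem(64, seed=9, n_out=12)
    cfg = sn.NetworkConfig((25, 100, 100, 12))
    table = lr_range_test(["adamax"], [0.01], X, Y, epochs=3,
                          net_config=cfg, seed=9)
    assert len(table) == 1
    assert set(table.columns) == {"optimizer", "lr", "loss", "diverged"}
    with pytest.raises(ConfigurationError):
        lr_range_test(["adamax"], [], X, Y)


def test_lr_range_test_records_divergence_without_raising(monkeypatch):
    X, Y = synthetic_problem(64, seed=10, n_out=8)
    cfg = sn.NetworkConfig((25, 100, 100, 8))
    import scarnet.surrogate as sg

    real_train = sg.train

    def exploding_train(model, *args, **kwargs):
        tc = kwargs.get("config")
        if tc is not None and tc.learning_rate > 0.5:
            raise TrainingError("diverged", epoch=1)
        return real_train(model, *args, **kwargs)

    monkeypatch.setattr(sg, "train", exploding_train)
    table = sg.lr_range_test(["sgd"], [1e-3, 0.9], X, Y, epochs=2,
                             net_config=cfg, seed=10)
    bad = table[table.lr == 0.9].iloc[0]
    assert bad.diverged and np.isinf(bad.loss)
    good = table[table.lr == 1e-3].iloc[0]
    assert not good.diverged and np.isfinite(good.loss)


def test_largest_lr_cell_no_better_than_the_optimizers_best():
    X, Y = synthetic_problem(96, seed=11, n_out=10)
    cfg = sn.NetworkConfig((25, 100, 100, 10))
    table = lr_range_test(["sgd"], [1e-3, 1e-2, 0.9], X, Y, epochs=8,
                          net_config=cfg, seed=11)
    sgd = table[table.optimizer == "sgd"]
    at_09 = float(sgd[sgd.lr == 0.9].loss.iloc[0])
    assert at_09 >= float(sgd.loss.min()) - 1e-12


# ----------------------------------------------------------------------
# prediction
# ----------------------------------------------------------------------

def test_predict_applies_scaler_and_warns_out_of_range():
    scaler = sn.ScalerParams(data_min=np.zeros(25), data_max=np.ones(25))
    model = sn.build_network(seed=12, scaler=scaler)
    inside = np.full((3, 25), 0.5)
    out = sn.predict(model, inside)
    assert out.shape == (3, 365)
    assert np.all((out > 0) & (out < 1))
    with pytest.warns(UserWarning):
        sn.predict(model, np.full((1, 25), 2.5))


def test_model_round_trips_through_disk(tmp_path):
    scaler = sn.ScalerParams(data_min=np.zeros(25), data_max=np.ones(25))
    model = sn.build_network(seed=13, scaler=scaler,
                             feature_names=sn.VARIED_PARAMETERS)
    X = np.random.default_rng(13).uniform(size=(5, 25))
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = sn.SurrogateModel.load(path)
    assert np.array_equal(loaded.forward(X), model.forward(X))
    assert loaded.feature_names == sn.VARIED_PARAMETERS
    assert np.array_equal(loaded.scaler.data_min, scaler.data_min)
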