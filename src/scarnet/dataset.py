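"""Training-corpus generation: stability-constrained uniform parameter
sampling, per-sample simulation, and scaled, split, cross-validation-ready
arrays.

Each corpus row is one simulated patient/wound: the 25 varied parameters
(drawn uniformly within their ranges, rejection-resampled until the
stability condition k_c < delta_c * rho_bar * a_c_II holds) and the
365-day RSA course the finite-element solver produces for them.  Inputs
are Min-Max scaled on the training portion only; targets are left
unscaled (they already live in (0, 1], matching the surrogate's sigmoid
output).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from sklearn.model_selection import KFold, train_test_split
from sklearn.preprocessing import MinMaxScaler

from .errors import ConfigurationError, SolverError
from .fem_solver import Mesh, SolverConfig, simulate
from .model_core import VARIED_PARAMETERS, ParameterSet, check_stability

__all__ = ["RangeSpec", "Corpus", "ScalerParams", "SplitData",
           "sample_parameters", "generate_corpus", "split_and_scale",
           "default_ranges"]

_MAX_REJECTIONS = 100_000


@dataclass(frozen=True)
class RangeSpec:
    """Per-parameter sampling specification.

    ``varied`` maps the 25 varied parameter names (in feature order) to
    (min, max); ``fixed`` maps every other parameter to its value.
    """

    varied: Dict[str, Tuple[float, float]]
    fixed: Dict[str, float]

    def __post_init__(self):
        if tuple(self.varied) != VARIED_PARAMETERS:
            if set(self.varied) != set(VARIED_PARAMETERS):
                missing = set(VARIED_PARAMETERS) ^ set(self.varied)
                raise ConfigurationError(
                    f"exactly the 25 varied parameters must be flagged; "
                    f"mismatch on {sorted(missing)}")
            # normalize ordering to the canonical feature order
            object.__setattr__(self, "varied",
                               {k: self.varied[k] for k in VARIED_PARAMETERS})
        for name, (lo, hi) in self.varied.items():
            if not lo <= hi:
                raise ConfigurationError(f"range of {name}: min {lo} > max {hi}")

    @property
    def feature_names(self) -> Tuple[str, ...]:
        return tuple(self.varied)

    @property
    def bounds(self) -> np.ndarray:
        """(25, 2) array of [min, max] in feature order."""
        return np.array([self.varied[k] for k in self.varied])

    def build(self, values: Sequence[float]) -> ParameterSet:
        """ParameterSet from a 25-vector in feature order plus the fixed values."""
        kwargs = dict(self.fixed)
        kwargs.update(dict(zip(self.varied, values)))
        return ParameterSet(**kwargs)

    @classmethod
    def from_dict(cls, spec: Dict) -> "RangeSpec":
        entries = spec.get("parameters", spec)
        varied, fixed = {}, {}
        for name, entry in entries.items():
            if entry.get("varied"):
                varied[name] = (float(entry["min"]), float(entry["max"]))
            elif "value" in entry:
                fixed[name] = float(entry["value"])
            else:
                raise ConfigurationError(
                    f"parameter {name}: need either 'value' or min/max/varied")
        return cls(varied=varied, fixed=fixed)

    @classmethod
    def from_yaml(cls, path) -> "RangeSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> Dict:
        out = {name: {"min": lo, "max": hi, "varied": True}
               for name, (lo, hi) in self.varied.items()}
        out.update({name: {"value": v} for name, v in self.fixed.items()})
        return {"parameters": out}


def default_ranges() -> RangeSpec:
    """The package's shipped parameter ranges (25 varied + fixed values)."""
    ref = resources.files("scarnet.data").joinpath("default_ranges.yaml")
    return RangeSpec.from_dict(yaml.safe_load(ref.read_text()))


def sample_parameters(ranges: RangeSpec, rng_seed) -> ParameterSet:
    """Draw one stability-admissible parameter set.

    Uniform draw of the full 25-vector, rejected and fully re-drawn until
    the stability condition holds.  ``rng_seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    bounds = ranges.bounds
    names = ranges.feature_names

    def pick(draw, name):
        return draw[names.index(name)] if name in names else ranges.fixed[name]

    for _ in range(_MAX_REJECTIONS):
        draw = rng.uniform(bounds[:, 0], bounds[:, 1])
        # cheap pre-check of the admissibility inequality before building
        # the full parameter set
        if not (pick(draw, "k_c")
                < pick(draw, "delta_c") * pick(draw, "rho_bar")
                * pick(draw, "a_c_II")):
            continue
        params = ranges.build(draw)
        if check_stability(params):
            return params
    raise ConfigurationError(
        f"no stability-admissible draw in {_MAX_REJECTIONS} attempts; "
        "check the k_c / delta_c / a_c_II ranges")


@dataclass
class Corpus:
    """Simulation corpus: X (n x 25 raw inputs), Y (n x 365 RSA targets)."""

    X: np.ndarray
    Y: np.ndarray
    seeds: np.ndarray                      # per-row seed used for the draw
    feature_names: Tuple[str, ...]
    ranges: Optional[RangeSpec] = None
    solver_config: Optional[SolverConfig] = None
    n_nodes: int = 202
    master_seed: Optional[int] = None

    def __post_init__(self):
        if not (self.X.shape[0] == self.Y.shape[0] == self.seeds.shape[0]):
            raise ConfigurationError("X, Y and seeds row counts disagree")
        if self.X.shape[1] != len(self.feature_names):
            raise ConfigurationError("X width does not match feature names")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    # ----------------------------- persistence -----------------------------
    def save(self, path) -> None:
        """HDF5 container (X, Y, seeds) + JSON sidecar with provenance."""
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as fh:
            fh.create_dataset("X", data=self.X)
            fh.create_dataset("Y", data=self.Y)
            fh.create_dataset("seeds", data=self.seeds)
            fh.attrs["feature_names"] = list(self.feature_names)
        sidecar = {
            "feature_names": list(self.feature_names),
            "n": int(self.n),
            "n_nodes": int(self.n_nodes),
            "master_seed": self.master_seed,
            "ranges": self.ranges.to_dict() if self.ranges else None,
            "solver_config": {
                "dt": self.solver_config.dt,
                "total_time": self.solver_config.total_time,
            } if self.solver_config else None,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "Corpus":
        import h5py

        path = Path(path)
        with h5py.File(path, "r") as fh:
            X = fh["X"][...]
            Y = fh["Y"][...]
            seeds = fh["seeds"][...]
            names = tuple(fh.attrs["feature_names"])
        ranges = None
        sidecar = path.with_suffix(path.suffix + ".json")
        master_seed = None
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if meta.get("ranges"):
                ranges = RangeSpec.from_dict(meta["ranges"])
            master_seed = meta.get("master_seed")
        return cls(X=X, Y=Y, seeds=seeds, feature_names=names, ranges=ranges,
                   master_seed=master_seed)

    def to_csv(self, path) -> None:
        """Flat CSV export (small corpora only): features then day columns."""
        import pandas as pd

        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        for d in range(self.Y.shape[1]):
            df[f"rsa_day_{d + 1}"] = self.Y[:, d]
        df.to_csv(path, index=False)


def _row_rng(master_seed: int, row: int, attempt: int = 0) -> np.random.Generator:
    """Counter-based per-row stream: reproducible independently of order."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(row, attempt)))


def generate_corpus(n: int, ranges: Optional[RangeSpec] = None,
                    solver_config: Optional[SolverConfig] = None,
                    master_seed: int = 0, n_nodes: int = 202,
                    max_failure_rate: float = 0.05,
                    progress: bool = False) -> Corpus:
    """Simulate ``n`` stability-admissible parameter draws.

    Row ``i`` is reproducible from ``(master_seed, i)`` alone.  Solver
    failures (non-convergence, mesh tangling) are logged and the row is
    re-drawn from its own stream; if more than ``max_failure_rate`` of all
    attempts fail the run aborts with diagnostics.
    """
    if n < 1:
        raise ConfigurationError("corpus size must be >= 1")
    ranges = ranges or default_ranges()
    solver_config = solver_config or SolverConfig()
    mesh = Mesh.uniform(n_nodes, ranges.fixed.get("domain_length", 10.0))
    n_days = int(round(solver_config.total_time))

    X = np.empty((n, len(ranges.feature_names)))
    Y = np.empty((n, n_days))
    seeds = np.empty(n, dtype=np.int64)
    failures: List[str] = []

    iterator = range(n)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="simulating corpus")

    for i in iterator:
        for attempt in range(20):
            rng = _row_rng(master_seed, i, attempt)
            params = sample_parameters(ranges, rng)
            try:
                result = simulate(params, mesh, solver_config)
            except SolverError as exc:
                failures.append(f"row {i} attempt {attempt}: {exc}")
                if len(failures) > max(10, max_failure_rate * n):
                    raise SolverError(
                        f"solver failure rate exceeded {max_failure_rate:.0%}: "
                        + "; ".join(failures[-5:]))
                continue
            X[i] = [getattr(params, k) for k in ranges.feature_names]
            Y[i] = result.rsa
            seeds[i] = i
            break
        else:
            raise SolverError(f"row {i}: no successful simulation in 20 attempts")

    return Corpus(X=X, Y=Y, seeds=seeds, feature_names=ranges.feature_names,
                  ranges=ranges, solver_config=solver_config, n_nodes=n_nodes,
                  master_seed=master_seed)


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature Min-Max parameters fitted on the training inputs only."""

    data_min: np.ndarray
    data_max: np.ndarray

    def __post_init__(self):
        if np.any(self.data_max <= self.data_min):
            raise ConfigurationError(
                "Min-Max scaling needs max > min for every feature")

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.data_min) / (self.data_max - self.data_min)

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, float) * (self.data_max - self.data_min) + self.data_min

    @classmethod
    def fit(cls, X_train: np.ndarray) -> "ScalerParams":
        scaler = MinMaxScaler().fit(X_train)
        return cls(data_min=scaler.data_min_.copy(),
                   data_max=scaler.data_max_.copy())


@dataclass
class SplitData:
    """80/20 train–test split with K-fold indices over the training portion.

    ``X_train``/``X_test`` are Min-Max scaled with parameters fitted on the
    training inputs only; targets are unscaled RSA courses.
    """

    X_train: np.ndarray
    Y_train: np.ndarray
    X_test: np.ndarray
    Y_test: np.ndarray
    folds: List[Tuple[np.ndarray, np.ndarray]]   # (fit_idx, val_idx) per fold
    scaler: ScalerParams
    train_indices: np.ndarray
    test_indices: np.ndarray


def split_and_scale(corpus: Corpus, train_fraction: float = 0.8,
                    n_folds: int = 10, seed: int = 0) -> SplitData:
    """Hold out the test set, fit the scaler on the training inputs only,
    and partition the training portion into K cross-validation folds."""
    n = corpus.n
    n_test = n - int(round(train_fraction * n))
    if n_test < 1 or n - n_test < n_folds:
        raise ConfigurationError(
            f"n={n} too small for train_fraction={train_fraction}, "
            f"n_folds={n_folds}")
    idx_train, idx_test = train_test_split(
        np.arange(n), test_size=n_test, random_state=seed, shuffle=True)

    scaler = ScalerParams.fit(corpus.X[idx_train])
    X_train = scaler.transform(corpus.X[idx_train])
    X_test = scaler.transform(corpus.X[idx_test])

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(fit, val) for fit, val in kf.split(X_train)]

    return SplitData(X_train=X_train, Y_train=corpus.Y[idx_train],
                     X_test=X_test, Y_test=corpus.Y[idx_test],
                     folds=folds, scaler=scaler,
                     train_indices=idx_train, test_indices=idx_test)
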