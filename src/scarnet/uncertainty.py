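"""Monte-Carlo uncertainty propagation through the trained surrogate.

A patient scenario assigns each of the 25 input parameters either a point
value or a uniform range (reflecting what is actually known about the
patient and wound).  Draws are filtered by the same stability condition
used for training, predicted in one batch through the surrogate, and
summarized as per-day quantile curves, the distributions of the minimum
and last RSA, and the probability that peak contraction (1 - min RSA)
exceeds a clinical threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .dataset import RangeSpec
from .errors import ConfigurationError, ScenarioError
from .model_core import VARIED_PARAMETERS
from .surrogate import SurrogateModel, predict

__all__ = ["PatientScenario", "MCSummary", "run_monte_carlo",
           "summarize_report"]

_DEFAULT_QUANTILES = (5.0, 25.0, 50.0, 75.0, 95.0)


@dataclass(frozen=True)
class PatientScenario:
    """Distribution spec for the 25 surrogate inputs.

    ``distributions`` maps each varied parameter name to either
    ``{"value": x}`` (point mass) or ``{"min": a, "max": b}`` (uniform).
    ``fixed`` holds the non-varied model parameters (needed for the
    stability filter); defaults come from the range spec used in training.
    """

    distributions: Dict[str, dict]
    fixed: Dict[str, float]
    draws: int = 5000
    seed: int = 0
    quantiles: Tuple[float, ...] = _DEFAULT_QUANTILES
    contraction_threshold: float = 0.4   # P(1 - min RSA > threshold)

    def __post_init__(self):
        if set(self.distributions) != set(VARIED_PARAMETERS):
            missing = set(VARIED_PARAMETERS) ^ set(self.distributions)
            raise ConfigurationError(
                f"scenario must specify all 25 varied parameters; "
                f"mismatch on {sorted(missing)}")
        if self.draws < 1:
            raise ConfigurationError("draws must be >= 1")
        q = tuple(float(x) for x in self.quantiles)
        if any(not 0 <= x <= 100 for x in q) or list(q) != sorted(q):
            raise ConfigurationError("quantiles must be sorted percentages")
        object.__setattr__(self, "quantiles", q)
        for name, spec in self.distributions.items():
            if "value" in spec:
                continue
            if not {"min", "max"} <= set(spec):
                raise ConfigurationError(
                    f"{name}: need 'value' or 'min'/'max'")
            if spec["min"] > spec["max"]:
                raise ConfigurationError(f"{name}: min > max")

    @classmethod
    def from_yaml(cls, path, ranges: Optional[RangeSpec] = None,
                  **overrides) -> "PatientScenario":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        dists = spec.get("distributions", {})
        fixed = spec.get("fixed", {})
        if ranges is not None:
            base = dict(ranges.fixed)
            base.update(fixed)
            fixed = base
            for name in VARIED_PARAMETERS:
                dists.setdefault(name, {"min": ranges.varied[name][0],
                                        "max": ranges.varied[name][1]})
        kwargs = {k: spec[k] for k in ("draws", "seed", "quantiles",
                                       "contraction_threshold") if k in spec}
        kwargs.update(overrides)
        return cls(distributions=dists, fixed=fixed, **kwargs)

    @classmethod
    def from_ranges(cls, ranges: RangeSpec, point: Optional[Dict[str, float]] = None,
                    **kwargs) -> "PatientScenario":
        """Scenario spanning the training ranges, with optional point pins."""
        point = point or {}
        dists = {}
        for name in VARIED_PARAMETERS:
            if name in point:
                dists[name] = {"value": float(point[name])}
            else:
                lo, hi = ranges.varied[name]
                dists[name] = {"min": lo, "max": hi}
        return cls(distributions=dists, fixed=dict(ranges.fixed), **kwargs)


@dataclass
class MCSummary:
    """Summaries of the induced RSA-course distribution."""

    quantile_levels: Tuple[float, ...]
    quantile_curves: np.ndarray          # (n_quantiles, 365), pointwise ordered
    min_rsa: np.ndarray                  # per-draw minimum RSA
    last_rsa: np.ndarray                 # per-draw last RSA
    exceedance_probability: float        # P(1 - min RSA > threshold)
    contraction_threshold: float
    n_draws: int
    n_rejected: int
    draw_predictions: Optional[np.ndarray] = None   # (n_draws, 365), capped
    draw_inputs: Optional[np.ndarray] = None

    def scalar_summaries(self) -> Dict[str, float]:
        return {
            "n_draws": int(self.n_draws),
            "n_rejected": int(self.n_rejected),
            "contraction_threshold": float(self.contraction_threshold),
            "exceedance_probability": float(self.exceedance_probability),
            "min_rsa_mean": float(self.min_rsa.mean()),
            "min_rsa_sd": float(self.min_rsa.std(ddof=1)) if self.n_draws > 1 else 0.0,
            "last_rsa_mean": float(self.last_rsa.mean()),
            "last_rsa_sd": float(self.last_rsa.std(ddof=1)) if self.n_draws > 1 else 0.0,
        }


def _sample_scenario(scenario: PatientScenario, rng: np.random.Generator,
                     size: int) -> np.ndarray:
    X = np.empty((size, len(VARIED_PARAMETERS)))
    for j, name in enumerate(VARIED_PARAMETERS):
        spec = scenario.distributions[name]
        if "value" in spec:
            X[:, j] = float(spec["value"])
        else:
            X[:, j] = rng.uniform(float(spec["min"]), float(spec["max"]), size)
    return X


def _stability_mask(X: np.ndarray, scenario: PatientScenario) -> np.ndarray:
    names = list(VARIED_PARAMETERS)

    def col(name):
        if name in names:
            return X[:, names.index(name)]
        return np.full(X.shape[0], float(scenario.fixed[name]))

    return col("k_c") < col("delta_c") * col("rho_bar") * col("a_c_II")


def run_monte_carlo(model: SurrogateModel, scenario: PatientScenario,
                    store_draws: bool = True,
                    max_stored_draws: int = 20000) -> MCSummary:
    """Sample the scenario, filter by stability, predict in batch, summarize.

    Reproducible given the scenario seed.  Raises
    :class:`~scarnet.errors.ScenarioError` when the scenario admits no
    stability-compliant draws.
    """
    rng = np.random.default_rng(scenario.seed)
    accepted = []
    n_rejected = 0
    # oversample in batches until enough admissible draws are collected
    for _ in range(1000):
        need = scenario.draws - sum(len(a) for a in accepted)
        if need <= 0:
            break
        batch = _sample_scenario(scenario, rng, max(need * 2, 64))
        mask = _stability_mask(batch, scenario)
        n_rejected += int((~mask).sum())
        batch = batch[mask][:need]
        if len(batch):
            accepted.append(batch)
        if n_rejected > 1000 and not accepted:
            break
    if not accepted:
        raise ScenarioError(
            "no draw satisfied the stability condition; the scenario's "
            "k_c/delta_c/a_c_II specification is inadmissible")
    X = np.vstack(accepted)
    if X.shape[0] < scenario.draws:
        raise ScenarioError(
            f"only {X.shape[0]} admissible draws out of the requested "
            f"{scenario.draws}")

    Y = predict(model, X)
    qc = np.percentile(Y, scenario.quantiles, axis=0)
    min_rsa = Y.min(axis=1)
    last_rsa = Y[:, -1]
    exceed = float(np.mean(1.0 - min_rsa > scenario.contraction_threshold))

    keep = min(X.shape[0], max_stored_draws) if store_draws else 0
    return MCSummary(
        quantile_levels=scenario.quantiles,
        quantile_curves=qc,
        min_rsa=min_rsa,
        last_rsa=last_rsa,
        exceedance_probability=exceed,
        contraction_threshold=scenario.contraction_threshold,
        n_draws=int(X.shape[0]),
        n_rejected=n_rejected,
        draw_predictions=Y[:keep] if keep else None,
        draw_inputs=X[:keep] if keep else None,
    )


def summarize_report(summary: MCSummary, out_dir, plot: bool = False) -> Dict[str, Path]:
    """Write the quantile curves (CSV), scalar summaries (JSON) and an
    optional fan-chart plot; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    n_days = summary.quantile_curves.shape[1]
    df = pd.DataFrame(
        {f"q{lvl:g}": summary.quantile_curves[i]
         for i, lvl in enumerate(summary.quantile_levels)},
        index=pd.RangeIndex(1, n_days + 1, name="day"))
    paths["quantiles_csv"] = out_dir / "rsa_quantiles.csv"
    df.to_csv(paths["quantiles_csv"])

    paths["summary_json"] = out_dir / "mc_summary.json"
    paths["summary_json"].write_text(
        json.dumps(summary.scalar_summaries(), indent=2))

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        days = np.arange(1, n_days + 1)
        nq = len(summary.quantile_levels)
        for i in range(nq // 2):
            ax.fill_between(days, summary.quantile_curves[i],
                            summary.quantile_curves[nq - 1 - i],
                            alpha=0.25, color="C0", lw=0)
        ax.plot(days, summary.quantile_curves[nq // 2], color="C0",
                label="median RSA")
        ax.set_xlabel("day")
        ax.set_ylabel("relative surface area")
        ax.set_ylim(0, 1.05)
        ax.legend()
        fig.tight_layout()
        paths["plot"] = out_dir / "rsa_fan.png"
        fig.savefig(paths["plot"], dpi=120)
        plt.close(fig)

    return paths
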