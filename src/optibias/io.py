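"""Configuration loading, result serialisation and seeded test fixtures."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bandit import BanditConfig, run_bandit
from .belief_updating import run_belief_trial
from .development import DevelopmentConfig, run_development
from .model import DirichletCounts, GenerativeModel, Modality, StateFactor, one_hot

__all__ = ["load_config", "write_results", "make_fixture", "config_hash"]

CONFIG_CLASSES = {"exp1": DevelopmentConfig, "exp3": BanditConfig}


@dataclasses.dataclass(frozen=True)
class BeliefUpdatingConfig:
    """Experiment-2 run settings (levels swept at run time)."""

    n_runs: int = 70
    n_trials: int = 70
    a_good: float | None = None
    a_bad: float | None = None
    sweep: bool = True
    p_good_news: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.n_runs < 1 or self.n_trials < 1:
            raise ValueError("n_runs and n_trials must be >= 1")
        for name in ("a_good", "a_bad"):
            v = getattr(self, name)
            if v is not None and not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly inside (0, 1)")


CONFIG_CLASSES["exp2"] = BeliefUpdatingConfig


def load_config(path, experiment: str):
    """Parse and validate a YAML/JSON experiment configuration.

    Missing keys take the experiment's defaults; unknown keys are rejected
    with an error listing them.  The returned object always carries an
    explicit seed (0 if the file gives none).
    """
    cls = CONFIG_CLASSES.get(experiment)
    if cls is None:
        raise ValueError(f"unknown experiment {experiment!r}; expected one of {sorted(CONFIG_CLASSES)}")
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown configuration keys for {experiment}: {unknown}")
    if "preference_weights" in data:
        data["preference_weights"] = tuple(data["preference_weights"])
    cfg = cls(**data)
    if cfg.seed is None:
        cfg = dataclasses.replace(cfg, seed=0)
    return cfg


def config_hash(config) -> str:
    """Short stable hash of a configuration for output provenance."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(table: pd.DataFrame, path, format: str = "csv", seed=None, config=None) -> Path:
    """Write a result table deterministically with a provenance header.

    Columns keep their construction order; floats are fixed at 10
    significant digits, so identical results yield byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": seed,
        "version": __version__,
        "config_hash": config_hash(config) if config is not None else None,
    }
    if format == "csv":
        header = "".join(f"# {k}={v}\n" for k, v in meta.items() if v is not None)
        body = table.to_csv(index=False, float_format="%.10g", lineterminator="\n")
        path.write_text(header + body)
    elif format == "json":
        payload = {"metadata": {k: v for k, v in meta.items() if v is not None},
                   "rows": json.loads(table.to_json(orient="records", double_precision=10))}
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _tiny_model(seed: int):
    """2-state model whose exact Bayes posterior is bundled alongside."""
    rng = np.random.default_rng(seed)
    A = np.array([[0.8, 0.3], [0.2, 0.7]])
    prior = rng.dirichlet(np.ones(2))
    model = GenerativeModel(
        factors=[StateFactor("state", DirichletCounts(prior, learnable=False), np.eye(2)[:, :, None])],
        modalities=[Modality("outcome", DirichletCounts(A, learnable=False))],
        policies=np.zeros((1, 0, 1), int),
        horizon=1,
    )
    obs = one_hot(0, 2)
    bayes = prior * (A.T @ obs)
    return {"model": model, "observation": obs, "bayes_posterior": bayes / bayes.sum()}


def make_fixture(name: str, seed: int = 0):
    """Small, seeded model/data bundles used by the test-suite and docs."""
    if name == "tiny-model":
        return _tiny_model(seed)
    if name == "exp1-mini":
        cfg = DevelopmentConfig(
            n_agents=2, obs_level_trials=10, state_level_trials=2, p_negative=1.0, seed=seed
        )
        result = run_development(cfg)
        return {"config": cfg, "result": result, "expect_optimism_below_initial": True}
    if name == "exp2-mini":
        trial = run_belief_trial(np.array([0.6, 0.4]), 0.9, "good", (0.75, 0.95))
        return {"trial": trial, "precisions": (0.75, 0.95)}
    if name == "exp3-mini":
        cfg = BanditConfig(optimism_level=0.7, n_trials=5, seed=seed)
        traj = run_bandit(cfg)
        return {"config": cfg, "trajectory": traj}
    raise ValueError(f"unknown fixture {name!r}")
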