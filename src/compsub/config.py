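"""Run configuration: a flat key-value file (TOML syntax) plus flag overrides."""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass

from .model import ModelParameters

__all__ = ["RunConfig", "parse_config", "CONFIG_KEYS"]

REQUIRED_KEYS = ("two_N", "theta", "Ns", "two_N_rho", "seed")
DEFAULTS = {
    "replicates": 1000,
    "max_generations": 50_000_000,
    "n_nodes": 64,
    "qmatrix_mode": "arrow_rates",
}
CONFIG_KEYS = REQUIRED_KEYS + tuple(DEFAULTS)


@dataclass(frozen=True)
class RunConfig:
    two_N: int
    theta: float
    Ns: float
    two_N_rho: float
    seed: int
    replicates: int = DEFAULTS["replicates"]
    max_generations: int = DEFAULTS["max_generations"]
    n_nodes: int = DEFAULTS["n_nodes"]
    qmatrix_mode: str = DEFAULTS["qmatrix_mode"]

    def parameters(self) -> ModelParameters:
        return ModelParameters.from_scaled(self.two_N, self.theta, self.Ns, self.two_N_rho)

    def to_dict(self) -> dict:
        return asdict(self)


def parse_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a validated RunConfig from a file and/or flag overrides.

    Flag overrides take precedence over file values; unknown keys are
    rejected; the resulting scaled parameters are validated (in particular
    Ns/N >= 1, i.e. s >= 1, is refused).
    """
    values: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            values.update(tomllib.load(fh))
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(values) - set(CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    missing = [k for k in REQUIRED_KEYS if k not in values]
    if missing:
        raise ValueError(f"missing required configuration keys: {missing}")

    merged = {**DEFAULTS, **values}
    try:
        cfg = RunConfig(
            two_N=int(merged["two_N"]),
            theta=float(merged["theta"]),
            Ns=float(merged["Ns"]),
            two_N_rho=float(merged["two_N_rho"]),
            seed=int(merged["seed"]),
            replicates=int(merged["replicates"]),
            max_generations=int(merged["max_generations"]),
            n_nodes=int(merged["n_nodes"]),
            qmatrix_mode=str(merged["qmatrix_mode"]),
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration value: {exc}") from exc
    cfg.parameters()  # validates the scaled-parameter constraints
    if cfg.replicates < 1:
        raise ValueError("replicates must be >= 1")
    if cfg.max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    return cfg
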