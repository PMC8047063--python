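"""Run configuration: every tunable knob of the pipeline in one dataclass.

Defaults follow the conventions of the neighborhood-regularized logistic
matrix factorization family: importance level ``c = 2``, feature dimensions
``k1 = 12`` (drugs) and ``k2 = 45`` (metabolites), restart probability 0.5
for the random-walk diffusion, and a Vicus neighborhood of 10 with diffusion
constant 0.9.  ``lam`` (the L2 weight, serialized as ``lambda``) and ``phi``
(the graph-regularization weight) are the natural targets for grid search;
their defaults come from a grid search on the synthetic emulation preset
(see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    r: int = 8                  # latent dimension of the factorization
    c: float = 2.0              # importance level on observed pairs (>= 1)
    lam: float = 1.0            # L2 weight on the projections U, V
    phi: float = 4.0            # Vicus graph-regularization weight
    k1: int = 12                # fused feature dimension, row entities (drugs)
    k2: int = 45                # fused feature dimension, column entities (metabolites)
    vicus_k: int = 10           # Vicus neighborhood size
    vicus_alpha: float = 0.9    # Vicus label-diffusion constant, in (0, 1)
    smooth_K: int = 5           # neighbor count for latent-vector smoothing
    smooth_decay: float = 0.5   # geometric decay of neighbor weights, in [0, 1]
    rwr_restart: float = 0.5    # random-walk restart probability, in (0, 1)
    gamma_prime: float = 1.0    # input bandwidth of the Gaussian profile kernel
    learn_rate: float = 0.1     # AdaGrad base learning rate
    max_iter: int = 100         # optimizer iteration budget
    seed: int = 0               # RNG seed for U, V initialization

    # keys accepted on disk but renamed in the dataclass
    _ALIASES = {"lambda": "lam"}

    def validate(self) -> "RunConfig":
        if self.r < 1:
            raise ConfigError("r must be >= 1")
        if self.c < 1:
            raise ConfigError("c must be >= 1")
        if self.lam < 0 or self.phi < 0:
            raise ConfigError("lambda and phi must be >= 0")
        if not 0 < self.vicus_alpha < 1:
            raise ConfigError("vicus_alpha must lie in (0, 1)")
        if not 0 <= self.smooth_decay <= 1:
            raise ConfigError("smooth_decay must lie in [0, 1]")
        if not 0 < self.rwr_restart < 1:
            raise ConfigError("rwr_restart must lie in (0, 1)")
        if self.k1 < 1 or self.k2 < 1 or self.vicus_k < 1 or self.smooth_K < 1:
            raise ConfigError("k1, k2, vicus_k, smooth_K must be >= 1")
        if self.gamma_prime <= 0:
            raise ConfigError("gamma_prime must be > 0")
        if self.learn_rate <= 0 or self.max_iter < 1:
            raise ConfigError("learn_rate must be > 0 and max_iter >= 1")
        return self

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            name = cls._ALIASES.get(key, key)
            if name not in fields:
                raise ConfigError(f"unknown config field: {key!r}")
            kwargs[name] = value
        return cls(**kwargs).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON; missing fields keep their defaults."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["lambda"] = out.pop("lam")
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def replace(self, **changes: Any) -> "RunConfig":
        changes = {self._ALIASES.get(k, k): v for k, v in changes.items()}
        return dataclasses.replace(self, **changes).validate()
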