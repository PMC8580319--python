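"""Pipeline configuration: validated key-value config with a stable hash."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from acsarch.classify import config_hash

#: Known configuration keys and their domains (None = unconstrained).
KNOWN_KEYS = {
    "motif_source": ("file", "discover"),
    "p_threshold": None,
    "pseudocount": None,
    "gap_open": None,
    "gap_extend": None,
    "matrix": None,
    "q_position": None,
    "n_position": None,
    "strict_n217": (True, False),
    "distance_model": ("p", "poisson"),
    "bootstrap": None,
    "seed": None,
    "min_width": None,
    "max_width": None,
    "max_motifs": None,
    "n_restarts": None,
    "conservation": None,
    "n_positive": None,
    "spacer_mean": None,
    "output_dir": None,
}

DEFAULTS = {
    "motif_source": "file",
    "p_threshold": 1e-4,
    "pseudocount": 0.375,
    "gap_open": 11.0,
    "gap_extend": 1.0,
    "matrix": "BLOSUM62",
    "q_position": 98,
    "n_position": 217,
    "strict_n217": True,
    "distance_model": "poisson",
    "bootstrap": 1000,
}

#: Stages that must be given an explicit seed (no silent default).
STOCHASTIC_STAGES = ("discover", "simulate", "phylo")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    values: dict = field(default_factory=dict)

    _NUMERIC = ("p_threshold", "pseudocount", "gap_open", "gap_extend",
                "conservation", "spacer_mean")

    def __post_init__(self) -> None:
        # YAML reads scientific notation without a dot ("1e-4") as a string
        coerced = dict(self.values)
        for key in self._NUMERIC:
            if key in coerced and isinstance(coerced[key], str):
                coerced[key] = float(coerced[key])
        object.__setattr__(self, "values", coerced)
        unknown = sorted(set(self.values) - set(KNOWN_KEYS))
        if unknown:
            raise ConfigError(f"invalid config keys: {unknown}; "
                              f"known keys: {sorted(KNOWN_KEYS)}")
        for key, val in self.values.items():
            domain = KNOWN_KEYS[key]
            if domain is not None and val not in domain:
                raise ConfigError(
                    f"config key {key}={val!r} outside domain {domain}")
        p = self.get("p_threshold")
        if p is not None and not (0 < p <= 1):
            raise ConfigError(f"p_threshold {p} outside (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path} must contain a key-value mapping")
        return cls(data)

    def get(self, key: str, *fallback):
        if key in self.values:
            return self.values[key]
        if key in DEFAULTS:
            return DEFAULTS[key]
        return fallback[0] if fallback else None

    def require_seed(self, stage: str) -> int:
        seed = self.values.get("seed")
        if seed is None:
            raise ConfigError(
                f"stage {stage!r} is stochastic: an explicit seed is "
                "required in the config or via --seed")
        return int(seed)

    @property
    def hash(self) -> str:
        merged = {**DEFAULTS, **self.values}
        return config_hash(merged)
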