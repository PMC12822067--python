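"""Pipeline configuration: YAML schema, validation, seed fan-out."""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .model import MDRConfig
from .simulate import CommunityParams

__all__ = ["PipelineConfig", "stage_seed"]

_STAGES = {"synthetic": 0, "observe": 1, "infer": 2, "context": 3}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one (documented derivation:
    ``default_rng([global_seed, stage_index])`` drawn once)."""
    rng = np.random.default_rng([int(global_seed), _STAGES[stage]])
    return int(rng.integers(0, 2**31 - 1))


@dataclass
class SyntheticBlock:
    """Synthetic-data source: community parameters plus the observation step."""

    n_taxa: int = 12
    n_steps: int = 300
    burn_in: int = 100
    connectance: float = 0.10
    strength_low: float = 0.05
    strength_high: float = 0.25
    frac_positive: float = 0.5
    self_limit: float = 0.4
    r0: float = 0.8
    r_temp_sens: float = 0.01
    sigma_proc: float = 0.05
    sigma_obs: float = 0.0
    temp_mean: float = 18.0
    temp_amplitude: float = 4.0
    temp_noise_sd: float = 0.3
    sample_interval: int = 1
    missing_fraction: float = 0.0
    relative: bool = True

    def community_params(self, seed: int) -> CommunityParams:
        from .simulate import random_interaction_matrix

        rng = np.random.default_rng([seed, 0])
        A = random_interaction_matrix(
            self.n_taxa,
            connectance=self.connectance,
            strength_low=self.strength_low,
            strength_high=self.strength_high,
            frac_positive=self.frac_positive,
            self_limit=self.self_limit,
            rng=rng,
        )
        return CommunityParams(
            n_taxa=self.n_taxa,
            r0=self.r0,
            r_temp_sens=self.r_temp_sens,
            A=A,
            sigma_proc=self.sigma_proc,
            sigma_obs=self.sigma_obs,
            temp_mean=self.temp_mean,
            temp_amplitude=self.temp_amplitude,
            temp_noise_sd=self.temp_noise_sd,
            seed=seed,
        )


@dataclass
class PreprocessingBlock:
    detection: float = 0.001
    occupancy: float = 0.5
    detection_mode: str = "present_mean"
    bin_candidates: tuple = (4,)
    aggregator: str = "mean"


@dataclass
class MetricsBlock:
    strength_threshold: float | None = None
    occurrence_threshold: float | None = None
    keystone_fraction: float = 0.10
    orientation: str = "source"


@dataclass
class ContextBlock:
    alpha: float = 0.05
    stress_cutoff: float = 0.2
    run_ordination: bool = False


@dataclass
class PipelineConfig:
    """Full pipeline configuration (exactly one data source).

    Either ``abundance_path``/``temperature_path`` point at input files or a
    ``synthetic`` block describes the simulated study; never both.
    """

    abundance_path: str | None = None
    temperature_path: str | None = None
    synthetic: SyntheticBlock | None = None
    preprocessing: PreprocessingBlock = field(default_factory=PreprocessingBlock)
    mdr: MDRConfig = field(default_factory=MDRConfig)
    metrics: MetricsBlock = field(default_factory=MetricsBlock)
    context: ContextBlock = field(default_factory=ContextBlock)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        has_paths = self.abundance_path is not None or self.temperature_path is not None
        has_synth = self.synthetic is not None
        if has_paths and has_synth:
            raise ValueError("config must specify input paths OR a synthetic block, not both")
        if not has_paths and not has_synth:
            raise ValueError("config must specify input paths or a synthetic block")
        if has_paths and (self.abundance_path is None or self.temperature_path is None):
            raise ValueError("both abundance_path and temperature_path are required")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticBlock(**d["synthetic"])
        for key, klass in (
            ("preprocessing", PreprocessingBlock),
            ("metrics", MetricsBlock),
            ("context", ContextBlock),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        if "mdr" in d and isinstance(d["mdr"], dict):
            mdr = dict(d["mdr"])
            for g in ("theta_grid", "lambda_grid"):
                if g in mdr:
                    mdr[g] = tuple(mdr[g])
            d["mdr"] = MDRConfig(**mdr)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_canonical_yaml(self) -> str:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        return yaml.safe_dump(listify(asdict(self)), sort_keys=True, default_flow_style=False)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_yaml().encode()).hexdigest()
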